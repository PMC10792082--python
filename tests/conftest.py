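import pandas as pd
import pytest

from oralgut import AbundanceTable, MarkerTable, SimConfig, generate_cohort

META_COLS = ["sample_id", "subject_id", "body_site", "study_id", "visit"]


def make_table(meta_rows, abundance_rows) -> AbundanceTable:
    """Build a validated AbundanceTable from row tuples.

    meta_rows: (sample_id, subject_id, body_site[, study_id, visit])
    abundance_rows: (sample_id, species, relative_abundance)
    """
    meta_rows = [
        tuple(r) + ("study1", 1)[len(r) - 3 :] if len(r) < 5 else tuple(r)
        for r in meta_rows
    ]
    meta = pd.DataFrame(meta_rows, columns=META_COLS).set_index("sample_id")
    data = pd.DataFrame(
        abundance_rows, columns=["sample_id", "species", "relative_abundance"]
    )
    return AbundanceTable(data=data, meta=meta)


def make_markers(marker_map: dict, entries) -> MarkerTable:
    """marker_map: marker_id -> species; entries: (sample_id, marker_id, value)."""
    mmap = pd.Series(marker_map, name="species")
    mmap.index.name = "marker_id"
    df = pd.DataFrame(entries, columns=["sample_id", "marker_id", "value"])
    return MarkerTable(entries=df, marker_map=mmap)


# reduced pools keep cohort generation fast while preserving every
# structural feature (niche pools, planted sharing, marker repertoires)
SMALL_SIM_KWARGS = dict(
    n_subjects=20,
    n_oral_species=10,
    n_gut_species=12,
    n_generalist_species=2,
    n_markers_per_species=40,
    n_shared_subjects=3,
    marker_dropout_prob=0.0,
    seed=11,
)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(SimConfig(**SMALL_SIM_KWARGS))
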