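"""Seeded synthetic paired stool/oral cohorts with planted strain sharing.

The generator emulates the statistical structure the downstream analysis
assumes: each subject contributes one stool sample plus one sample per oral
site; species come from niche-adapted pools (oral, gut, generalist) with
Bernoulli occupancy by niche and sparse log-normal relative-abundance
magnitudes renormalized to sum to 100 per sample; strains of a species are
defined by which subset of its clade-specific marker genes they carry,
derived from an all-present reference repertoire by independent per-marker
gene loss.  A configurable number of subjects is planted with an identical
stool/oral repertoire for one species at one oral site — the ground truth the
strain caller is asked to recover.

Marker detection can optionally fail per marker (sequencing-depth dropout);
absent markers are never falsely detected, because clade-specific markers
are by construction unique to their species.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    ORAL_SITES,
    STOOL,
    AbundanceTable,
    MarkerTable,
    write_abundance_table,
    write_marker_table,
)

logger = logging.getLogger(__name__)

#: the five frequently overlapping oral species used for marker comparison
DEFAULT_SHARED_SPECIES = (
    "Streptococcus_parasanguinis",
    "Haemophilus_parainfluenzae",
    "Streptococcus_salivarius",
    "Streptococcus_mitis",
    "Veillonella_parvula",
)

_GUT_FLAVOR = ("Phocaeicola_vulgatus", "Bacteroides_uniformis")

#: minimum fraction of a species' markers a noise-free strain must retain,
#: so that every true repertoire passes the downstream coverage filter
REPERTOIRE_FLOOR = 0.9

_MAX_DRAW_ATTEMPTS = 1000


class GenerationError(RuntimeError):
    """The simulator could not satisfy a structural constraint."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate the scale of the real multi-cohort dataset: 125 subjects
    with all four oral sites give 500 stool/oral pairs, and 7 subjects are
    planted with a shared strain, mirroring the headline count of individuals
    whose marker patterns were consistent with same-strain colonization.
    """

    n_subjects: int = 125
    oral_sites: tuple[str, ...] = ORAL_SITES
    n_oral_species: int = 40
    n_gut_species: int = 60
    n_generalist_species: int = 10
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 2.0
    occupancy_oral_in_oral: float = 0.9
    occupancy_gut_in_gut: float = 0.95
    occupancy_oral_in_gut: float = 0.3
    n_markers_per_species: int = 100
    gene_loss_prob: float = 0.02
    marker_dropout_prob: float = 0.0
    n_shared_subjects: int = 7
    shared_species: tuple[str, ...] = DEFAULT_SHARED_SPECIES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_shared_subjects > self.n_subjects:
            raise ValueError(
                f"n_shared_subjects ({self.n_shared_subjects}) exceeds "
                f"n_subjects ({self.n_subjects})"
            )
        if self.n_shared_subjects < 0:
            raise ValueError("n_shared_subjects must be >= 0")
        unknown = set(self.oral_sites) - set(ORAL_SITES)
        if unknown:
            raise ValueError(f"unknown oral site(s): {sorted(unknown)}")
        if not self.oral_sites:
            raise ValueError("at least one oral site is required")
        for name in (
            "occupancy_oral_in_oral",
            "occupancy_gut_in_gut",
            "occupancy_oral_in_gut",
            "marker_dropout_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.gene_loss_prob <= 0.1:
            raise ValueError("gene_loss_prob must be in [0, 0.1]")
        if self.n_markers_per_species < 10:
            raise ValueError("n_markers_per_species must be >= 10")
        if self.n_shared_subjects > 0 and not self.shared_species:
            raise ValueError("shared_species must be non-empty when planting sharing")

    @property
    def oral_pool(self) -> list[str]:
        pool = list(self.shared_species)
        i = 1
        while len(pool) < self.n_oral_species:
            name = f"Oral_species_{i:03d}"
            if name not in pool:
                pool.append(name)
            i += 1
        return pool

    @property
    def gut_pool(self) -> list[str]:
        pool = list(_GUT_FLAVOR[: self.n_gut_species])
        i = 1
        while len(pool) < self.n_gut_species:
            pool.append(f"Gut_species_{i:03d}")
            i += 1
        return pool

    @property
    def generalist_pool(self) -> list[str]:
        return [f"Generalist_species_{i:03d}" for i in range(1, self.n_generalist_species + 1)]


@dataclass(frozen=True)
class StrainRepertoire:
    """One strain of one species: which of its marker genes it carries."""

    species_name: str
    marker_presence: tuple[int, ...]

    @property
    def n_present(self) -> int:
        return int(sum(self.marker_presence))

    @property
    def fraction_present(self) -> float:
        return self.n_present / len(self.marker_presence)


@dataclass
class GroundTruth:
    """Planted strain-sharing labels for a synthetic cohort."""

    shared: set[tuple[str, str, str]] = field(default_factory=set)
    strain_assignment: dict[tuple[str, str], StrainRepertoire] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.shared)
        return pd.DataFrame(rows, columns=["subject_id", "species", "oral_site"])


@dataclass
class SyntheticCohort:
    abundance: AbundanceTable
    markers: MarkerTable
    truth: GroundTruth
    config: SimConfig

    def write(self, out_dir) -> dict[str, str]:
        """Write the interchange TSVs plus the ground-truth table."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "metadata": out / "metadata.tsv",
            "abundance": out / "abundance.tsv",
            "markers": out / "markers.tsv",
            "marker_map": out / "marker_map.tsv",
            "truth": out / "truth.tsv",
        }
        write_abundance_table(self.abundance, paths["abundance"], paths["metadata"])
        write_marker_table(self.markers, paths["markers"], paths["marker_map"])
        self.truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
        return {k: str(v) for k, v in paths.items()}


def draw_strain_repertoires(
    species_name: str,
    n_strains: int,
    gene_loss_prob: float,
    n_markers: int,
    rng: np.random.Generator,
) -> list[StrainRepertoire]:
    """Draw ``n_strains`` pairwise-distinct marker repertoires for a species.

    Each repertoire starts from the all-present reference and loses markers
    independently with ``gene_loss_prob``; draws violating the coverage floor
    (>= 90% present) or colliding with an already accepted repertoire are
    rejected and retried, up to a global attempt cap.
    """
    if n_strains < 0:
        raise ValueError("n_strains must be >= 0")
    floor = math.ceil(REPERTOIRE_FLOOR * n_markers)
    accepted: list[tuple[int, ...]] = []
    attempts = 0
    while len(accepted) < n_strains:
        if attempts >= _MAX_DRAW_ATTEMPTS:
            raise GenerationError(
                f"could not draw {n_strains} distinct repertoires for "
                f"{species_name} (gene_loss_prob={gene_loss_prob}) in "
                f"{_MAX_DRAW_ATTEMPTS} attempts"
            )
        attempts += 1
        presence = (rng.random(n_markers) >= gene_loss_prob).astype(int)
        if int(presence.sum()) < floor:
            continue
        vec = tuple(int(x) for x in presence)
        if vec in accepted:
            continue
        accepted.append(vec)
    return [StrainRepertoire(species_name, vec) for vec in accepted]


def simulate_marker_detection(
    repertoire: StrainRepertoire,
    marker_dropout_prob: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Observe a repertoire through depth-dependent per-marker dropout.

    Present markers are each detected with probability 1 - dropout; absent
    markers are never detected (markers are clade-specific, so there are no
    false detections).
    """
    truth = np.asarray(repertoire.marker_presence, dtype=int)
    keep = rng.random(truth.size) >= marker_dropout_prob
    return (truth * keep).astype(int)


def _draw_presence(
    rng: np.random.Generator, n_samples: int, probs: np.ndarray
) -> np.ndarray:
    """Bernoulli presence matrix (samples x species); empty rows are redrawn."""
    pres = rng.random((n_samples, probs.size)) < probs
    for _ in range(_MAX_DRAW_ATTEMPTS):
        empty = ~pres.any(axis=1)
        if not empty.any():
            return pres
        pres[empty] = rng.random((int(empty.sum()), probs.size)) < probs
    raise GenerationError(
        "could not draw a non-empty species set for some samples; "
        "occupancy probabilities are too small"
    )


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate one seeded cohort: abundances, markers, and ground truth."""
    rng = np.random.default_rng(config.seed)
    subjects = [f"subj_{i:04d}" for i in range(1, config.n_subjects + 1)]
    sites = (STOOL,) + tuple(config.oral_sites)

    oral_pool = config.oral_pool
    gut_pool = config.gut_pool
    gen_pool = config.generalist_pool
    species = np.array(oral_pool + gut_pool + gen_pool)
    n_oral, n_gut, n_gen = len(oral_pool), len(gut_pool), len(gen_pool)

    # occupancy probabilities per niche, in pool order (oral, gut, generalist)
    p_stool = np.concatenate([
        np.full(n_oral, config.occupancy_oral_in_gut),
        np.full(n_gut, config.occupancy_gut_in_gut),
        np.full(n_gen, config.occupancy_gut_in_gut),
    ])
    p_oral = np.concatenate([
        np.full(n_oral, config.occupancy_oral_in_oral),
        np.zeros(n_gut),
        np.full(n_gen, config.occupancy_oral_in_oral),
    ])

    sample_ids: dict[tuple[str, str], str] = {}
    site_presence: dict[str, np.ndarray] = {}  # site -> (n_subjects x n_species) bool
    for site in sites:
        probs = p_stool if site == STOOL else p_oral
        site_presence[site] = _draw_presence(rng, config.n_subjects, probs)
        for subj in subjects:
            sample_ids[(subj, site)] = f"{subj}_{site}"

    # plant shared-strain subjects: one species at one oral site each,
    # forced present in both members of the pair
    truth = GroundTruth()
    planted: dict[tuple[str, str], str] = {}  # (subject, species) -> oral site
    if config.n_shared_subjects > 0:
        chosen = rng.choice(config.n_subjects, size=config.n_shared_subjects, replace=False)
        shared_idx = {s: oral_pool.index(s) for s in config.shared_species}
        for subj_i in sorted(int(i) for i in chosen):
            subj = subjects[subj_i]
            sp = str(rng.choice(list(config.shared_species)))
            site = str(rng.choice(list(config.oral_sites)))
            col = shared_idx[sp]
            site_presence[STOOL][subj_i, col] = True
            site_presence[site][subj_i, col] = True
            truth.shared.add((subj, sp, site))
            planted[(subj, sp)] = site

    # abundance magnitudes: sparse log-normal, renormalized to 100 per sample
    frames = []
    subj_arr = np.array(subjects)
    for site in sites:
        pres = site_presence[site]
        mags = rng.lognormal(config.lognormal_mu, config.lognormal_sigma, size=pres.shape)
        mags = np.where(pres, mags, 0.0)
        mags = mags / mags.sum(axis=1, keepdims=True) * 100.0
        rows, cols = np.nonzero(pres)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": np.char.add(subj_arr[rows], f"_{site}"),
                    "species": species[cols],
                    "relative_abundance": mags[rows, cols],
                }
            )
        )
    abundance_data = pd.concat(frames, ignore_index=True)

    meta = pd.DataFrame(
        {
            "sample_id": [sample_ids[(subj, site)] for site in sites for subj in subjects],
            "subject_id": [subj for _site in sites for subj in subjects],
            "body_site": [site for site in sites for _subj in subjects],
            "study_id": "synthetic",
            "visit": 1,
        }
    ).set_index("sample_id")
    abundance = AbundanceTable(data=abundance_data, meta=meta)

    # strain repertoires for every shared species carried by a sample
    marker_ids = {
        sp: [f"{sp}__m{j:04d}" for j in range(1, config.n_markers_per_species + 1)]
        for sp in config.shared_species
    }
    shared_cols = {sp: oral_pool.index(sp) for sp in config.shared_species}
    marker_records: list[tuple[str, str, float]] = []
    for subj_i, subj in enumerate(subjects):
        for sp in config.shared_species:
            col = shared_cols[sp]
            carriers = [
                site for site in sites if site_presence[site][subj_i, col]
            ]
            if not carriers:
                continue
            planted_site = planted.get((subj, sp))
            pair_planted = (
                planted_site is not None
                and STOOL in carriers
                and planted_site in carriers
            )
            n_distinct = len(carriers) - (1 if pair_planted else 0)
            reps = draw_strain_repertoires(
                sp, n_distinct, config.gene_loss_prob,
                config.n_markers_per_species, rng,
            )
            assignment: dict[str, StrainRepertoire] = {}
            if pair_planted:
                assignment[STOOL] = reps[0]
                assignment[planted_site] = reps[0]
                rest = [s for s in carriers if s not in (STOOL, planted_site)]
                for site, rep in zip(rest, reps[1:]):
                    assignment[site] = rep
            else:
                for site, rep in zip(carriers, reps):
                    assignment[site] = rep
            for site, rep in assignment.items():
                sid = sample_ids[(subj, site)]
                truth.strain_assignment[(sid, sp)] = rep
                observed = simulate_marker_detection(
                    rep, config.marker_dropout_prob, rng
                )
                for j in np.flatnonzero(observed):
                    value = float(rng.lognormal(2.0, 0.5))
                    marker_records.append((sid, marker_ids[sp][j], value))

    marker_map = pd.Series(
        {m: sp for sp in config.shared_species for m in marker_ids[sp]},
        name="species",
        dtype=object,
    )
    marker_map.index.name = "marker_id"
    import warnings as _warnings

    with _warnings.catch_warnings():
        if not config.shared_species:  # an empty marker table is intended here
            _warnings.simplefilter("ignore", UserWarning)
        markers = MarkerTable(
            entries=pd.DataFrame(marker_records, columns=["sample_id", "marker_id", "value"]),
            marker_map=marker_map,
        )

    logger.info(
        "generated cohort: %d subjects, %d samples, %d species, "
        "%d planted shared subjects",
        config.n_subjects, len(meta), species.size, config.n_shared_subjects,
    )
    return SyntheticCohort(abundance=abundance, markers=markers, truth=truth, config=config)
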