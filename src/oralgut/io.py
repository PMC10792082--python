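"""Tabular data model for paired oral/stool metagenomic profiles.

The interchange representation is long-format TSV:

* metadata:   ``sample_id  subject_id  body_site  study_id  visit``
* abundance:  ``sample_id  species  relative_abundance``  (percent)
* markers:    ``sample_id  marker_id  value``  (nonnegative, e.g. RPK)
* marker map: ``marker_id  species``

Absent (sample, species) combinations are exact zeros, matching MetaPhlAn
output semantics.  Relative abundances are percentages of the classified
fraction, so per-sample sums are at most 100 (plus a small numerical
tolerance); an unclassified fraction may leave them below 100.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STOOL = "stool"
ORAL_SITES = ("saliva", "buccal_mucosa", "supragingival_plaque", "tongue_dorsum")
BODY_SITES = (STOOL,) + ORAL_SITES

#: numerical tolerance on the per-sample abundance sum ceiling of 100
SUM_TOLERANCE = 1e-6

METADATA_COLUMNS = ["sample_id", "subject_id", "body_site", "study_id", "visit"]
ABUNDANCE_COLUMNS = ["sample_id", "species", "relative_abundance"]
MARKER_COLUMNS = ["sample_id", "marker_id", "value"]
MARKER_MAP_COLUMNS = ["marker_id", "species"]


class ValidationError(ValueError):
    """A table violates one of the data-model invariants."""


class TableParseError(ValueError):
    """A TSV file is structurally malformed (bad header, unparseable row)."""


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    subject_id: str
    body_site: str
    study_id: str
    visit: int

    def __post_init__(self) -> None:
        if self.body_site not in BODY_SITES:
            raise ValidationError(
                f"unknown body_site {self.body_site!r} for sample "
                f"{self.sample_id!r}; expected one of {BODY_SITES}"
            )
        if self.visit < 1:
            raise ValidationError(
                f"visit must be >= 1, got {self.visit} for sample {self.sample_id!r}"
            )


@dataclass(frozen=True)
class SamplePair:
    """A within-subject stool/oral sample pair for one oral site."""

    subject_id: str
    stool_sample_id: str
    oral_sample_id: str
    oral_site: str


@dataclass
class SamplePairSet:
    oral_site: str
    pairs: list[SamplePair]

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def stool_sample_ids(self) -> list[str]:
        return [p.stool_sample_id for p in self.pairs]

    @property
    def oral_sample_ids(self) -> list[str]:
        return [p.oral_sample_id for p in self.pairs]

    @property
    def all_sample_ids(self) -> list[str]:
        """Union of both members of every pair, deduplicated, order-stable."""
        seen: dict[str, None] = {}
        for p in self.pairs:
            seen.setdefault(p.stool_sample_id)
            seen.setdefault(p.oral_sample_id)
        return list(seen)


@dataclass
class AbundanceTable:
    """Species x sample relative abundances (percent) with sample metadata.

    ``data`` is a long frame with columns sample_id/species/relative_abundance
    holding the explicitly recorded entries; ``meta`` is indexed by sample_id.
    """

    data: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        meta = self.meta
        if meta.index.name != "sample_id":
            raise ValidationError("metadata must be indexed by sample_id")
        if meta.index.duplicated().any():
            dups = sorted(meta.index[meta.index.duplicated()].unique())
            raise ValidationError(f"duplicate sample_id in metadata: {dups}")
        bad_sites = sorted(set(meta["body_site"]) - set(BODY_SITES))
        if bad_sites:
            raise ValidationError(
                f"unknown body_site value(s) {bad_sites}; expected one of {BODY_SITES}"
            )
        if (meta["visit"] < 1).any():
            raise ValidationError("visit must be >= 1 for every sample")
        df = self.data
        ab = df["relative_abundance"].to_numpy(dtype=float)
        if np.any(ab < 0) or np.any(ab > 100):
            bad = df.loc[(ab < 0) | (ab > 100)]
            raise ValidationError(
                "relative_abundance outside [0, 100] for "
                f"{bad[['sample_id', 'species']].to_records(index=False).tolist()}"
            )
        dup = df.duplicated(subset=["sample_id", "species"], keep=False)
        if dup.any():
            keys = sorted(
                set(map(tuple, df.loc[dup, ["sample_id", "species"]].to_numpy()))
            )
            raise ValidationError(f"duplicate (sample_id, species) entries: {keys}")
        unknown = sorted(set(df["sample_id"]) - set(meta.index))
        if unknown:
            raise ValidationError(
                f"abundance rows reference sample_id(s) missing from metadata: {unknown}"
            )
        sums = df.groupby("sample_id")["relative_abundance"].sum()
        over = sums[sums > 100 + SUM_TOLERANCE]
        if not over.empty:
            raise ValidationError(
                f"per-sample abundance sums exceed 100: {over.to_dict()}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.meta.index)

    @property
    def species(self) -> list[str]:
        return sorted(self.data["species"].unique())

    def sample_meta(self, sample_id: str) -> SampleMeta:
        row = self.meta.loc[sample_id]
        return SampleMeta(
            sample_id=sample_id,
            subject_id=str(row["subject_id"]),
            body_site=str(row["body_site"]),
            study_id=str(row["study_id"]),
            visit=int(row["visit"]),
        )

    def matrix(self, sample_ids: list[str] | None = None) -> pd.DataFrame:
        """Dense species x sample matrix; absent entries are exact zeros."""
        df = self.data
        if sample_ids is not None:
            missing = sorted(set(sample_ids) - set(self.meta.index))
            if missing:
                raise ValidationError(f"unknown sample_id(s): {missing}")
            df = df[df["sample_id"].isin(sample_ids)]
        mat = df.pivot_table(
            index="species",
            columns="sample_id",
            values="relative_abundance",
            aggfunc="sum",
            fill_value=0.0,
        )
        cols = sorted(sample_ids) if sample_ids is not None else sorted(mat.columns)
        mat = mat.reindex(columns=cols, fill_value=0.0).sort_index()
        return mat.astype(float)

    def abundance(self, sample_id: str, species: str) -> float:
        sel = self.data[
            (self.data["sample_id"] == sample_id) & (self.data["species"] == species)
        ]
        return float(sel["relative_abundance"].sum()) if len(sel) else 0.0


@dataclass
class MarkerTable:
    """Per-sample clade-specific marker-gene values plus a marker->species map."""

    entries: pd.DataFrame
    marker_map: pd.Series  # index marker_id, values species

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.marker_map.index.duplicated().any():
            dups = sorted(self.marker_map.index[self.marker_map.index.duplicated()])
            raise ValidationError(
                f"marker_id(s) mapped to more than one species: {dups}"
            )
        vals = self.entries["value"].to_numpy(dtype=float)
        if np.any(vals < 0):
            bad = self.entries.loc[vals < 0, ["sample_id", "marker_id"]]
            raise ValidationError(
                f"negative marker value(s) for {bad.to_records(index=False).tolist()}"
            )
        unmapped = sorted(set(self.entries["marker_id"]) - set(self.marker_map.index))
        if unmapped:
            raise ValidationError(
                f"marker_id(s) with no species mapping: {unmapped}"
            )
        if self.entries.duplicated(subset=["sample_id", "marker_id"]).any():
            dup = self.entries[
                self.entries.duplicated(subset=["sample_id", "marker_id"], keep=False)
            ]
            keys = sorted(set(map(tuple, dup[["sample_id", "marker_id"]].to_numpy())))
            raise ValidationError(f"duplicate (sample_id, marker_id) entries: {keys}")
        if self.entries.empty:
            warnings.warn("marker table has no entries", stacklevel=3)

    @property
    def species(self) -> list[str]:
        return sorted(self.marker_map.unique())

    def markers_for(self, species: str) -> list[str]:
        """All marker ids mapped to ``species``, in sorted (canonical) order."""
        return sorted(self.marker_map.index[self.marker_map == species])


def _read_tsv(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise TableParseError(f"{path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise TableParseError(f"{path}: missing column(s) {missing}")
    return df[columns]


def _to_numeric(df: pd.DataFrame, column: str, path: str | Path) -> pd.DataFrame:
    num = pd.to_numeric(df[column], errors="coerce")
    bad = num.isna() & df[column].astype(str).ne("")
    bad |= df[column].astype(str).eq("")
    if bad.any():
        # +2: header line plus 1-based numbering
        lines = [int(i) + 2 for i in df.index[bad][:5]]
        raise TableParseError(
            f"{path}: non-numeric {column!r} at line(s) {lines}"
        )
    out = df.copy()
    out[column] = num.astype(float)
    return out


def load_metadata(metadata_path: str | Path) -> pd.DataFrame:
    meta = _read_tsv(metadata_path, METADATA_COLUMNS)
    meta = _to_numeric(meta, "visit", metadata_path)
    meta["visit"] = meta["visit"].astype(int)
    return meta.set_index("sample_id")


def load_abundance_table(
    abundance_path: str | Path, metadata_path: str | Path
) -> AbundanceTable:
    """Read and validate the abundance + metadata TSV pair."""
    meta = load_metadata(metadata_path)
    df = _read_tsv(abundance_path, ABUNDANCE_COLUMNS)
    df = _to_numeric(df, "relative_abundance", abundance_path)
    table = AbundanceTable(data=df.reset_index(drop=True), meta=meta)
    logger.info(
        "loaded abundance table: %d samples, %d species, %d entries",
        len(meta), df["species"].nunique(), len(df),
    )
    return table


def load_marker_table(
    marker_path: str | Path, marker_map_path: str | Path
) -> MarkerTable:
    """Read and validate the marker-value and marker-map TSV pair."""
    mmap = _read_tsv(marker_map_path, MARKER_MAP_COLUMNS)
    entries = _read_tsv(marker_path, MARKER_COLUMNS)
    entries = _to_numeric(entries, "value", marker_path)
    table = MarkerTable(
        entries=entries.reset_index(drop=True),
        marker_map=mmap.set_index("marker_id")["species"],
    )
    logger.info(
        "loaded marker table: %d entries, %d mapped markers, %d species",
        len(entries), len(table.marker_map), len(table.species),
    )
    return table


def write_abundance_table(
    table: AbundanceTable, abundance_path: str | Path, metadata_path: str | Path
) -> None:
    """Write the table back as TSVs with deterministic row order."""
    meta = table.meta.reset_index().sort_values("sample_id")
    meta.to_csv(metadata_path, sep="\t", index=False)
    data = table.data.sort_values(["sample_id", "species"])
    data.to_csv(abundance_path, sep="\t", index=False)


def write_marker_table(
    table: MarkerTable, marker_path: str | Path, marker_map_path: str | Path
) -> None:
    entries = table.entries.sort_values(["sample_id", "marker_id"])
    entries.to_csv(marker_path, sep="\t", index=False)
    mmap = table.marker_map.rename("species").reset_index()
    mmap.columns = MARKER_MAP_COLUMNS
    mmap.sort_values("marker_id").to_csv(marker_map_path, sep="\t", index=False)


def build_sample_pairs(table: AbundanceTable, oral_site: str) -> SamplePairSet:
    """Pair stool with ``oral_site`` samples within each (subject, visit).

    When a subject has several candidate samples of one type at the same
    visit, the lexicographically smallest sample_id is used — a deterministic
    stand-in for the study's pair-by-collection-proximity rule, whose
    timestamps are not part of the interchange tables.
    """
    if oral_site == STOOL:
        raise ValueError("oral_site must be one of the oral sites, not 'stool'")
    if oral_site not in ORAL_SITES:
        raise ValueError(f"unknown oral site {oral_site!r}; expected one of {ORAL_SITES}")
    meta = table.meta.reset_index()
    pairs: list[SamplePair] = []
    grouped = meta.groupby(["subject_id", "visit"], sort=True)
    for (subject_id, _visit), grp in grouped:
        stool_ids = sorted(grp.loc[grp["body_site"] == STOOL, "sample_id"])
        oral_ids = sorted(grp.loc[grp["body_site"] == oral_site, "sample_id"])
        if stool_ids and oral_ids:
            pairs.append(
                SamplePair(
                    subject_id=str(subject_id),
                    stool_sample_id=stool_ids[0],
                    oral_sample_id=oral_ids[0],
                    oral_site=oral_site,
                )
            )
    logger.info("paired %d subjects at site %s", len(pairs), oral_site)
    return SamplePairSet(oral_site=oral_site, pairs=pairs)
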