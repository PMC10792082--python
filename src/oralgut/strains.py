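"""Clade-specific marker-gene presence/absence strain-consistency calls.

Different strains of one species can carry different subsets of the species'
clade-specific marker genes (gene gain and loss), so the binary pattern of
marker presence/absence distinguishes strains — up to SNP-level variation,
which marker presence cannot see.  A within-subject stool and oral sample
whose patterns are identical for a species are therefore called "consistent
with same-strain colonization", never "the same strain": the call may
overestimate, but not underestimate, true strain overlap.

To avoid mistaking low sequencing depth for gene loss, only samples covering
at least 90% of the species' markers are compared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ORAL_SITES, STOOL, MarkerTable

logger = logging.getLogger(__name__)

#: the five frequently overlapping species examined for strain consistency
DEFAULT_SPECIES = (
    "Streptococcus_parasanguinis",
    "Haemophilus_parainfluenzae",
    "Streptococcus_salivarius",
    "Streptococcus_mitis",
    "Veillonella_parvula",
)

DEFAULT_COVERAGE_MIN = 0.9


@dataclass(frozen=True)
class MarkerPattern:
    """Binary marker presence for one (sample, species), over the species'
    full marker set in sorted marker_id order."""

    sample_id: str
    species_name: str
    presence: tuple[int, ...]
    coverage: float


@dataclass(frozen=True)
class StrainCall:
    subject_id: str
    species_name: str
    matched_oral_sites: frozenset[str]
    stool_sample_id: str

    @property
    def is_consistent(self) -> bool:
        return bool(self.matched_oral_sites)


def binarize_pattern(
    markers: MarkerTable,
    sample_id: str,
    species_name: str,
    marker_presence_threshold: float = 0.0,
) -> MarkerPattern:
    """Presence/absence vector for one sample over one species' markers.

    A marker is present when its value is strictly above the threshold;
    markers with no entry for the sample are absent.  Coverage is the present
    fraction of the species' full marker set.
    """
    marker_ids = markers.markers_for(species_name)
    if not marker_ids:
        raise ValueError(f"species {species_name!r} has no mapped markers")
    df = markers.entries
    sel = df[(df["sample_id"] == sample_id) & (df["value"] > marker_presence_threshold)]
    present = set(sel["marker_id"])
    presence = tuple(1 if m in present else 0 for m in marker_ids)
    return MarkerPattern(
        sample_id=sample_id,
        species_name=species_name,
        presence=presence,
        coverage=sum(presence) / len(presence),
    )


def eligible_samples(
    markers: MarkerTable,
    sample_ids,
    species_name: str,
    coverage_min: float = DEFAULT_COVERAGE_MIN,
    marker_presence_threshold: float = 0.0,
) -> list[MarkerPattern]:
    """Patterns with marker coverage >= coverage_min (inclusive), in sorted
    sample_id order."""
    if not 0.0 <= coverage_min <= 1.0:
        raise ValueError("coverage_min must be in [0, 1]")
    out = []
    for sid in sorted(set(sample_ids)):
        pat = binarize_pattern(markers, sid, species_name, marker_presence_threshold)
        if pat.coverage >= coverage_min:
            out.append(pat)
    return out


def _eligible_from_entries(
    entries_sp: pd.DataFrame,
    marker_ids: list[str],
    sample_ids: list[str],
    species_name: str,
    coverage_min: float,
    marker_presence_threshold: float,
) -> list[MarkerPattern]:
    """Vectorized equivalent of ``eligible_samples`` over a pre-filtered
    per-species entry frame."""
    detected = entries_sp[entries_sp["value"] > marker_presence_threshold]
    by_sample = {
        sid: set(grp["marker_id"]) for sid, grp in detected.groupby("sample_id")
    }
    out = []
    for sid in sorted(set(sample_ids)):
        present = by_sample.get(sid, set())
        presence = tuple(1 if m in present else 0 for m in marker_ids)
        coverage = sum(presence) / len(presence)
        if coverage >= coverage_min:
            out.append(
                MarkerPattern(
                    sample_id=sid,
                    species_name=species_name,
                    presence=presence,
                    coverage=coverage,
                )
            )
    return out


def pattern_match(stool: MarkerPattern, oral: MarkerPattern) -> bool:
    """True iff the two binary patterns are identical at every marker."""
    if stool.species_name != oral.species_name:
        raise ValueError(
            f"cannot compare patterns of different species: "
            f"{stool.species_name!r} vs {oral.species_name!r}"
        )
    if len(stool.presence) != len(oral.presence):
        raise ValueError("pattern lengths differ")
    return stool.presence == oral.presence


def call_shared_strains(
    markers: MarkerTable,
    metadata: pd.DataFrame,
    species_list=None,
    coverage_min: float = DEFAULT_COVERAGE_MIN,
    marker_presence_threshold: float = 0.0,
) -> list[StrainCall]:
    """Same-strain-consistency calls for every (subject, species) with an
    eligible stool pattern and at least one eligible oral pattern.

    ``metadata`` is indexed by sample_id with subject_id and body_site
    columns.  A subject is consistent for a species when ANY eligible stool
    pattern is identical to ANY eligible oral pattern; matched_oral_sites
    collects every oral site with a matching sample.  Subjects lacking an
    eligible stool or oral pattern for a species are omitted.
    """
    if species_list is None:
        species_list = list(DEFAULT_SPECIES)
    meta = metadata
    if meta.index.name != "sample_id":
        raise ValueError("metadata must be indexed by sample_id")
    known_species = set(markers.species)
    calls: list[StrainCall] = []
    sample_ids_with_markers = set(markers.entries["sample_id"])
    for sp in species_list:
        if sp not in known_species:
            logger.warning("species %s has no mapped markers; skipped", sp)
            continue
        sp_markers = set(markers.markers_for(sp))
        entries_sp = markers.entries[markers.entries["marker_id"].isin(sp_markers)]
        if coverage_min > 0:
            # samples with no marker entry for this species have coverage 0
            candidates = sorted(set(entries_sp["sample_id"]) & set(meta.index))
        else:
            candidates = sorted(sample_ids_with_markers & set(meta.index))
        patterns = _eligible_from_entries(
            entries_sp, markers.markers_for(sp), candidates, sp,
            coverage_min, marker_presence_threshold,
        )
        by_subject: dict[str, dict[str, list[MarkerPattern]]] = {}
        for pat in patterns:
            row = meta.loc[pat.sample_id]
            by_subject.setdefault(str(row["subject_id"]), {}).setdefault(
                str(row["body_site"]), []
            ).append(pat)
        for subject_id in sorted(by_subject):
            sites = by_subject[subject_id]
            stool_pats = sites.get(STOOL, [])
            oral_pats = [
                (site, pat)
                for site in ORAL_SITES
                for pat in sites.get(site, [])
            ]
            if not stool_pats or not oral_pats:
                continue
            matched_sites: set[str] = set()
            matching_stools: set[str] = set()
            for st in stool_pats:
                for site, op in oral_pats:
                    if pattern_match(st, op):
                        matched_sites.add(site)
                        matching_stools.add(st.sample_id)
            stool_id = (
                min(matching_stools)
                if matching_stools
                else min(p.sample_id for p in stool_pats)
            )
            calls.append(
                StrainCall(
                    subject_id=subject_id,
                    species_name=sp,
                    matched_oral_sites=frozenset(matched_sites),
                    stool_sample_id=stool_id,
                )
            )
        logger.info(
            "species %s: %d eligible samples, %d subjects testable, %d consistent",
            sp,
            len(patterns),
            sum(1 for c in calls if c.species_name == sp),
            sum(1 for c in calls if c.species_name == sp and c.is_consistent),
        )
    return calls


def count_consistent_individuals(calls: list[StrainCall]) -> int:
    """Distinct subjects with at least one consistent call; a subject
    matching for several species or sites still counts once."""
    return len({c.subject_id for c in calls if c.is_consistent})


def consistent_triples(calls: list[StrainCall]) -> set[tuple[str, str, str]]:
    """(subject, species, oral_site) triples with a consistent pattern —
    directly comparable to a synthetic cohort's planted ground truth."""
    return {
        (c.subject_id, c.species_name, site)
        for c in calls
        if c.is_consistent
        for site in c.matched_oral_sites
    }


def calls_frame(calls: list[StrainCall]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": c.subject_id,
            "species": c.species_name,
            "stool_sample_id": c.stool_sample_id,
            "matched_oral_sites": ",".join(sorted(c.matched_oral_sites)),
            "is_consistent": c.is_consistent,
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=["subject_id", "species", "stool_sample_id", "matched_oral_sites", "is_consistent"],
    )


def pattern_matrix(patterns: list[MarkerPattern], markers: MarkerTable) -> pd.DataFrame:
    """Binary marker x sample matrix for one species (heatmap backing data)."""
    if not patterns:
        raise ValueError("no patterns supplied")
    species = {p.species_name for p in patterns}
    if len(species) != 1:
        raise ValueError("patterns must all belong to one species")
    sp = species.pop()
    marker_ids = markers.markers_for(sp)
    data = {p.sample_id: list(p.presence) for p in patterns}
    return pd.DataFrame(data, index=marker_ids)
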