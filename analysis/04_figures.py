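#!/usr/bin/env python
"""Render the figure set: per-site overlap bar charts, fecal/oral abundance
boxplots, -log10(q) significance plots, and per-species marker heatmaps with
asterisks on stool samples that have a matching oral pattern.

Run 01_simulate_cohort.py, 02_species_overlap.py and 03_strain_inference.py
first.  Every number rendered here is already written as TSV by those steps.
"""

import logging
from pathlib import Path

from oralgut import (
    ORAL_SITES,
    build_sample_pairs,
    call_shared_strains,
    compare_niche_abundances,
    find_overlapping_species,
    load_abundance_table,
    load_marker_table,
)
from oralgut.io import load_metadata
from oralgut.plots import render_marker_heatmap, render_overlap_report
from oralgut.strains import DEFAULT_COVERAGE_MIN, DEFAULT_SPECIES, _eligible_from_entries

logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")


def main() -> None:
    table = load_abundance_table("results/cohort/abundance.tsv",
                                 "results/cohort/metadata.tsv")
    markers = load_marker_table("results/cohort/markers.tsv",
                                "results/cohort/marker_map.tsv")
    meta = load_metadata("results/cohort/metadata.tsv")

    written = []
    for site in ORAL_SITES:
        pairs = build_sample_pairs(table, site)
        overlapping = find_overlapping_species(table, pairs)
        results = compare_niche_abundances(table, pairs, overlapping)
        written += render_overlap_report(results, Path("results/figures") / site)

    calls = call_shared_strains(markers, meta)
    patterns = []
    for sp in DEFAULT_SPECIES:
        sp_markers = set(markers.markers_for(sp))
        entries_sp = markers.entries[markers.entries["marker_id"].isin(sp_markers)]
        cands = sorted(set(entries_sp["sample_id"]) & set(meta.index))
        patterns += _eligible_from_entries(
            entries_sp, markers.markers_for(sp), cands, sp, DEFAULT_COVERAGE_MIN, 0.0
        )
    written += render_marker_heatmap(
        patterns, calls, Path("results/figures/marker_patterns.png"), metadata=meta
    )
    print(f"wrote {len(written)} figure/table files under results/figures/")


if __name__ == "__main__":
    main()
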