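#!/usr/bin/env python
"""Species-level overlap between stool and each oral site.

For every oral site: pair samples within subject, apply the prevalence
filter, keep species overlapping in >= 10% of pairs, and compare fecal vs.
oral relative abundance (paired Wilcoxon signed-rank, BH-adjusted).  Writes
per-site overlapping_species.tsv and abundance_comparison.tsv under
results/overlap/<site>/ and prints a per-site summary.

Run 01_simulate_cohort.py first.
"""

import logging
from pathlib import Path

import pandas as pd

from oralgut import (
    ORAL_SITES,
    build_sample_pairs,
    compare_niche_abundances,
    find_overlapping_species,
    load_abundance_table,
)
from oralgut.overlap import results_frame

logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")


def main() -> None:
    table = load_abundance_table("results/cohort/abundance.tsv",
                                 "results/cohort/metadata.tsv")
    out = Path("results/overlap")
    for site in ORAL_SITES:
        pairs = build_sample_pairs(table, site)
        overlapping = find_overlapping_species(table, pairs)
        results = compare_niche_abundances(table, pairs, overlapping)
        frame = results_frame(results)
        site_dir = out / site
        site_dir.mkdir(parents=True, exist_ok=True)
        cols = ["species", "n_pairs", "n_overlapping_pairs", "overlap_frequency"]
        (frame[cols] if not frame.empty else pd.DataFrame(columns=cols)).to_csv(
            site_dir / "overlapping_species.tsv", sep="\t", index=False)
        frame.to_csv(site_dir / "abundance_comparison.tsv", sep="\t", index=False)
        n_oral = sum(1 for r in results if r.inferred_origin == "oral")
        n_fecal = sum(1 for r in results if r.inferred_origin == "fecal")
        print(f"{site}: {len(pairs)} pairs, {len(overlapping)} overlapping "
              f"species ({n_oral} oral origin, {n_fecal} fecal origin, "
              f"{len(overlapping) - n_oral - n_fecal} indeterminate)")


if __name__ == "__main__":
    main()
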