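#!/usr/bin/env python
"""Marker presence/absence strain-consistency calls.

Compares the binary clade-specific marker-gene patterns of within-subject
stool and oral samples for the five frequently overlapping oral species,
restricted to samples covering >= 90% of the species' markers.  Writes
strain_calls.tsv under results/strains/ and checks the calls against the
cohort's planted ground truth.

Run 01_simulate_cohort.py first.
"""

import logging
from pathlib import Path

import pandas as pd

from oralgut import (
    call_shared_strains,
    consistent_triples,
    count_consistent_individuals,
    load_marker_table,
)
from oralgut.io import load_metadata
from oralgut.strains import calls_frame

logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")


def main() -> None:
    markers = load_marker_table("results/cohort/markers.tsv",
                                "results/cohort/marker_map.tsv")
    meta = load_metadata("results/cohort/metadata.tsv")
    calls = call_shared_strains(markers, meta)
    out = Path("results/strains")
    out.mkdir(parents=True, exist_ok=True)
    calls_frame(calls).to_csv(out / "strain_calls.tsv", sep="\t", index=False)

    n = count_consistent_individuals(calls)
    print(f"testable (subject, species) combinations: {len(calls)}")
    print(f"individuals consistent with same-strain colonization: {n}")

    truth_path = Path("results/cohort/truth.tsv")
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t")
        planted = set(map(tuple, truth.to_numpy()))
        called = consistent_triples(calls)
        print(f"planted shared strains recovered: {len(called & planted)}/{len(planted)}"
              f" (false calls: {len(called - planted)})")


if __name__ == "__main__":
    main()
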