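"""Figure rendering for overlap and marker-pattern results.

Figures are views: every number they show is also written as TSV by the
pipeline (or alongside the figure here), so no result exists only as pixels.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .io import ORAL_SITES, STOOL
from .overlap import OverlapResult, results_frame
from .strains import MarkerPattern, StrainCall

logger = logging.getLogger(__name__)


def render_overlap_report(
    results: list[OverlapResult], output_dir: str | Path
) -> list[Path]:
    """Bar chart of overlap frequencies, paired fecal/oral abundance
    boxplots (whiskers at the most extreme points within 1.5 x IQR), and a
    -log10(q) significance plot with the q = 0.05 line.

    Returns the written paths; empty results are a warned no-op.
    """
    if not results:
        warnings.warn("no overlap results to render", stacklevel=2)
        return []
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame = results_frame(results)
    written: list[Path] = []

    tsv = out / "overlap_report.tsv"
    frame.to_csv(tsv, sep="\t", index=False)
    written.append(tsv)

    site = results[0].oral_site
    species = frame["species"].tolist()
    x = np.arange(len(species))

    fig, ax = plt.subplots(figsize=(max(4, 0.4 * len(species)), 4))
    ax.bar(x, frame["overlap_frequency"], color="#4878a8")
    ax.set_xticks(x)
    ax.set_xticklabels(species, rotation=90, fontsize=7)
    ax.set_ylabel("pairwise overlap frequency")
    ax.set_title(f"stool vs {site}: species overlap")
    fig.tight_layout()
    p = out / "overlap_frequency.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    written.append(p)

    fig, axes = plt.subplots(1, 2, figsize=(max(6, 0.8 * len(species)), 4), sharey=True)
    for ax, niche in zip(axes, ("fecal", "oral")):
        boxes = [
            {
                "med": r[f"{niche}_median"],
                "q1": r[f"{niche}_q1"],
                "q3": r[f"{niche}_q3"],
                "whislo": r[f"{niche}_whisker_low"],
                "whishi": r[f"{niche}_whisker_high"],
                "label": r["species"],
            }
            for _, r in frame.iterrows()
        ]
        ax.bxp(boxes, showfliers=False)
        ax.set_title(f"{niche} relative abundance (%)")
        ax.tick_params(axis="x", rotation=90, labelsize=7)
    fig.tight_layout()
    p = out / "abundance_boxplots.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    written.append(p)

    fig, ax = plt.subplots(figsize=(max(4, 0.4 * len(species)), 4))
    with np.errstate(divide="ignore"):
        neglog_q = -np.log10(frame["q_value"].to_numpy(dtype=float))
    ax.scatter(x, neglog_q, color="#333333")
    ax.axhline(-np.log10(0.05), color="red", lw=1, label="q = 0.05")
    ax.set_xticks(x)
    ax.set_xticklabels(species, rotation=90, fontsize=7)
    ax.set_ylabel(r"$-\log_{10}(q)$")
    ax.set_title(f"stool vs {site}: fecal/oral abundance comparison")
    ax.legend()
    fig.tight_layout()
    p = out / "qvalues.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    written.append(p)

    logger.info("rendered overlap report for %s: %d species", site, len(species))
    return written


def _column_order(patterns: list[MarkerPattern], metadata: pd.DataFrame | None) -> list[str]:
    sids = sorted({p.sample_id for p in patterns})
    if metadata is None:
        return sids
    site_rank = {STOOL: 0, **{s: i + 1 for i, s in enumerate(ORAL_SITES)}}

    def key(sid: str):
        row = metadata.loc[sid]
        return (str(row["subject_id"]), site_rank.get(str(row["body_site"]), 99), sid)

    return sorted(sids, key=key)


def render_marker_heatmap(
    patterns: list[MarkerPattern],
    calls: list[StrainCall],
    output_path: str | Path,
    metadata: pd.DataFrame | None = None,
) -> list[Path]:
    """Binary marker presence/absence heatmaps, one file per species.

    Samples are grouped by subject (stool first within a subject when
    metadata is supplied); stool samples with at least one matching oral
    sample from the same individual are marked with an asterisk.
    """
    if not patterns:
        raise ValueError("no marker patterns supplied")
    output_path = Path(output_path)
    consistent_stools = {
        c.stool_sample_id for c in calls if c.is_consistent
    }
    by_species: dict[str, list[MarkerPattern]] = {}
    for p in patterns:
        by_species.setdefault(p.species_name, []).append(p)
    written: list[Path] = []
    for sp in sorted(by_species):
        pats = by_species[sp]
        order = _column_order(pats, metadata)
        by_id = {p.sample_id: p for p in pats}
        mat = np.array([by_id[sid].presence for sid in order]).T  # markers x samples
        fig, ax = plt.subplots(
            figsize=(min(40, max(3, 0.3 * len(order))), max(3, 0.02 * mat.shape[0]))
        )
        ax.imshow(mat, aspect="auto", cmap="Greys", interpolation="nearest")
        starred = [i for i, sid in enumerate(order) if sid in consistent_stools]
        if len(order) <= 80:
            labels = [
                sid + (" *" if sid in consistent_stools else "") for sid in order
            ]
            ax.set_xticks(np.arange(len(order)))
            ax.set_xticklabels(labels, rotation=90, fontsize=6)
        else:
            ax.set_xticks([])
            ax.set_xlabel(f"{len(order)} samples")
        if starred:
            ax.scatter(
                starred, [-1.5] * len(starred), marker="*", color="red",
                clip_on=False, zorder=3,
            )
        ax.set_yticks([])
        ax.set_ylabel("marker gene")
        ax.set_title(sp.replace("_", " "))
        fig.tight_layout()
        path = output_path.with_name(f"{output_path.stem}_{sp}{output_path.suffix or '.png'}")
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)
    logger.info("rendered %d marker heatmap(s)", len(written))
    return written
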