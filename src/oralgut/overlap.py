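"""Species-level overlap statistics between paired stool and oral samples.

For one oral site, the analysis (i) restricts to species passing a prevalence
filter over the pooled pair samples, (ii) computes each species' pairwise
overlap frequency — the fraction of within-subject stool/oral pairs in which
the species is detected in BOTH members — and keeps species overlapping in at
least a configurable fraction of pairs, then (iii) compares fecal vs. oral
relative abundances with a paired Wilcoxon signed-rank test, adjusting p
values across the per-site species family with Benjamini–Hochberg, and calls
a likely niche of origin from the significant direction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import braycurtis as _scipy_braycurtis
from statsmodels.stats.multitest import multipletests

from .io import AbundanceTable, SamplePairSet

logger = logging.getLogger(__name__)

#: switch from the exact signed-rank null to the normal approximation above
#: this effective sample size (pairs with nonzero difference)
EXACT_MAX_N = 25


class UndefinedTestError(ValueError):
    """The test statistic is undefined (e.g. every paired difference is zero)."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds for the overlap and niche-abundance analysis.

    ``presence_threshold`` is in percent relative abundance and presence is
    strict (> threshold), so the default 0 means "detected at all".
    A species is retained by the prevalence filter when detected in at least
    max(prevalence_min_count, ceil(prevalence_min_fraction * N)) of the N
    samples under consideration — the "occurred >= 3 times in >= 10% of the
    samples" rule, read so that it stays well defined for small N.
    """

    presence_threshold: float = 0.0
    prevalence_min_fraction: float = 0.10
    prevalence_min_count: int = 3
    overlap_min_fraction: float = 0.10
    q_threshold: float = 0.05
    paired_test: bool = True  # fall back to unpaired rank-sum when False

    def __post_init__(self) -> None:
        for name in ("prevalence_min_fraction", "overlap_min_fraction", "q_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.presence_threshold < 0 or self.prevalence_min_count < 0:
            raise ValueError("thresholds must be nonnegative")


@dataclass
class BoxSummary:
    """Tukey boxplot summary: median, quartiles, non-outlier extremes."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float


@dataclass
class OverlapResult:
    species_name: str
    oral_site: str
    n_pairs: int
    n_overlapping_pairs: int
    overlap_frequency: float
    fecal_abundance_summary: BoxSummary
    oral_abundance_summary: BoxSummary
    p_value: float
    q_value: float
    significant: bool
    inferred_origin: str  # oral | fecal | indeterminate
    degenerate_test: bool = False  # all paired differences were zero


def box_summary(values) -> BoxSummary:
    """Median, quartiles, and whiskers at the most extreme points within
    1.5 x IQR of the box."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty value list")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return BoxSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(v[v >= lo_fence].min()),
        whisker_high=float(v[v <= hi_fence].max()),
    )


def prevalence_filter(
    table: AbundanceTable,
    sample_ids: list[str],
    config: AnalysisConfig = AnalysisConfig(),
) -> list[str]:
    """Species detected in at least max(min_count, ceil(min_fraction*N)) of
    the N listed samples, sorted lexicographically."""
    if not sample_ids:
        raise ValueError("sample_ids must be non-empty")
    unknown = sorted(set(sample_ids) - set(table.meta.index))
    if unknown:
        raise ValueError(f"unknown sample_id(s): {unknown}")
    n = len(set(sample_ids))
    needed = max(config.prevalence_min_count, math.ceil(config.prevalence_min_fraction * n))
    df = table.data
    df = df[df["sample_id"].isin(sample_ids) & (df["relative_abundance"] > config.presence_threshold)]
    counts = df.groupby("species")["sample_id"].nunique()
    kept = sorted(counts.index[counts >= needed])
    logger.info(
        "prevalence filter: kept %d/%d species (>= %d of %d samples)",
        len(kept), df["species"].nunique(), needed, n,
    )
    return kept


def _presence_sets(
    table: AbundanceTable, species_name: str, config: AnalysisConfig
) -> set[str]:
    df = table.data
    sel = df[(df["species"] == species_name) & (df["relative_abundance"] > config.presence_threshold)]
    return set(sel["sample_id"])


def pairwise_overlap_frequency(
    table: AbundanceTable,
    pairs: SamplePairSet,
    species_name: str,
    config: AnalysisConfig = AnalysisConfig(),
) -> tuple[int, int, float]:
    """(n_pairs, n_overlapping_pairs, frequency) for one species.

    A pair overlaps when the species is detected in both its members.
    """
    if not pairs.pairs:
        raise ValueError("pair set is empty")
    present = _presence_sets(table, species_name, config)
    n_overlap = sum(
        1
        for p in pairs.pairs
        if p.stool_sample_id in present and p.oral_sample_id in present
    )
    n = len(pairs.pairs)
    return n, n_overlap, n_overlap / n


def find_overlapping_species(
    table: AbundanceTable,
    pairs: SamplePairSet,
    config: AnalysisConfig = AnalysisConfig(),
) -> list[str]:
    """Prevalence-passing species overlapping in >= overlap_min_fraction of
    pairs, sorted by descending overlap frequency (ties lexicographic)."""
    pooled = pairs.all_sample_ids
    candidates = prevalence_filter(table, pooled, config)
    freqs = {}
    for sp in candidates:
        _, _, f = pairwise_overlap_frequency(table, pairs, sp, config)
        if f >= config.overlap_min_fraction:
            freqs[sp] = f
    ordered = sorted(freqs, key=lambda sp: (-freqs[sp], sp))
    logger.info(
        "site %s: %d species overlap in >= %.0f%% of %d pairs",
        pairs.oral_site, len(ordered), 100 * config.overlap_min_fraction, len(pairs),
    )
    return ordered


def _signed_rank_statistic(diffs: np.ndarray) -> tuple[float, np.ndarray]:
    """W+ (sum of ranks of positive differences) and the midranks used."""
    ranks = stats.rankdata(np.abs(diffs))
    return float(ranks[diffs > 0].sum()), ranks


def _exact_signed_rank_p(w_plus: float, ranks: np.ndarray) -> float:
    """Two-sided exact p under the sign-flip null, supporting midranks.

    Ranks are doubled to integers and the null distribution of 2*W+ is built
    by dynamic programming over all 2^n equally likely sign assignments.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2 * w_plus))
    cdf = counts[: w2 + 1].sum()
    sf = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(cdf, sf)))


def _approx_signed_rank_p(w_plus: float, ranks: np.ndarray) -> float:
    """Normal approximation with tie correction and continuity correction."""
    n = ranks.size
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        raise UndefinedTestError("zero variance in signed-rank statistic")
    d = w_plus - mean
    d -= 0.5 * np.sign(d)  # continuity correction toward the mean
    z = d / math.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def paired_wilcoxon(fecal_values, oral_values) -> float:
    """Two-sided paired Wilcoxon signed-rank p value.

    Zero differences are dropped before ranking (the classic procedure); tied
    absolute differences receive midranks.  The null distribution is exact
    (full sign-flip enumeration) when the effective n is at most 25 and a
    tie-corrected normal approximation with continuity correction otherwise.
    """
    f = np.asarray(fecal_values, dtype=float)
    o = np.asarray(oral_values, dtype=float)
    if f.shape != o.shape or f.ndim != 1 or f.size == 0:
        raise ValueError("fecal and oral value lists must be equal-length, non-empty")
    diffs = f - o
    diffs = diffs[diffs != 0]
    if diffs.size == 0:
        raise UndefinedTestError("all paired differences are zero")
    w_plus, ranks = _signed_rank_statistic(diffs)
    if diffs.size <= EXACT_MAX_N:
        return _exact_signed_rank_p(w_plus, ranks)
    return _approx_signed_rank_p(w_plus, ranks)


def bh_adjust(p_values) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p values (clipped to 1),
    positionally aligned with the input."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in q]


def compare_niche_abundances(
    table: AbundanceTable,
    pairs: SamplePairSet,
    species_list: list[str],
    config: AnalysisConfig = AnalysisConfig(),
) -> list[OverlapResult]:
    """Per-species fecal vs. oral abundance comparison over one pair set.

    The BH family is the supplied species list (one family per oral-site
    dataset).  A species whose paired differences are all zero is flagged
    degenerate and reported non-significant with p = q = 1.
    """
    results: list[OverlapResult] = []
    mat = table.matrix(pairs.all_sample_ids)
    p_values: list[float] = []
    rows: list[dict] = []
    for sp in species_list:
        fecal = np.array(
            [mat.at[sp, p.stool_sample_id] if sp in mat.index else 0.0 for p in pairs.pairs]
        )
        oral = np.array(
            [mat.at[sp, p.oral_sample_id] if sp in mat.index else 0.0 for p in pairs.pairs]
        )
        n, n_overlap, freq = pairwise_overlap_frequency(table, pairs, sp, config)
        degenerate = False
        try:
            p = paired_wilcoxon(fecal, oral) if config.paired_test else float(
                stats.mannwhitneyu(fecal, oral, alternative="two-sided").pvalue
            )
        except UndefinedTestError:
            degenerate = True
            p = 1.0
            logger.warning(
                "species %s at %s: all paired differences zero; reported "
                "non-significant", sp, pairs.oral_site,
            )
        p_values.append(p)
        rows.append(
            dict(
                species_name=sp,
                n_pairs=n,
                n_overlapping_pairs=n_overlap,
                overlap_frequency=freq,
                fecal=fecal,
                oral=oral,
                degenerate=degenerate,
            )
        )
    q_values = bh_adjust(p_values)
    for row, p, q in zip(rows, p_values, q_values):
        fs = box_summary(row["fecal"])
        os_ = box_summary(row["oral"])
        significant = (not row["degenerate"]) and q < config.q_threshold
        if significant and os_.median > fs.median:
            origin = "oral"
        elif significant and fs.median > os_.median:
            origin = "fecal"
        else:
            origin = "indeterminate"
        results.append(
            OverlapResult(
                species_name=row["species_name"],
                oral_site=pairs.oral_site,
                n_pairs=row["n_pairs"],
                n_overlapping_pairs=row["n_overlapping_pairs"],
                overlap_frequency=row["overlap_frequency"],
                fecal_abundance_summary=fs,
                oral_abundance_summary=os_,
                p_value=float(p),
                q_value=float(q),
                significant=significant,
                inferred_origin=origin,
                degenerate_test=row["degenerate"],
            )
        )
    return results


def bray_curtis(a, b) -> float:
    """Bray–Curtis dissimilarity sum|a-b| / sum(a+b) in [0, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("abundance vectors must be nonnegative")
    if a.sum() == 0 and b.sum() == 0:
        raise UndefinedTestError("Bray-Curtis undefined for two all-zero vectors")
    return float(_scipy_braycurtis(a, b))


def distance_matrix(table: AbundanceTable, sample_ids: list[str]) -> pd.DataFrame:
    """Pairwise Bray–Curtis distances over the given samples (sorted order)."""
    mat = table.matrix(sample_ids)  # species x samples, columns sorted
    x = mat.to_numpy().T
    n = x.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = bray_curtis(x[i], x[j])
    return pd.DataFrame(out, index=mat.columns, columns=mat.columns)


def log_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """log10(x + pseudocount), pseudocount = smallest nonzero abundance."""
    vals = matrix.to_numpy()
    nonzero = vals[vals > 0]
    if nonzero.size == 0:
        raise ValueError("matrix has no nonzero entries")
    pc = float(nonzero.min())
    return np.log10(matrix + pc)


def results_frame(results: list[OverlapResult]) -> pd.DataFrame:
    """Flatten OverlapResults for TSV output."""
    rows = []
    for r in results:
        rows.append(
            {
                "species": r.species_name,
                "oral_site": r.oral_site,
                "n_pairs": r.n_pairs,
                "n_overlapping_pairs": r.n_overlapping_pairs,
                "overlap_frequency": r.overlap_frequency,
                "fecal_median": r.fecal_abundance_summary.median,
                "fecal_q1": r.fecal_abundance_summary.q1,
                "fecal_q3": r.fecal_abundance_summary.q3,
                "fecal_whisker_low": r.fecal_abundance_summary.whisker_low,
                "fecal_whisker_high": r.fecal_abundance_summary.whisker_high,
                "oral_median": r.oral_abundance_summary.median,
                "oral_q1": r.oral_abundance_summary.q1,
                "oral_q3": r.oral_abundance_summary.q3,
                "oral_whisker_low": r.oral_abundance_summary.whisker_low,
                "oral_whisker_high": r.oral_abundance_summary.whisker_high,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "significant": r.significant,
                "inferred_origin": r.inferred_origin,
                "degenerate_test": r.degenerate_test,
            }
        )
    return pd.DataFrame(rows)
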