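"""End-to-end orchestration: pairing, overlap statistics, strain calls.

A run is driven by a YAML config that either references the four interchange
TSVs (``inputs``) or embeds generator settings for a self-contained synthetic
run (``simulate``).  All result tables are written as TSV under the output
directory, together with a manifest (config hash, seed, input checksums)
sufficient to reproduce the run bit-identically from the same inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from scipy.spatial.distance import pdist, squareform

from . import __version__
from .io import (
    ORAL_SITES,
    AbundanceTable,
    SamplePairSet,
    build_sample_pairs,
    load_abundance_table,
    load_marker_table,
)
from .overlap import (
    AnalysisConfig,
    OverlapResult,
    compare_niche_abundances,
    find_overlapping_species,
    results_frame,
)
from .simulate import SimConfig, SyntheticCohort, generate_cohort
from .strains import (
    DEFAULT_COVERAGE_MIN,
    DEFAULT_SPECIES,
    StrainCall,
    call_shared_strains,
    calls_frame,
    count_consistent_individuals,
    pattern_matrix,
    _eligible_from_entries,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is module-qualified."""


@dataclass
class ReportBundle:
    """Everything one run computed, plus the provenance manifest."""

    pairs: dict[str, SamplePairSet]
    overlapping_species: dict[str, list[str]]
    overlap_results: dict[str, list[OverlapResult]]
    strain_calls: list[StrainCall]
    n_consistent_individuals: int
    distances: dict[str, pd.DataFrame]
    manifest: dict
    output_dir: Path
    written: list[Path] = field(default_factory=list)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(cfg: dict) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()


def load_config(config_path: str | Path) -> dict:
    path = Path(config_path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg


def _validate_config(cfg: dict) -> None:
    sites = cfg.get("oral_sites", list(ORAL_SITES))
    if not sites:
        raise ValueError("config: oral_sites must be a non-empty list")
    unknown = set(sites) - set(ORAL_SITES)
    if unknown:
        raise ValueError(f"config: unknown oral site(s) {sorted(unknown)}")
    has_sim = "simulate" in cfg
    has_inputs = "inputs" in cfg
    if has_sim == has_inputs:
        raise ValueError("config: exactly one of 'simulate' or 'inputs' is required")


def run_pipeline(
    config_path: str | Path,
    output_dir: str | Path | None = None,
    seed: int | None = None,
) -> ReportBundle:
    """Execute pairing -> prevalence filter -> overlap -> abundance
    comparison -> strain inference for every configured oral site.

    Partial outputs are removed when any stage fails.
    """
    cfg = load_config(config_path)
    _validate_config(cfg)
    out = Path(output_dir or cfg.get("output_dir", "results/run"))
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run(cfg, out, seed, written)
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        if isinstance(exc, (PipelineError, FileNotFoundError)):
            raise
        raise PipelineError(f"pipeline failed: {exc}") from exc


def _write_tsv(df: pd.DataFrame, path: Path, written: list[Path]) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    written.append(path)


def _run(cfg: dict, out: Path, seed: int | None, written: list[Path]) -> ReportBundle:
    sites = list(cfg.get("oral_sites", list(ORAL_SITES)))
    input_checksums: dict[str, str] = {}

    # --- stage: inputs ---
    if "simulate" in cfg:
        sim_kwargs = dict(cfg["simulate"] or {})
        if seed is not None:
            sim_kwargs["seed"] = seed
        if "oral_sites" not in sim_kwargs:
            sim_kwargs["oral_sites"] = tuple(sites)
        if "shared_species" in sim_kwargs:
            sim_kwargs["shared_species"] = tuple(sim_kwargs["shared_species"])
        sim_kwargs["oral_sites"] = tuple(sim_kwargs["oral_sites"])
        try:
            sim_config = SimConfig(**sim_kwargs)
            cohort: SyntheticCohort = generate_cohort(sim_config)
        except (TypeError, ValueError) as exc:
            raise PipelineError(f"synthetic_cohort: {exc}") from exc
        paths = cohort.write(out / "cohort")
        written.extend(Path(p) for p in paths.values())
        table, markers = cohort.abundance, cohort.markers
        run_seed = sim_config.seed
        input_checksums = {k: _sha256(Path(p)) for k, p in paths.items()}
    else:
        inputs = cfg["inputs"]
        for key in ("metadata", "abundance"):
            if key not in inputs:
                raise PipelineError(f"data_model_io: config inputs missing {key!r}")
        try:
            table = load_abundance_table(inputs["abundance"], inputs["metadata"])
            markers = None
            if "markers" in inputs and "marker_map" in inputs:
                markers = load_marker_table(inputs["markers"], inputs["marker_map"])
        except FileNotFoundError:
            raise
        except ValueError as exc:
            raise PipelineError(f"data_model_io: {exc}") from exc
        run_seed = seed
        input_checksums = {
            k: _sha256(Path(v)) for k, v in inputs.items() if Path(str(v)).exists()
        }

    analysis_cfg = AnalysisConfig(**(cfg.get("analysis") or {}))
    strains_cfg = dict(cfg.get("strains") or {})
    species_list = list(strains_cfg.get("species", DEFAULT_SPECIES))
    coverage_min = float(strains_cfg.get("coverage_min", DEFAULT_COVERAGE_MIN))
    presence_thr = float(strains_cfg.get("marker_presence_threshold", 0.0))

    # --- stage: per-site overlap analysis ---
    pairs_by_site: dict[str, SamplePairSet] = {}
    species_by_site: dict[str, list[str]] = {}
    results_by_site: dict[str, list[OverlapResult]] = {}
    distances: dict[str, pd.DataFrame] = {}
    for site in sites:
        try:
            pairs = build_sample_pairs(table, site)
        except ValueError as exc:
            raise PipelineError(f"data_model_io: {exc}") from exc
        pairs_by_site[site] = pairs
        if not pairs.pairs:
            logger.warning("site %s: no stool/oral pairs; skipped", site)
            species_by_site[site] = []
            results_by_site[site] = []
            continue
        try:
            overlapping = find_overlapping_species(table, pairs, analysis_cfg)
            results = compare_niche_abundances(table, pairs, overlapping, analysis_cfg)
        except ValueError as exc:
            raise PipelineError(f"overlap_analysis: {exc}") from exc
        species_by_site[site] = overlapping
        results_by_site[site] = results
        site_dir = out / site
        frame = results_frame(results)
        _write_tsv(
            frame[["species", "n_pairs", "n_overlapping_pairs", "overlap_frequency"]]
            if not frame.empty
            else pd.DataFrame(
                columns=["species", "n_pairs", "n_overlapping_pairs", "overlap_frequency"]
            ),
            site_dir / "overlapping_species.tsv",
            written,
        )
        _write_tsv(frame, site_dir / "abundance_comparison.tsv", written)
        dm = _bray_curtis_matrix(table, pairs)
        distances[site] = dm
        dm_out = dm.reset_index().rename(columns={"index": "sample_id"})
        _write_tsv(dm_out, site_dir / "bray_curtis.tsv", written)
        logger.info(
            "site %s: %d pairs, %d overlapping species", site, len(pairs), len(overlapping)
        )

    # --- stage: strain inference ---
    calls: list[StrainCall] = []
    n_consistent = 0
    if markers is not None and not markers.entries.empty:
        try:
            calls = call_shared_strains(
                markers, table.meta, species_list, coverage_min, presence_thr
            )
        except ValueError as exc:
            raise PipelineError(f"strain_inference: {exc}") from exc
        n_consistent = count_consistent_individuals(calls)
        _write_tsv(calls_frame(calls), out / "strain_calls.tsv", written)
        for sp in species_list:
            if sp not in set(markers.species):
                continue
            sp_markers = set(markers.markers_for(sp))
            entries_sp = markers.entries[markers.entries["marker_id"].isin(sp_markers)]
            cands = sorted(set(entries_sp["sample_id"]) & set(table.meta.index))
            pats = _eligible_from_entries(
                entries_sp, markers.markers_for(sp), cands, sp,
                coverage_min, presence_thr,
            )
            if not pats:
                continue
            mat = pattern_matrix(pats, markers)
            # columns grouped by subject, stool first within subject
            order = sorted(
                mat.columns,
                key=lambda sid: (
                    str(table.meta.at[sid, "subject_id"]),
                    str(table.meta.at[sid, "body_site"]) != "stool",
                    sid,
                ),
            )
            mat = mat[order]
            _write_tsv(
                mat.reset_index().rename(columns={"index": "marker_id"}),
                out / f"marker_patterns_{sp}.tsv",
                written,
            )
        logger.info("strain inference: %d consistent individuals", n_consistent)
    else:
        logger.warning("no marker table supplied; strain inference skipped")

    manifest = {
        "config_hash": _config_hash(cfg),
        "seed": run_seed,
        "input_checksums": input_checksums,
        "oral_sites": sites,
        "n_pairs": {s: len(p) for s, p in pairs_by_site.items()},
        "n_overlapping_species": {s: len(v) for s, v in species_by_site.items()},
        "n_consistent_individuals": n_consistent,
        "package_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(manifest_path)

    return ReportBundle(
        pairs=pairs_by_site,
        overlapping_species=species_by_site,
        overlap_results=results_by_site,
        strain_calls=calls,
        n_consistent_individuals=n_consistent,
        distances=distances,
        manifest=manifest,
        output_dir=out,
        written=written,
    )


def _bray_curtis_matrix(table: AbundanceTable, pairs: SamplePairSet) -> pd.DataFrame:
    """Bray–Curtis distances among all samples of a pair set, in sorted
    sample order (deterministic)."""
    mat = table.matrix(sorted(set(pairs.all_sample_ids)))
    x = mat.to_numpy().T
    dm = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(dm, index=mat.columns, columns=mat.columns)
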