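"""End-to-end orchestration: filter -> log2 -> normalize -> impute -> enrich.

A single nested YAML config drives each run; outputs are plain TSV/JSON under
one output directory, with a manifest recording the config hash, seed, stage
row counts and package version.  Outputs contain no timestamps, so a rerun
with the same config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrichment import compare_groups, top_hits
from .imputation import impute
from .md_metrics import MetricSpec, default_metric_specs, metric_series
from .normalization import apply_factors, estimate_factors, pairwise_modes
from .quant_io import (
    ProteinQuantTable,
    SampleDesign,
    filter_quantifiable,
    log2_transform,
    read_protein_table,
    read_sample_design,
    write_protein_table,
)
from .screen import classify_hits, rank_screen, read_screen_table
from .synthetic import LfqSimConfig, TrajSimConfig, generate_lfq_dataset, generate_toy_trajectory
from .trajectory import read_multimodel_pdb, write_multimodel_pdb

logger = logging.getLogger(__name__)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


_PULLDOWN_CONFIG_KEYS = (
    "seed", "inputs", "filters", "normalization", "imputation", "enrichment",
)


def _config_hash(config: dict, keys: tuple[str, ...] | None = None) -> str:
    if keys is not None:
        config = {k: config[k] for k in keys if k in config}
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g",
              index=index_label is not None, index_label=index_label)


class _StageTimer:
    def __init__(self, stage: str):
        self.stage = stage

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: start", self.stage)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc_type is None:
            logger.info("stage %s: done in %.2f s", self.stage, dt)
        else:
            logger.error("stage %s: failed after %.2f s", self.stage, dt)
        return False


def run_pulldown_analysis(
    config: dict,
    outdir: str | Path,
    table: ProteinQuantTable | None = None,
    design: SampleDesign | None = None,
) -> dict:
    """Run the pull-down quantification pipeline and write its result bundle.

    ``config`` keys (all optional unless inputs are not passed in memory):
    ``inputs`` (table, design paths, dialect), ``filters`` (min_peptides),
    ``normalization`` (min_shared, enabled), ``imputation`` (shift_sd,
    scale_sd), ``enrichment`` (baits, control, top_n, min_log2fc, max_q),
    ``seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    inputs = config.get("inputs", {})
    enrich_cfg = config.get("enrichment", {})
    control = enrich_cfg.get("control")
    baits = enrich_cfg.get("baits")

    if table is None:
        with _StageTimer("read"):
            table = read_protein_table(
                inputs["table"], dialect=inputs.get("dialect", "fragpipe_combined")
            )
    if design is None:
        design = read_sample_design(inputs["design"])
    if baits is None:
        groups = design.groups
        control = control or groups[0]
        baits = [g for g in groups if g != control]
    if control is None or control not in design.groups:
        raise ValueError(f"control group {control!r} not in design {design.groups}")
    for bait in baits:
        if bait not in design.groups:
            raise ValueError(f"bait group {bait!r} not in design {design.groups}")

    counts = {"input": table.n_proteins}
    with _StageTimer("filter"):
        min_pep = int(config.get("filters", {}).get("min_peptides", 2))
        filtered = filter_quantifiable(table, min_peptides=min_pep)
    counts["filtered"] = filtered.n_proteins
    write_protein_table(filtered, outdir / "filtered_table.tsv")

    with _StageTimer("normalize"):
        log2 = log2_transform(filtered)
        norm_cfg = config.get("normalization", {})
        if norm_cfg.get("enabled", True):
            modes = pairwise_modes(log2, min_shared=int(norm_cfg.get("min_shared", 30)))
            factors = estimate_factors(modes)
            normalized = apply_factors(log2, factors)
            pd.DataFrame(
                {"factor": factors.factors}
            ).to_csv(outdir / "normalization_factors.tsv", sep="\t",
                     index_label="sample_id", float_format="%.10g")
        else:
            factors = None
            normalized = log2

    with _StageTimer("impute"):
        imp_cfg = config.get("imputation", {})
        imputed, mask = impute(
            normalized,
            shift_sd=float(imp_cfg.get("shift_sd", 1.8)),
            scale_sd=float(imp_cfg.get("scale_sd", 0.3)),
            seed=seed,
            allow_raw=not config.get("normalization", {}).get("enabled", True),
        )
    _write_tsv(imputed.values, outdir / "imputed_matrix.tsv", index_label="protein_id")
    _write_tsv(mask.astype(int), outdir / "imputed_mask.tsv", index_label="protein_id")

    observed_mask = ~mask
    results = {}
    with _StageTimer("enrich"):
        for bait in baits:
            enr = compare_groups(imputed, design, bait, control, observed_mask=observed_mask)
            enr["gene"] = filtered.meta["gene"]
            hits = top_hits(
                enr,
                n=int(enrich_cfg.get("top_n", 20)),
                min_log2fc=float(enrich_cfg.get("min_log2fc", 1.0)),
                max_q=float(enrich_cfg.get("max_q", 0.05)),
            )
            _write_tsv(enr, outdir / f"enrichment_{bait}_vs_{control}.tsv",
                       index_label="protein_id")
            _write_tsv(hits, outdir / f"top_hits_{bait}_vs_{control}.tsv",
                       index_label="protein_id")
            results[bait] = {"enrichment": enr, "top_hits": hits}
    counts.update({f"hits_{b}": len(r["top_hits"]) for b, r in results.items()})

    manifest = {
        "tool": "receptorkit",
        "version": __version__,
        "config_hash": _config_hash(config, _PULLDOWN_CONFIG_KEYS),
        "seed": seed,
        "rng": "numpy default_rng (PCG64)",
        "stage_counts": counts,
        "baits": list(baits),
        "control": control,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {
        "table": filtered,
        "factors": factors,
        "imputed": imputed,
        "mask": mask,
        "enrichment": results,
        "manifest": manifest,
    }


_METRIC_BUILDERS = {
    "hbond_count": MetricSpec.hbond,
    "insertion_depth": MetricSpec.insertion,
    "pocket_distance": MetricSpec.pocket,
}


def _specs_from_config(md_cfg: dict) -> list[MetricSpec]:
    raw = md_cfg.get("metrics")
    if raw is None:
        return default_metric_specs()
    specs = []
    for entry in raw:
        entry = dict(entry)
        name = entry.pop("metric")
        builder = _METRIC_BUILDERS.get(name)
        if builder is None:
            raise ValueError(f"unknown metric {name!r}")
        entry = {k: tuple(v) if isinstance(v, list) else v for k, v in entry.items()}
        specs.append(builder(**entry))
    return specs


def run_md_analysis(config: dict, outdir: str | Path) -> dict:
    """Evaluate interface metrics for each configured trajectory.

    Writes one ``<traj>_<metric>.tsv`` series per (trajectory, metric) and a
    ``md_summary.tsv`` with mean, min and the fraction of frames with a
    count >= 1 for h-bond metrics.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    md_cfg = config.get("md", {})
    specs = _specs_from_config(md_cfg)
    if not specs:
        warnings.warn("empty metric spec list; writing summary only", stacklevel=2)
    stride = float(md_cfg.get("stride_ns", 1.0))
    rows, bundle = [], {}
    for traj_path in md_cfg.get("trajectories", []):
        traj_path = Path(traj_path)
        with _StageTimer(f"md:{traj_path.name}"):
            traj = read_multimodel_pdb(traj_path, frame_dt_ns=float(md_cfg.get("frame_dt_ns", 1.0)))
            for spec in specs:
                series = metric_series(traj, spec, stride_ns=stride)
                out = outdir / f"{traj_path.stem}_{spec.metric}.tsv"
                series.to_tsv(out)
                rows.append(
                    {
                        "trajectory": traj_path.stem,
                        "metric": spec.metric,
                        "mean": float(series.values.mean()),
                        "min": float(series.values.min()),
                        "frac_frames_ge1": float((series.values >= 1).mean()),
                        "n_frames": len(series.values),
                    }
                )
                bundle[(traj_path.stem, spec.metric)] = series
    summary = pd.DataFrame(
        rows, columns=["trajectory", "metric", "mean", "min", "frac_frames_ge1", "n_frames"]
    )
    _write_tsv(summary, outdir / "md_summary.tsv")
    return {"summary": summary, "series": bundle}


def run_screen_analysis(config: dict, outdir: str | Path) -> pd.DataFrame:
    """Classify and rank an ipTM screen table; writes ``screen_ranked.tsv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    screen_cfg = config.get("screen", {})
    records = read_screen_table(screen_cfg["table"])
    ranked = rank_screen(
        classify_hits(records, threshold=float(screen_cfg.get("threshold", 0.5)))
    )
    _write_tsv(ranked, outdir / "screen_ranked.tsv")
    return ranked


def run_all(config: dict, outdir: str | Path) -> dict:
    """Simulate (if configured) then run every analysis stage under one root.

    With a ``simulate`` section, synthetic LFQ tables and a toy trajectory
    are generated from ``seed`` and fed to the downstream stages; otherwise
    the ``inputs``/``md``/``screen`` sections must name real files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    config = dict(config)
    config.setdefault("seed", seed)
    results: dict = {}

    sim_cfg = config.get("simulate")
    table = design = None
    if sim_cfg is not None:
        with _StageTimer("simulate"):
            lfq_kwargs = dict(sim_cfg.get("lfq", {}))
            lfq_kwargs.setdefault("seed", seed)
            table, design, truth = generate_lfq_dataset(LfqSimConfig(**lfq_kwargs))
            sim_dir = outdir / "simulated"
            sim_dir.mkdir(exist_ok=True)
            write_protein_table(table, sim_dir / "lfq_table.tsv")
            _write_tsv(
                pd.DataFrame({"true_factor": truth.true_factors}),
                sim_dir / "true_factors.tsv", index_label="sample_id",
            )
            (sim_dir / "spiked_ids.txt").write_text(
                "\n".join(sorted(truth.spiked_ids)) + "\n"
            )
            traj_kwargs = dict(sim_cfg.get("trajectory", {}))
            traj_kwargs.setdefault("seed", seed)
            traj, _ = generate_toy_trajectory(TrajSimConfig(**traj_kwargs))
            traj_path = sim_dir / "toy_trajectory.pdb"
            write_multimodel_pdb(traj, traj_path)
            config.setdefault("md", {})["trajectories"] = [str(traj_path)]
            results["ground_truth"] = truth

    results["pulldown"] = run_pulldown_analysis(
        config, outdir / "pulldown", table=table, design=design
    )
    if config.get("md", {}).get("trajectories"):
        results["md"] = run_md_analysis(config, outdir / "md")
    if config.get("screen", {}).get("table"):
        results["screen"] = run_screen_analysis(config, outdir / "screen")
    return results
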