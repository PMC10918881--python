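"""End-to-end orchestration: read/filter -> networks -> metrics -> comparisons.

A run is driven by a plain dict config (YAML on disk). Outputs are CSV/TSV
bundles plus a resolved config and a per-stage count log, all deterministic
for a fixed config and seed (logs carry no timestamps for that reason).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import compare, io, metrics, network, simulate
from .types import RepertoireSample

DEFAULT_CONFIG: dict = {
    "mode": "simulate",  # simulate | bulk | single_cell
    "seed": 1,
    "out_dir": "bcrnet_run",
    "inputs": {"bulk_reports": [], "contigs": None, "metadata": None},
    "simulate": {
        "n_patients": 4,
        "n_chains": 400,
        "tissues": ["SG_labial", "SG_parotid"],
        "cluster_enrichment": 4.0,
    },
    "network": {"d_min": 0, "d_max": 3},
    "metrics": {"weight": "read_count", "scale": "log_total"},
    "compare": {
        "n_downsample": 1000,
        "n_replicates": 5,
        "metrics": [
            "total_igh_count",
            "adjusted_shannon",
            "usage_IGHA2",
            "usage_IGHG1",
            "kappa_lambda_ratio",
        ],
        "essdai_metrics": ["kappa_lambda_ratio", "adjusted_shannon"],
    },
}


def merge_config(overrides: Optional[dict] = None) -> dict:
    """Defaults overlaid with user overrides (one level of nesting)."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for key, value in (overrides or {}).items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def validate_config(cfg: dict) -> list[str]:
    """All constraint violations in the config; empty list means valid.

    Reporting only — never executes any pipeline stage.
    """
    problems: list[str] = []
    mode = cfg.get("mode")
    if mode not in ("simulate", "bulk", "single_cell"):
        problems.append(f"mode must be simulate|bulk|single_cell, got {mode!r}")
    net = cfg.get("network", {})
    d_min, d_max = net.get("d_min", 0), net.get("d_max", 3)
    if d_min > d_max:
        problems.append(f"network.d_min ({d_min}) > network.d_max ({d_max})")
    comp = cfg.get("compare", {})
    if comp.get("n_replicates", 5) < 2:
        problems.append("compare.n_replicates must be >= 2 for a t-test")
    if comp.get("n_downsample", 1000) < 2:
        problems.append("compare.n_downsample must be >= 2")
    if mode == "bulk" and not cfg.get("inputs", {}).get("bulk_reports"):
        problems.append("mode=bulk requires inputs.bulk_reports")
    if mode == "single_cell" and not cfg.get("inputs", {}).get("contigs"):
        problems.append("mode=single_cell requires inputs.contigs")
    if mode in ("bulk", "single_cell"):
        meta = cfg.get("inputs", {}).get("metadata")
        if meta and not Path(meta).exists():
            problems.append(f"inputs.metadata does not exist: {meta}")
        for path in cfg.get("inputs", {}).get("bulk_reports") or []:
            if not Path(path).exists():
                problems.append(f"input path does not exist: {path}")
        contigs = cfg.get("inputs", {}).get("contigs")
        if mode == "single_cell" and contigs and not Path(contigs).exists():
            problems.append(f"input path does not exist: {contigs}")
    scale = cfg.get("metrics", {}).get("scale", "log_total")
    if scale not in ("log_total", "total"):
        problems.append(f"metrics.scale must be log_total|total, got {scale!r}")
    return problems


def run(cfg: dict) -> dict:
    """Execute the configured pipeline; returns {stage: output path}.

    Raises ValueError before any stage runs if the config is invalid.
    """
    cfg = merge_config(cfg)
    problems = validate_config(cfg)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))

    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    outputs: dict[str, str] = {}
    seed = int(cfg["seed"])

    samples = _load_samples(cfg, out, log, outputs)
    log.append(f"samples loaded: {len(samples)}")

    # filtered chains as one AIRR table
    airr_path = out / "chains.airr.tsv"
    all_chains = [c for s in samples for c in s.iter_chains()]
    io.write_airr(all_chains, airr_path)
    outputs["airr"] = str(airr_path)
    log.append(f"chains written to AIRR table: {len(all_chains)}")

    # metrics
    mcfg = cfg["metrics"]
    table = metrics.metrics_table(samples, weight=mcfg["weight"], scale=mcfg["scale"])
    table_path = out / "metrics.csv"
    table.to_csv(table_path, index=False)
    outputs["metrics"] = str(table_path)
    log.append(f"metrics rows: {len(table)}")

    # example network on the first pSS sample's heavy chains
    ncfg = cfg["network"]
    pss = [s for s in samples if s.group == "pSS"] or samples
    pool0 = compare.unique_cdr3_pool(pss[:1])
    net = network.build_network(
        pool0, mode="single_chain", d_min=ncfg["d_min"], d_max=ncfg["d_max"]
    )
    retained = network.retain_connected(net)
    network.export_network(retained, out / "network_edges.csv", out / "network_nodes.csv")
    _, avg_cc = network.clustering_coefficients(retained)
    stats = {
        "sample_id": pss[0].sample_id,
        "nodes_total": net.number_of_nodes(),
        "nodes_retained": retained.number_of_nodes(),
        "edges": retained.number_of_edges(),
        "avg_clustering_coefficient": avg_cc,
    }
    (out / "network_stats.json").write_text(json.dumps(stats, indent=2, sort_keys=True) + "\n")
    outputs["network"] = str(out / "network_edges.csv")
    log.append(
        f"network ({pss[0].sample_id}): {stats['nodes_retained']} connected of "
        f"{stats['nodes_total']} nodes, {stats['edges']} edges"
    )

    # group comparisons
    ccfg = cfg["compare"]
    pool_ctrl = compare.unique_cdr3_pool([s for s in samples if s.group == "control"])
    pool_pss = compare.unique_cdr3_pool([s for s in samples if s.group == "pSS"])
    if (
        len(pool_ctrl) >= ccfg["n_downsample"]
        and len(pool_pss) >= ccfg["n_downsample"]
    ):
        ds = compare.downsample_network_test(
            pool_ctrl,
            pool_pss,
            n_downsample=ccfg["n_downsample"],
            n_replicates=ccfg["n_replicates"],
            seed=seed,
            d_max=ncfg["d_max"],
        )
        ds["replicates"].to_csv(out / "downsample_replicates.csv", index=False)
        ds["tests"].to_csv(out / "downsample_tests.csv", index=False)
        outputs["downsample"] = str(out / "downsample_tests.csv")
        log.append(f"downsample comparison: {ccfg['n_replicates']} replicates "
                   f"x {ccfg['n_downsample']} sequences per group")
    else:
        log.append("downsample comparison skipped: pools smaller than n_downsample")

    tt = [
        compare.group_ttest(table, m)
        for m in ccfg["metrics"]
        if m in table.columns
    ]
    tt_frames = [t for t in tt if len(t)]
    if tt_frames:
        ttests = pd.concat(tt_frames, ignore_index=True)
        ttests.to_csv(out / "group_ttests.csv", index=False)
        outputs["ttests"] = str(out / "group_ttests.csv")
        log.append(f"group t-tests: {len(ttests)} strata x metrics")

    corr_frames = [
        compare.essdai_correlation(table, m)
        for m in ccfg["essdai_metrics"]
        if m in table.columns
    ]
    corr_frames = [c for c in corr_frames if len(c)]
    if corr_frames:
        corrs = pd.concat(corr_frames, ignore_index=True)
        corrs.to_csv(out / "essdai_correlations.csv", index=False)
        outputs["correlations"] = str(out / "essdai_correlations.csv")
        log.append(f"ESSDAI correlations: {len(corrs)} strata x metrics")

    sharing = compare.paired_tissue_sharing(samples)
    if len(sharing):
        sharing.to_csv(out / "tissue_sharing.csv", index=False)
        outputs["sharing"] = str(out / "tissue_sharing.csv")
        log.append(f"paired tissue sharing rows: {len(sharing)}")

    # resolved config is written alongside the outputs, so record the
    # output location relative to itself — runs differing only in out_dir
    # produce byte-identical bundles
    resolved = dict(cfg, out_dir=".")
    (out / "config.resolved.yaml").write_text(yaml.safe_dump(resolved, sort_keys=True))
    (out / "run.log").write_text("\n".join(log) + "\n")
    outputs["log"] = str(out / "run.log")
    return outputs


def _load_samples(cfg: dict, out: Path, log: list[str], outputs: dict) -> list[RepertoireSample]:
    mode = cfg["mode"]
    if mode == "simulate":
        scfg = cfg["simulate"]
        sim = simulate.SimConfig(
            n_patients=int(scfg["n_patients"]),
            n_chains=int(scfg["n_chains"]),
            tissues=tuple(scfg["tissues"]),
            seed=int(cfg["seed"]),
        )
        cases, controls = simulate.plant_case_control(
            sim, float(scfg["cluster_enrichment"])
        )
        samples = cases + controls
        raw = out / "raw"
        raw.mkdir(exist_ok=True)
        for s in samples:
            simulate.write_trust4_report(s, raw / f"{s.sample_id}.tsv")
        simulate.write_metadata(samples, raw / "metadata.csv")
        log.append(f"simulated {len(cases)} case and {len(controls)} control samples")
        # exercise the real reader path on the emitted files
        meta = io.read_metadata(raw / "metadata.csv")
        samples = [
            io.read_bulk_report(raw / f"{s.sample_id}.tsv", metadata=meta)
            for s in samples
        ]
        outputs["raw"] = str(raw)
        return samples
    meta = None
    meta_path = cfg["inputs"].get("metadata")
    if meta_path:
        meta = io.read_metadata(meta_path)
    if mode == "bulk":
        return [
            io.read_bulk_report(p, metadata=meta) for p in cfg["inputs"]["bulk_reports"]
        ]
    cells = io.read_sc_contigs(cfg["inputs"]["contigs"], metadata=meta)
    by_sample: dict[str, list] = {}
    for cell in cells:
        by_sample.setdefault(cell.heavy.sample_id, []).append(cell)
    samples = []
    for sid in sorted(by_sample):
        group_cells = by_sample[sid]
        first = group_cells[0]
        ann = (
            meta.loc[sid]
            if meta is not None and sid in meta.index
            else {"group": "control", "essdai": float("nan")}
        )
        essdai = ann.get("essdai")
        samples.append(
            RepertoireSample(
                sample_id=sid,
                patient=first.patient,
                tissue=first.tissue,
                group=str(ann.get("group", "control")),
                essdai=None if pd.isna(essdai) else float(essdai),
                cells=group_cells,
            )
        )
    return samples
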