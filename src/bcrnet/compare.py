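"""Comparative statistics between patient groups.

* the replicated downsampled-network comparison: repeatedly draw equal
  numbers of unique CDR3aa sequences from the pooled case and control
  repertoires, build the distance <= 3 similarity network on each draw,
  and compare connected-node counts and average clustering coefficients
  between groups with a two-tailed t-test;
* per-tissue two-tailed t-tests of per-sample metrics (pSS vs control),
  Welch form by default, with N.S. labelling at p > 0.05;
* Pearson correlation of per-sample metrics with the ESSDAI
  disease-activity score, restricted to pSS samples;
* per-patient labial-parotid repertoire sharing (Morisita-Horn) and
  adjusted-Shannon differences per chain locus.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import adjusted_shannon, cdr3_counts, morisita_horn
from .network import build_network, clustering_coefficients, connected_node_count
from .types import RepertoireSample

__all__ = [
    "unique_cdr3_pool",
    "downsample_network_test",
    "group_ttest",
    "essdai_correlation",
    "paired_tissue_sharing",
]


def unique_cdr3_pool(
    samples: Iterable[RepertoireSample], locus: str = "IGH"
) -> list[str]:
    """Pooled unique CDR3aa sequences across samples, first-seen order."""
    seen: dict[str, None] = {}
    for sample in samples:
        for chain in sample.iter_chains():
            if chain.locus == locus:
                seen.setdefault(chain.cdr3_aa, None)
    return list(seen)


def downsample_network_test(
    pool_a: Sequence[str],
    pool_b: Sequence[str],
    n_downsample: int = 5000,
    n_replicates: int = 5,
    seed: int = 0,
    d_max: int = 3,
    labels: tuple[str, str] = ("control", "pSS"),
    equal_var: bool = False,
) -> dict:
    """Replicated equal-depth network comparison of two sequence pools.

    For each replicate and group, ``n_downsample`` unique sequences are
    drawn without replacement (replicate i uses seed ``seed + i``), the
    distance <= ``d_max`` network is built on unique-sequence nodes, and
    the connected node count (degree >= 1) and average clustering
    coefficient are recorded. Groups are compared metric-wise with a
    two-tailed t-test across replicates.

    Returns a dict with ``replicates`` (tidy DataFrame) and ``tests``
    (DataFrame: metric, t, p, group means).
    """
    pool_a, pool_b = list(dict.fromkeys(pool_a)), list(dict.fromkeys(pool_b))
    for label, pool in zip(labels, (pool_a, pool_b)):
        if len(pool) < n_downsample:
            raise ValueError(
                f"group {label!r} pool has {len(pool)} unique sequences, "
                f"fewer than n_downsample={n_downsample}; lower n_downsample "
                "uniformly across groups"
            )
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2 for a t-test")

    rows = []
    for rep in range(n_replicates):
        rng = np.random.default_rng(seed + rep)
        for label, pool in zip(labels, (pool_a, pool_b)):
            idx = rng.choice(len(pool), size=n_downsample, replace=False)
            draw = [pool[i] for i in idx]
            net = build_network(draw, mode="single_chain", d_min=0, d_max=d_max)
            _, avg_cc = clustering_coefficients(net)
            rows.append(
                {
                    "replicate": rep,
                    "group": label,
                    "connected_nodes": connected_node_count(net),
                    "avg_clustering_coefficient": avg_cc,
                }
            )
    replicates = pd.DataFrame(rows)

    tests = []
    for metric in ("connected_nodes", "avg_clustering_coefficient"):
        a = replicates.loc[replicates["group"] == labels[0], metric].to_numpy(float)
        b = replicates.loc[replicates["group"] == labels[1], metric].to_numpy(float)
        t, p = _ttest(a, b, equal_var=equal_var)
        tests.append(
            {
                "metric": metric,
                f"mean_{labels[0]}": a.mean(),
                f"mean_{labels[1]}": b.mean(),
                "t": t,
                "p": p,
                "label": _ns_label(p),
            }
        )
    return {"replicates": replicates, "tests": pd.DataFrame(tests)}


def _ttest(a: np.ndarray, b: np.ndarray, equal_var: bool = False) -> tuple[float, float]:
    if np.std(a) == 0 and np.std(b) == 0 and np.mean(a) == np.mean(b):
        return 0.0, 1.0
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def _ns_label(p: float) -> str:
    if not np.isfinite(p):
        return "undefined"
    return "N.S." if p > 0.05 else f"p={p:.3g}"


def group_ttest(
    metrics: pd.DataFrame,
    metric: str,
    strata: str = "tissue",
    group_col: str = "group",
    groups: tuple[str, str] = ("pSS", "control"),
    equal_var: bool = False,
) -> pd.DataFrame:
    """Two-tailed t-test of a per-sample metric between groups, within
    each stratum (tissue). Strata with <2 samples in either group are
    skipped with a warning. Welch form by default."""
    rows = []
    for stratum, sub in metrics.groupby(strata, sort=True):
        a = sub.loc[sub[group_col] == groups[0], metric].dropna().to_numpy(float)
        b = sub.loc[sub[group_col] == groups[1], metric].dropna().to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            warnings.warn(
                f"stratum {stratum!r}: fewer than 2 samples per group; skipped"
            )
            continue
        t, p = _ttest(a, b, equal_var=equal_var)
        rows.append(
            {
                "stratum": stratum,
                "metric": metric,
                f"n_{groups[0]}": len(a),
                f"n_{groups[1]}": len(b),
                f"mean_{groups[0]}": a.mean(),
                f"mean_{groups[1]}": b.mean(),
                "t": t,
                "p": p,
                "label": _ns_label(p),
            }
        )
    return pd.DataFrame(rows)


def essdai_correlation(
    metrics: pd.DataFrame,
    metric: str,
    strata: str = "tissue",
    group: str = "pSS",
) -> pd.DataFrame:
    """Pearson correlation of a per-sample metric with ESSDAI per tissue.

    Non-pSS samples are excluded; samples missing either the metric or
    the score are dropped pairwise. Correlations on fewer than 3 samples
    are reported undefined (NaN) with a warning.
    """
    sub = metrics[metrics["group"] == group]
    rows = []
    for stratum, grp in sub.groupby(strata, sort=True):
        pair = grp[[metric, "essdai"]].dropna()
        n = len(pair)
        if n < 3:
            warnings.warn(f"stratum {stratum!r}: only {n} usable samples; r undefined")
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(pair[metric], pair["essdai"])
        rows.append(
            {"stratum": stratum, "metric": metric, "r": float(r), "p": float(p), "n": n}
        )
    return pd.DataFrame(rows)


def paired_tissue_sharing(
    samples: Sequence[RepertoireSample],
    tissue_a: str = "SG_labial",
    tissue_b: str = "SG_parotid",
    weight: str = "read_count",
    scale: str = "log_total",
    loci: tuple[str, ...] = ("IGH", "IGK", "IGL"),
) -> pd.DataFrame:
    """Per-patient repertoire sharing between two tissues.

    For every patient with both tissues present, computes per chain
    locus the Morisita-Horn similarity of the CDR3aa compositions and
    the absolute difference in adjusted Shannon diversity. Patients with
    only one tissue are skipped with a warning.
    """
    by_patient: dict[str, dict[str, RepertoireSample]] = {}
    for s in samples:
        if s.tissue in (tissue_a, tissue_b):
            by_patient.setdefault(s.patient, {})[s.tissue] = s
    rows = []
    for patient in sorted(by_patient):
        pair = by_patient[patient]
        if tissue_a not in pair or tissue_b not in pair:
            warnings.warn(f"patient {patient!r}: unpaired tissues; skipped")
            continue
        sa, sb = pair[tissue_a], pair[tissue_b]
        for locus in loci:
            xa = cdr3_counts(sa.iter_chains(), locus, weight)
            xb = cdr3_counts(sb.iter_chains(), locus, weight)
            if not xa or not xb:
                warnings.warn(f"patient {patient!r} locus {locus}: empty repertoire; skipped")
                continue
            mhs = morisita_horn(xa, xb)
            delta = np.nan
            if sum(xa.values()) >= 2 and sum(xb.values()) >= 2:
                delta = abs(adjusted_shannon(xa, scale) - adjusted_shannon(xb, scale))
            rows.append(
                {
                    "patient": patient,
                    "group": sa.group,
                    "locus": locus,
                    "mhs": mhs,
                    "d_adjusted_shannon": delta,
                }
            )
    return pd.DataFrame(rows, columns=["patient", "group", "locus", "mhs", "d_adjusted_shannon"])
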