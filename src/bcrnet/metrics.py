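"""Per-sample repertoire statistics.

Chain counts, clonotype sizes, Shannon diversity and its count-adjusted
form, Morisita-Horn repertoire overlap, isotype usage fractions, and the
kappa-lambda light-chain usage ratio.

Diversity is computed on CDR3 amino-acid identity by default (each
distinct CDR3aa is one category, with read-count weights in bulk mode).
The adjusted Shannon divides the raw entropy H by ln(N), N the total
(weighted) chain count, yielding a [0, 1] evenness-like quantity that is
comparable across samples of very different sequencing depth; dividing by
raw N is available as an alternative scale factor.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import ISOTYPES, BCell, ChainRecord, RepertoireSample

__all__ = [
    "clone_sizes",
    "shannon",
    "adjusted_shannon",
    "morisita_horn",
    "isotype_usage",
    "kappa_lambda_ratio",
    "cdr3_counts",
    "metrics_table",
]


def clone_sizes(cells: Sequence[BCell], definition: str = "paired_cdr3") -> dict[str, int]:
    """Clone-size tally over single cells.

    ``definition="paired_cdr3"`` groups cells by identical paired
    (heavy, light) CDR3aa; ``"clone_id"`` trusts the upstream clonotype
    label. Sizes sum to the cell count.
    """
    if definition not in ("paired_cdr3", "clone_id"):
        raise ValueError(f"unknown clonotype definition {definition!r}")
    sizes: Counter[str] = Counter()
    for cell in cells:
        if definition == "paired_cdr3":
            key = f"{cell.heavy.cdr3_aa}|{cell.light.cdr3_aa}"
        else:
            key = cell.clone_id
        sizes[key] += 1
    return dict(sizes)


def shannon(counts: Mapping[str, float] | Sequence[float]) -> float:
    """Shannon entropy H = -sum p_i ln p_i (nats) over clonotype counts.

    Zero-count categories are ignored; an all-zero tally is an error.
    """
    values = np.asarray(
        list(counts.values()) if isinstance(counts, Mapping) else list(counts), dtype=float
    )
    if np.any(values < 0):
        raise ValueError("counts must be nonnegative")
    values = values[values > 0]
    if values.size == 0:
        raise ValueError("shannon requires at least one positive count")
    p = values / values.sum()
    return float(-(p * np.log(p)).sum())


def adjusted_shannon(
    counts: Mapping[str, float] | Sequence[float], scale: str = "log_total"
) -> float:
    """Count-adjusted Shannon diversity: H divided by a scale factor for
    the total count N (default ln N; ``scale="total"`` divides by N)."""
    values = list(counts.values()) if isinstance(counts, Mapping) else list(counts)
    total = float(sum(values))
    if total < 2:
        raise ValueError("adjusted Shannon requires total count >= 2")
    h = shannon(counts)
    if scale == "log_total":
        return h / math.log(total)
    if scale == "total":
        return h / total
    raise ValueError(f"unknown scale rule {scale!r}")


def morisita_horn(x: Mapping[str, float], y: Mapping[str, float]) -> float:
    """Morisita-Horn similarity of two count compositions, in [0, 1].

    MH = 2 sum(x_i y_i) / ((sum x_i^2 / X^2 + sum y_i^2 / Y^2) X Y),
    indexed over the union of categories; invariant to proportional
    rescaling of either composition.
    """
    X = float(sum(x.values()))
    Y = float(sum(y.values()))
    if X <= 0 or Y <= 0:
        raise ValueError("both compositions need a positive total")
    cross = sum(cx * y.get(k, 0.0) for k, cx in x.items())
    dx = sum(v * v for v in x.values()) / (X * X)
    dy = sum(v * v for v in y.values()) / (Y * Y)
    return float(2.0 * cross / ((dx + dy) * X * Y))


def _weight(chain: ChainRecord, weight: str) -> int:
    return chain.read_count if weight == "read_count" else 1


def cdr3_counts(
    chains: Iterable[ChainRecord], locus: str = "IGH", weight: str = "read_count"
) -> dict[str, int]:
    """Weighted CDR3aa tally for one locus — the diversity input."""
    tally: Counter[str] = Counter()
    for chain in chains:
        if chain.locus == locus:
            tally[chain.cdr3_aa] += _weight(chain, weight)
    return dict(tally)


def isotype_usage(
    source: RepertoireSample | Sequence[BCell] | Sequence[ChainRecord],
    weight: str = "read_count",
) -> pd.Series:
    """Isotype usage fractions over the nine IgH classes.

    For a bag of cells the denominator is the cell count (each cell's
    heavy chain votes once); for bulk chains it is the weighted IgH chain
    total. Undetected isotypes report 0; fractions sum to 1.
    """
    if isinstance(source, RepertoireSample):
        chains = list(source.iter_chains())
        if source.cells:
            weight = "record"
    elif source and isinstance(source[0], BCell):
        chains = [c.heavy for c in source]
        weight = "record"
    else:
        chains = list(source)
    tally = {iso: 0.0 for iso in ISOTYPES}
    total = 0.0
    for chain in chains:
        if chain.locus != "IGH":
            continue
        w = _weight(chain, weight)
        total += w
        if chain.isotype in tally:
            tally[chain.isotype] += w
    if total == 0:
        raise ValueError("no IGH chains present")
    return pd.Series({iso: tally[iso] / total for iso in ISOTYPES}, name="usage")


def kappa_lambda_ratio(
    source: RepertoireSample | Sequence[BCell] | Sequence[ChainRecord],
    weight: str = "read_count",
) -> Optional[float]:
    """Weighted kappa/lambda usage ratio; None (missing) when no lambda
    chains are observed; error when no light chains at all."""
    if isinstance(source, RepertoireSample):
        chains = list(source.iter_chains())
        if source.cells:
            weight = "record"
    elif source and isinstance(source[0], BCell):
        chains = [c.light for c in source]
        weight = "record"
    else:
        chains = list(source)
    kappa = sum(_weight(c, weight) for c in chains if c.locus == "IGK")
    lam = sum(_weight(c, weight) for c in chains if c.locus == "IGL")
    if kappa + lam == 0:
        raise ValueError("no light chains present")
    if lam == 0:
        return None
    return kappa / lam


def metrics_table(
    samples: Sequence[RepertoireSample],
    weight: str = "read_count",
    scale: str = "log_total",
) -> pd.DataFrame:
    """One row of derived statistics per sample.

    Columns: sample annotation; weighted chain totals per locus; raw and
    adjusted Shannon diversity of IgH CDR3aa; isotype usage fractions
    (``usage_<ISOTYPE>``); kappa-lambda ratio (NaN when missing).
    """
    rows = []
    for sample in samples:
        chains = list(sample.iter_chains())
        w = "record" if sample.cells else weight
        totals = {
            locus: sum(_weight(c, w) for c in chains if c.locus == locus)
            for locus in ("IGH", "IGK", "IGL")
        }
        row = {
            "sample_id": sample.sample_id,
            "patient": sample.patient,
            "tissue": sample.tissue,
            "group": sample.group,
            "essdai": np.nan if sample.essdai is None else sample.essdai,
            "total_igh_count": totals["IGH"],
            "total_igk_count": totals["IGK"],
            "total_igl_count": totals["IGL"],
        }
        igh = cdr3_counts(chains, "IGH", w)
        row["shannon_H"] = shannon(igh) if igh else np.nan
        row["adjusted_shannon"] = (
            adjusted_shannon(igh, scale) if igh and sum(igh.values()) >= 2 else np.nan
        )
        try:
            usage = isotype_usage(sample, weight=w)
        except ValueError:
            usage = pd.Series({iso: np.nan for iso in ISOTYPES})
        for iso, frac in usage.items():
            row[f"usage_{iso}"] = frac
        try:
            ratio = kappa_lambda_ratio(sample, weight=w)
            row["kappa_lambda_ratio"] = np.nan if ratio is None else ratio
        except ValueError:
            row["kappa_lambda_ratio"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
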