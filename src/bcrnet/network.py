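"""CDR3 similarity networks.

Nodes are B cells (single-cell mode; identical sequences on distinct
cells are distinct nodes) or unique CDR3 amino-acid sequences (bulk /
downsampled mode). Two nodes are joined when the Levenshtein distance
between their CDR3aa strings falls inside ``[d_min, d_max]`` — the main
single-chain network uses distance < 4 (``d_min=0, d_max=3``), the strict
paired-chain network distance 1..3 on the summed heavy+light distance.

All-pairs search is exact: cheap lower bounds (length difference, and
half the L1 distance between residue-composition vectors — a single
substitution moves the composition by at most 2, an indel by 1) prune the
candidate set, and surviving pairs are verified with a banded edit-distance
computation. Results are identical to the naive O(n^2) scan.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Optional, Sequence, Union

import edlib
import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .types import BCell

__all__ = [
    "levenshtein",
    "build_network",
    "retain_connected",
    "classify_edges",
    "clustering_coefficients",
    "pairwise_distances",
    "export_network",
]

#: collapse map used for the tissue edge classification (PB vs gland)
TISSUE_COLLAPSE = {"PB": "PB", "SG_labial": "SG", "SG_parotid": "SG"}


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insertions, deletions, substitutions)."""
    if a == b:
        return 0
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


def _bounded_levenshtein(a: str, b: str, k: int) -> int:
    """Edit distance if <= k, else -1."""
    if a == b:
        return 0
    if abs(len(a) - len(b)) > k:
        return -1
    return edlib.align(a, b, task="distance", k=k)["editDistance"]


def _composition_matrix(seqs: Sequence[str]) -> np.ndarray:
    """Residue-count vectors; columns indexed over the characters present."""
    vocab = sorted(set(itertools.chain.from_iterable(seqs)))
    index = {ch: i for i, ch in enumerate(vocab)}
    mat = np.zeros((len(seqs), max(len(vocab), 1)), dtype=np.float32)
    for row, seq in enumerate(seqs):
        for ch in seq:
            mat[row, index[ch]] += 1
    return mat


def _candidate_pairs(seqs: Sequence[str], d_max: int, block: int = 512):
    """Yield (i, j) with i < j whose composition/length lower bound <= d_max."""
    n = len(seqs)
    if n < 2:
        return
    comp = _composition_matrix(seqs)
    lengths = np.array([len(s) for s in seqs], dtype=np.int32)
    for start in range(0, n, block):
        stop = min(start + block, n)
        # L1 composition distance of this block against all later sequences
        l1 = cdist(comp[start:stop], comp, metric="cityblock")
        len_diff = np.abs(lengths[start:stop, None] - lengths[None, :])
        bound = np.maximum(np.ceil(l1 / 2.0), len_diff)
        ii, jj = np.nonzero(bound <= d_max)
        for bi, j in zip(ii, jj):
            i = start + int(bi)
            if i < j:
                yield i, int(j)


def pairwise_distances(
    seqs: Sequence[str], d_min: int = 0, d_max: int = 3
) -> list[tuple[int, int, int]]:
    """All index pairs (i<j) of ``seqs`` with d_min <= distance <= d_max."""
    if d_min > d_max:
        raise ValueError(f"d_min ({d_min}) > d_max ({d_max})")
    out = []
    for i, j in _candidate_pairs(seqs, d_max):
        d = _bounded_levenshtein(seqs[i], seqs[j], d_max)
        if d >= d_min:
            out.append((i, j, d))
    return out


def _paired_distances(
    pairs: Sequence[tuple[str, str]], d_min: int, d_max: int
) -> list[tuple[int, int, int]]:
    """Pairs with d_min <= lev(heavy)+lev(light) <= d_max."""
    heavies = [p[0] for p in pairs]
    lights = [p[1] for p in pairs]
    comp_h = _composition_matrix(heavies)
    comp_l = _composition_matrix(lights)
    len_h = np.array([len(s) for s in heavies], dtype=np.int32)
    len_l = np.array([len(s) for s in lights], dtype=np.int32)
    n = len(pairs)
    out = []
    block = 512
    for start in range(0, n, block):
        stop = min(start + block, n)
        lb_h = np.maximum(
            np.ceil(cdist(comp_h[start:stop], comp_h, metric="cityblock") / 2.0),
            np.abs(len_h[start:stop, None] - len_h[None, :]),
        )
        lb_l = np.maximum(
            np.ceil(cdist(comp_l[start:stop], comp_l, metric="cityblock") / 2.0),
            np.abs(len_l[start:stop, None] - len_l[None, :]),
        )
        ii, jj = np.nonzero(lb_h + lb_l <= d_max)
        for bi, j in zip(ii, jj):
            i = start + int(bi)
            if i >= j:
                continue
            dh = _bounded_levenshtein(heavies[i], heavies[j], d_max)
            if dh < 0:
                continue
            dl = _bounded_levenshtein(lights[i], lights[j], d_max - dh)
            if dl < 0:
                continue
            d = dh + dl
            if d_min <= d <= d_max:
                out.append((i, j, d))
    return out


def build_network(
    items: Union[Sequence[str], Sequence[BCell]],
    mode: str = "single_chain",
    d_min: Optional[int] = None,
    d_max: int = 3,
) -> nx.Graph:
    """Build the undirected CDR3 similarity network.

    Parameters
    ----------
    items
        Plain CDR3aa strings (unique-sequence nodes, bulk mode) or
        :class:`BCell` objects (one node per cell).
    mode
        ``"single_chain"`` — distance on the heavy CDR3aa, default bounds
        0..3 (identical sequences from distinct cells are connected);
        ``"paired_strict"`` — distance is the sum of heavy and light
        CDR3aa distances, default bounds 1..3 (identical pairs excluded).
    """
    if mode not in ("single_chain", "paired_strict"):
        raise ValueError(f"unknown mode {mode!r}")
    if d_min is None:
        d_min = 1 if mode == "paired_strict" else 0
    if d_min > d_max:
        raise ValueError(f"d_min ({d_min}) > d_max ({d_max})")

    graph = nx.Graph()
    items = list(items)
    is_cells = bool(items) and isinstance(items[0], BCell)

    for idx, item in enumerate(items):
        if is_cells:
            graph.add_node(
                idx,
                label=item.barcode,
                sequence=item.heavy.cdr3_aa,
                tissue=item.tissue,
                patient=item.patient,
                cell_type=item.cell_type,
                isotype=item.heavy.isotype,
            )
        else:
            graph.add_node(idx, label=str(item), sequence=str(item))
    if not items:
        return graph

    if mode == "paired_strict":
        if not is_cells:
            raise ValueError("paired_strict mode requires BCell items")
        pairs = [(c.heavy.cdr3_aa, c.light.cdr3_aa) for c in items]
        for i, j, d in _paired_distances(pairs, d_min, d_max):
            graph.add_edge(i, j, distance=d)
        return graph

    seqs = [c.heavy.cdr3_aa for c in items] if is_cells else [str(s) for s in items]
    # distances on unique sequences, then expanded to all carrying nodes
    unique: dict[str, list[int]] = {}
    for idx, seq in enumerate(seqs):
        unique.setdefault(seq, []).append(idx)
    uniq_seqs = list(unique)
    for ui, uj, d in pairwise_distances(uniq_seqs, max(d_min, 1), d_max):
        for i in unique[uniq_seqs[ui]]:
            for j in unique[uniq_seqs[uj]]:
                graph.add_edge(i, j, distance=d)
    if d_min == 0:
        for members in unique.values():
            for i, j in itertools.combinations(members, 2):
                graph.add_edge(i, j, distance=0)
    return graph


def retain_connected(graph: nx.Graph) -> nx.Graph:
    """Subgraph of nodes with at least one connection; edges unchanged."""
    keep = [n for n in graph.nodes if graph.degree(n) >= 1]
    return graph.subgraph(keep).copy()


def classify_edges(
    graph: nx.Graph,
    attribute: str,
    collapse: Optional[dict] = None,
) -> pd.DataFrame:
    """Label every edge by the unordered pair of its endpoints' attribute
    values and tabulate counts and fractions.

    ``collapse`` optionally maps raw values onto coarser classes first
    (e.g. :data:`TISSUE_COLLAPSE` folds both gland tissues into ``SG`` so
    cross-compartment edges read ``PB-SG``).
    """
    counts: dict[str, int] = {}
    for u, v in graph.edges:
        vals = []
        for node in (u, v):
            attrs = graph.nodes[node]
            if attribute not in attrs:
                raise KeyError(f"node {node!r} is missing attribute {attribute!r}")
            value = attrs[attribute]
            vals.append(collapse.get(value, value) if collapse else value)
        label = "-".join(sorted(str(v) for v in vals))
        counts[label] = counts.get(label, 0) + 1
    total = sum(counts.values())
    rows = [
        {"edge_class": k, "count": c, "fraction": c / total if total else 0.0}
        for k, c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["edge_class", "count", "fraction"])


def clustering_coefficients(
    graph: nx.Graph, include_low_degree: bool = True
) -> tuple[dict, float]:
    """Local clustering coefficients and their network average.

    ``C_v = 2 T_v / (k_v (k_v - 1))`` with ``T_v`` the triangles through
    ``v``; nodes of degree < 2 have ``C_v = 0``. The average runs over all
    nodes by default (the graph-tool convention); set
    ``include_low_degree=False`` to average over degree >= 2 nodes only.
    """
    local = nx.clustering(graph)
    if not local:
        return {}, 0.0
    if include_low_degree:
        values = list(local.values())
    else:
        values = [c for n, c in local.items() if graph.degree(n) >= 2]
    avg = float(np.mean(values)) if values else 0.0
    return local, avg


def connected_node_count(graph: nx.Graph) -> int:
    """Number of nodes with degree >= 1."""
    return sum(1 for n in graph.nodes if graph.degree(n) >= 1)


def export_network(graph: nx.Graph, edges_path, nodes_path, graphml_path=None) -> None:
    """Write edge-list and node-table CSVs (and optionally GraphML)."""
    edge_rows = [
        {"source": u, "target": v, "distance": d.get("distance", "")}
        for u, v, d in graph.edges(data=True)
    ]
    pd.DataFrame(edge_rows, columns=["source", "target", "distance"]).to_csv(
        edges_path, index=False
    )
    node_rows = []
    for n, attrs in graph.nodes(data=True):
        row = {"id": n}
        for key in ("label", "sequence", "tissue", "patient", "cell_type", "isotype"):
            if key in attrs:
                row[key] = attrs[key]
        node_rows.append(row)
    pd.DataFrame(node_rows).to_csv(nodes_path, index=False)
    if graphml_path is not None:
        nx.write_graphml(graph, graphml_path)
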