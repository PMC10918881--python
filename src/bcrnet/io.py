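"""Readers and writers for repertoire tables.

Three on-disk formats are understood:

* 10X-style ``filtered_contig_annotations.csv`` (one row per assembled
  contig per cell barcode) — read into paired :class:`~bcrnet.types.BCell`
  records after chain-completeness filtering;
* TRUST4-style bulk reconstruction reports (TSV, one row per assembled
  chain with read support) — read into :class:`~bcrnet.types.ChainRecord`
  after the full-information filter;
* AIRR Rearrangement TSV (MiAIRR column names) — written and read for
  interchange with the wider AIRR tool ecosystem.

Filtering rules
---------------
Single-cell: a cell is kept only if it has exactly one complete productive
IGH contig and exactly one complete productive IGK/IGL contig; CDR3 amino
acid sequences must be complete (20 standard residues only). Barcodes with
multiple productive chains of the same class are dropped by default
(``multiplet_policy="drop"``) or resolved to the highest-UMI chain
(``multiplet_policy="best"``).

Bulk: a chain is kept only if V, J and C gene calls are all present (no
``.``/``*``/empty placeholders) and the CDR3aa is complete with no
wildcard characters. Heavy chains additionally require a recognisable
isotype from the C call.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .types import (
    BCell,
    ChainRecord,
    RepertoireSample,
    is_complete_cdr3aa,
    isotype_from_c_gene,
)

logger = logging.getLogger(__name__)

_GENE_PLACEHOLDERS = {"", ".", "*", "na", "nan", "none", "null"}

#: Minimal AIRR Rearrangement columns we write (MiAIRR names).
AIRR_COLUMNS = [
    "sequence_id",
    "sample_id",
    "locus",
    "v_call",
    "j_call",
    "c_call",
    "junction",
    "junction_aa",
    "duplicate_count",
]


class FormatError(ValueError):
    """Raised when an input table is missing required structure."""


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")


def _is_placeholder(value) -> bool:
    if value is None:
        return True
    text = str(value).strip()
    return text.lower() in _GENE_PLACEHOLDERS


def _truthy(value) -> bool:
    return str(value).strip().lower() in {"true", "t", "yes", "1"}


# ---------------------------------------------------------------------------
# sample metadata


def read_metadata(path) -> pd.DataFrame:
    """Read the per-sample clinical annotation table.

    Expected columns: ``sample_id, patient, tissue, group, essdai``
    (``essdai`` may be blank for controls).
    """
    meta = pd.read_csv(path)
    _require_columns(meta, ["sample_id", "patient", "tissue", "group"], path)
    if "essdai" not in meta.columns:
        meta["essdai"] = float("nan")
    meta["essdai"] = pd.to_numeric(meta["essdai"], errors="coerce")
    return meta.set_index("sample_id", drop=False)


def _sample_annotation(metadata: Optional[pd.DataFrame], sample_id: str) -> dict:
    defaults = {
        "patient": sample_id,
        "tissue": "PB",
        "group": "control",
        "essdai": None,
    }
    if metadata is None or sample_id not in metadata.index:
        if metadata is not None:
            warnings.warn(
                f"sample {sample_id!r} not found in metadata; using defaults"
            )
        return defaults
    row = metadata.loc[sample_id]
    essdai = row.get("essdai")
    return {
        "patient": str(row["patient"]),
        "tissue": str(row["tissue"]),
        "group": str(row["group"]),
        "essdai": None if pd.isna(essdai) else float(essdai),
    }


# ---------------------------------------------------------------------------
# single-cell contigs


def read_sc_contigs(
    path,
    metadata: Optional[pd.DataFrame] = None,
    sample_id: Optional[str] = None,
    multiplet_policy: str = "drop",
) -> list[BCell]:
    """Read a 10X-style contig annotation CSV into paired B cells.

    Parameters
    ----------
    path
        Delimited contig table with at least ``barcode, chain, v_gene,
        j_gene, cdr3, productive`` columns (``c_gene``, ``cdr3_nt``,
        ``umis``, ``raw_clonotype_id``, ``sample_id`` are used when
        present).
    metadata
        Sample annotation table from :func:`read_metadata`; supplies
        patient/tissue labels.
    sample_id
        Sample label applied to every row when the table has no
        ``sample_id`` column.
    multiplet_policy
        ``"drop"`` discards barcodes with >1 productive chain of a class;
        ``"best"`` keeps the highest-UMI chain per class.
    """
    if multiplet_policy not in ("drop", "best"):
        raise ValueError(f"unknown multiplet_policy: {multiplet_policy!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(
        df, ["barcode", "chain", "v_gene", "j_gene", "cdr3", "productive"], path
    )
    if "sample_id" not in df.columns:
        df["sample_id"] = sample_id if sample_id is not None else "sample"

    n_input = len(df)
    # productive flag, when the column carries information
    df = df[df["productive"].map(_truthy).astype(bool)]
    # known locus; unknown values are skipped with a warning
    known = df["chain"].isin(["IGH", "IGK", "IGL"])
    if (~known).any():
        bad = sorted(df.loc[~known, "chain"].unique())
        warnings.warn(f"skipping {int((~known).sum())} contig(s) with unknown locus: {bad}")
    df = df[known]
    # complete CDR3aa
    df = df[df["cdr3"].map(is_complete_cdr3aa).astype(bool)]
    logger.info("contigs: %d rows in, %d after chain-level filters", n_input, len(df))

    if "umis" in df.columns:
        df = df.assign(_umis=pd.to_numeric(df["umis"], errors="coerce").fillna(0))
    else:
        df = df.assign(_umis=1.0)

    cells: list[BCell] = []
    for (sid, barcode), grp in df.groupby(["sample_id", "barcode"], sort=True):
        heavies = grp[grp["chain"] == "IGH"]
        lights = grp[grp["chain"] != "IGH"]
        if len(heavies) == 0 or len(lights) == 0:
            continue
        if len(heavies) > 1 or len(lights) > 1:
            if multiplet_policy == "drop":
                continue
            heavies = heavies.sort_values("_umis", ascending=False).head(1)
            lights = lights.sort_values("_umis", ascending=False).head(1)
        hrow = heavies.iloc[0]
        lrow = lights.iloc[0]
        ann = _sample_annotation(metadata, sid)
        heavy = _contig_to_chain(hrow, sid)
        light = _contig_to_chain(lrow, sid)
        clone = str(hrow.get("raw_clonotype_id", "")) or f"{heavy.cdr3_aa}|{light.cdr3_aa}"
        cells.append(
            BCell(
                barcode=str(barcode),
                patient=ann["patient"],
                tissue=ann["tissue"],
                cell_type=str(hrow.get("cell_type", "") or "memory"),
                heavy=heavy,
                light=light,
                clone_id=clone,
            )
        )
    _assign_clone_sizes(cells)
    logger.info("contigs: %d paired cells retained", len(cells))
    return cells


def _contig_to_chain(row, sample_id: str) -> ChainRecord:
    count = pd.to_numeric(row.get("umis", 1), errors="coerce")
    return ChainRecord(
        sequence_id=str(row.get("contig_id", "") or f"{row['barcode']}_{row['chain']}"),
        sample_id=str(sample_id),
        locus=str(row["chain"]),
        v_gene=str(row["v_gene"]),
        j_gene=str(row["j_gene"]),
        c_gene=str(row.get("c_gene", "")),
        cdr3_nt=str(row.get("cdr3_nt", "")),
        cdr3_aa=str(row["cdr3"]),
        read_count=int(count) if pd.notna(count) and count >= 1 else 1,
    )


def _assign_clone_sizes(cells: list[BCell]) -> None:
    sizes: dict[tuple[str, str], int] = {}
    for cell in cells:
        key = (cell.heavy.sample_id, cell.clone_id)
        sizes[key] = sizes.get(key, 0) + 1
    for cell in cells:
        cell.clone_size = sizes[(cell.heavy.sample_id, cell.clone_id)]


# ---------------------------------------------------------------------------
# bulk reconstruction reports


def _infer_locus(v: str, j: str, c: str) -> Optional[str]:
    for gene in (v, j, c):
        g = str(gene).strip().upper()
        for locus in ("IGH", "IGK", "IGL"):
            if g.startswith(locus):
                return locus
    return None


def filter_bulk_chains(
    records: Iterable[ChainRecord], strict: bool = False
) -> list[ChainRecord]:
    """Apply the full-information bulk filter to chain records.

    Keeps only chains with non-placeholder V, J and C calls and a complete
    wildcard-free CDR3aa; heavy chains must map to one of the nine
    isotypes. Idempotent: filtering already-filtered output is a no-op.
    """
    kept = []
    for rec in records:
        if _is_placeholder(rec.v_gene) or _is_placeholder(rec.j_gene):
            continue
        if _is_placeholder(rec.c_gene):
            continue
        if not is_complete_cdr3aa(rec.cdr3_aa):
            continue
        if rec.locus == "IGH" and isotype_from_c_gene(rec.c_gene) == "none":
            continue
        if rec.read_count < 1:
            if strict:
                raise ValueError(f"{rec.sequence_id}: read_count < 1")
            rec.read_count = 1
        kept.append(rec)
    return kept


def read_bulk_report(
    path,
    metadata: Optional[pd.DataFrame] = None,
    sample_id: Optional[str] = None,
    strict: bool = False,
) -> RepertoireSample:
    """Read a TRUST4-style report into a bulk :class:`RepertoireSample`.

    The report is a TSV with one row per assembled chain. Recognised
    column spellings: ``#count``/``count``/``duplicate_count`` for read
    support, ``CDR3aa``/``cdr3aa``/``CDR3_aa``, ``V``/``v_call`` etc.
    Locus is inferred from the V (falling back to J, then C) gene-name
    prefix. Chains failing the full-information filter are dropped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.lstrip("#") for c in df.columns]
    colmap = {}
    for want, options in {
        "count": ["count", "duplicate_count", "consensus_count"],
        "cdr3_nt": ["CDR3nt", "cdr3nt", "CDR3_nt", "junction"],
        "cdr3_aa": ["CDR3aa", "cdr3aa", "CDR3_aa", "junction_aa"],
        "v": ["V", "v_call", "v_gene"],
        "j": ["J", "j_call", "j_gene"],
        "c": ["C", "c_call", "c_gene"],
        "cid": ["cid", "sequence_id", "contig_id"],
    }.items():
        for opt in options:
            if opt in df.columns:
                colmap[want] = opt
                break
    for want in ("count", "cdr3_aa", "v", "j", "c"):
        if want not in colmap:
            raise FormatError(f"{path}: missing required column for {want!r}")

    sid = sample_id if sample_id is not None else Path(str(path)).stem
    records: list[ChainRecord] = []
    n_bad_count = 0
    for i, row in enumerate(df.itertuples(index=False)):
        getv = lambda key, default="": getattr(row, colmap[key], default) if key in colmap else default
        v, j, c = str(getv("v")), str(getv("j")), str(getv("c"))
        locus = _infer_locus(v, j, c)
        if locus is None:
            warnings.warn(f"{path}: row {i}: cannot infer locus; skipped")
            continue
        raw_count = getv("count", "1")
        try:
            count = int(float(raw_count))
            if count < 1:
                raise ValueError
        except (TypeError, ValueError):
            if strict:
                raise ValueError(f"{path}: row {i}: unparseable read count {raw_count!r}")
            n_bad_count += 1
            count = 1
        records.append(
            ChainRecord(
                sequence_id=str(getv("cid") or f"{sid}_row{i}"),
                sample_id=sid,
                locus=locus,
                v_gene=v,
                j_gene=j,
                c_gene=c,
                cdr3_nt=str(getv("cdr3_nt")),
                cdr3_aa=str(getv("cdr3_aa")),
                read_count=count,
            )
        )
    if n_bad_count:
        warnings.warn(f"{path}: {n_bad_count} row(s) with unparseable read count treated as 1")

    kept = filter_bulk_chains(records, strict=strict)
    logger.info("bulk report %s: %d rows in, %d chains retained", path, len(df), len(kept))
    if not kept:
        warnings.warn(f"{path}: all {len(df)} rows removed by filters; empty sample")
    ann = _sample_annotation(metadata, sid)
    return RepertoireSample(sample_id=sid, chains=kept, **ann)


# ---------------------------------------------------------------------------
# AIRR interchange


def write_airr(records: Iterable[ChainRecord], path) -> None:
    """Write chain records as an AIRR Rearrangement-style TSV."""
    rows = [
        {
            "sequence_id": r.sequence_id,
            "sample_id": r.sample_id,
            "locus": r.locus,
            "v_call": r.v_gene,
            "j_call": r.j_gene,
            "c_call": r.c_gene,
            "junction": r.cdr3_nt,
            "junction_aa": r.cdr3_aa,
            "duplicate_count": r.read_count,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=AIRR_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_airr(path) -> list[ChainRecord]:
    """Read an AIRR Rearrangement TSV written by :func:`write_airr`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ["sequence_id", "locus", "v_call", "j_call", "junction_aa"], path)
    records = []
    for row in df.itertuples(index=False):
        count = pd.to_numeric(getattr(row, "duplicate_count", 1), errors="coerce")
        records.append(
            ChainRecord(
                sequence_id=str(row.sequence_id),
                sample_id=str(getattr(row, "sample_id", "sample")),
                locus=str(row.locus),
                v_gene=str(row.v_call),
                j_gene=str(row.j_call),
                c_gene=str(getattr(row, "c_call", "")),
                cdr3_nt=str(getattr(row, "junction", "")),
                cdr3_aa=str(row.junction_aa),
                read_count=int(count) if pd.notna(count) else 1,
            )
        )
    return records
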