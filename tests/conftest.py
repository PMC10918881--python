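"""Shared fixtures: tiny hand-enumerable input tables and an independent
dynamic-programming edit-distance oracle (kept separate from the package
implementation on purpose)."""

from __future__ import annotations

import pytest


def dp_levenshtein(a: str, b: str) -> int:
    """Textbook O(len(a)*len(b)) edit-distance DP; the reference oracle."""
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


CONTIG_HEADER = (
    "barcode,contig_id,chain,v_gene,j_gene,c_gene,cdr3,cdr3_nt,productive,umis,raw_clonotype_id"
)

#: three barcodes: complete pair / missing light chain / CDR3 with a stop
CONTIG_ROWS = [
    "BC1,BC1_c1,IGH,IGHV3-23,IGHJ4,IGHG1,CARDYW,TGTGCT,True,12,clono1",
    "BC1,BC1_c2,IGK,IGKV1-39,IGKJ1,IGKC,CQQSYSTPW,TGTCAA,True,8,clono1",
    "BC2,BC2_c1,IGH,IGHV1-2,IGHJ6,IGHM,CARGGGW,TGTGCA,True,5,clono2",
    "BC3,BC3_c1,IGH,IGHV4-34,IGHJ3,IGHA1,CAR*DYW,TGTGCC,True,7,clono3",
    "BC3,BC3_c2,IGL,IGLV1-44,IGLJ2,IGLC2,CQAWDSSTW,TGTCAG,True,6,clono3",
]

#: one barcode carrying three productive chains (IGH + IGK + IGL)
CONTIG_TRIPLE_ROWS = [
    "BC9,BC9_c1,IGH,IGHV3-23,IGHJ4,IGHG1,CARDYW,TGTGCT,True,12,clono9",
    "BC9,BC9_c2,IGK,IGKV1-39,IGKJ1,IGKC,CQQSYSTPW,TGTCAA,True,8,clono9",
    "BC9,BC9_c3,IGL,IGLV1-44,IGLJ2,IGLC2,CQAWDSSTW,TGTCAG,True,4,clono9",
]

TRUST4_HEADER = "#count\tfrequency\tCDR3nt\tCDR3aa\tV\tD\tJ\tC\tcid\tcid_full_length"

#: 10 rows: 3 lack a C call ('.'), 2 carry '_' inside the CDR3aa -> 5 kept
TRUST4_ROWS = [
    "7\t0.1\tTGTGCT\tCARDGYW\tIGHV3-23\t.\tIGHJ4\tIGHA2\tr1\t1",
    "3\t0.05\tTGTGCA\tCARTTVW\tIGHV1-2\t.\tIGHJ6\tIGHG1\tr2\t1",
    "2\t0.03\tTGTCAA\tCQQSYSTPW\tIGKV1-39\t.\tIGKJ1\tIGKC\tr3\t1",
    "9\t0.12\tTGTCAG\tCQAWDSSTW\tIGLV1-44\t.\tIGLJ2\tIGLC2\tr4\t1",
    "4\t0.06\tTGTGCC\tCARNNPW\tIGHV4-34\t.\tIGHJ3\tIGHM\tr5\t1",
    "5\t0.07\tTGTGCT\tCARDLLW\tIGHV3-30\t.\tIGHJ4\t.\tr6\t1",
    "6\t0.08\tTGTGCA\tCARWWTW\tIGHV5-51\t.\tIGHJ5\t.\tr7\t1",
    "1\t0.01\tTGTCAA\tCQQYNSW\tIGKV3-20\t.\tIGKJ2\t.\tr8\t1",
    "8\t0.11\tTGTGCT\tCAR_GYW\tIGHV3-23\t.\tIGHJ4\tIGHG2\tr9\t1",
    "2\t0.03\tTGTCAG\tCQA_SSW\tIGLV2-14\t.\tIGLJ3\tIGLC2\tr10\t1",
]

METADATA_CSV = (
    "sample_id,patient,tissue,group,essdai\n"
    "sampleA,Pat1,SG_labial,pSS,12\n"
    "sampleB,Pat1,SG_parotid,pSS,12\n"
    "sampleC,Pat2,SG_labial,control,\n"
)


@pytest.fixture
def contig_csv(tmp_path):
    path = tmp_path / "contigs.csv"
    path.write_text("\n".join([CONTIG_HEADER, *CONTIG_ROWS]) + "\n")
    return path


@pytest.fixture
def contig_triple_csv(tmp_path):
    path = tmp_path / "contigs_triple.csv"
    path.write_text("\n".join([CONTIG_HEADER, *CONTIG_TRIPLE_ROWS]) + "\n")
    return path


@pytest.fixture
def trust4_tsv(tmp_path):
    path = tmp_path / "sampleA.tsv"
    path.write_text("\n".join([TRUST4_HEADER, *TRUST4_ROWS]) + "\n")
    return path


@pytest.fixture
def metadata_csv(tmp_path):
    path = tmp_path / "metadata.csv"
    path.write_text(METADATA_CSV)
    return path
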