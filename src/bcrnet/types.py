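"""Core domain containers for BCR repertoire analysis.

A repertoire is observed either at single-cell resolution (paired heavy +
light chains per barcode, from scBCRseq) or at chain resolution (unpaired
assembled chains with read support, from bulk RNA-seq repertoire
reconstruction). Both views normalise to :class:`ChainRecord`; the
single-cell view additionally pairs chains into :class:`BCell`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

#: The nine human IgH constant-region classes, in conventional order.
ISOTYPES: tuple[str, ...] = (
    "IGHM",
    "IGHD",
    "IGHG1",
    "IGHG2",
    "IGHG3",
    "IGHG4",
    "IGHA1",
    "IGHA2",
    "IGHE",
)

#: The 20 standard amino-acid one-letter codes.
STANDARD_AA: frozenset[str] = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Characters treated as wildcards / placeholders inside a CDR3 amino-acid
#: string (reconstruction tools emit '_' and '?'; '.' and '*' mark missing
#: or stop positions; 'X' is an ambiguous residue). Any character outside
#: STANDARD_AA also disqualifies a CDR3.
CDR3_WILDCARDS: frozenset[str] = frozenset("*_X?.")

LOCI: tuple[str, ...] = ("IGH", "IGK", "IGL")
TISSUES: tuple[str, ...] = ("PB", "SG_labial", "SG_parotid")
CELL_TYPES: tuple[str, ...] = ("naive", "memory", "plasma")
GROUPS: tuple[str, ...] = ("pSS", "control")


def isotype_from_c_gene(c_gene: Optional[str]) -> str:
    """Map an IgH constant-gene call to one of the nine isotypes.

    Matching is case-insensitive on the gene-name prefix, longest name
    first, so ``IGHG1*01`` -> ``IGHG1`` while a bare ``IGHG`` (ambiguous
    subclass) maps to ``none``.
    """
    if not c_gene:
        return "none"
    upper = c_gene.strip().upper()
    for name in sorted(ISOTYPES, key=len, reverse=True):
        if upper.startswith(name):
            return name
    return "none"


def is_complete_cdr3aa(cdr3_aa: Optional[str]) -> bool:
    """True iff the CDR3 amino-acid string is nonempty and uses only the
    20 standard residues (no wildcards, stops, or placeholders)."""
    if not cdr3_aa:
        return False
    return all(ch in STANDARD_AA for ch in cdr3_aa)


@dataclass
class ChainRecord:
    """One assembled or observed BCR chain."""

    sequence_id: str
    sample_id: str
    locus: str  # IGH | IGK | IGL
    v_gene: str
    j_gene: str
    c_gene: str = ""
    cdr3_nt: str = ""
    cdr3_aa: str = ""
    isotype: str = "none"  # derived from c_gene for IGH chains
    read_count: int = 1

    def __post_init__(self) -> None:
        if self.locus == "IGH" and self.isotype == "none":
            self.isotype = isotype_from_c_gene(self.c_gene)


@dataclass
class BCell:
    """A barcode-level B cell with exactly one paired heavy and light chain."""

    barcode: str
    patient: str
    tissue: str  # PB | SG_labial | SG_parotid
    cell_type: str  # naive | memory | plasma
    heavy: ChainRecord
    light: ChainRecord
    clone_id: str = ""
    clone_size: int = 1

    def __post_init__(self) -> None:
        if self.heavy.locus != "IGH":
            raise ValueError(
                f"cell {self.barcode}: heavy chain has locus {self.heavy.locus}"
            )
        if self.light.locus not in ("IGK", "IGL"):
            raise ValueError(
                f"cell {self.barcode}: light chain has locus {self.light.locus}"
            )


@dataclass
class RepertoireSample:
    """A repertoire observation for one (patient, tissue) sample.

    Exactly one of ``chains`` (bulk mode) or ``cells`` (single-cell mode)
    is populated. ``essdai`` is the clinical disease-activity score and is
    meaningful only for pSS samples.
    """

    sample_id: str
    patient: str
    tissue: str
    group: str  # pSS | control
    essdai: Optional[float] = None
    chains: list[ChainRecord] = field(default_factory=list)
    cells: list[BCell] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.chains and self.cells:
            raise ValueError(
                f"sample {self.sample_id}: populate either chains or cells, not both"
            )

    @property
    def mode(self) -> str:
        return "single_cell" if self.cells else "bulk"

    def iter_chains(self):
        """All chain records in the sample, regardless of mode."""
        if self.cells:
            for cell in self.cells:
                yield cell.heavy
                yield cell.light
        else:
            yield from self.chains
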