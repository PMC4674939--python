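"""Core record types shared across the pipeline.

Coordinates are 0-based, half-open everywhere inside the package; 1-based
coordinates appear only at the TSV/SAM boundary (see :mod:`polymethyl.io_formats`).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum, IntEnum
from typing import Optional

GENOMES = ("A", "B", "D")

#: Cytosine sequence contexts (H = A, C or T).
CONTEXTS = ("CpG", "CHG", "CHH")

#: Methylation-string symbols (Bismark XM dialect): upper case = methylated.
SYMBOL_BY_CONTEXT = {"CpG": "Z", "CHG": "X", "CHH": "H", "unknown": "U"}
CONTEXT_BY_SYMBOL = {
    "Z": "CpG", "z": "CpG",
    "X": "CHG", "x": "CHG",
    "H": "CHH", "h": "CHH",
    "U": "unknown", "u": "unknown",
}


class GenomeLabel(IntEnum):
    """Sub-genome assignment of a read, encoded as a bitmask over (A, B, D).

    Pair labels arise from biallelic homoeologous SNPs (a read carrying the
    shared allele of, say, the B and D sub-genomes can only be narrowed to the
    BD pair); ABD never survives a genuine SNP and is kept for completeness.
    """

    UNASSIGNED = 0
    A = 1
    B = 2
    D = 4
    AB = 3
    AD = 5
    BD = 6
    ABD = 7

    @property
    def genomes(self) -> tuple[str, ...]:
        return tuple(g for g, bit in zip(GENOMES, (1, 2, 4)) if self.value & bit)

    @property
    def is_single(self) -> bool:
        return self.value in (1, 2, 4)

    @property
    def is_pair(self) -> bool:
        return self.value in (3, 5, 6)


#: Tally column order used throughout the site tables.
TALLY_LABELS = (
    GenomeLabel.A, GenomeLabel.B, GenomeLabel.D,
    GenomeLabel.AB, GenomeLabel.AD, GenomeLabel.BD,
)

#: The three biallelic partitions: (single genome, complementary pair).
PARTITIONS = (
    (GenomeLabel.A, GenomeLabel.BD),
    (GenomeLabel.B, GenomeLabel.AD),
    (GenomeLabel.D, GenomeLabel.AB),
)


class MethState(Enum):
    METHYLATED = "Methylated"
    UNMETHYLATED = "Unmethylated"
    INTERMEDIATE = "Intermediate"
    NOCALL = "NoCall"


#: Site-pattern vocabulary. ``unresolved`` marks a coverage-passing site whose
#: three genome states cannot all be established from the local SNP evidence;
#: such sites are excluded from pattern denominators.
PATTERNS = (
    "tri", "uni_A", "uni_B", "uni_D", "bi_AB", "bi_AD", "bi_BD",
    "intermediate", "none", "unresolved",
)

UNI_PATTERNS = ("uni_A", "uni_B", "uni_D")
BI_PATTERNS = ("bi_AB", "bi_AD", "bi_BD")
#: Patterns that count as "methylated in one or more sub-genomes".
METHYLATED_PATTERNS = ("tri",) + UNI_PATTERNS + BI_PATTERNS + ("intermediate",)

ANNOTATION_CLASSES = ("exon", "intron", "promoter", "non_transcribed", "unknown")


@dataclass
class BisulfiteRead:
    """A bisulfite-converted read, pre-aligned to the analysis reference.

    ``xm`` is the per-base methylation string (one symbol per base, ``.`` at
    positions that are not a cytosine on the read's converted strand).
    ``strand_of_origin`` is one of OT/OB/CTOT/CTOB; only the implied
    conversion state (``xg``: CT or GA) matters analytically.
    """

    read_id: str
    contig: str
    pos: int  # 0-based leftmost
    mapq: int
    strand_of_origin: str
    seq: str
    xm: str

    @property
    def xg(self) -> str:
        return "CT" if self.strand_of_origin in ("OT", "CTOT") else "GA"

    def __len__(self) -> int:
        return len(self.seq)


def bisulfite_safe(allele_a: str, allele_b: str, allele_d: str) -> bool:
    """True unless any pair of distinct alleles is {C,T} or {G,A}.

    Either such pair is indistinguishable after bisulfite conversion on one
    strand, so those SNPs are useless (and misleading) in converted reads.
    """
    distinct = {allele_a, allele_b, allele_d}
    return not ({"C", "T"} <= distinct or {"G", "A"} <= distinct)


@dataclass(frozen=True)
class HomoeologousSNP:
    """A catalogued inter-sub-genome substitution with one allele per genome."""

    contig: str
    pos: int  # 0-based
    allele_a: str
    allele_b: str
    allele_d: str
    source: str = "progenitor"

    @property
    def alleles(self) -> tuple[str, str, str]:
        return (self.allele_a, self.allele_b, self.allele_d)

    @property
    def bisulfite_safe(self) -> bool:
        return bisulfite_safe(*self.alleles)

    @property
    def is_divergent(self) -> bool:
        return len(set(self.alleles)) >= 2


@dataclass(frozen=True)
class CytosineSite:
    contig: str
    pos: int
    strand: str  # '+' or '-'
    context: str
    annotation: str = "unknown"


@dataclass
class MethylationCall:
    state: MethState
    level: Optional[float]  # percentage, None for NoCall


@dataclass
class SiteGenomeCounts:
    """Per-cytosine methylated/total read tallies per resolvable genome group."""

    site: CytosineSite
    counts: dict[GenomeLabel, tuple[int, int]] = field(default_factory=dict)
    mode: str = "none"  # tri_resolved | biallelic_pair | none
    dominant_partition: Optional[tuple[GenomeLabel, GenomeLabel]] = None
    passes_coverage: bool = False

    def meth(self, label: GenomeLabel) -> int:
        return self.counts.get(label, (0, 0))[0]

    def total(self, label: GenomeLabel) -> int:
        return self.counts.get(label, (0, 0))[1]


@dataclass
class SitePattern:
    site: CytosineSite
    pattern: str
    comparison: Optional[str] = None  # e.g. "A_vs_BD"
    difference: Optional[float] = None
    p: Optional[float] = None
    q: Optional[float] = None


@dataclass(frozen=True)
class RegionAnnotation:
    region_id: str
    contig: str
    start: int
    end: int  # half-open
    cls: str
    gene_id: Optional[str] = None

    def __post_init__(self):
        if self.cls not in ANNOTATION_CLASSES:
            raise ValueError(f"unknown annotation class {self.cls!r}")
        if self.cls == "promoter" and not self.gene_id:
            raise ValueError(f"promoter region {self.region_id} lacks a gene id")

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class RegionSummary:
    region_id: str
    cls: str
    counts: dict[str, tuple[int, int]]  # genome -> (meth, total), pooled reads
    site_count: int

    def level(self, genome: str) -> Optional[float]:
        m, t = self.counts.get(genome, (0, 0))
        return 100.0 * m / t if t else None


@dataclass
class AllelicExpression:
    region_id: str
    raw: tuple[float, float, float]  # A, B, D
    pplr: tuple[Optional[float], Optional[float], Optional[float]] = (None, None, None)

    @property
    def expressed(self) -> bool:
        return sum(self.raw) > 0

    @property
    def normalized(self) -> Optional[tuple[float, float, float]]:
        s = sum(self.raw)
        if s <= 0:
            return None
        return tuple(100.0 * v / s for v in self.raw)
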