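"""Synthetic allohexaploid methyl-seq data with known ground truth.

The generator emulates the study design this package analyses: three
homoeologous sub-genome sequences (A, B, D) that differ at catalogued SNP
positions, per-cytosine per-sub-genome methylation states drawn from a
configurable uni/bi/tri/intermediate pattern mix, bisulfite reads with
incomplete conversion and sequencing error, an unmethylated control contig
(standing in for the chloroplast genome), and per-gene allelic expression
with promoter-methylation suppression.

Reads are emitted pre-aligned (read mapping is outside the scope of the
pipeline); a mapping-quality field is populated so the MAPQ filter is
exercisable.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .extraction import (
    _SYMBOLS,
    ContextMap,
    build_context_map,
    bytes_to_seq,
)
from .records import (
    GENOMES,
    AllelicExpression,
    BisulfiteRead,
    HomoeologousSNP,
    RegionAnnotation,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = 65, 67, 71, 84
_BASE_INDEX = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _BASE_INDEX[_b] = _i

CONTROL_CONTIG = "control"

PATTERN_ORDER = (
    "unmethylated", "tri", "uni_A", "uni_B", "uni_D",
    "bi_AB", "bi_AD", "bi_BD", "intermediate",
)
PATTERN_CODE = {name: i for i, name in enumerate(PATTERN_ORDER)}

#: Which genomes are "methylated" under each pattern label.
_PATTERN_GENOMES = {
    "unmethylated": (),
    "tri": (0, 1, 2),
    "uni_A": (0,), "uni_B": (1,), "uni_D": (2,),
    "bi_AB": (0, 1), "bi_AD": (0, 2), "bi_BD": (1, 2),
    "intermediate": (0, 1, 2),
}

_PRODUCTS = ("OT", "OB", "CTOT", "CTOB")
#: products whose alignment reflects the C->T conversion of the plus strand
_CT_PRODUCTS = (0, 2)  # OT, CTOT


@dataclass
class References:
    """Three homoeologous sub-genome sequence sets plus a control contig."""

    contigs: list[str]
    genomes: dict[str, dict[str, np.ndarray]]  # genome -> contig -> bytes
    control: np.ndarray
    snps: list[HomoeologousSNP]

    @property
    def lengths(self) -> dict[str, int]:
        return {c: self.genomes["A"][c].size for c in self.contigs}

    def reference(self) -> dict[str, np.ndarray]:
        """The analysis reference: sub-genome A plus the control contig."""
        ref = dict(self.genomes["A"])
        ref[CONTROL_CONTIG] = self.control
        return ref

    def reference_str(self) -> dict[str, str]:
        return {c: bytes_to_seq(s) for c, s in self.reference().items()}

    def snp_positions(self, contig: str) -> np.ndarray:
        return np.array(sorted(s.pos for s in self.snps if s.contig == contig),
                        dtype=np.int64)


@dataclass
class MethylationTruth:
    """Ground-truth methylation probabilities per (contig, strand, genome).

    ``prob_plus[contig]`` has shape (3, L): row g is genome g's methylation
    probability at each plus-strand cytosine (0 elsewhere). ``code_plus``
    holds the context code of truth-covered sites and -1 elsewhere;
    ``pattern_plus`` the pattern code (-1 elsewhere). Positions whose context
    window touches a SNP carry no truth (and no methylation calls in reads):
    their context differs between sub-genomes, so a single shared context
    cannot be recorded for them.
    """

    table: pd.DataFrame
    prob_plus: dict[str, np.ndarray]
    prob_minus: dict[str, np.ndarray]
    code_plus: dict[str, np.ndarray]
    code_minus: dict[str, np.ndarray]
    pattern_plus: dict[str, np.ndarray]
    pattern_minus: dict[str, np.ndarray]


@dataclass
class ReadBatch:
    """Column-oriented container of simulated (or ingested) aligned reads."""

    contigs: list[str]
    contig_idx: np.ndarray  # int32
    start: np.ndarray  # int32, 0-based
    product: np.ndarray  # int8, index into _PRODUCTS
    mapq: np.ndarray  # int16
    genome: np.ndarray  # int8: 0/1/2 = A/B/D truth, -1 = control/unknown
    seq: np.ndarray  # uint8 (n, read_length)
    xm: np.ndarray  # uint8 (n, read_length)

    @property
    def n(self) -> int:
        return self.start.size

    @property
    def read_length(self) -> int:
        return self.seq.shape[1] if self.seq.ndim == 2 else 0

    @property
    def xg_ct(self) -> np.ndarray:
        return np.isin(self.product, _CT_PRODUCTS)

    def subset(self, index: np.ndarray) -> "ReadBatch":
        return ReadBatch(self.contigs, self.contig_idx[index], self.start[index],
                         self.product[index], self.mapq[index], self.genome[index],
                         self.seq[index], self.xm[index])

    def iter_records(self) -> Iterator[BisulfiteRead]:
        for i in range(self.n):
            yield BisulfiteRead(
                read_id=f"read_{i}",
                contig=self.contigs[self.contig_idx[i]],
                pos=int(self.start[i]),
                mapq=int(self.mapq[i]),
                strand_of_origin=_PRODUCTS[self.product[i]],
                seq=self.seq[i].tobytes().decode("ascii"),
                xm=self.xm[i].tobytes().decode("ascii"),
            )

    @staticmethod
    def concat(batches: Sequence["ReadBatch"]) -> "ReadBatch":
        batches = [b for b in batches if b.n]
        if not batches:
            raise ValueError("nothing to concatenate")
        contigs = batches[0].contigs
        return ReadBatch(
            contigs,
            np.concatenate([b.contig_idx for b in batches]),
            np.concatenate([b.start for b in batches]),
            np.concatenate([b.product for b in batches]),
            np.concatenate([b.mapq for b in batches]),
            np.concatenate([b.genome for b in batches]),
            np.vstack([b.seq for b in batches]),
            np.vstack([b.xm for b in batches]),
        )


def _empty_batch(contigs: list[str], read_length: int) -> ReadBatch:
    return ReadBatch(
        contigs,
        np.empty(0, np.int32), np.empty(0, np.int32), np.empty(0, np.int8),
        np.empty(0, np.int16), np.empty(0, np.int8),
        np.empty((0, read_length), np.uint8), np.empty((0, read_length), np.uint8),
    )


# ---------------------------------------------------------------------------
# references and SNP truth


def generate_homoeologous_references(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None,
) -> References:
    """Three equal-length homologous sequences per contig, differing only at
    catalogued SNP positions, plus an unmethylated control contig.

    The allele model is heavily biallelic by default: at each divergent
    position one genome (chosen uniformly) carries a variant base, with a
    small configurable fraction of positions where all three genomes differ.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    contigs = [f"contig_{i:04d}" for i in range(config.n_contigs)]
    genomes: dict[str, dict[str, np.ndarray]] = {g: {} for g in GENOMES}
    snps: list[HomoeologousSNP] = []
    L = config.contig_length
    for contig in contigs:
        base_seq = _BASES[rng.integers(0, 4, L)]
        seqs = {g: base_seq.copy() for g in GENOMES}
        snp_mask = rng.random(L) < config.snp_rate
        positions = np.flatnonzero(snp_mask)
        for pos in positions:
            ref_base = chr(base_seq[pos])
            others = [b for b in "ACGT" if b != ref_base]
            if rng.random() < config.tri_allelic_fraction:
                picks = rng.permutation(3)
                alleles = [ref_base, others[picks[0]], others[picks[1]]]
                alleles = [alleles[i] for i in rng.permutation(3)]
            else:
                variant = others[rng.integers(0, 3)]
                distinct = rng.integers(0, 3)
                alleles = [ref_base] * 3
                alleles[distinct] = variant
            for g, a in zip(GENOMES, alleles):
                seqs[g][pos] = ord(a)
            snps.append(HomoeologousSNP(contig, int(pos), *alleles, source="truth"))
        for g in GENOMES:
            genomes[g][contig] = seqs[g]
    control = _BASES[rng.integers(0, 4, config.control_length)]
    n_cyt = int(np.count_nonzero(control == _C) + np.count_nonzero(control == _G))
    if n_cyt < 1000:
        raise ValueError(
            f"control contig holds only {n_cyt} cytosines; increase control_length")
    return References(contigs, genomes, control, snps)


def expected_snp_count(config: SimulationConfig) -> tuple[float, float]:
    """(mean, sd) of the SNP-truth size under the generator's allele model.

    Every position drawn at ``snp_rate`` is divergent (one or all three
    genomes carry a variant), so the count is Binomial(n_contigs *
    contig_length, snp_rate).
    """
    n = config.n_contigs * config.contig_length
    p = config.snp_rate
    return n * p, float(np.sqrt(n * p * (1 - p)))


# ---------------------------------------------------------------------------
# methylation truth


def _snp_window_masks(L: int, snp_pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Positions whose strand-specific context window touches a SNP."""
    snp = np.zeros(L, dtype=bool)
    snp[snp_pos] = True
    plus = snp.copy()  # site itself
    minus = snp.copy()
    for k in (1, 2):
        plus[:-k] |= snp[k:]   # SNP at pos + k
        minus[k:] |= snp[:-k]  # SNP at pos - k
    return plus, minus


def assign_methylation_truth(
    refs: References,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> MethylationTruth:
    """Assign a pattern and per-genome methylation probabilities to every
    eligible cytosine (both strands).

    Eligible means: classifiable context on the analysis reference and no SNP
    inside the site's context window. Patterns are drawn i.i.d. from
    ``pattern_mix``; because the calling thresholds admit an intermediate
    methylation state only at CpG sites, intermediate labels drawn at non-CpG
    sites are swapped with non-intermediate labels at randomly chosen CpG
    sites, preserving the overall mix exactly.

    Methylated genomes draw a level near the per-context mean (binary-extreme
    model); unmethylated genomes get probability exactly 0; the intermediate
    pattern draws each genome's level uniformly from
    ``intermediate_level_range``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    ref = refs.genomes["A"]
    site_contig: list[int] = []
    site_strand: list[np.ndarray] = []
    site_pos: list[np.ndarray] = []
    site_ctx: list[np.ndarray] = []
    maps: dict[str, ContextMap] = {}
    elig: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for ci, contig in enumerate(refs.contigs):
        seq = ref[contig]
        cmap = build_context_map(seq)
        maps[contig] = cmap
        win_plus, win_minus = _snp_window_masks(seq.size, refs.snp_positions(contig))
        elig_plus = cmap.plus_mask & ~win_plus
        elig_minus = cmap.minus_mask & ~win_minus
        elig[contig] = (elig_plus, elig_minus)
        for strand, mask, codes in (
            (0, elig_plus, cmap.plus_code), (1, elig_minus, cmap.minus_code),
        ):
            pos = np.flatnonzero(mask)
            site_contig.append(np.full(pos.size, ci, dtype=np.int32))
            site_strand.append(np.full(pos.size, strand, dtype=np.int8))
            site_pos.append(pos.astype(np.int32))
            site_ctx.append(codes[pos].astype(np.int8))
    contig_arr = np.concatenate([np.atleast_1d(a) for a in site_contig])
    strand_arr = np.concatenate(site_strand)
    pos_arr = np.concatenate(site_pos)
    ctx_arr = np.concatenate(site_ctx)
    n_sites = pos_arr.size

    mix_names = [p for p in PATTERN_ORDER if config.pattern_mix.get(p, 0.0) > 0]
    mix_probs = np.array([config.pattern_mix[p] for p in mix_names])
    mix_probs = mix_probs / mix_probs.sum()
    draws = rng.choice(len(mix_names), size=n_sites, p=mix_probs)
    pattern = np.array([PATTERN_CODE[p] for p in mix_names], dtype=np.int8)[draws]

    inter = PATTERN_CODE["intermediate"]
    bad = np.flatnonzero((pattern == inter) & (ctx_arr != 0))
    if bad.size:
        candidates = np.flatnonzero((ctx_arr == 0) & (pattern != inter))
        if candidates.size < bad.size:
            raise ValueError("not enough CpG sites to host the intermediate mix")
        chosen = rng.choice(candidates, size=bad.size, replace=False)
        pattern[chosen], pattern[bad] = pattern[bad].copy(), pattern[chosen].copy()

    probs = np.zeros((n_sites, 3), dtype=np.float32)
    means = np.array([config.context_level_means[c] for c in ("CpG", "CHG", "CHH")])
    lo, hi = config.intermediate_level_range
    for code, name in enumerate(PATTERN_ORDER):
        sel = np.flatnonzero(pattern == code)
        if not sel.size:
            continue
        if name == "intermediate":
            probs[sel] = rng.uniform(lo, hi, size=(sel.size, 3))
        else:
            for g in _PATTERN_GENOMES[name]:
                level = rng.normal(means[ctx_arr[sel]], config.level_sd)
                probs[sel, g] = np.clip(level, 0.55, 0.99)

    prob_plus: dict[str, np.ndarray] = {}
    prob_minus: dict[str, np.ndarray] = {}
    code_plus: dict[str, np.ndarray] = {}
    code_minus: dict[str, np.ndarray] = {}
    pattern_plus: dict[str, np.ndarray] = {}
    pattern_minus: dict[str, np.ndarray] = {}
    for ci, contig in enumerate(refs.contigs):
        L = ref[contig].size
        prob_plus[contig] = np.zeros((3, L), dtype=np.float32)
        prob_minus[contig] = np.zeros((3, L), dtype=np.float32)
        code_plus[contig] = np.full(L, -1, dtype=np.int8)
        code_minus[contig] = np.full(L, -1, dtype=np.int8)
        pattern_plus[contig] = np.full(L, -1, dtype=np.int8)
        pattern_minus[contig] = np.full(L, -1, dtype=np.int8)
        for strand in (0, 1):
            sel = np.flatnonzero((contig_arr == ci) & (strand_arr == strand))
            pp = prob_plus if strand == 0 else prob_minus
            cc = code_plus if strand == 0 else code_minus
            tt = pattern_plus if strand == 0 else pattern_minus
            pp[contig][:, pos_arr[sel]] = probs[sel].T
            cc[contig][pos_arr[sel]] = ctx_arr[sel]
            tt[contig][pos_arr[sel]] = pattern[sel]

    table = pd.DataFrame({
        "contig": pd.Categorical.from_codes(contig_arr, categories=refs.contigs),
        "pos": pos_arr,
        "strand": np.where(strand_arr == 0, "+", "-"),
        "context": pd.Categorical.from_codes(ctx_arr, categories=["CpG", "CHG", "CHH"]),
        "pattern": pd.Categorical.from_codes(
            pattern, categories=list(PATTERN_ORDER)),
        "p_A": probs[:, 0], "p_B": probs[:, 1], "p_D": probs[:, 2],
    })
    return MethylationTruth(table, prob_plus, prob_minus, code_plus, code_minus,
                            pattern_plus, pattern_minus)


# ---------------------------------------------------------------------------
# bisulfite reads


def _synthesize_reads(
    seq_g: np.ndarray,
    prob_g: np.ndarray,
    site_code: np.ndarray,
    starts: np.ndarray,
    ct: bool,
    read_length: int,
    conversion_rate: float,
    error_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized read synthesis for one (contig, genome, conversion) group.

    Returns (seq, xm) byte matrices. ``prob_g`` and ``site_code`` are the
    strand-appropriate truth arrays over reference positions.
    """
    idx = starts[:, None] + np.arange(read_length)
    base = seq_g[idx].copy()
    cyt_base, conv_base = (_C, _T) if ct else (_G, _A)
    cyt = base == cyt_base
    meth = cyt & (rng.random(idx.shape) < prob_g[idx])
    converted = cyt & ~meth & (rng.random(idx.shape) < conversion_rate)
    base[converted] = conv_base
    if error_rate > 0:
        emask = rng.random(idx.shape) < error_rate
        n_err = int(np.count_nonzero(emask))
        if n_err:
            cur = _BASE_INDEX[base[emask]]
            base[emask] = _BASES[(cur + rng.integers(1, 4, n_err)) % 4]
    xm = np.full(idx.shape, ord("."), dtype=np.uint8)
    code = site_code[idx]
    covered = code >= 0
    called_meth = covered & (base == cyt_base)
    called_unmeth = covered & (base == conv_base)
    xm[called_meth] = _SYMBOLS[code[called_meth], 1]
    xm[called_unmeth] = _SYMBOLS[code[called_unmeth], 0]
    return base, xm


def _draw_products(n: int, directional: bool, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 2 if directional else 4, n).astype(np.int8)


def _draw_mapq(n: int, low_fraction: float, rng: np.random.Generator) -> np.ndarray:
    mapq = np.full(n, 40, dtype=np.int16)
    if low_fraction > 0:
        mapq[rng.random(n) < low_fraction] = 10
    return mapq


def simulate_bisulfite_reads(
    refs: References,
    truth: MethylationTruth,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[ReadBatch, ReadBatch]:
    """Emit pre-aligned bisulfite reads for the three sub-genomes plus the
    unmethylated control contig.

    Each read carries a methylation string over the analysis reference:
    a methylated cytosine reads C (upper-case symbol); an unmethylated one
    reads T with probability ``conversion_rate`` (lower-case symbol) and C
    otherwise — the unconverted remainder is exactly the background a real
    conversion-rate control quantifies. Sequencing errors are applied after
    conversion, and the methylation string reflects the final base, as a
    reference-based methylation caller would see it. With
    ``directional=False`` reads are drawn from all four bisulfite strand
    products (the two complementary products carry the same conversion state
    as their originals).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    if config.depth == 0:
        warnings.warn("depth=0: no reads simulated")
        empty = _empty_batch(refs.contigs + [CONTROL_CONTIG], config.read_length)
        return empty, empty

    Lr = config.read_length
    all_contigs = refs.contigs + [CONTROL_CONTIG]
    control_map = build_context_map(refs.control)
    parts: list[ReadBatch] = []
    for ci, contig in enumerate(all_contigs):
        is_control = contig == CONTROL_CONTIG
        seq_len = refs.control.size if is_control else refs.genomes["A"][contig].size
        if seq_len < Lr:
            raise ValueError(f"contig {contig} shorter than read_length")
        n_reads = int(round(config.depth * seq_len / Lr))
        genome_ids = (-1,) if is_control else (0, 1, 2)
        for g in genome_ids:
            if is_control:
                seq_g = refs.control
                prob_plus = np.zeros(seq_len, dtype=np.float32)
                prob_minus = prob_plus
                code_plus = control_map.plus_code
                code_minus = control_map.minus_code
            else:
                seq_g = refs.genomes[GENOMES[g]][contig]
                prob_plus = truth.prob_plus[contig][g]
                prob_minus = truth.prob_minus[contig][g]
                code_plus = truth.code_plus[contig]
                code_minus = truth.code_minus[contig]
            starts = rng.integers(0, seq_len - Lr + 1, n_reads).astype(np.int32)
            product = _draw_products(n_reads, config.directional, rng)
            mapq = _draw_mapq(n_reads, config.low_mapq_fraction, rng)
            ct_mask = np.isin(product, _CT_PRODUCTS)
            seq_mat = np.empty((n_reads, Lr), dtype=np.uint8)
            xm_mat = np.empty((n_reads, Lr), dtype=np.uint8)
            for ct in (True, False):
                sel = np.flatnonzero(ct_mask == ct)
                if not sel.size:
                    continue
                prob = prob_plus if ct else prob_minus
                code = code_plus if ct else code_minus
                s, x = _synthesize_reads(
                    seq_g, prob, code, starts[sel], ct, Lr,
                    config.conversion_rate, config.error_rate, rng)
                seq_mat[sel] = s
                xm_mat[sel] = x
            parts.append(ReadBatch(
                all_contigs,
                np.full(n_reads, ci, dtype=np.int32), starts, product, mapq,
                np.full(n_reads, g, dtype=np.int8), seq_mat, xm_mat))
    batch = ReadBatch.concat(parts)
    is_control = batch.contig_idx == len(refs.contigs)
    return batch.subset(~is_control), batch.subset(is_control)


@dataclass(frozen=True)
class UntreatedRead:
    """A genome-labelled read without bisulfite conversion (SNP derivation)."""

    label: str  # single genome or pair, e.g. "A" or "BD"
    contig: str
    start: int
    seq: str


def simulate_untreated_reads(
    refs: References,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    depth: float = 30.0,
) -> list[UntreatedRead]:
    """Genome-assigned untreated reads, as used to derive the secondary SNP list."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    Lr = config.read_length
    out: list[UntreatedRead] = []
    for contig in refs.contigs:
        L = refs.genomes["A"][contig].size
        n_reads = int(round(depth * L / Lr))
        for g in GENOMES:
            seq = refs.genomes[g][contig]
            starts = rng.integers(0, L - Lr + 1, n_reads)
            for s in starts:
                arr = seq[s:s + Lr].copy()
                if config.error_rate > 0:
                    emask = rng.random(Lr) < config.error_rate
                    n_err = int(np.count_nonzero(emask))
                    if n_err:
                        cur = _BASE_INDEX[arr[emask]]
                        arr[emask] = _BASES[(cur + rng.integers(1, 4, n_err)) % 4]
                out.append(UntreatedRead(g, contig, int(s), bytes_to_seq(arr)))
    return out


# ---------------------------------------------------------------------------
# regions and expression


def default_regions(refs: References) -> list[RegionAnnotation]:
    """A simple annotation layout: four of every five contigs carry one gene
    (promoter, exon, intron, exon) followed by a gene-adjacent non-transcribed
    tail; every fifth contig is entirely non-transcribed with no gene."""
    regions: list[RegionAnnotation] = []
    for ci, contig in enumerate(refs.contigs):
        L = refs.genomes["A"][contig].size
        if ci % 5 == 4:
            regions.append(RegionAnnotation(
                f"r_{contig}_nt", contig, 0, L, "non_transcribed"))
            continue
        gene = f"g_{contig}"
        cuts = [0, int(0.3 * L), int(0.55 * L), int(0.7 * L), int(0.85 * L), L]
        classes = ["promoter", "exon", "intron", "exon", "non_transcribed"]
        for k, (s, e, cls) in enumerate(zip(cuts[:-1], cuts[1:], classes)):
            gene_id = gene if cls != "non_transcribed" else None
            regions.append(RegionAnnotation(
                f"r_{contig}_{k}", contig, s, e, cls, gene_id))
    return regions


@dataclass
class ExpressionTruth:
    expression: list[AllelicExpression]
    suppressed: dict[str, tuple[str, ...]]  # gene_id -> suppressed genomes
    de_flags: dict[str, tuple[bool, bool, bool]]


def simulate_expression(
    regions: Sequence[RegionAnnotation],
    truth: MethylationTruth,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> ExpressionTruth:
    """Per-gene allelic expression with promoter-methylation suppression.

    Baseline per-genome expression is drawn i.i.d. from a Gamma(20, 5)
    distribution (positive, coefficient of variation ~0.22); a genome whose
    promoter contains at least one uni-genome-methylated site has its
    expression multiplied by ``promoter_suppression``. PPLR values are
    simulated around the 0.5 no-change baseline with a ``de_fraction`` of
    regions shifted into the differential range.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 4)
    promoters: dict[str, RegionAnnotation] = {
        r.gene_id: r for r in regions if r.cls == "promoter" and r.gene_id}
    tbl = truth.table
    uni = tbl[tbl["pattern"].astype(str).str.startswith("uni_")]
    uni_by_contig = {str(c): grp for c, grp in uni.groupby("contig", observed=True)}
    out: list[AllelicExpression] = []
    suppressed: dict[str, tuple[str, ...]] = {}
    de_flags: dict[str, tuple[bool, bool, bool]] = {}
    for gene_id in sorted(promoters):
        prom = promoters[gene_id]
        grp = uni_by_contig.get(prom.contig)
        if grp is None:
            hit = ()
        else:
            in_prom = grp[(grp["pos"] >= prom.start) & (grp["pos"] < prom.end)]
            hit = tuple(
                g for g in GENOMES
                if (in_prom["pattern"] == f"uni_{g}").any())
        baseline = rng.gamma(20.0, 5.0, 3)
        factors = np.array([
            config.promoter_suppression if g in hit else 1.0 for g in GENOMES])
        raw = baseline * factors
        de = rng.random(3) < config.de_fraction
        pplr = np.clip(rng.normal(0.5, 0.03, 3), 0.01, 0.99)
        for k in range(3):
            if de[k]:
                shift = rng.uniform(0.15, 0.45)
                pplr[k] = 0.5 + shift if rng.random() < 0.5 else 0.5 - shift
        out.append(AllelicExpression(gene_id, tuple(float(v) for v in raw),
                                     tuple(float(v) for v in pplr)))
        suppressed[gene_id] = hit
        de_flags[gene_id] = tuple(bool(v) for v in de)
    return ExpressionTruth(out, suppressed, de_flags)
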