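"""End-to-end orchestration: simulate, assign, tally, classify, summarize.

The per-record operations in :mod:`partition` and :mod:`extraction` define
the semantics; this module implements the same logic over column-oriented
read batches so that study-scale simulations (hundreds of thousands of
reads) run in seconds. Equivalence of the two paths is asserted in the test
suite.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classification import ClassificationResult, classify_site_table
from .config import SimulationConfig, Thresholds
from .dmr import call_genome_specific_dmrs, summarize_regions
from .expression import correlate_methylation_expression, grand_mean_normalized
from .extraction import build_context_map, conversion_rate_from_xm_matrix
from .records import AllelicExpression, HomoeologousSNP, RegionAnnotation
from .snp_catalog import filter_bisulfite_ambiguous
from .synthetic import (
    CONTROL_CONTIG,
    ExpressionTruth,
    MethylationTruth,
    ReadBatch,
    References,
    assign_methylation_truth,
    default_regions,
    generate_homoeologous_references,
    simulate_bisulfite_reads,
    simulate_expression,
)

_C, _T, _G, _A = 67, 84, 71, 65
#: label bitmask -> tally column (A,B,D,AB,AD,BD); -1 = unassignable
_MASK_TO_COL = np.array([-1, 0, 1, 3, 2, 4, 5, -1], dtype=np.int8)
_COL_NAMES = ("A", "B", "D", "AB", "AD", "BD")
_CTX_NAMES = np.array(["CpG", "CHG", "CHH"])


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    refs: References
    truth: MethylationTruth
    reads: ReadBatch
    control_reads: ReadBatch
    regions: list[RegionAnnotation]
    expression: ExpressionTruth
    catalog: list[HomoeologousSNP]  # bisulfite-safe SNPs driving assignment


def simulate_dataset(
    config: SimulationConfig, seed: Optional[int] = None,
) -> SimulatedDataset:
    """Generate a complete synthetic experiment with known ground truth.

    Each stochastic stage gets an independent child generator spawned from
    one seed, so identical (config, seed) pairs reproduce every output
    byte-for-byte.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    rngs = [np.random.default_rng(s) for s in root.spawn(4)]
    refs = generate_homoeologous_references(config, rngs[0])
    truth = assign_methylation_truth(refs, config, rngs[1])
    reads, control = simulate_bisulfite_reads(refs, truth, config, rngs[2])
    regions = default_regions(refs)
    expression = simulate_expression(regions, truth, config, rngs[3])
    catalog = filter_bisulfite_ambiguous(refs.snps)
    return SimulatedDataset(config, refs, truth, reads, control, regions,
                            expression, catalog)


@dataclass
class PartitionStats:
    n_reads: int = 0
    n_low_mapq: int = 0
    n_unassigned_reads: int = 0
    n_conflicting_reads: int = 0
    n_observations: int = 0
    n_unassigned_observations: int = 0
    n_unknown_context: int = 0


def extract_and_partition(
    batch: ReadBatch,
    reference: dict[str, np.ndarray],
    catalog: Sequence[HomoeologousSNP],
    thresholds: Optional[Thresholds] = None,
) -> tuple[pd.DataFrame, PartitionStats]:
    """Assign reads to genome groups at catalogue SNPs and tally per-site
    methylated/total counts per label.

    Implements: MAPQ gate (> mapq_min); per-SNP allele matching under
    conversion compatibility; intersection of labels for reads spanning
    several SNPs (contradictions discard the read); per-site accumulation
    into the A/B/D/AB/AD/BD columns. Returns one row per cytosine site with
    at least one assigned observation.
    """
    thr = thresholds or Thresholds()
    stats = PartitionStats(n_reads=batch.n)
    snp_by_contig: dict[str, list[HomoeologousSNP]] = {}
    for snp in catalog:
        snp_by_contig.setdefault(snp.contig, []).append(snp)
    frames = []
    for ci, contig in enumerate(batch.contigs):
        if contig not in reference:
            continue
        ref = reference[contig]
        L = ref.size
        rows_all = np.flatnonzero(batch.contig_idx == ci)
        if not rows_all.size:
            continue
        mapq_ok = batch.mapq[rows_all] > thr.mapq_min
        stats.n_low_mapq += int(np.count_nonzero(~mapq_ok))
        rows = rows_all[mapq_ok]
        if not rows.size:
            continue
        starts = batch.start[rows]
        order = np.argsort(starts, kind="stable")
        rows = rows[order]
        starts = starts[order]
        seq = batch.seq[rows]
        xm = batch.xm[rows]
        ct = batch.xg_ct[rows]
        Lr = batch.read_length

        label_mask = np.full(rows.size, 7, dtype=np.uint8)
        hits = np.zeros(rows.size, dtype=np.int32)
        alleles = [(np.uint8(ord(s.allele_a)), np.uint8(ord(s.allele_b)),
                    np.uint8(ord(s.allele_d)), s.pos)
                   for s in snp_by_contig.get(contig, [])]
        for a_a, a_b, a_d, pos in alleles:
            lo = np.searchsorted(starts, pos - Lr + 1, side="left")
            hi = np.searchsorted(starts, pos, side="right")
            if lo == hi:
                continue
            sel = slice(lo, hi)
            base = seq[np.arange(lo, hi), pos - starts[sel]]
            ct_sel = ct[sel]
            m = np.zeros(hi - lo, dtype=np.uint8)
            for bit, al in ((1, a_a), (2, a_b), (4, a_d)):
                match = base == al
                match |= ct_sel & (al == _C) & (base == _T)
                match |= ~ct_sel & (al == _G) & (base == _A)
                m |= np.where(match, bit, 0).astype(np.uint8)
            label_mask[sel] &= m
            hits[sel] += 1
        label = np.where(hits > 0, label_mask, 0)
        stats.n_conflicting_reads += int(np.count_nonzero((label == 0) & (hits > 0)))
        stats.n_unassigned_reads += int(np.count_nonzero(hits == 0))
        col = _MASK_TO_COL[label]

        cmap = build_context_map(ref)
        tot = np.zeros((2, L * 6), dtype=np.int64)
        met = np.zeros((2, L * 6), dtype=np.int64)
        for is_ct, strand_idx in ((True, 0), (False, 1)):
            sub = np.flatnonzero(ct == is_ct)
            if not sub.size:
                continue
            x = xm[sub]
            active = (x != ord(".")) & (x != ord("U")) & (x != ord("u"))
            r, c = np.nonzero(active)
            if not r.size:
                continue
            pos = starts[sub][r] + c
            sym = x[r, c]
            meth = sym < ord("a")
            labcol = col[sub][r]
            stats.n_observations += r.size
            keep = labcol >= 0
            stats.n_unassigned_observations += int(np.count_nonzero(~keep))
            flat = pos[keep] * 6 + labcol[keep]
            tot[strand_idx] += np.bincount(flat, minlength=L * 6)
            met[strand_idx] += np.bincount(flat, weights=meth[keep],
                                           minlength=L * 6).astype(np.int64)
        for strand_idx, strand, codes in ((0, "+", cmap.plus_code),
                                          (1, "-", cmap.minus_code)):
            t = tot[strand_idx].reshape(L, 6)
            m = met[strand_idx].reshape(L, 6)
            covered = np.flatnonzero(t.sum(axis=1) > 0)
            if not covered.size:
                continue
            known = codes[covered] >= 0
            stats.n_unknown_context += int(np.count_nonzero(~known))
            covered = covered[known]
            frame = {"contig": contig, "pos": covered, "strand": strand,
                     "context": _CTX_NAMES[codes[covered]]}
            for k, name in enumerate(_COL_NAMES):
                frame[f"meth_{name}"] = m[covered, k]
                frame[f"tot_{name}"] = t[covered, k]
            frames.append(pd.DataFrame(frame))
    if not frames:
        cols = (["contig", "pos", "strand", "context"]
                + [f"{kind}_{n}" for n in _COL_NAMES for kind in ("meth", "tot")])
        return pd.DataFrame(columns=cols), stats
    out = pd.concat(frames, ignore_index=True)
    return out, stats


def annotate_truth(sites: pd.DataFrame, truth: MethylationTruth) -> pd.DataFrame:
    """Attach the generator's pattern label to each classified site."""
    from .synthetic import PATTERN_ORDER

    patterns = []
    for row in sites.itertuples():
        arr = (truth.pattern_plus if row.strand == "+"
               else truth.pattern_minus).get(str(row.contig))
        code = -1 if arr is None else int(arr[int(row.pos)])
        patterns.append(PATTERN_ORDER[code] if code >= 0 else None)
    out = sites.copy()
    out["truth_pattern"] = patterns
    return out


@dataclass
class PipelineResult:
    conversion_rate: Optional[float]
    sites: pd.DataFrame
    classification: ClassificationResult
    partition_stats: PartitionStats
    region_summaries: list = field(default_factory=list)
    genome_dmrs: Optional[pd.DataFrame] = None
    expression_summary: Optional[pd.DataFrame] = None
    expression_grand_mean: Optional[float] = None

    @property
    def patterns(self) -> pd.DataFrame:
        return self.classification.table


def run_pipeline(
    dataset: SimulatedDataset, thresholds: Optional[Thresholds] = None,
    with_truth: bool = True,
) -> PipelineResult:
    """Run the full within-sample analysis on a simulated dataset."""
    thr = thresholds or Thresholds()
    reference = dataset.refs.reference()
    sites, stats = extract_and_partition(
        dataset.reads, reference, dataset.catalog, thr)
    if with_truth:
        sites = annotate_truth(sites, dataset.truth)
    classification = classify_site_table(sites, thr)
    conversion = conversion_rate_from_xm_matrix(dataset.control_reads.xm)
    summaries = summarize_regions(classification.table, dataset.regions)
    dmrs = call_genome_specific_dmrs(summaries, thr)
    expr = dataset.expression.expression
    expr_summary = correlate_methylation_expression(
        classification.table, dataset.regions, expr)
    grand_mean = grand_mean_normalized(expr) if expr else None
    return PipelineResult(
        conversion_rate=conversion, sites=sites, classification=classification,
        partition_stats=stats, region_summaries=summaries, genome_dmrs=dmrs,
        expression_summary=expr_summary, expression_grand_mean=grand_mean)


def pattern_fractions(patterns: pd.DataFrame) -> dict[str, float]:
    """Percentages of methylated sites classified tri / uni+bi
    (differential) / intermediate, plus the methylated-site count.

    "Methylated" means classified tri, uni, bi or intermediate (methylation
    in at least one sub-genome); ``none``, ``unresolved`` and ``nocall``
    sites are outside the denominator.
    """
    counts = patterns["pattern"].value_counts()
    tri = int(counts.get("tri", 0))
    uni = sum(int(counts.get(f"uni_{g}", 0)) for g in "ABD")
    bi = sum(int(counts.get(f"bi_{p}", 0)) for p in ("AB", "AD", "BD"))
    inter = int(counts.get("intermediate", 0))
    denom = tri + uni + bi + inter
    if denom == 0:
        return {"n_methylated": 0, "tri_pct": np.nan,
                "differential_pct": np.nan, "intermediate_pct": np.nan}
    return {
        "n_methylated": denom,
        "tri_pct": 100.0 * tri / denom,
        "differential_pct": 100.0 * (uni + bi) / denom,
        "intermediate_pct": 100.0 * inter / denom,
    }
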