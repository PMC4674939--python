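"""Assignment of SNP-overlapping bisulfite reads to sub-genomes and
per-site per-genome methylation tallies.

The conversion-compatibility rule: on a C->T-converted strand product a read
T also matches a catalogued C allele (the C may simply be an unmethylated,
converted cytosine); symmetrically a read A matches a G allele on
G->A-converted products. Because the catalogue excludes C/T and G/A allele
pairs, this never makes two allele groups both match the same read base.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .config import Thresholds
from .extraction import SiteCall
from .records import (
    PARTITIONS,
    TALLY_LABELS,
    BisulfiteRead,
    CytosineSite,
    GenomeLabel,
    HomoeologousSNP,
    SiteGenomeCounts,
)

_GENOME_BITS = (GenomeLabel.A, GenomeLabel.B, GenomeLabel.D)


def base_matches_allele(base: str, allele: str, xg: str) -> bool:
    """Does a read base match an allele under the conversion model?"""
    if base == allele:
        return True
    if xg == "CT":
        return allele == "C" and base == "T"
    return allele == "G" and base == "A"


def assign_read(read: BisulfiteRead, snp: HomoeologousSNP) -> GenomeLabel:
    """Assign a read to a genome or genome pair from a single SNP.

    The read base at the SNP is compared to the three catalogued alleles
    under conversion compatibility; a unique allele group gives that label,
    anything else (no match, or a read not passing the MAPQ gate upstream)
    is UNASSIGNED.
    """
    offset = snp.pos - read.pos
    if not 0 <= offset < len(read):
        raise ValueError(f"read {read.read_id} does not overlap SNP at {snp.pos}")
    base = read.seq[offset]
    mask = 0
    for bit, allele in zip(_GENOME_BITS, snp.alleles):
        if base_matches_allele(base, allele, read.xg):
            mask |= bit.value
    if mask in (0, 7):
        return GenomeLabel.UNASSIGNED
    return GenomeLabel(mask)


def resolve_labels(labels: Iterable[GenomeLabel]) -> GenomeLabel:
    """Combine per-SNP labels for one read: intersection of genome sets.

    Consistent labels give the most specific label (A and AB -> A);
    contradictory labels (empty intersection) give UNASSIGNED. A label that
    is already UNASSIGNED is contradictory evidence, not missing evidence,
    and poisons the read.
    """
    mask = 7
    seen = False
    for lab in labels:
        seen = True
        mask &= lab.value
    if not seen or mask in (0, 7):
        return GenomeLabel.UNASSIGNED
    return GenomeLabel(mask)


def assign_read_over_snps(
    read: BisulfiteRead,
    snps: Sequence[HomoeologousSNP],
    mapq_min: int = 20,
) -> GenomeLabel:
    """Assign a read from all catalogue SNPs it overlaps (MAPQ-gated)."""
    if read.mapq <= mapq_min:
        return GenomeLabel.UNASSIGNED
    overlapping = [s for s in snps
                   if s.contig == read.contig and read.pos <= s.pos < read.pos + len(read)]
    if not overlapping:
        return GenomeLabel.UNASSIGNED
    return resolve_labels(assign_read(read, s) for s in overlapping)


@dataclass
class TallyResult:
    sites: dict[CytosineSite, SiteGenomeCounts] = field(default_factory=dict)
    unassigned_observations: int = 0


def evaluate_coverage(
    counts: SiteGenomeCounts, thresholds: Optional[Thresholds] = None,
) -> SiteGenomeCounts:
    """Set resolution mode, dominant partition and the coverage gate.

    tri_resolved requires every single-genome label at ``single_depth`` or
    more; otherwise the partition with the largest single+pair total is
    taken, passing when the single reaches ``single_depth`` and the pair
    ``pair_depth``. Pair labels are never split arithmetically.
    """
    thr = thresholds or Thresholds()
    singles = [counts.total(g) for g in _GENOME_BITS]
    if all(t >= thr.single_depth for t in singles):
        counts.mode = "tri_resolved"
        counts.dominant_partition = None
        counts.passes_coverage = True
        return counts
    best = None
    best_total = -1
    for single, pair in PARTITIONS:
        total = counts.total(single) + counts.total(pair)
        if total > best_total:
            best_total = total
            best = (single, pair)
    counts.mode = "biallelic_pair"
    counts.dominant_partition = best
    single, pair = best
    counts.passes_coverage = (counts.total(single) >= thr.single_depth
                              and counts.total(pair) >= thr.pair_depth)
    return counts


def tally_sites(
    calls: Iterable[SiteCall],
    read_labels: dict[str, GenomeLabel],
    thresholds: Optional[Thresholds] = None,
) -> TallyResult:
    """Accumulate per-site methylated/total counts per genome label."""
    acc: dict[CytosineSite, dict[GenomeLabel, list[int]]] = defaultdict(
        lambda: defaultdict(lambda: [0, 0]))
    result = TallyResult()
    for call in calls:
        label = read_labels.get(call.read_id, GenomeLabel.UNASSIGNED)
        if label == GenomeLabel.UNASSIGNED or label == GenomeLabel.ABD:
            result.unassigned_observations += 1
            continue
        cell = acc[call.site][label]
        cell[1] += 1
        if call.methylated:
            cell[0] += 1
    for site, by_label in acc.items():
        counts = SiteGenomeCounts(
            site=site,
            counts={lab: (m, t) for lab, (m, t) in by_label.items()},
        )
        result.sites[site] = evaluate_coverage(counts, thresholds)
    return result


def pool_replicates(replicates: Sequence[SiteGenomeCounts],
                    thresholds: Optional[Thresholds] = None) -> SiteGenomeCounts:
    """Sum counts label-wise across replicates of the same site and
    re-evaluate the coverage gate on the pooled counts."""
    if not replicates:
        raise ValueError("no replicates to pool")
    site = replicates[0].site
    if any(r.site != site for r in replicates):
        raise ValueError("pool_replicates requires counts for one site")
    pooled: dict[GenomeLabel, tuple[int, int]] = {}
    for lab in TALLY_LABELS:
        m = sum(r.meth(lab) for r in replicates)
        t = sum(r.total(lab) for r in replicates)
        if t:
            pooled[lab] = (m, t)
    return evaluate_coverage(SiteGenomeCounts(site=site, counts=pooled), thresholds)
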