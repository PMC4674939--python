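"""Building, filtering and merging the homoeologous SNP catalogue.

A homoeologous SNP is a fixed difference between the A, B and D sub-genomes
(not a within-population polymorphism): a position where each sub-genome
shows exactly one unambiguous allele and at least one differs. SNPs whose
distinct alleles include a {C,T} or {G,A} pair are useless in bisulfite
data (conversion makes them indistinguishable from methylation state) and
are removed before read assignment.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .records import GENOMES, HomoeologousSNP, bisulfite_safe

#: pileup type: (contig, pos) -> genome -> base counts
Pileups = Mapping[tuple[str, int], Mapping[str, Mapping[str, int]]]


@dataclass
class FilterReport:
    kept: int = 0
    removed_bisulfite: int = 0
    excluded_low_depth: int = 0
    excluded_heterozygous: int = 0
    excluded_no_divergence: int = 0
    excluded_maf: int = 0
    excluded_no_consensus: int = 0


def derive_snps_from_progenitors(
    pileups: Pileups,
    min_depth: int = 5,
    min_maf: float = 0.1,
    report: Optional[FilterReport] = None,
) -> list[HomoeologousSNP]:
    """Homoeologous SNPs from per-sub-genome progenitor base calls.

    A position is emitted only when every sub-genome shows a single
    unambiguous allele at ``min_depth`` or more, at least one allele
    differs, and the pooled minor-allele frequency exceeds ``min_maf``.
    Heterozygous calls (more than one base per genome) exclude the
    position.
    """
    rep = report if report is not None else FilterReport()
    out: list[HomoeologousSNP] = []
    for (contig, pos), by_genome in sorted(pileups.items()):
        alleles = []
        ok = True
        for g in GENOMES:
            counts = {b: c for b, c in by_genome.get(g, {}).items() if c > 0}
            if len(counts) > 1:
                rep.excluded_heterozygous += 1
                ok = False
                break
            if not counts or max(counts.values()) < min_depth:
                rep.excluded_low_depth += 1
                ok = False
                break
            (base, _), = counts.items()
            if base not in "ACGT":
                raise ValueError(f"invalid base {base!r} at {contig}:{pos}")
            alleles.append(base)
        if not ok:
            continue
        if len(set(alleles)) < 2:
            rep.excluded_no_divergence += 1
            continue
        pooled: Counter = Counter()
        for g in GENOMES:
            pooled.update(by_genome[g])
        total = sum(pooled.values())
        minor = total - pooled.most_common(1)[0][1]
        if total == 0 or minor / total <= min_maf:
            rep.excluded_maf += 1
            continue
        out.append(HomoeologousSNP(contig, pos, *alleles, source="progenitor"))
        rep.kept += 1
    return out


def filter_bisulfite_ambiguous(
    snps: Iterable[HomoeologousSNP],
    report: Optional[FilterReport] = None,
) -> list[HomoeologousSNP]:
    """Remove SNPs whose distinct alleles include a {C,T} or {G,A} pair.

    Idempotent: applying it twice changes nothing.
    """
    kept = []
    removed = 0
    for snp in snps:
        if bisulfite_safe(*snp.alleles):
            kept.append(snp)
        else:
            removed += 1
    if report is not None:
        report.removed_bisulfite += removed
    return kept


@dataclass
class MergeStats:
    n_primary: int = 0
    n_secondary: int = 0
    n_shared: int = 0
    n_conserved: int = 0
    n_conflicts: int = 0

    @property
    def conservation(self) -> Optional[float]:
        """Fraction of shared positions with identical alleles, or None when
        no positions are shared (statistic not applicable)."""
        if self.n_shared == 0:
            return None
        return self.n_conserved / self.n_shared


def merge_snp_sources(
    primary: Sequence[HomoeologousSNP],
    secondary: Sequence[HomoeologousSNP],
    policy: str = "prefer_primary",
) -> tuple[list[HomoeologousSNP], MergeStats]:
    """Union of two catalogues keyed on (contig, position).

    At shared positions the allele triples are compared for the conservation
    statistic; conflicting positions are resolved by ``policy``
    (prefer_primary keeps the primary's alleles — the progenitor-derived
    list is the reference, the second source fills gaps). Records at shared
    positions have their source set to ``merged``.
    """
    if policy not in ("prefer_primary", "prefer_secondary"):
        raise ValueError(f"unknown merge policy {policy!r}")
    stats = MergeStats(n_primary=len(primary), n_secondary=len(secondary))
    by_key = {(s.contig, s.pos): s for s in primary}
    merged: dict[tuple[str, int], HomoeologousSNP] = dict(by_key)
    for snp in secondary:
        key = (snp.contig, snp.pos)
        if key in by_key:
            stats.n_shared += 1
            prior = by_key[key]
            if prior.alleles == snp.alleles:
                stats.n_conserved += 1
            else:
                stats.n_conflicts += 1
            winner = prior if policy == "prefer_primary" else snp
            merged[key] = HomoeologousSNP(
                winner.contig, winner.pos, *winner.alleles, source="merged")
        else:
            merged[key] = snp
    return [merged[k] for k in sorted(merged)], stats


def derive_snps_from_assigned_reads(
    reads: Iterable,
    reference: Mapping[str, str],
    min_depth: int = 5,
    min_maf: float = 0.1,
    consensus: float = 0.9,
    report: Optional[FilterReport] = None,
) -> list[HomoeologousSNP]:
    """Homoeologous SNPs from genome-labelled untreated reads.

    ``reads`` yield objects with ``label`` (a genome or genome pair, e.g.
    "A" or "BD"), ``contig``, ``start`` and ``seq``. At each position with
    an alternative allele (pooled MAF > ``min_maf`` at depth >=
    ``min_depth``), the per-label base consensus (>= ``consensus`` of bases
    agreeing, each label at >= ``min_depth``) defines per-genome alleles;
    positions where any genome is uncovered or non-consensus are skipped.
    """
    rep = report if report is not None else FilterReport()
    # (contig, pos) -> label -> Counter
    piles: dict[tuple[str, int], dict[str, Counter]] = {}
    for read in reads:
        for offset, base in enumerate(read.seq):
            if base not in "ACGT":
                continue
            key = (read.contig, read.start + offset)
            piles.setdefault(key, {}).setdefault(read.label, Counter())[base] += 1
    out: list[HomoeologousSNP] = []
    for (contig, pos), by_label in sorted(piles.items()):
        pooled: Counter = Counter()
        for c in by_label.values():
            pooled.update(c)
        total = sum(pooled.values())
        minor = total - pooled.most_common(1)[0][1]
        if total < min_depth or minor / total <= min_maf:
            continue  # no alternative allele here
        alleles = {}
        ok = True
        for g in GENOMES:
            votes: Counter = Counter()
            for label, counts in by_label.items():
                if g in label:
                    votes.update(counts)
            depth = sum(votes.values())
            if depth < min_depth:
                rep.excluded_low_depth += 1
                ok = False
                break
            base, n = votes.most_common(1)[0]
            if n / depth < consensus:
                rep.excluded_no_consensus += 1
                ok = False
                break
            alleles[g] = base
        if not ok:
            continue
        triple = tuple(alleles[g] for g in GENOMES)
        if len(set(triple)) < 2:
            rep.excluded_no_divergence += 1
            continue
        out.append(HomoeologousSNP(contig, pos, *triple, source="assigned_reads"))
        rep.kept += 1
    return out
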