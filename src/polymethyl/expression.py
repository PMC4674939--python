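"""Allelic-expression normalization, co-expression categories and
methylation-expression integration.

Expression per region is normalized so the three sub-genome shares sum to
100% (balanced expression = ~33.3% each). Methylated sites are joined to
the normalized expression of the region they fall in — promoters and
gene-adjacent non-transcribed regions inherit the expression of their
linked/nearest gene — and summarized per (pattern group x annotation class)
stratum as a 20-bin histogram with mean, 75th percentile and excess
kurtosis.
"""
from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import Thresholds
from .records import (
    GENOMES,
    AllelicExpression,
    RegionAnnotation,
)

HIST_EDGES = np.arange(0.0, 105.0, 5.0)  # [k, k+5), last bin [95, 100] closed


def normalize_allelic_expression(
    raw: Sequence[float],
) -> Optional[tuple[float, float, float]]:
    """Per-genome expression shares in percent, summing to 100.

    Returns None for a non-expressed region (raw sum 0), which is excluded
    from all distributional analyses.
    """
    if any(v < 0 for v in raw):
        raise ValueError("expression levels must be non-negative")
    total = sum(raw)
    if total <= 0:
        return None
    return tuple(100.0 * v / total for v in raw)


def categorize_coexpression(
    normalized: Sequence[float], window: float = 5.0,
) -> str:
    """Co-expression category of a normalized (A, B, D) triple.

    conserved: all three within ``window`` of each other; uni_dominant_X: X
    at least ``window`` above both others, which are within ``window`` of
    each other; bi_dominant_XY: X and Y each at least ``window`` above the
    third and within ``window`` of each other; otherwise all_differ.
    """
    v = dict(zip(GENOMES, normalized))
    if max(v.values()) - min(v.values()) <= window:
        return "conserved"
    for x in GENOMES:
        others = [g for g in GENOMES if g != x]
        if (all(v[x] >= v[y] + window for y in others)
                and abs(v[others[0]] - v[others[1]]) <= window):
            return f"uni_dominant_{x}"
    for x, y in (("A", "B"), ("A", "D"), ("B", "D")):
        z = next(g for g in GENOMES if g not in (x, y))
        if (v[x] >= v[z] + window and v[y] >= v[z] + window
                and abs(v[x] - v[y]) <= window):
            return f"bi_dominant_{x}{y}"
    return "all_differ"


def flag_differential_expression(
    pplr: float, thresholds: Optional[Thresholds] = None,
) -> str:
    """PPLR-based differential-expression flag.

    PPLR (probability of positive log ratio) of 0.5 means no change;
    deviations of +-0.1 or more (<=0.4 / >=0.6) flag differential
    expression and <0.10 / >0.90 high-confidence differential expression
    (the high flags subsume the plain ones).
    """
    thr = thresholds or Thresholds()
    if not 0.0 <= pplr <= 1.0:
        raise ValueError(f"PPLR {pplr} outside [0, 1]")
    if pplr < thr.pplr_highde_low:
        return "highly_DE_down"
    if pplr > thr.pplr_highde_high:
        return "highly_DE_up"
    if pplr <= thr.pplr_de_low:
        return "DE_down"
    if pplr >= thr.pplr_de_high:
        return "DE_up"
    return "not_DE"


# ---------------------------------------------------------------------------
# methylation-expression integration


def link_region_to_gene(
    region: RegionAnnotation, regions: Sequence[RegionAnnotation],
) -> Optional[str]:
    """Gene whose expression a region inherits.

    Transcribed regions and promoters carry their own gene id; a
    non-transcribed region inherits the nearest gene-linked region on the
    same contig (ties broken downstream, i.e. the gene starting at or after
    the region).
    """
    if region.gene_id:
        return region.gene_id
    genes = [(r.start, r.end, r.gene_id) for r in regions
             if r.contig == region.contig and r.gene_id]
    if not genes:
        return None
    mid = (region.start + region.end) // 2

    def distance(span):
        s, e, _ = span
        if s <= mid < e:
            return 0
        return min(abs(mid - s), abs(mid - (e - 1)))

    best = min(distance(g) for g in genes)
    tied = [g for g in genes if distance(g) == best]
    downstream = [g for g in tied if g[0] >= mid]
    return (downstream[0] if downstream else tied[0])[2]


@dataclass
class _RegionIndex:
    starts: dict[str, list[int]]
    regions: dict[str, list[RegionAnnotation]]

    @classmethod
    def build(cls, regions: Sequence[RegionAnnotation]) -> "_RegionIndex":
        starts: dict[str, list[int]] = {}
        by_contig: dict[str, list[RegionAnnotation]] = {}
        for r in sorted(regions, key=lambda r: (r.contig, r.start)):
            starts.setdefault(r.contig, []).append(r.start)
            by_contig.setdefault(r.contig, []).append(r)
        return cls(starts, by_contig)

    def find(self, contig: str, pos: int) -> Optional[RegionAnnotation]:
        if contig not in self.starts:
            return None
        i = bisect_left(self.starts[contig], pos + 1) - 1
        if i < 0:
            return None
        r = self.regions[contig][i]
        return r if r.contains(pos) else None


_PATTERN_GROUP = {"tri": "tri"}
_PATTERN_GROUP.update({f"uni_{g}": "uni" for g in GENOMES})
_PATTERN_GROUP.update({f"bi_{p}": "bi" for p in ("AB", "AD", "BD")})


def correlate_methylation_expression(
    patterns: pd.DataFrame,
    regions: Sequence[RegionAnnotation],
    expression: Sequence[AllelicExpression],
) -> pd.DataFrame:
    """Distribution of allelic expression per methylation stratum.

    For every tri/uni/bi-classified site and every genome methylated under
    its pattern, the normalized expression share of that genome in the
    site's region is recorded; strata are (pattern group x annotation
    class). Expression is keyed by gene id; promoters and non-transcribed
    regions inherit their linked/nearest gene's expression. Returns one row
    per stratum: n, mean, 75th percentile, excess kurtosis and the 20-bin
    histogram over [0, 100].
    """
    index = _RegionIndex.build(regions)
    norm_by_gene: dict[str, tuple[float, float, float]] = {}
    for e in expression:
        n = e.normalized
        if n is not None:
            norm_by_gene[e.region_id] = n
    gene_cache: dict[str, Optional[str]] = {}
    values: dict[tuple[str, str], list[float]] = {}
    for row in patterns.itertuples():
        group = _PATTERN_GROUP.get(row.pattern)
        if group is None:
            continue
        region = index.find(str(row.contig), int(row.pos))
        if region is None:
            continue
        if region.region_id not in gene_cache:
            gene_cache[region.region_id] = link_region_to_gene(region, regions)
        gene = gene_cache[region.region_id]
        if gene is None or gene not in norm_by_gene:
            continue
        norm = norm_by_gene[gene]
        if row.pattern == "tri":
            meth_genomes = GENOMES
        elif group == "uni":
            meth_genomes = (row.pattern[-1],)
        else:
            meth_genomes = tuple(row.pattern[-2:])
        for g in meth_genomes:
            values.setdefault((group, region.cls), []).append(
                norm[GENOMES.index(g)])
    rows = []
    for (group, cls), vals in sorted(values.items()):
        arr = np.asarray(vals)
        hist, _ = np.histogram(arr, bins=HIST_EDGES)
        rows.append({
            "pattern_group": group, "annotation": cls, "n": arr.size,
            "mean": float(arr.mean()),
            "p75": float(np.percentile(arr, 75)),
            "excess_kurtosis": float(stats.kurtosis(arr, fisher=True, bias=False))
            if arr.size >= 4 else np.nan,
            **{f"bin_{int(lo)}": int(h)
               for lo, h in zip(HIST_EDGES[:-1], hist)},
        })
    return pd.DataFrame(rows)


def compare_category_means(
    values1: Sequence[float], values2: Sequence[float],
) -> tuple[float, int, float]:
    """Pooled-variance two-sample t test: (t, df, two-tailed p).

    The sign of t follows the argument order (positive when the first group
    mean is larger). Degenerate zero-variance inputs give an infinite t and
    p = 0.
    """
    a = np.asarray(values1, dtype=float)
    b = np.asarray(values2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two values per group")
    df = a.size + b.size - 2
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), df, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), df, float(p)


def ks_normality(values: Sequence[float]) -> float:
    """Kolmogorov-Smirnov p against a normal with the sample mean/sd."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two values")
    sd = arr.std(ddof=1)
    if sd == 0:
        return 0.0
    return float(stats.kstest(arr, "norm", args=(arr.mean(), sd)).pvalue)


def grand_mean_normalized(expression: Sequence[AllelicExpression]) -> float:
    """Mean normalized share over all genomes of all expressed regions.

    Analytically 100/3 for any expressed set, because each region's three
    shares sum to 100.
    """
    shares = [s for e in expression if e.normalized for s in e.normalized]
    if not shares:
        raise ValueError("no expressed regions")
    return float(np.mean(shares))
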