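"""Per-region methylation summaries and differentially methylated regions.

The analysis unit is the extended-bait region supplied by the annotation
(no sliding windows): per region and genome, methylated/total read counts
from single-genome labels are pooled read-weighted, and DMRs are called on
the pooled counts with Fisher's exact test, a 25% minimum difference and
q < 0.01.
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classification import bh_adjust, differential_test
from .config import Thresholds
from .records import GENOMES, RegionAnnotation, RegionSummary


def summarize_regions(
    sites: pd.DataFrame,
    regions: Sequence[RegionAnnotation],
) -> list[RegionSummary]:
    """Pool per-site single-genome counts into per-region summaries.

    Pooling is read-weighted: the region percentage is 100 * (sum of
    methylated reads) / (sum of total reads), so deeply covered sites weigh
    more. Only single-genome labels contribute (pair labels cannot be
    attributed to one genome). Regions without any counted site are omitted.
    """
    out: list[RegionSummary] = []
    by_contig: dict[str, pd.DataFrame] = {
        str(c): grp for c, grp in sites.groupby("contig", observed=True)}
    for region in regions:
        grp = by_contig.get(region.contig)
        if grp is None:
            continue
        sel = grp[(grp["pos"] >= region.start) & (grp["pos"] < region.end)]
        if sel.empty:
            continue
        counts = {}
        n_sites = 0
        for g in GENOMES:
            t = int(sel[f"tot_{g}"].sum())
            if t:
                counts[g] = (int(sel[f"meth_{g}"].sum()), t)
        n_sites = int((sel[[f"tot_{g}" for g in GENOMES]].sum(axis=1) > 0).sum())
        if counts and n_sites:
            out.append(RegionSummary(region.region_id, region.cls, counts, n_sites))
    return out


def call_genome_specific_dmrs(
    summaries: Sequence[RegionSummary],
    thresholds: Optional[Thresholds] = None,
) -> pd.DataFrame:
    """Regions where a single genome is hypermethylated against both others.

    Genome X is the DMR genome iff level(X) - level(Y) >= dmr_diff for BOTH
    other genomes Y and both X-vs-Y Fisher tests reach q < q_cutoff (BH over
    each unordered genome pair's family). At most one genome can satisfy
    the difference requirement per region. Regions missing any genome
    summary are skipped and counted in the ``skipped`` attribute.
    """
    thr = thresholds or Thresholds()
    pairs = [("A", "B"), ("A", "D"), ("B", "D")]
    rows = []
    skipped = 0
    for s in summaries:
        if any(g not in s.counts for g in GENOMES):
            skipped += 1
            continue
        for g1, g2 in pairs:
            m1, t1 = s.counts[g1]
            m2, t2 = s.counts[g2]
            d, p = differential_test(m1, t1, m2, t2)
            rows.append((s.region_id, s.cls, g1, g2,
                         100.0 * m1 / t1 - 100.0 * m2 / t2, d, p))
    tests = pd.DataFrame(rows, columns=[
        "region_id", "cls", "g1", "g2", "signed_diff", "difference", "p"])
    result_rows = []
    if not tests.empty:
        tests["q"] = np.nan
        for _, grp in tests.groupby(["g1", "g2"]):
            tests.loc[grp.index, "q"] = bh_adjust(grp["p"].to_numpy())
        for region_id, grp in tests.groupby("region_id", sort=False):
            lookup = {(r.g1, r.g2): r for r in grp.itertuples()}
            for x in GENOMES:
                others = [g for g in GENOMES if g != x]
                ok = True
                worst_q = 0.0
                min_diff = np.inf
                for y in others:
                    r = lookup.get((x, y)) or lookup.get((y, x))
                    signed = r.signed_diff if r.g1 == x else -r.signed_diff
                    if signed < thr.dmr_diff or r.q >= thr.q_cutoff:
                        ok = False
                        break
                    worst_q = max(worst_q, r.q)
                    min_diff = min(min_diff, signed)
                if ok:
                    result_rows.append((region_id, grp.iloc[0]["cls"], x,
                                        float(min_diff), float(worst_q)))
                    break  # at most one genome can exceed both others by >= 25%
    out = pd.DataFrame(result_rows, columns=[
        "region_id", "cls", "genome", "min_difference", "max_q"])
    out.attrs["skipped"] = skipped
    return out


def call_between_sample_dmrs(
    summaries1: Sequence[RegionSummary],
    summaries2: Sequence[RegionSummary],
    thresholds: Optional[Thresholds] = None,
) -> pd.DataFrame:
    """Per-genome DMRs between two samples on shared regions (pooled region
    counts, minimum difference ``dmr_diff``, q < q_cutoff per genome family)."""
    thr = thresholds or Thresholds()
    by_id1 = {s.region_id: s for s in summaries1}
    by_id2 = {s.region_id: s for s in summaries2}
    rows = []
    for rid in sorted(set(by_id1) & set(by_id2)):
        s1, s2 = by_id1[rid], by_id2[rid]
        for g in GENOMES:
            if g in s1.counts and g in s2.counts:
                m1, t1 = s1.counts[g]
                m2, t2 = s2.counts[g]
                d, p = differential_test(m1, t1, m2, t2)
                rows.append((rid, g, 100.0 * m1 / t1, 100.0 * m2 / t2, d, p))
    out = pd.DataFrame(rows, columns=[
        "region_id", "genome", "level_1", "level_2", "difference", "p"])
    if out.empty:
        out["q"] = out["significant"] = []
        return out
    out["q"] = np.nan
    for _, grp in out.groupby("genome"):
        out.loc[grp.index, "q"] = bh_adjust(grp["p"].to_numpy())
    out["significant"] = ((out["q"] < thr.q_cutoff)
                          & (out["difference"] >= thr.dmr_diff))
    return out
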