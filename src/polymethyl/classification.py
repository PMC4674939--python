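"""Methylation-state calls, differential tests and uni/bi/tri-genome
pattern classification.

State thresholds (percent methylated reads at a site):

* CpG: >= 75 Methylated, <= 25 Unmethylated, otherwise Intermediate. The
  intermediate band exists because a genome-pair label averages two genomes;
  a pair at, say, 50% cannot be called "both methylated" or "both
  unmethylated".
* CHG/CHH: > 10 Methylated, otherwise Unmethylated. Non-CpG methylation is
  overwhelmingly low-level, so the call is binary: exceeding 10% denotes a
  highly methylated residue (or two methylated genomes behind a pair label),
  anything at or below it low-level background.

Differential calls use two-sided Fisher's exact tests with
Benjamini-Hochberg q-values per comparison family (all sites entering one
pairwise comparison form one family), combined with a minimum methylation
difference.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import Thresholds
from .records import (
    GENOMES,
    MethState,
    MethylationCall,
    SiteGenomeCounts,
    SitePattern,
    GenomeLabel,
)

SITE_KEY = ["contig", "pos", "strand"]
_STATE_U, _STATE_M, _STATE_I, _STATE_NA = 0, 1, 2, 3

_PAIR_OF = {"A": ("AB", "AD"), "B": ("AB", "BD"), "D": ("AD", "BD")}
_OTHERS = {"A": ("B", "D"), "B": ("A", "D"), "D": ("A", "B")}
_PAIR_NAME = {frozenset("AB"): "AB", frozenset("AD"): "AD", frozenset("BD"): "BD"}


def call_methylation_state(
    meth: int, total: int, context: str, thresholds: Optional[Thresholds] = None,
) -> MethylationCall:
    """Categorize one genome group's counts at a site."""
    thr = thresholds or Thresholds()
    if total <= 0:
        return MethylationCall(MethState.NOCALL, None)
    level = 100.0 * meth / total
    if context == "CpG":
        if level >= thr.cpg_meth:
            state = MethState.METHYLATED
        elif level <= thr.cpg_unmeth:
            state = MethState.UNMETHYLATED
        else:
            state = MethState.INTERMEDIATE
    else:
        if level > thr.non_cpg_meth:
            state = MethState.METHYLATED
        else:
            state = MethState.UNMETHYLATED
    return MethylationCall(state, level)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def fisher_p(m1: int, t1: int, m2: int, t2: int) -> float:
    """Two-sided Fisher's exact p for [[m1, u1], [m2, u2]]."""
    table = [[m1, t1 - m1], [m2, t2 - m2]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def differential_test(
    m1: int, t1: int, m2: int, t2: int,
) -> tuple[float, float]:
    """(methylation difference in %, two-sided Fisher p) for two count pairs.

    q-values are a family property; use :func:`bh_adjust` over the whole
    comparison family (as the table-level functions below do).
    """
    if t1 <= 0 or t2 <= 0:
        raise ValueError("both totals must be positive")
    diff = abs(100.0 * m1 / t1 - 100.0 * m2 / t2)
    return diff, fisher_p(m1, t1, m2, t2)


# ---------------------------------------------------------------------------
# site-table classification

_COUNT_COLS = [f"{kind}_{lab}" for lab in ("A", "B", "D", "AB", "AD", "BD")
               for kind in ("meth", "tot")]


def _state_codes(meth, tot, is_cpg, min_depth, thr: Thresholds) -> np.ndarray:
    level = np.divide(100.0 * meth, tot, out=np.full(meth.shape, np.nan),
                      where=tot > 0)
    state = np.full(meth.shape, _STATE_NA, dtype=np.int8)
    gated = tot >= min_depth
    m = np.where(is_cpg, level >= thr.cpg_meth, level > thr.non_cpg_meth)
    u = np.where(is_cpg, level <= thr.cpg_unmeth, level <= thr.non_cpg_meth)
    state[gated & m] = _STATE_M
    state[gated & u] = _STATE_U
    state[gated & ~m & ~u] = _STATE_I
    return state


def _resolve_genome_state(
    single: np.ndarray, tot_single: np.ndarray,
    pairs: Sequence[tuple[np.ndarray, np.ndarray]],
) -> np.ndarray:
    """One genome's state, preferring direct over averaged evidence.

    The genome's own coverage-gated single-label call is a direct
    measurement and always wins when present. Without one, a gated pair
    label containing the genome fills in, but only when its call is
    Methylated or Unmethylated — such a pair pins both of its genomes,
    whereas an Intermediate pair may be split between its genomes and pins
    neither. Two informative pairs are reconciled by read depth; with no
    informative evidence the state is unknown. Pair averages never override
    a single-genome call: a pair mixing one methylated and one unmethylated
    genome can itself clear a methylation threshold without either genome
    actually being at that level.
    """
    weights = []
    states = []
    for pair_state, pair_tot in pairs:
        informative = np.isin(pair_state, (_STATE_M, _STATE_U))
        states.append(np.where(informative, pair_state, _STATE_NA))
        weights.append(np.where(informative, pair_tot, -1))
    states = np.vstack(states)
    weights = np.vstack(weights)
    pick = np.argmax(weights, axis=0)
    cols = np.arange(single.size)
    from_pairs = states[pick, cols]
    from_pairs[weights[pick, cols] < 0] = _STATE_NA
    return np.where(single != _STATE_NA, single, from_pairs)


@dataclass
class ClassificationResult:
    table: pd.DataFrame  # input rows + pattern/comparison/difference/p/q
    n_coverage_failed: int = 0
    n_unresolved: int = 0


def classify_site_table(
    sites: pd.DataFrame, thresholds: Optional[Thresholds] = None,
) -> ClassificationResult:
    """Classify every coverage-passing site as tri / uni_X / bi_XY /
    intermediate / none / unresolved.

    ``sites`` carries one row per cytosine with ``contig, pos, strand,
    context`` and meth/tot counts for A, B, D, AB, AD, BD (missing labels as
    zeros). Sites failing the coverage gate are labelled ``nocall`` and take
    no further part; ``unresolved`` marks passing sites where the local SNP
    evidence cannot pin all three genome states (no informative label for
    some genome) — keeping them out of pattern denominators avoids biasing
    the uni/bi proportions by SNP-partition availability.

    Uni/bi candidates additionally need a significant one-versus-rest
    Fisher test (q < q_cutoff within the comparison family, difference >=
    within_sample_diff); a candidate failing its defining test is ambiguous
    between noise and genuine differential methylation and is labelled
    unresolved.
    """
    thr = thresholds or Thresholds()
    df = sites.copy()
    for col in _COUNT_COLS:
        if col not in df:
            df[col] = 0
    n = len(df)
    is_cpg = (df["context"].astype(str) == "CpG").to_numpy()
    cnt = {c: df[c].to_numpy(dtype=np.int64) for c in _COUNT_COLS}

    single = {g: _state_codes(cnt[f"meth_{g}"], cnt[f"tot_{g}"], is_cpg,
                              thr.single_depth, thr) for g in GENOMES}
    pair = {p: _state_codes(cnt[f"meth_{p}"], cnt[f"tot_{p}"], is_cpg,
                            thr.pair_depth, thr) for p in ("AB", "AD", "BD")}
    resolved = {
        g: _resolve_genome_state(
            single[g], cnt[f"tot_{g}"],
            [(pair[p], cnt[f"tot_{p}"]) for p in _PAIR_OF[g]])
        for g in GENOMES}

    passes = _coverage_mask(cnt, thr)
    any_inter = np.zeros(n, dtype=bool)
    for g in GENOMES:
        any_inter |= resolved[g] == _STATE_I
    any_unknown = np.zeros(n, dtype=bool)
    for g in GENOMES:
        any_unknown |= resolved[g] == _STATE_NA
    # an Intermediate pair is positive evidence of intermediate-level (or
    # split) methylation: when it leaves genome states unpinned the site is
    # intermediate, not merely unresolved
    any_pair_inter = np.zeros(n, dtype=bool)
    for p in ("AB", "AD", "BD"):
        any_pair_inter |= pair[p] == _STATE_I
    n_meth = sum((resolved[g] == _STATE_M).astype(np.int8) for g in GENOMES)

    pattern = np.full(n, "nocall", dtype=object)
    pattern[passes & any_inter] = "intermediate"
    undecided = passes & ~any_inter
    pattern[undecided & any_unknown & any_pair_inter] = "intermediate"
    pattern[undecided & any_unknown & ~any_pair_inter] = "unresolved"
    decided = undecided & ~any_unknown
    pattern[decided & (n_meth == 3)] = "tri"
    pattern[decided & (n_meth == 0)] = "none"

    comparison = np.full(n, None, dtype=object)
    diff = np.full(n, np.nan)
    pvals = np.full(n, np.nan)
    qvals = np.full(n, np.nan)
    candidates: list[tuple[int, str, str, float, float]] = []
    for i in np.flatnonzero(decided & ((n_meth == 1) | (n_meth == 2))):
        meth_gs = [g for g in GENOMES if resolved[g][i] == _STATE_M]
        if len(meth_gs) == 1:
            x = meth_gs[0]
            y, z = _OTHERS[x]
            own = (cnt[f"meth_{x}"][i], cnt[f"tot_{x}"][i])
            rest_pair = _PAIR_NAME[frozenset(y + z)]
            opp = (cnt[f"meth_{y}"][i] + cnt[f"meth_{z}"][i]
                   + cnt[f"meth_{rest_pair}"][i],
                   cnt[f"tot_{y}"][i] + cnt[f"tot_{z}"][i]
                   + cnt[f"tot_{rest_pair}"][i])
            label = f"uni_{x}"
            comp = f"{x}_vs_{rest_pair}"
        else:
            x, y = meth_gs
            z = next(g for g in GENOMES if g not in meth_gs)
            pr = _PAIR_NAME[frozenset(x + y)]
            own = (cnt[f"meth_{x}"][i] + cnt[f"meth_{y}"][i] + cnt[f"meth_{pr}"][i],
                   cnt[f"tot_{x}"][i] + cnt[f"tot_{y}"][i] + cnt[f"tot_{pr}"][i])
            opp = (cnt[f"meth_{z}"][i], cnt[f"tot_{z}"][i])
            label = f"bi_{pr}"
            comp = f"{pr}_vs_{z}"
        if own[1] == 0 or opp[1] == 0:
            # states pinned only by pair fills with no testable counts
            pattern[i] = "unresolved"
            continue
        d, p = differential_test(own[0], own[1], opp[0], opp[1])
        candidates.append((i, label, comp, d, p))

    if candidates:
        cand = pd.DataFrame(candidates, columns=["row", "label", "comp", "d", "p"])
        cand["q"] = np.nan
        for _, grp in cand.groupby("comp"):
            cand.loc[grp.index, "q"] = bh_adjust(grp["p"].to_numpy())
        ok = (cand["q"] < thr.q_cutoff) & (cand["d"] >= thr.within_sample_diff)
        rows = cand["row"].to_numpy()
        # a candidate failing its defining test is ambiguous between noise
        # and genuine differential methylation: excluded, not relabelled
        pattern[rows] = np.where(ok, cand["label"], "unresolved")
        comparison[rows] = cand["comp"]
        diff[rows] = cand["d"]
        pvals[rows] = cand["p"]
        qvals[rows] = cand["q"]

    df["pattern"] = pattern
    df["comparison"] = comparison
    df["difference"] = diff
    df["p"] = pvals
    df["q"] = qvals
    return ClassificationResult(
        table=df,
        n_coverage_failed=int(np.count_nonzero(~passes)),
        n_unresolved=int(np.count_nonzero(pattern == "unresolved")),
    )


def _coverage_mask(cnt: dict[str, np.ndarray], thr: Thresholds) -> np.ndarray:
    """Spec coverage gate: all three singles >= single_depth (tri-resolved)
    or, for the dominant biallelic partition, single >= single_depth and
    pair >= pair_depth."""
    tri = ((cnt["tot_A"] >= thr.single_depth)
           & (cnt["tot_B"] >= thr.single_depth)
           & (cnt["tot_D"] >= thr.single_depth))
    part_ok = np.zeros_like(tri)
    totals = []
    oks = []
    for g, pr in (("A", "BD"), ("B", "AD"), ("D", "AB")):
        totals.append(cnt[f"tot_{g}"] + cnt[f"tot_{pr}"])
        oks.append((cnt[f"tot_{g}"] >= thr.single_depth)
                   & (cnt[f"tot_{pr}"] >= thr.pair_depth))
    dominant = np.argmax(np.vstack(totals), axis=0)
    for k in range(3):
        part_ok |= (dominant == k) & oks[k]
    return tri | part_ok


def classify_pattern(
    counts: SiteGenomeCounts, thresholds: Optional[Thresholds] = None,
) -> SitePattern:
    """Classify a single site (convenience wrapper over the table path;
    the q-value equals p because the family has size one)."""
    row = {"contig": counts.site.contig, "pos": counts.site.pos,
           "strand": counts.site.strand, "context": counts.site.context}
    for lab_name in ("A", "B", "D", "AB", "AD", "BD"):
        lab = GenomeLabel[lab_name]
        row[f"meth_{lab_name}"] = counts.meth(lab)
        row[f"tot_{lab_name}"] = counts.total(lab)
    res = classify_site_table(pd.DataFrame([row]), thresholds)
    r = res.table.iloc[0]
    return SitePattern(
        site=counts.site, pattern=r["pattern"], comparison=r["comparison"],
        difference=None if pd.isna(r["difference"]) else float(r["difference"]),
        p=None if pd.isna(r["p"]) else float(r["p"]),
        q=None if pd.isna(r["q"]) else float(r["q"]),
    )


# ---------------------------------------------------------------------------
# replicate noise and sample comparisons


def filter_replicate_noise(
    replicates: Sequence[pd.DataFrame], thresholds: Optional[Thresholds] = None,
) -> set[tuple]:
    """Sites showing 'background methylation' between replicates.

    For every within-condition replicate pair and every genome label with
    reads on both sides, a Fisher test is run; a site is excluded when any
    such comparison is significant (q < q_cutoff within that replicate
    pair's family, difference >= within_sample_diff). With fewer than two
    replicates the exclusion set is empty.
    """
    thr = thresholds or Thresholds()
    excluded: set[tuple] = set()
    labels = ("A", "B", "D", "AB", "AD", "BD")
    for i in range(len(replicates)):
        for j in range(i + 1, len(replicates)):
            a = replicates[i].set_index(SITE_KEY)
            b = replicates[j].set_index(SITE_KEY)
            shared = a.index.intersection(b.index)
            rows = []
            for key in shared:
                ra, rb = a.loc[key], b.loc[key]
                for lab in labels:
                    ta = int(ra.get(f"tot_{lab}", 0))
                    tb = int(rb.get(f"tot_{lab}", 0))
                    if ta > 0 and tb > 0:
                        d, p = differential_test(
                            int(ra[f"meth_{lab}"]), ta, int(rb[f"meth_{lab}"]), tb)
                        rows.append((key, d, p))
            if rows:
                q = bh_adjust([r[2] for r in rows])
                for (key, d, _), qv in zip(rows, q):
                    if qv < thr.q_cutoff and d >= thr.within_sample_diff:
                        excluded.add(key)
    return excluded


def compare_between_samples(
    sample1: pd.DataFrame,
    sample2: pd.DataFrame,
    thresholds: Optional[Thresholds] = None,
    exclude: Optional[set] = None,
) -> pd.DataFrame:
    """Per-genome differential methylation between two samples.

    Pairwise comparisons are within-genome (A-A, B-B, D-D) on pooled counts,
    at the between-sample difference threshold (default 25%). Returns one row
    per (site, genome) tested, with ``significant`` set per q < q_cutoff and
    difference >= between_sample_diff, plus ``n_genomes_changed`` per site.
    """
    thr = thresholds or Thresholds()
    a = sample1.set_index(SITE_KEY)
    b = sample2.set_index(SITE_KEY)
    shared = a.index.intersection(b.index)
    if exclude:
        shared = pd.Index([k for k in shared if k not in exclude])
    rows = []
    for key in shared:
        ra, rb = a.loc[key], b.loc[key]
        for g in GENOMES:
            t1, t2 = int(ra.get(f"tot_{g}", 0)), int(rb.get(f"tot_{g}", 0))
            if t1 >= thr.single_depth and t2 >= thr.single_depth:
                d, p = differential_test(
                    int(ra[f"meth_{g}"]), t1, int(rb[f"meth_{g}"]), t2)
                rows.append(key + (g, d, p))
    out = pd.DataFrame(rows, columns=SITE_KEY + ["genome", "difference", "p"])
    if out.empty:
        out["q"] = out["significant"] = out["n_genomes_changed"] = []
        return out
    out["q"] = np.nan
    for _, grp in out.groupby("genome"):
        out.loc[grp.index, "q"] = bh_adjust(grp["p"].to_numpy())
    out["significant"] = ((out["q"] < thr.q_cutoff)
                          & (out["difference"] >= thr.between_sample_diff))
    changed = out[out["significant"]].groupby(SITE_KEY)["genome"].size()
    out = out.merge(changed.rename("n_genomes_changed"), how="left",
                    left_on=SITE_KEY, right_index=True)
    out["n_genomes_changed"] = out["n_genomes_changed"].fillna(0).astype(int)
    return out


def compare_diploid_to_subgenome(
    diploid: pd.DataFrame,
    subgenome: pd.DataFrame,
    genome: str = "D",
    thresholds: Optional[Thresholds] = None,
) -> pd.DataFrame:
    """Differential sites between a diploid relative and one sub-genome.

    The diploid table carries plain ``meth``/``tot`` per site (no
    partitioning); tests run at the diploid comparison threshold (default
    50%, reflecting lower diploid coverage). Each significant site is
    labelled ``gain`` when the sub-genome level exceeds the diploid level,
    else ``loss``.
    """
    thr = thresholds or Thresholds()
    a = diploid.set_index(SITE_KEY)
    b = subgenome.set_index(SITE_KEY)
    shared = a.index.intersection(b.index)
    rows = []
    for key in shared:
        ra, rb = a.loc[key], b.loc[key]
        t1, t2 = int(ra["tot"]), int(rb.get(f"tot_{genome}", 0))
        if t1 >= thr.single_depth and t2 >= thr.single_depth:
            m1, m2 = int(ra["meth"]), int(rb[f"meth_{genome}"])
            d, p = differential_test(m1, t1, m2, t2)
            direction = "gain" if 100.0 * m2 / t2 > 100.0 * m1 / t1 else "loss"
            rows.append(key + (d, p, direction))
    out = pd.DataFrame(rows, columns=SITE_KEY + ["difference", "p", "direction"])
    if out.empty:
        out["q"] = out["significant"] = []
        return out
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = ((out["q"] < thr.q_cutoff)
                          & (out["difference"] >= thr.diploid_compare_diff))
    return out
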