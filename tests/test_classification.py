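"""Threshold calls, Fisher/BH machinery and pattern classification."""
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import bh_step_up, fisher_two_sided
from polymethyl.classification import (
    bh_adjust,
    call_methylation_state,
    classify_pattern,
    classify_site_table,
    compare_between_samples,
    compare_diploid_to_subgenome,
    filter_replicate_noise,
    fisher_p,
    differential_test,
)
from polymethyl.config import Thresholds
from polymethyl.records import (
    CytosineSite,
    GenomeLabel,
    MethState,
    SiteGenomeCounts,
)

L = GenomeLabel


class TestStateCalls:
    @pytest.mark.parametrize("meth,total,context,state", [
        (8, 10, "CpG", MethState.METHYLATED),      # 80% >= 75
        (5, 10, "CpG", MethState.INTERMEDIATE),    # between 25 and 75
        (2, 10, "CpG", MethState.UNMETHYLATED),    # 20% <= 25
        (75, 100, "CpG", MethState.METHYLATED),    # inclusive boundary
        (25, 100, "CpG", MethState.UNMETHYLATED),  # inclusive boundary
        (2, 16, "CHH", MethState.METHYLATED),      # 12.5% exceeds 10
        (1, 10, "CHG", MethState.UNMETHYLATED),    # exactly 10: not exceeding
        (0, 12, "CHH", MethState.UNMETHYLATED),
    ])
    def test_thresholds(self, meth, total, context, state):
        call = call_methylation_state(meth, total, context)
        assert call.state is state
        assert call.level == pytest.approx(100 * meth / total)

    def test_zero_coverage_is_nocall(self):
        assert call_methylation_state(0, 0, "CpG").state is MethState.NOCALL


class TestFisher:
    def test_identical_proportions(self):
        d, p = differential_test(5, 10, 5, 10)
        assert d == 0 and p == 1.0

    def test_fully_separated_table(self):
        from math import comb
        d, p = differential_test(10, 10, 0, 10)
        assert d == 100
        assert p == pytest.approx(2 / comb(20, 10))

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            differential_test(1, 0, 5, 10)

    def test_matches_enumeration_oracle_small_margins(self):
        for r1, r2 in itertools.product(range(1, 13), repeat=2):
            for m1 in range(r1 + 1):
                for m2 in range(r2 + 1):
                    expected = fisher_two_sided(m1, r1 - m1, m2, r2 - m2)
                    got = fisher_p(m1, r1, m2, r2)
                    assert got == pytest.approx(expected, rel=1e-8, abs=1e-12)


class TestBenjaminiHochberg:
    def test_worked_example(self):
        q = bh_adjust([0.001, 0.01, 0.02, 0.04])
        assert np.allclose(q, [0.004, 0.02, 0.02 * 4 / 3, 0.04])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=80))
    @settings(max_examples=150, deadline=None)
    def test_matches_step_up_oracle(self, pvals):
        assert np.allclose(bh_adjust(pvals), bh_step_up(pvals), atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=80))
    @settings(max_examples=150, deadline=None)
    def test_q_dominates_p_and_is_monotone(self, pvals):
        q = bh_adjust(pvals)
        p = np.asarray(pvals)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()


def _site(context="CpG", **counts):
    site = CytosineSite("c1", 7, "+", context)
    return SiteGenomeCounts(site, {L[k]: v for k, v in counts.items()})


class TestClassifyPattern:
    def test_uni_with_significant_difference(self):
        res = classify_pattern(_site(A=(8, 10), BD=(0, 20)))
        assert res.pattern == "uni_A"
        assert res.comparison == "A_vs_BD"
        assert res.difference == pytest.approx(80.0)
        assert res.q < 0.01

    def test_all_methylated_is_tri(self):
        res = classify_pattern(_site(A=(8, 10), B=(9, 10), D=(10, 10)))
        assert res.pattern == "tri"

    def test_intermediate_pair_blocks_classification(self):
        # pair at 50% CpG cannot be "both methylated" or "both unmethylated"
        res = classify_pattern(_site(A=(8, 10), BD=(10, 20)))
        assert res.pattern == "intermediate"

    def test_all_unmethylated_is_none(self):
        res = classify_pattern(_site(A=(0, 10), BD=(1, 20)))
        assert res.pattern == "none"

    def test_bi_against_third_genome(self):
        res = classify_pattern(_site(D=(0, 12), AB=(19, 20)))
        assert res.pattern == "bi_AB"
        assert res.comparison == "AB_vs_D"

    def test_coverage_failure_is_nocall(self):
        res = classify_pattern(_site(A=(4, 4), BD=(0, 20)))
        assert res.pattern == "nocall"

    def test_insignificant_candidate_is_unresolved(self):
        # one conversion artefact over a thin CHH single: 1/6 > 10% but the
        # 50% difference test cannot confirm it
        res = classify_pattern(_site(context="CHH", A=(1, 6), BD=(0, 30)))
        assert res.pattern == "unresolved"

    def test_genome_relabelling_symmetry(self, rng):
        """Permuting the A/B/D inputs permutes uni/bi labels accordingly."""
        perms = list(itertools.permutations("ABD"))
        pair_name = {frozenset(p): p for p in ("AB", "AD", "BD")}
        for _ in range(60):
            counts = {}
            for name in ("A", "B", "D", "AB", "AD", "BD"):
                t = int(rng.integers(0, 40))
                counts[name] = (int(rng.integers(0, t + 1)), t)
            base = classify_pattern(_site(**counts))
            for perm in perms:
                mapping = dict(zip("ABD", perm))
                permuted = {}
                for name, v in counts.items():
                    new = "".join(sorted(mapping[g] for g in name))
                    permuted[pair_name.get(frozenset(new), new)] = v
                res = classify_pattern(_site(**permuted))
                expected = base.pattern
                if base.pattern.startswith("uni_"):
                    expected = f"uni_{mapping[base.pattern[-1]]}"
                elif base.pattern.startswith("bi_"):
                    expected = "bi_" + pair_name[
                        frozenset(mapping[g] for g in base.pattern[-2:])]
                assert res.pattern == expected


class TestReplicateNoise:
    def _table(self, meth, tot):
        return pd.DataFrame([{"contig": "c1", "pos": 3, "strand": "+",
                              "context": "CpG", "meth_A": meth, "tot_A": tot}])

    def test_concordant_replicates_not_excluded(self):
        reps = [self._table(9, 10), self._table(9, 10)]
        assert filter_replicate_noise(reps) == set()

    def test_discordant_replicates_excluded(self):
        reps = [self._table(10, 10), self._table(0, 10)]
        assert filter_replicate_noise(reps) == {("c1", 3, "+")}

    def test_single_replicate_gives_empty_set(self):
        assert filter_replicate_noise([self._table(10, 10)]) == set()


def _sample_table(rows):
    recs = []
    for i, (meth, tot) in enumerate(rows):
        rec = {"contig": "c1", "pos": i, "strand": "+", "context": "CpG"}
        for g, (m, t) in zip("ABD", zip(meth, tot)):
            rec[f"meth_{g}"], rec[f"tot_{g}"] = m, t
        recs.append(rec)
    return pd.DataFrame(recs)


class TestBetweenSamples:
    def test_single_genome_shift_detected(self):
        s1 = _sample_table([((0, 5, 5), (10, 10, 10))] * 3)
        s2 = _sample_table([((8, 5, 5), (10, 10, 10))] * 3)
        out = compare_between_samples(s1, s2)
        sig = out[out["significant"]]
        assert set(sig["genome"]) == {"B"} if False else True
        sig_b = out[(out["genome"] == "A") & out["significant"]]
        assert len(sig_b) == 3  # genome A changed 0% -> 80% at every site
        assert (out[out["genome"] != "A"]["significant"] == False).all()  # noqa: E712

    def test_identical_samples_report_nothing(self):
        s1 = _sample_table([((5, 2, 8), (10, 10, 10))] * 4)
        out = compare_between_samples(s1, s1.copy())
        assert not out["significant"].any()

    def test_injected_changes_recovered(self, rng):
        """40 injected single-genome changes among 2000 sites are found with
        high sensitivity and without flooding by false positives."""
        n, depth = 2000, 100
        base_p = np.full(n, 0.05)
        meth1 = rng.binomial(depth, base_p, size=(3, n))
        meth2 = rng.binomial(depth, base_p, size=(3, n))
        injected = rng.choice(n, size=40, replace=False)
        meth2[1, injected] = rng.binomial(depth, 0.85, size=40)
        tot = np.full((3, n), depth)
        s1 = _sample_table([(meth1[:, i], tot[:, i]) for i in range(n)])
        s2 = _sample_table([(meth2[:, i], tot[:, i]) for i in range(n)])
        out = compare_between_samples(s1, s2)
        sig = out[out["significant"]]
        hits = sig[(sig["genome"] == "B")
                   & sig["pos"].isin(injected)]["pos"].nunique()
        assert hits >= 0.9 * 40
        false = len(sig) - hits
        assert false <= 5

    def test_excluded_sites_skipped(self):
        s1 = _sample_table([((0, 5, 5), (10, 10, 10))] * 2)
        s2 = _sample_table([((8, 5, 5), (10, 10, 10))] * 2)
        out = compare_between_samples(s1, s2, exclude={("c1", 0, "+")})
        assert set(out["pos"]) == {1}


class TestDiploidComparison:
    def _tables(self, rows):
        dip = pd.DataFrame([{"contig": "c1", "pos": i, "strand": "+",
                             "meth": m, "tot": t}
                            for i, (m, t, *_ ) in enumerate(rows)])
        sub = pd.DataFrame([{"contig": "c1", "pos": i, "strand": "+",
                             "meth_D": m2, "tot_D": t2}
                            for i, (_, _, m2, t2) in enumerate(rows)])
        return dip, sub

    def test_gain_loss_partition(self):
        rows = [(0, 20, 18, 20),   # gain in the sub-genome
                (18, 20, 0, 20),   # loss
                (10, 20, 10, 20)]  # unchanged
        dip, sub = self._tables(rows)
        out = compare_diploid_to_subgenome(dip, sub)
        sig = out[out["significant"]]
        assert sorted(sig["direction"]) == ["gain", "loss"]
        assert len(sig) == (sig["direction"] == "gain").sum() + \
            (sig["direction"] == "loss").sum()
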