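"""Generator: references, SNP truth, methylation truth, reads, expression."""
import numpy as np
import pandas as pd
import pytest

from polymethyl.config import SimulationConfig
from polymethyl.extraction import (
    bytes_to_seq,
    classify_context,
    conversion_rate_from_xm_matrix,
)
from polymethyl.pipeline import simulate_dataset
from polymethyl.records import GENOMES
from polymethyl.synthetic import (
    assign_methylation_truth,
    default_regions,
    expected_snp_count,
    generate_homoeologous_references,
    simulate_bisulfite_reads,
    simulate_expression,
)


def _flat_config(**kw):
    """All-unmethylated mix unless overridden."""
    mix = {"unmethylated": 1.0}
    return SimulationConfig(pattern_mix=kw.pop("pattern_mix", mix), **kw)


class TestReferences:
    def test_zero_snp_rate_gives_identical_genomes(self):
        cfg = SimulationConfig(n_contigs=2, contig_length=500, snp_rate=0.0,
                               read_length=100, seed=1)
        refs = generate_homoeologous_references(cfg)
        assert refs.snps == []
        for contig in refs.contigs:
            a, b, d = (refs.genomes[g][contig] for g in GENOMES)
            assert np.array_equal(a, b) and np.array_equal(a, d)

    def test_genomes_differ_only_at_snp_positions(self):
        cfg = SimulationConfig(n_contigs=3, contig_length=1000, seed=2)
        refs = generate_homoeologous_references(cfg)
        for contig in refs.contigs:
            a, b, d = (refs.genomes[g][contig] for g in GENOMES)
            divergent = np.flatnonzero((a != b) | (a != d))
            assert set(divergent) == {s.pos for s in refs.snps
                                      if s.contig == contig}
        for snp in refs.snps:
            for g, allele in zip(GENOMES, snp.alleles):
                assert chr(refs.genomes[g][snp.contig][snp.pos]) == allele
            assert snp.is_divergent

    def test_snp_count_matches_analytic_expectation(self):
        cfg = SimulationConfig(n_contigs=10, contig_length=2000, snp_rate=0.01,
                               seed=7)
        refs = generate_homoeologous_references(cfg)
        mean, sd = expected_snp_count(cfg)
        # independent count straight off the sequences
        observed = sum(
            int(np.count_nonzero(
                (refs.genomes["A"][c] != refs.genomes["B"][c])
                | (refs.genomes["A"][c] != refs.genomes["D"][c])))
            for c in refs.contigs)
        assert observed == len(refs.snps)
        assert abs(observed - mean) <= 3 * sd

    def test_control_contig_has_cytosines_and_no_snps(self):
        cfg = SimulationConfig(n_contigs=1, contig_length=1000, seed=3)
        refs = generate_homoeologous_references(cfg)
        control = bytes_to_seq(refs.control)
        assert control.count("C") + control.count("G") >= 1000

    def test_too_short_contig_rejected(self):
        cfg = SimulationConfig(n_contigs=1, contig_length=300, snp_rate=0.001,
                               read_length=100)
        with pytest.raises(ValueError, match="too short"):
            cfg.validate()

    def test_seed_determinism_bytes(self, small_config):
        a = simulate_dataset(small_config)
        b = simulate_dataset(small_config)
        for contig in a.refs.contigs:
            for g in GENOMES:
                assert bytes_to_seq(a.refs.genomes[g][contig]) == \
                    bytes_to_seq(b.refs.genomes[g][contig])
        assert a.refs.snps == b.refs.snps
        assert np.array_equal(a.reads.seq, b.reads.seq)
        assert np.array_equal(a.reads.xm, b.reads.xm)
        assert np.array_equal(a.reads.start, b.reads.start)
        pd.testing.assert_frame_equal(a.truth.table, b.truth.table)


class TestMethylationTruth:
    def test_all_tri_mix_methylates_every_genome(self):
        cfg = SimulationConfig(n_contigs=1, contig_length=800,
                               pattern_mix={"tri": 1.0}, seed=4)
        refs = generate_homoeologous_references(cfg)
        truth = assign_methylation_truth(refs, cfg)
        assert (truth.table[["p_A", "p_B", "p_D"]] > 0).all().all()

    def test_uni_pattern_methylates_one_genome(self, small_dataset):
        tbl = small_dataset.truth.table
        uni_a = tbl[tbl["pattern"] == "uni_A"]
        assert len(uni_a) > 0
        assert (uni_a["p_A"] > 0).all()
        assert (uni_a["p_B"] == 0).all() and (uni_a["p_D"] == 0).all()

    def test_intermediate_pattern_only_at_cpg(self, small_dataset):
        tbl = small_dataset.truth.table
        inter = tbl[tbl["pattern"] == "intermediate"]
        assert len(inter) > 0
        assert (inter["context"] == "CpG").all()

    def test_tri_fraction_recovers_configured_mix(self):
        cfg = SimulationConfig(n_contigs=100, contig_length=2050, seed=11)
        refs = generate_homoeologous_references(
            cfg, np.random.default_rng(11))
        truth = assign_methylation_truth(refs, cfg, np.random.default_rng(12))
        assigned = truth.table[truth.table["pattern"] != "unmethylated"]
        n = len(assigned)
        assert n >= 10_000
        tri = (assigned["pattern"] == "tri").mean()
        se = np.sqrt(0.45 * 0.55 / n)
        assert abs(tri - 0.45) <= 3 * se

    def test_context_recorded_matches_reference(self, small_dataset):
        refs = small_dataset.refs
        tbl = small_dataset.truth.table.sample(200, random_state=0)
        ref = refs.reference_str()
        for row in tbl.itertuples():
            assert classify_context(ref[str(row.contig)], int(row.pos),
                                    row.strand) == str(row.context)


class TestReads:
    def test_complete_conversion_reads_all_thymine(self):
        cfg = _flat_config(n_contigs=1, contig_length=600, depth=20,
                          conversion_rate=1.0, error_rate=0.0,
                          read_length=100, seed=5)
        refs = generate_homoeologous_references(cfg)
        truth = assign_methylation_truth(refs, cfg)
        reads, control = simulate_bisulfite_reads(refs, truth, cfg)
        sym = reads.xm[reads.xm != ord(".")]
        assert sym.size > 0
        assert (sym >= ord("a")).all()  # every call unmethylated
        assert conversion_rate_from_xm_matrix(reads.xm) == 100.0
        assert conversion_rate_from_xm_matrix(control.xm) == 100.0

    def test_no_conversion_reads_all_cytosine(self):
        cfg = _flat_config(n_contigs=1, contig_length=600, depth=20,
                          conversion_rate=0.0, error_rate=0.0,
                          read_length=100, seed=5)
        refs = generate_homoeologous_references(cfg)
        truth = assign_methylation_truth(refs, cfg)
        reads, _ = simulate_bisulfite_reads(refs, truth, cfg)
        sym = reads.xm[reads.xm != ord(".")]
        assert (sym < ord("a")).all()
        assert conversion_rate_from_xm_matrix(reads.xm) == 0.0

    def test_interior_coverage_matches_depth(self):
        cfg = _flat_config(n_contigs=1, contig_length=2000, depth=100,
                          read_length=100, seed=6)
        refs = generate_homoeologous_references(cfg)
        truth = assign_methylation_truth(refs, cfg)
        reads, _ = simulate_bisulfite_reads(refs, truth, cfg)
        L, Lr = 2000, 100
        cov = np.zeros(L)
        one_genome = reads.genome == 0
        for s in reads.start[one_genome]:
            cov[s:s + Lr] += 1
        interior = cov[Lr:L - Lr]
        assert abs(interior.mean() - 100) / 100 < 0.10

    def test_depth_zero_warns_and_returns_empty(self):
        cfg = _flat_config(n_contigs=1, contig_length=600, depth=0,
                          read_length=100, seed=6)
        refs = generate_homoeologous_references(cfg)
        truth = assign_methylation_truth(refs, cfg)
        with pytest.warns(UserWarning, match="depth=0"):
            reads, control = simulate_bisulfite_reads(refs, truth, cfg)
        assert reads.n == 0 and control.n == 0

    def test_symbol_conservation_per_read(self, small_dataset):
        # methylated + unmethylated + non-cytosine positions = read length
        xm = small_dataset.reads.xm
        meth = (xm >= ord("A")) & (xm <= ord("Z"))
        unmeth = xm >= ord("a")
        dot = xm == ord(".")
        assert ((meth + unmeth + dot).sum(axis=1) == xm.shape[1]).all()

    def test_directional_library_uses_two_products(self):
        cfg = _flat_config(n_contigs=1, contig_length=600, depth=10,
                          directional=True, read_length=100, seed=6)
        refs = generate_homoeologous_references(cfg)
        truth = assign_methylation_truth(refs, cfg)
        reads, _ = simulate_bisulfite_reads(refs, truth, cfg)
        assert set(np.unique(reads.product)) <= {0, 1}

    def test_truth_consistency_of_methylation_strings(self, small_dataset):
        """XM symbols agree with the reference context at their position."""
        ref = small_dataset.refs.reference_str()
        batch = small_dataset.reads
        by_symbol = {"Z": "CpG", "X": "CHG", "H": "CHH"}
        rng = np.random.default_rng(0)
        for i in rng.integers(0, batch.n, 50):
            read = None
            for j, rec in enumerate(batch.subset(np.array([i])).iter_records()):
                read = rec
            strand = "+" if read.xg == "CT" else "-"
            for off, sym in enumerate(read.xm):
                if sym != ".":
                    expected = by_symbol[sym.upper()]
                    assert classify_context(
                        ref[read.contig], read.pos + off, strand) == expected


class TestExpression:
    def test_full_silencing_zeroes_suppressed_genome(self):
        cfg = SimulationConfig(n_contigs=40, contig_length=1500,
                               promoter_suppression=0.0, seed=8)
        refs = generate_homoeologous_references(cfg)
        truth = assign_methylation_truth(refs, cfg)
        regions = default_regions(refs)
        et = simulate_expression(regions, truth, cfg)
        seen = 0
        for e in et.expression:
            flagged = et.suppressed[e.region_id]
            if len(flagged) == 3:
                assert e.normalized is None  # fully silenced region
                continue
            for g in flagged:
                assert e.normalized[GENOMES.index(g)] == 0.0
                seen += 1
        assert seen > 0

    def test_null_suppression_leaves_genomes_exchangeable(self):
        cfg = SimulationConfig(n_contigs=300, contig_length=1200, depth=1,
                               promoter_suppression=1.0, read_length=100,
                               seed=9)
        refs = generate_homoeologous_references(cfg)
        truth = assign_methylation_truth(refs, cfg)
        regions = default_regions(refs)
        et = simulate_expression(regions, truth, cfg)
        sup, unsup = [], []
        for e in et.expression:
            flagged = et.suppressed[e.region_id]
            for k, g in enumerate(GENOMES):
                (sup if g in flagged else unsup).append(e.normalized[k])
        assert len(sup) > 50
        # suppression factor 1.0: same distribution, equal means within noise
        se = np.sqrt(np.var(sup) / len(sup) + np.var(unsup) / len(unsup))
        assert abs(np.mean(sup) - np.mean(unsup)) < 4 * se

    def test_partial_suppression_matches_closed_form(self):
        cfg = SimulationConfig(n_contigs=1500, contig_length=1200, depth=1,
                               promoter_suppression=0.8, read_length=100,
                               seed=9)
        refs = generate_homoeologous_references(cfg, np.random.default_rng(1))
        truth = assign_methylation_truth(refs, cfg, np.random.default_rng(2))
        regions = default_regions(refs)
        et = simulate_expression(regions, truth, cfg, np.random.default_rng(3))
        vals = []
        for e in et.expression:
            flagged = et.suppressed[e.region_id]
            if len(flagged) == 1 and e.normalized:
                vals.append(e.normalized[GENOMES.index(flagged[0])])
        assert len(vals) > 200
        closed_form = 100 * 0.8 / 2.8  # equal baseline means
        assert np.mean(vals) < 100 / 3
        assert abs(np.mean(vals) - closed_form) < 0.7
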