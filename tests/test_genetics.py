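import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ipmsnet import genetics
from ipmsnet.genetics import (
    Locus,
    annotate_genes_to_snps,
    compute_r2,
    competitive_geneset_test,
    gene_based_test,
    genes_in_locus,
    ld_clump_locus,
    prioritize_locus_genes,
    social_manhattan_table,
)
from ipmsnet.io import GeneAnnotation, GwasSummary, ReferencePanel, ValidationError
from ipmsnet.network import build_network
from ipmsnet.synthetic import PanelSimConfig, simulate_reference_panel

from test_network import stats_from_sets


def make_gwas(rows):
    return GwasSummary(pd.DataFrame(rows, columns=["snp", "chrom", "pos", "p"]))


class TestAnnotateSnps:
    def test_window_boundaries(self, toy_annotation):
        gwas = make_gwas([
            ("in_window", "1", 60_000, 0.5),     # 40 kb left of GA start
            ("too_far", "1", 49_999, 0.5),       # 50,001 bp left of GA start
            ("at_edge", "1", 50_000, 0.5),       # exactly 50 kb left
            ("inside", "1", 105_000, 0.5),
        ])
        out = annotate_genes_to_snps(toy_annotation, gwas, window=50_000, mhc=None)
        assert set(out["GA"]) == {"in_window", "at_edge", "inside"}

    def test_mhc_snps_excluded_everywhere(self):
        ann = GeneAnnotation(pd.DataFrame(
            [("HLAish", "6", 29_000_000, 30_500_000),
             ("other", "6", 40_000_000, 40_010_000)],
            columns=["gene", "chrom", "start", "end"]))
        gwas = make_gwas([
            ("mhc_snp", "6", 30_000_000, 0.5),
            ("edge_snp", "6", 33_400_000, 0.5),     # closed interval: excluded
            ("outside", "6", 33_400_001, 0.5),      # hmm, not near any gene though
            ("near_other", "6", 40_005_000, 0.5),
        ])
        out = annotate_genes_to_snps(ann, gwas, window=50_000)
        assert "HLAish" not in out
        assert out["other"] == ["near_other"]

    def test_snp_may_belong_to_multiple_genes(self):
        ann = GeneAnnotation(pd.DataFrame(
            [("G1", "1", 100, 200), ("G2", "1", 250, 400)],
            columns=["gene", "chrom", "start", "end"]))
        gwas = make_gwas([("s", "1", 225, 0.5)])
        out = annotate_genes_to_snps(ann, gwas, window=100, mhc=None)
        assert out == {"G1": ["s"], "G2": ["s"]}

    def test_assignments_invariant_to_gene_order(self, toy_annotation):
        gwas = make_gwas([("a", "1", 105_000, 0.5), ("b", "2", 55_000, 0.5)])
        fwd = annotate_genes_to_snps(toy_annotation, gwas, mhc=None)
        shuffled = GeneAnnotation(toy_annotation.table.iloc[::-1].reset_index(drop=True))
        rev = annotate_genes_to_snps(shuffled, gwas, mhc=None)
        assert fwd == rev

    def test_no_assignment_errors(self, toy_annotation):
        gwas = make_gwas([("far", "9", 1, 0.5)])
        with pytest.raises(ValidationError):
            annotate_genes_to_snps(toy_annotation, gwas)


class TestR2:
    def test_identical_vectors(self):
        assert compute_r2([0, 1, 2, 1], [0, 1, 2, 1]) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        assert compute_r2([0, 1, 2, 1], [2, 1, 0, 1]) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        assert compute_r2([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0)

    def test_pairwise_complete_on_missing(self):
        a = [0, 1, 2, np.nan, 1]
        b = [0, 1, 2, 2, np.nan]
        assert compute_r2(a, b) == pytest.approx(1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            compute_r2([1, 1, 1, 1], [0, 1, 2, 1])


class TestLdClump:
    def brute_force_members(self, panel, index, r2_min):
        var = panel.variants.set_index("snp")
        chrom = var.loc[index, "chrom"]
        idx = panel.dosage(index)
        members = [index]
        for snp in var.index[var["chrom"] == chrom]:
            if snp == index:
                continue
            try:
                if compute_r2(idx, panel.dosage(snp)) > r2_min:
                    members.append(snp)
            except ValidationError:
                continue
        return set(members)

    def test_pad_only_locus(self):
        dos = pd.DataFrame({"rs1": [0., 1, 2, 1, 0, 2], "rs2": [1., 1, 0, 2, 2, 0]},
                           index=[f"s{i}" for i in range(6)])
        var = pd.DataFrame({"snp": ["rs1", "rs2"], "chrom": "1",
                            "pos": [1_000_000, 5_000_000]})
        locus = ld_clump_locus("rs1", ReferencePanel(dos, var), r2_min=0.99)
        assert (locus.start, locus.end) == (950_000, 1_050_000)
        assert locus.end - locus.start + 1 == 100_001  # 100 kb + 1 bp
        assert locus.members == ["rs1"]

    def test_tight_block_members_and_boundaries(self):
        # near-perfect latent LD with matched allele frequencies so the
        # genotype-scale r^2 (attenuated by thresholding) stays above 0.6
        panel = simulate_reference_panel(PanelSimConfig(
            n_samples=1500, n_snps=5, rho=0.999, bp_spacing=100_000, seed=3,
            maf_range=(0.4, 0.5)))
        index = panel.variants["snp"].iloc[2]
        locus = ld_clump_locus(index, panel, r2_min=0.6, pad=50_000)
        assert set(locus.members) == set(panel.variants["snp"])
        positions = panel.variants["pos"]
        assert locus.start == positions.min() - 50_000
        assert locus.end == positions.max() + 50_000

    def test_members_equal_brute_force_scan(self):
        for seed in range(4):
            panel = simulate_reference_panel(PanelSimConfig(
                n_samples=200, n_snps=60, rho=0.8, bp_spacing=5_000, seed=seed))
            index = panel.variants["snp"].iloc[30]
            locus = ld_clump_locus(index, panel, r2_min=0.6)
            assert set(locus.members) == self.brute_force_members(panel, index, 0.6)

    def test_absent_index_rejected(self):
        panel = simulate_reference_panel(PanelSimConfig(n_samples=50, n_snps=5, seed=1))
        with pytest.raises(ValidationError):
            ld_clump_locus("nope", panel)


class TestGeneBasedTest:
    def test_single_snp_identity(self):
        for p in (0.5, 0.01, 1e-6):
            assert gene_based_test([p]) == pytest.approx(p, rel=1e-12)

    def test_chi2_closed_form(self):
        # R = I, m=2, z = (1.96, 0): m*T = 3.8416, p = exp(-q/2) for chi2_2
        p_snp = [2 * stats.norm.sf(1.96), 1.0]
        p = gene_based_test(p_snp, np.eye(2))
        assert p == pytest.approx(np.exp(-3.8416 / 2), rel=1e-4)

    def test_correlated_null_matches_simulation(self):
        m = 10
        R = 0.8 ** np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
        rng = np.random.default_rng(5)
        L = np.linalg.cholesky(R)
        draws = L @ rng.standard_normal((m, 100_000))
        qs = (draws**2).sum(axis=0)
        lam = np.linalg.eigvalsh(R)
        for q in (10.0, 25.0, 40.0):
            analytic = genetics.quadform_tail(q, lam)
            empirical = (qs > q).mean()
            se = np.sqrt(empirical * (1 - empirical) / qs.size)
            assert abs(analytic - empirical) < 4 * se + 1e-4

    def test_satterthwaite_fallback_close_to_imhof(self):
        lam = np.linalg.eigvalsh(0.5 ** np.abs(np.subtract.outer(np.arange(6),
                                                                 np.arange(6))))
        q = 9.0
        full = genetics.quadform_tail(q, lam)
        approx = genetics._satterthwaite_tail(q, np.maximum(lam, 0))
        assert abs(full - approx) < 0.05

    def test_no_snps_rejected(self):
        with pytest.raises(ValidationError):
            gene_based_test([])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            gene_based_test([0.5, 0.5], np.eye(3))


class TestCompetitiveTest:
    def _frame(self, z, members=None, n=200, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"G{i}" for i in range(n)]
        return pd.DataFrame({
            "z": z, "log_length": rng.normal(9, 1, n),
            "log_n_snps": rng.normal(2, 0.5, n),
        }, index=genes)

    def test_constant_z_gives_half(self):
        frame = self._frame(np.ones(200))
        res = competitive_geneset_test(frame, [f"G{i}" for i in range(20)])
        assert res["beta"] == pytest.approx(0.0, abs=1e-10)
        assert res["p"] == pytest.approx(0.5)

    def test_conditional_equal_to_global_when_background_is_everything(self):
        rng = np.random.default_rng(1)
        frame = self._frame(rng.normal(0, 1, 200))
        members = [f"G{i}" for i in range(30)]
        res_g = competitive_geneset_test(frame, members)
        res_c = competitive_geneset_test(frame, members, background=frame.index)
        assert res_g["p"] == pytest.approx(res_c["p"], rel=1e-12)

    def test_detects_injected_signal(self):
        rng = np.random.default_rng(2)
        z = rng.normal(0, 1, 300)
        z[:40] += 1.0
        frame = self._frame(z, n=300)
        res = competitive_geneset_test(frame, [f"G{i}" for i in range(40)])
        assert res["p"] < 0.01 and res["beta"] > 0.5

    def test_permutation_p_agrees_with_analytic(self):
        rng = np.random.default_rng(3)
        z = rng.normal(0, 1, 300)
        z[:40] += 0.6
        frame = self._frame(z, n=300)
        res = competitive_geneset_test(frame, [f"G{i}" for i in range(40)],
                                       permutations=999, seed=11)
        assert abs(res["p_permutation"] - res["p"]) < 0.03

    def test_constant_covariate_dropped_with_warning(self):
        frame = self._frame(np.random.default_rng(4).normal(0, 1, 100), n=100)
        frame["log_length"] = 5.0
        with pytest.warns(UserWarning, match="log_length"):
            res = competitive_geneset_test(frame, [f"G{i}" for i in range(10)])
        assert "log_length" not in res["covariates"]

    def test_too_small_set_rejected(self):
        frame = self._frame(np.zeros(50), n=50)
        with pytest.raises(ValidationError):
            competitive_geneset_test(frame, ["G0"])


class TestPrioritization:
    def _setup(self, toy_annotation):
        net_ec = build_network(
            [stats_from_sets("GA", ["GB", "GX"], ["GB"], "d1")], scope="EC")
        net_smc = build_network(
            [stats_from_sets("GA", ["GE", "GB"], ["GE", "GB"], "d2")], scope="SMC")
        loci = [
            Locus("rs1", "1", 90_000, 330_000, 100_000),   # covers GA, GB
            Locus("rs2", "2", 480_000, 540_000, 500_000),  # covers GE
            Locus("rs3", "1", 2_000_000, 2_100_000, 2_050_000),  # empty
        ]
        return loci, {"EC": net_ec, "SMC": net_smc}

    def test_flags_and_links(self, toy_annotation):
        loci, nets = self._setup(toy_annotation)
        table, summary = prioritize_locus_genes(loci, toy_annotation, nets)
        gb = table[table["gene"] == "GB"].iloc[0]
        assert gb["is_interactor"] and gb["linking_baits"] == "GA"
        ga = table[table["gene"] == "GA"].iloc[0]
        assert ga["is_index"]
        assert summary["n_unique_prioritized"] == 3  # GA, GB, GE deduplicated
        assert summary["per_network"]["EC"] == 2     # GA (index) + GB

    def test_no_overlap_gives_empty(self, toy_annotation):
        loci = [Locus("rs9", "1", 5_000_000, 5_100_000, 5_050_000)]
        net = build_network([stats_from_sets("GA", ["GB"], ["GB"])], scope="EC")
        table, summary = prioritize_locus_genes(loci, toy_annotation, {"EC": net})
        assert summary["n_unique_prioritized"] == 0

    def test_genes_in_locus_inclusive_overlap(self, toy_annotation):
        locus = Locus("rs1", "1", 110_000, 299_999, 150_000)
        assert genes_in_locus(locus, toy_annotation) == ["GA"]

    def test_social_manhattan_edges_subset_of_network(self, toy_annotation):
        loci, nets = self._setup(toy_annotation)
        table, _ = prioritize_locus_genes(loci, toy_annotation, nets)
        gwas = make_gwas([("rs1", "1", 100_000, 1e-8), ("rs2", "2", 500_000, 1e-6),
                          ("rs3", "1", 2_050_000, 1e-5)])
        nodes, edges = social_manhattan_table(table, gwas, nets)
        assert set(nodes["gene"]) == {"GA", "GB", "GE"}
        all_pairs = set()
        for net in nets.values():
            all_pairs |= net.edge_pairs
        for e in edges.itertuples(index=False):
            assert (e.gene_a, e.gene_b) in all_pairs
        row = nodes.set_index("gene").loc["GA"]
        assert row["minus_log10_p"] == pytest.approx(8.0)

    def test_gene_without_tagging_snp_excluded_with_warning(self, toy_annotation):
        loci, nets = self._setup(toy_annotation)
        table, _ = prioritize_locus_genes(loci, toy_annotation, nets)
        gwas = make_gwas([("rs1", "1", 100_000, 1e-8)])  # rs2 absent
        with pytest.warns(UserWarning, match="rs2"):
            nodes, _ = social_manhattan_table(table, gwas, nets)
        assert "GE" not in set(nodes["gene"])


def test_gene_p_uniform_under_null_blocks():
    """Gene p from the SNP-wise mean statistic is Uniform(0,1) when z-scores
    follow the null MVN with the same R used for the eigenvalues."""
    m, rho = 10, 0.5
    R = rho ** np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
    L = np.linalg.cholesky(R)
    rng = np.random.default_rng(17)
    ps = []
    for _ in range(400):
        z = L @ rng.standard_normal(m)
        ps.append(gene_based_test(2 * stats.norm.sf(np.abs(z)), R))
    assert stats.kstest(ps, "uniform").pvalue > 0.01
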