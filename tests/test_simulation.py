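import numpy as np
import pytest
from scipy import stats

from pathsgl.simulate import (
    EFFECT_CALIBRATION,
    SimScenario,
    disjoint_pathways,
    draw_causal_study1,
    draw_causal_study2,
    gene_min_p,
    power_fpr,
    qtt,
    ring_pathways,
    run_study1,
    run_study2,
    simulate_genotypes_hwe,
    simulate_genotypes_ldblocks,
    simulate_phenotype_gamma,
    simulate_phenotype_gv,
)
from pathsgl.mapping import SnpGeneMap


class TestHweGenotypes:
    def test_entries_are_allele_counts(self):
        G = simulate_genotypes_hwe(200, 50, (0.05, 0.5), seed=0)
        assert set(np.unique(G.values)) <= {0.0, 1.0, 2.0}
        assert G.values.shape == (200, 50)

    def test_homozygote_frequency_at_low_maf(self):
        # at MAF 0.05 the minor-homozygote frequency is 0.0025 under HWE
        N = 200_000
        rng = np.random.default_rng(1)
        G = rng.binomial(2, 0.05, size=N)  # reference draw
        G2 = simulate_genotypes_hwe(N, 1, (0.05, 0.05), seed=2)
        p_hat = (G2.values == 2).mean()
        se = np.sqrt(0.0025 * 0.9975 / N)
        assert abs(p_hat - 0.0025) < 3 * se

    def test_hwe_chisquare_calibrated(self):
        G = simulate_genotypes_hwe(2000, 400, (0.1, 0.5), seed=3)
        crit = stats.chi2.ppf(1 - 0.001, df=1)
        n_reject = 0
        for j in range(400):
            g = G.values[:, j]
            m = g.mean() / 2
            exp = 2000 * np.array([(1 - m) ** 2, 2 * m * (1 - m), m**2])
            obs = np.array([(g == 0).sum(), (g == 1).sum(), (g == 2).sum()])
            chi2 = ((obs - exp) ** 2 / np.maximum(exp, 1e-12)).sum()
            n_reject += chi2 > crit
        assert n_reject <= 4  # nominal 0.1% of 400, generous slack


class TestLdBlockGenotypes:
    def test_zero_rho_marginals_match_hwe_sim(self):
        Ga = simulate_genotypes_ldblocks(4000, 10, 10, 0.0, (0.1, 0.5), seed=4)
        Gb = simulate_genotypes_hwe(4000, 100, (0.1, 0.5), seed=5)
        fa = np.sort(Ga.values.mean(axis=0) / 2)
        fb = np.sort(Gb.values.mean(axis=0) / 2)
        # per-SNP MAFs are uniform draws in both; compare distributions
        ks = stats.ks_2samp(fa, fb)
        assert ks.pvalue > 1e-3

    def test_adjacent_r2_monotone_in_rho(self):
        means = []
        for rho in (0.0, 0.5, 0.9):
            G = simulate_genotypes_ldblocks(2000, 10, 8, rho, (0.2, 0.5), seed=6)
            r2 = []
            for b in range(10):
                for j in range(7):
                    c = np.corrcoef(
                        G.values[:, b * 8 + j], G.values[:, b * 8 + j + 1]
                    )[0, 1]
                    r2.append(c * c)
            means.append(np.mean(r2))
        assert means[0] < means[1] < means[2]

    def test_cross_block_correlation_near_zero(self):
        N = 3000
        G = simulate_genotypes_ldblocks(N, 6, 10, 0.9, (0.2, 0.5), seed=7)
        cors = [
            np.corrcoef(G.values[:, b * 10 + 3], G.values[:, (b + 1) * 10 + 3])[0, 1]
            for b in range(5)
        ]
        assert np.abs(cors).max() < 3 / np.sqrt(N - 3)


class TestPathwayConstructions:
    def test_disjoint_counts(self):
        coll = disjoint_pathways(50, 50)
        assert coll.snp_universe.size == 2500
        assert (coll.sizes == 50).all()

    def test_ring_counts(self):
        coll = ring_pathways(50, 30, 10)
        assert coll.snp_universe.size == 1000
        assert (coll.sizes == 30).all()

    def test_ring_neighbour_overlap_exact(self):
        L = 12
        coll = ring_pathways(L, 30, 10)
        for l in range(L):
            nxt = (l + 1) % L
            shared = np.intersect1d(coll.groups[l], coll.groups[nxt])
            assert shared.size == 10
            far = np.intersect1d(coll.groups[l], coll.groups[(l + 2) % L])
            assert far.size == 0


class TestCausalDraws:
    def test_study1_single_pathway(self, rng):
        coll = disjoint_pathways(10, 20)
        causal, pw = draw_causal_study1(coll, 5, rng)
        assert causal.size == 5
        assert pw.size == 1
        assert np.isin(causal, coll.groups[pw[0]]).all()

    def test_study2_causal_pathway_count_and_membership(self, rng):
        coll = ring_pathways(20, 30, 10)
        counts = []
        for _ in range(300):
            causal, pw = draw_causal_study2(coll, rng, 10)
            counts.append(pw.size)
            # no causal SNP belongs to more than two pathways
            membership = np.array(
                [sum(int(s in set(g.tolist())) for g in coll.groups) for s in causal]
            )
            assert membership.max() <= 2
        assert set(counts) <= {1, 2}
        assert 2 in counts


class TestPhenotypes:
    def test_gamma_zero_is_pure_noise(self):
        G = simulate_genotypes_hwe(500, 20, seed=8)
        ph = simulate_phenotype_gamma(G, np.arange(5), 0.0, seed=9)
        assert abs(ph.y.std() - 1.0) < 0.2
        assert abs(ph.y.mean()) < 1e-12

    def test_variance_monotone_in_gamma(self):
        G = simulate_genotypes_hwe(2000, 20, seed=10)
        variances = [
            simulate_phenotype_gamma(G, np.arange(10), g, seed=11).y.var()
            for g in (0.0, 0.2, 0.5)
        ]
        assert variances[0] < variances[1] < variances[2]

    def test_ols_recovers_calibrated_effect(self):
        N, gamma = 4000, 0.3
        G = simulate_genotypes_hwe(N, 6, (0.2, 0.5), seed=12)
        causal = np.array([2])
        pheno = simulate_phenotype_gamma(G, causal, gamma, seed=13)
        x = G.values[:, 2]
        x = (x - x.mean()) / x.std()
        slope = (x @ pheno.y) / (x @ x)
        se = 1.0 / np.sqrt(N)
        assert abs(slope - EFFECT_CALIBRATION * gamma) < 3 * se

    def test_gv_variance_decomposition(self):
        N, k, GV = 2000, 5, 0.04
        G = simulate_genotypes_hwe(N, 50, (0.1, 0.5), seed=14)
        causal = np.arange(5)
        pheno = simulate_phenotype_gv(G, causal, GV, seed=15)
        Xc = G.values[:, causal]
        coef, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(N), Xc]), pheno.y, rcond=None
        )
        fitted = np.column_stack([np.ones(N), Xc]) @ coef
        frac = fitted.var() / pheno.y.var()
        assert abs(frac - k * GV) < 0.02

    def test_gv_scaling_doubles_per_locus_variance(self):
        G = simulate_genotypes_hwe(5000, 10, (0.2, 0.5), seed=16)
        causal = np.array([0])
        f = []
        for gv in (0.02, 0.04):
            pheno = simulate_phenotype_gv(G, causal, gv, seed=17)
            x = G.values[:, 0]
            r2 = np.corrcoef(x, pheno.y)[0, 1] ** 2
            f.append(r2)
        assert f[1] / f[0] == pytest.approx(2.0, rel=0.25)

    def test_gv_constraint(self):
        G = simulate_genotypes_hwe(100, 10, seed=18)
        with pytest.raises(ValueError):
            simulate_phenotype_gv(G, np.arange(6), 0.2, seed=19)


class TestQtt:
    def test_duplicated_response_snp_has_tiny_p(self, rng):
        X = rng.standard_normal((200, 5))
        y = 3.0 * X[:, 2] + 0.01 * rng.standard_normal(200)
        p = qtt(X, y)
        assert p[2] < 1e-20

    def test_null_pvalues_uniform(self, rng):
        X = rng.binomial(2, 0.3, size=(300, 4000)).astype(float)
        y = rng.standard_normal(300)
        p = qtt(X, y)
        assert stats.kstest(p, "uniform").pvalue > 0.001

    def test_gene_ranking_min_p_monotone(self):
        sg = SnpGeneMap(
            snp_to_genes={0: {"A"}, 1: {"A"}, 2: {"B"}},
            gene_to_snps={"A": {0, 1}, "B": {2}},
        )
        p = np.array([0.5, 0.01, 0.2])
        ranking = gene_min_p(p, sg)
        assert ranking.index[0] == "A"
        # adding a worse SNP to A cannot change its score
        sg2 = SnpGeneMap(
            snp_to_genes={0: {"A"}, 1: {"A"}, 2: {"B"}, 3: {"A"}},
            gene_to_snps={"A": {0, 1, 3}, "B": {2}},
        )
        p2 = np.array([0.5, 0.01, 0.2, 0.9])
        assert gene_min_p(p2, sg2)["A"] == ranking["A"]


class TestPowerFpr:
    @pytest.mark.parametrize(
        "sel,caus,expect",
        [
            ([1, 2, 3], [1, 2, 3], (1.0, 0.0)),
            ([4, 5], [1, 2], (0.0, 1.0)),
            (list(range(10)), [0, 1, 2, 20, 21], (0.6, 0.7)),
            ([], [1, 2], (0.0, 0.0)),
        ],
    )
    def test_arithmetic(self, sel, caus, expect):
        power, fpr = power_fpr(np.array(sel), np.array(caus))
        assert (power, fpr) == pytest.approx(expect)


class TestStudyRunners:
    def test_study2_deterministic_given_seed(self):
        sc = SimScenario(N=120, L=8, pathway_size=12, overlap=4, k_causal=4,
                         n_mc=3, seed=42)
        r1 = run_study2(sc, gamma_grid=(0.1,))
        r2 = run_study2(sc, gamma_grid=(0.1,))
        assert r1.summary.equals(r2.summary)

    def test_study2_scenario_validation(self):
        with pytest.raises(ValueError):
            SimScenario(maf_range=(0.0, 0.5))
        with pytest.raises(ValueError):
            SimScenario(effect_mode="gv", GV=0.2, k_causal=10)

    def test_study1_null_effect_power_at_chance(self):
        sc = SimScenario(N=100, L=10, pathway_size=20, k_causal=3, n_mc=4,
                         seed=7, overlap=0)
        res = run_study1(sc, gamma_grid=(0.0,))
        assert res.summary["power_sgl"].iloc[0] <= 0.35
        assert res.summary["power_lasso"].iloc[0] <= 0.35

    def test_study2_purple_region_guard(self):
        sc = SimScenario(N=80, L=6, pathway_size=8, overlap=3, k_causal=50,
                         n_mc=1, seed=0)
        with pytest.raises(ValueError, match="purple"):
            run_study2(sc, gamma_grid=(0.05,))
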