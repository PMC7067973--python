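import numpy as np
import pytest

import haploblup as hb
from haploblup.gblup import grm_solve
from haploblup.hapcode import standardize

from _oracles import reml_direct


def naive_grm(X, p):
    """Double-loop VanRaden construction for the oracle comparison."""
    M = X - 2 * p
    c = 2 * np.sum(p * (1 - p))
    n = X.shape[0]
    G = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            G[i, j] = np.dot(M[i], M[j]) / c
    return G


class TestBuildGrm:
    def test_matches_naive_double_loop(self, rng):
        X = rng.integers(0, 3, size=(50, 200)).astype(float)
        p = X.sum(axis=0) / 100
        keep = (p > 0) & (p < 1)
        G = hb.build_grm(X, freqs=p)
        expected = naive_grm(X[:, keep], p[keep])
        np.testing.assert_allclose(
            G.values - G.ridge * np.eye(50), expected, atol=1e-10
        )

    def test_duplicated_individual_rows_identical(self, rng):
        X = rng.integers(0, 3, size=(30, 100)).astype(float)
        X[7] = X[3]
        G = hb.build_grm(X)
        raw = G.values - G.ridge * np.eye(G.n)
        np.testing.assert_allclose(raw[3], raw[7], atol=1e-12)
        np.testing.assert_allclose(raw[:, 3], raw[:, 7], atol=1e-12)

    def test_diag_mean_near_one_for_unrelated(self, small_sim):
        _, g, _, _ = small_sim
        G = hb.build_grm(hb.snp_design(g))
        assert abs(G.diag_mean - 1.0) < 0.1

    def test_symmetry_and_psd(self, small_sim):
        _, g, _, _ = small_sim
        G = hb.build_grm(hb.snp_design(g))
        np.testing.assert_allclose(G.values, G.values.T, atol=1e-10)
        assert np.linalg.eigvalsh(G.values).min() > 0  # after ridge

    def test_all_fixed_columns_error(self):
        X = np.full((10, 5), 2.0)
        with pytest.raises(ValueError, match="fixed"):
            hb.build_grm(X)

    def test_paper_literal_mode_double_scales(self, rng):
        X = rng.integers(0, 3, size=(40, 120)).astype(float)
        p = X.sum(axis=0) / 80
        keep = (p > 0) & (p < 1)
        G = hb.build_grm(X, mode="paper_literal", freqs=p)
        Ms = (X[:, keep] - 2 * p[keep]) / np.sqrt(2 * p[keep] * (1 - p[keep]))
        c = 2 * np.sum(p[keep] * (1 - p[keep]))
        np.testing.assert_allclose(
            G.values - G.ridge * np.eye(40), Ms @ Ms.T / c, atol=1e-10
        )


def _sim_gblup_data(rng, n=200, m=400, h2=0.4):
    X = rng.integers(0, 3, size=(n, m)).astype(float)
    p = X.sum(axis=0) / (2 * n)
    keep = (p > 0) & (p < 1)
    M = X[:, keep] - 2 * p[keep]
    c = 2 * np.sum(p[keep] * (1 - p[keep]))
    G = M @ M.T / c
    u = rng.normal(size=keep.sum()) * np.sqrt(h2 / (c * (1 - h2)))
    gvals = M @ u
    y = 3.0 + gvals + rng.normal(size=n) * np.sqrt(max(1 - h2, 1e-6))
    Xf = np.column_stack([np.ones(n), rng.integers(0, 2, n), rng.uniform(24, 36, n)])
    return hb.MixedModelSpec(y, Xf, np.arange(n)), hb.build_grm(X, freqs=p), M


class TestRemlFit:
    def test_agrees_with_direct_likelihood_maximization(self, rng):
        spec, G, _ = _sim_gblup_data(rng, n=150, m=300)
        mine = hb.reml_fit(spec, G)
        _, _, h2_ref = reml_direct(spec.y, spec.X, G.values)
        assert mine.h2 == pytest.approx(h2_ref, abs=2e-4)

    def test_pure_noise_recovers_boundary(self, rng):
        n = 300
        X = rng.integers(0, 3, size=(n, 500)).astype(float)
        G = hb.build_grm(X)
        h2s = []
        for _ in range(5):
            y = rng.normal(size=n)
            spec = hb.MixedModelSpec(y, np.ones((n, 1)), np.arange(n))
            h2s.append(hb.reml_fit(spec, G).h2)
        assert np.mean(h2s) <= 0.05

    def test_recovers_moderate_heritability(self, rng):
        h2s = []
        for _ in range(5):
            spec, G, _ = _sim_gblup_data(rng, n=250, m=500, h2=0.4)
            h2s.append(hb.reml_fit(spec, G).h2)
        assert np.mean(h2s) == pytest.approx(0.4, abs=0.1)

    def test_best_loglik_trace_is_monotone(self, rng):
        spec, G, _ = _sim_gblup_data(rng)
        v = hb.reml_fit(spec, G)
        assert all(b >= a - 1e-12 for a, b in zip(v.trace, v.trace[1:]))

    def test_reports_standard_errors(self, rng):
        spec, G, _ = _sim_gblup_data(rng)
        v = hb.reml_fit(spec, G)
        assert np.isfinite(v.se_h2) and v.se_h2 > 0


class TestBlup:
    def test_zero_genetic_variance_gives_zero_gebv(self, rng):
        spec, G, _ = _sim_gblup_data(rng)
        v = hb.VarianceEstimate(0.0, 1.0, 0.0, 0, 0, 0, 0.0, 1, True)
        sol = hb.blup_gebv(spec, G, v)
        np.testing.assert_allclose(sol.g_hat, 0, atol=1e-12)

    def test_exact_fixed_effects_recovered(self, rng):
        n = 100
        Xf = np.column_stack([np.ones(n), rng.uniform(24, 36, n)])
        b_true = np.array([5.0, 2.0])
        y = Xf @ b_true  # no noise, no genetics
        spec = hb.MixedModelSpec(y, Xf, np.arange(n))
        G = hb.build_grm(rng.integers(0, 3, size=(n, 200)).astype(float))
        v = hb.VarianceEstimate(1e-8, 1.0, 0.0, 0, 0, 0, 0.0, 1, True)
        sol = hb.blup_gebv(spec, G, v)
        np.testing.assert_allclose(sol.beta, b_true, atol=1e-6)
        np.testing.assert_allclose(sol.g_hat, 0, atol=1e-5)

    def test_backsolve_reconstruction_identity(self, rng):
        spec, G, M = _sim_gblup_data(rng)
        v = hb.reml_fit(spec, G)
        sol = hb.blup_gebv(spec, G, v)
        u = hb.backsolve_marker_effects(M, G, sol.g_hat)
        np.testing.assert_allclose(M @ u, sol.g_hat, atol=1e-8)

    def test_heldout_routes_coincide(self, rng):
        n, m = 150, 400
        X = rng.integers(0, 3, size=(n, m)).astype(float)
        tr, te = np.arange(120), np.arange(120, n)
        p = X[tr].sum(axis=0) / (2 * len(tr))
        keep = (p > 0) & (p < 1)
        M_tr = X[np.ix_(tr, np.flatnonzero(keep))] - 2 * p[keep]
        M_te = X[np.ix_(te, np.flatnonzero(keep))] - 2 * p[keep]
        G = hb.build_grm(X[tr], freqs=p)
        g_hat = M_tr @ rng.normal(size=keep.sum()) * 0.1
        G_new = M_te @ M_tr.T / G.scale_const
        r1 = hb.predict_new(G_new, G, g_hat)
        r2 = M_te @ hb.backsolve_marker_effects(M_tr, G, g_hat)
        np.testing.assert_allclose(r1, r2, atol=1e-8)

    def test_permuting_individuals_permutes_ghat_not_u(self, rng):
        spec, G, M = _sim_gblup_data(rng, n=120, m=300)
        v = hb.reml_fit(spec, G)
        sol = hb.blup_gebv(spec, G, v)
        u = hb.backsolve_marker_effects(M, G, sol.g_hat)
        perm = rng.permutation(len(spec.y))
        spec_p = hb.MixedModelSpec(spec.y[perm], spec.X[perm], spec.ids[perm])
        G_p = hb.GRM(G.values[np.ix_(perm, perm)], G.mode, G.scale_const,
                     G.n_markers, G.ridge)
        sol_p = hb.blup_gebv(spec_p, G_p, v)
        np.testing.assert_allclose(sol_p.g_hat, sol.g_hat[perm], atol=1e-8)
        u_p = hb.backsolve_marker_effects(M[perm], G_p, sol_p.g_hat)
        np.testing.assert_allclose(u_p, u, atol=1e-8)

    def test_paper_literal_backsolve_divides_by_n(self, rng):
        spec, G, M = _sim_gblup_data(rng, n=80, m=200)
        g_hat = rng.normal(size=80)
        u1 = hb.backsolve_marker_effects(M, G, g_hat, mode="paper_literal")
        expected = (M.T @ grm_solve(G, g_hat)) / 80
        np.testing.assert_allclose(u1, expected, atol=1e-12)


class TestPipelineDirection:
    def test_haplotype_model_estimates_higher_h2_on_allelic_trait(self):
        """With allele-level QTL, the haplotype design explains more variance."""
        wins = 0
        for seed in range(3):
            cfg = hb.SimConfig(
                n_individuals=300, chrom_lengths=(1_600_000, 1_600_000),
                n_snps_per_chrom=(400, 400), seed=seed,
                architecture="haplotype_allelic", n_qtl=25,
            )
            g, pheno, _ = hb.simulate(cfg)
            spec = hb.fixed_effects_design(pheno, "cwt")
            h2_snp = hb.reml_fit(spec, hb.build_grm(hb.snp_design(g))).h2
            part, _ = hb.blocks_by_ld_clustering(g, 5)
            m = hb.encode_diplotypes(g, hb.enumerate_alleles(g, part))
            h2_hap = hb.reml_fit(spec, hb.build_grm(m)).h2
            wins += h2_hap >= h2_snp
        assert wins >= 2
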