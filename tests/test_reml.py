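"""REML engine: boundary behaviour, grid-search oracles, GBLUP/ridge
equivalence and the dominance likelihood-ratio test."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg

from hetvar import (
    ModelSpec,
    TraitTruth,
    blup_solve,
    build_spec,
    genomic_matrices,
    heterozygosity,
    lrt_dominance,
    reml_fit,
    simulate_phenotypes,
    truth_from_fractions,
)


def restricted_ll(y, X, Ks, theta):
    """Independent restricted log-likelihood (direct dense formula)."""
    n = y.size
    V = theta[-1] * np.eye(n)
    for K, th in zip(Ks, theta[:-1]):
        V = V + th * K
    Vinv = np.linalg.inv(V)
    XtVX = X.T @ Vinv @ X
    P = Vinv - Vinv @ X @ np.linalg.inv(XtVX) @ X.T @ Vinv
    return -0.5 * (np.linalg.slogdet(V)[1] + np.linalg.slogdet(XtVX)[1] + y @ P @ y)


class TestRemlFit:
    def test_null_model_pins_genetic_components_at_zero(self, small_family_data):
        G, _ = small_family_data
        rng = np.random.default_rng(0)
        y = rng.normal(size=G.n_animals)
        Gm, Dm, _ = genomic_matrices(G)
        fit = reml_fit(build_spec(y, random_terms=[("additive", Gm), ("dominance", Dm)]))
        assert fit.sigma2["additive"] <= 0.05
        assert fit.sigma2["dominance"] <= 0.05
        assert fit.vp == pytest.approx(1.0, abs=0.2)

    def test_one_way_balanced_oracle(self):
        """Block-diagonal relationship (groups of repeated records) matches
        both the closed-form balanced one-way REML (ANOVA) estimators and a
        1-D restricted-likelihood grid search."""
        rng = np.random.default_rng(5)
        g, k = 40, 5  # 40 groups of 5
        n = g * k
        u = rng.normal(0, np.sqrt(2.0), size=g)
        y = np.repeat(u, k) + rng.normal(0, 1.0, size=n)
        K = np.kron(np.eye(g), np.ones((k, k)))
        X = np.ones((n, 1))
        fit = reml_fit(ModelSpec(y, X, [("group", K)]))
        # ANOVA / REML closed form for balanced one-way
        ybar_g = y.reshape(g, k).mean(axis=1)
        msb = k * np.sum((ybar_g - y.mean()) ** 2) / (g - 1)
        msw = np.sum((y.reshape(g, k) - ybar_g[:, None]) ** 2) / (g * (k - 1))
        assert fit.sigma2["residual"] == pytest.approx(msw, rel=1e-3)
        assert fit.sigma2["group"] == pytest.approx((msb - msw) / k, rel=1e-3)
        # grid search over sigma_u at the fitted residual
        grid = np.linspace(0.5, 4.0, 141)
        lls = [restricted_ll(y, X, [K], np.array([s, fit.sigma2["residual"]]))
               for s in grid]
        assert abs(grid[int(np.argmax(lls))] - fit.sigma2["group"]) <= 0.05

    def test_two_kernel_grid_oracle_small_n(self):
        """At n = 50 the AI-REML optimum matches a dense 2-D grid search."""
        from hetvar import SimConfig, simulate_genotypes

        cfg = SimConfig(n_breeds=1, animals_per_breed=50, n_sires_per_breed=5,
                        n_snps=120, seed=31)
        G, ped = simulate_genotypes(cfg)
        truth = truth_from_fractions(G, 0.35, 0.25, seed=32)
        y, _ = simulate_phenotypes(G, ped, truth, seed=33)
        Gm, Dm, _ = genomic_matrices(G)
        X = np.ones((G.n_animals, 1))
        fit = reml_fit(ModelSpec(y, X, [("g", Gm.values), ("d", Dm.values)]))
        grid = np.linspace(0.01, 1.2, 35)
        best, best_ll = None, -np.inf
        for sg in grid:
            for sd in grid:
                ll = restricted_ll(y, X, [Gm.values, Dm.values],
                                   np.array([sg, sd, fit.sigma2["residual"]]))
                if ll > best_ll:
                    best, best_ll = (sg, sd), ll
        res = np.diff(grid)[0]
        assert abs(best[0] - fit.sigma2["g"]) <= res
        assert abs(best[1] - fit.sigma2["d"]) <= res
        assert fit.loglik >= best_ll - 1e-6

    def test_fixed_effect_parameterization_invariance(self, two_breed_data):
        G, ped = two_breed_data
        truth = truth_from_fractions(G, 0.4, 0.1, seed=41)
        y, _ = simulate_phenotypes(G, ped, truth, seed=42)
        Gm, _, _ = genomic_matrices(G)
        breed = ped.set_index("animal").loc[G.animals, "breed"].values
        d1 = (breed == "B2").astype(float)
        X1 = np.column_stack([np.ones_like(d1), d1])         # treatment coding
        X2 = np.column_stack([d1, 1 - d1])                   # cell means coding
        f1 = reml_fit(ModelSpec(y, X1, [("g", Gm.values)]))
        f2 = reml_fit(ModelSpec(y, X2, [("g", Gm.values)]))
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-4)
        assert f1.sigma2["g"] == pytest.approx(f2.sigma2["g"], rel=1e-3)

    def test_am_adm_additive_agreement_on_hwe_data(self, small_family_data):
        """With near-orthogonal codings the AM and ADM additive fractions
        agree within 0.02."""
        G, ped = small_family_data
        truth = truth_from_fractions(G, 0.4, 0.1, seed=51)
        y, _ = simulate_phenotypes(G, ped, truth, seed=52)
        Gm, Dm, _ = genomic_matrices(G)
        het = heterozygosity(G)
        am = reml_fit(build_spec(y, het=het, random_terms=[("additive", Gm)]))
        adm = reml_fit(build_spec(y, het=het, random_terms=[("additive", Gm),
                                                            ("dominance", Dm)]))
        assert abs(am.ratio("additive") - adm.ratio("additive")) < 0.02

    def test_het_t_sign_tracks_dominance_direction(self, small_family_data):
        G, ped = small_family_data
        Gm, Dm, freqs = genomic_matrices(G)
        het = heterozygosity(G, freqs)
        for direction in (+1, -1):
            truth = truth_from_fractions(G, 0.2, 0.3, dominance_direction=direction,
                                         seed=61)
            y, _ = simulate_phenotypes(G, ped, truth, seed=62)
            fit = reml_fit(build_spec(y, het=het,
                                      random_terms=[("additive", Gm), ("dominance", Dm)]))
            assert np.sign(fit.het_t) == direction

    def test_confounded_fixed_column_dropped_with_name(self):
        y = np.arange(10.0)
        X = np.column_stack([np.ones(10), np.ones(10)])
        spec = ModelSpec(y, X, [], fixed_names=["intercept", "dup"])
        assert spec.dropped_fixed == ["dup"]


class TestLrt:
    def test_trivial_values(self, small_family_data):
        G, _ = small_family_data
        rng = np.random.default_rng(3)
        y = rng.normal(size=G.n_animals)
        Gm, Dm, _ = genomic_matrices(G)
        am = reml_fit(build_spec(y, random_terms=[("additive", Gm)]))
        assert lrt_dominance(am, am)[0] == 0.0
        assert lrt_dominance(am, am)[1] == 1.0
        # chi2(1) quantile check through the same interface
        fake = reml_fit(build_spec(y, random_terms=[("additive", Gm)]))
        fake.loglik = am.loglik + 3.841 / 2
        stat, p = lrt_dominance(am, fake)
        assert stat == pytest.approx(3.841)
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_mismatched_data_rejected(self, small_family_data):
        G, _ = small_family_data
        rng = np.random.default_rng(3)
        Gm, _, _ = genomic_matrices(G)
        f1 = reml_fit(build_spec(rng.normal(size=G.n_animals),
                                 random_terms=[("additive", Gm)]))
        f2 = reml_fit(build_spec(rng.normal(size=G.n_animals),
                                 random_terms=[("additive", Gm)]))
        with pytest.raises(ValueError, match="same data"):
            lrt_dominance(f1, f2)


class TestBlup:
    def test_zero_variance_gives_zero_blup(self, small_family_data):
        G, _ = small_family_data
        rng = np.random.default_rng(9)
        y = rng.normal(size=G.n_animals)
        Gm, _, _ = genomic_matrices(G)
        fit = reml_fit(build_spec(y, random_terms=[("additive", Gm)]))
        if fit.sigma2["additive"] == 0.0:
            assert np.allclose(blup_solve(fit)["additive"], 0.0)
        else:  # tiny spurious component: predictions scale with it
            assert np.abs(blup_solve(fit)["additive"]).max() < 0.5

    def test_gblup_equals_snp_ridge(self):
        """Relationship-matrix BLUP a_hat, d_hat equal T u_hat, H v_hat from
        the equivalent per-SNP ridge model solved through the mixed-model
        equations (independent route)."""
        from hetvar import SimConfig, simulate_genotypes
        from hetvar.kinship import additive_coding, allele_frequencies, dominance_coding

        cfg = SimConfig(n_breeds=1, animals_per_breed=200, n_sires_per_breed=10,
                        n_snps=500, seed=71)
        G, ped = simulate_genotypes(cfg)
        truth = truth_from_fractions(G, 0.4, 0.15, seed=72)
        y, _ = simulate_phenotypes(G, ped, truth, seed=73)
        freqs = allele_frequencies(G)
        T = additive_coding(G, freqs).values
        H = dominance_coding(G, freqs).values
        m = T.shape[1]
        Gm = T @ T.T / m
        Dm = H @ H.T / m
        X = np.ones((G.n_animals, 1))
        fit = reml_fit(ModelSpec(y, X, [("g", Gm), ("d", Dm)]))
        sg, sd, se = fit.sigma2["g"], fit.sigma2["d"], fit.sigma2["residual"]
        preds = blup_solve(fit)
        # MME for y = Xb + T u + H v + e, Var(u) = I sg/m, Var(v) = I sd/m
        lam_u, lam_v = m * se / sg, m * se / sd
        W = np.hstack([X, T, H])
        C = W.T @ W
        C[1:m + 1, 1:m + 1] += lam_u * np.eye(m)
        C[m + 1:, m + 1:] += lam_v * np.eye(m)
        sol = np.linalg.solve(C, W.T @ y)
        u_hat, v_hat = sol[1:m + 1], sol[m + 1:]
        np.testing.assert_allclose(preds["g"], T @ u_hat, atol=1e-6)
        np.testing.assert_allclose(preds["d"], H @ v_hat, atol=1e-6)

    def test_cross_prediction_matches_joint_solve(self, small_family_data):
        """Predicting held-out animals through the cross block equals fitting
        with their phenotypes masked in a joint MME solve."""
        G, _ = small_family_data
        rng = np.random.default_rng(15)
        Gm, _, _ = genomic_matrices(G)
        truth = truth_from_fractions(G, 0.5, 0.0, seed=16)
        ped = pd.DataFrame({"animal": G.animals, "sire": None, "dam": None})
        y, _ = simulate_phenotypes(G, ped, truth, seed=17)
        n = G.n_animals
        train = np.arange(0, n - 50)
        test = np.arange(n - 50, n)
        Ktt = Gm.values[np.ix_(train, train)]
        fit = reml_fit(ModelSpec(y[train], np.ones((train.size, 1)), [("g", Ktt)]))
        preds = blup_solve(fit, cross={"g": Gm.values[np.ix_(test, train)]})
        # direct formula sigma^2 K_cross V^-1 (y - X beta)
        sg, se = fit.sigma2["g"], fit.sigma2["residual"]
        V = sg * Ktt + se * np.eye(train.size)
        r = y[train] - fit.beta[0]
        direct = sg * Gm.values[np.ix_(test, train)] @ np.linalg.solve(V, r)
        np.testing.assert_allclose(preds["g"], direct, atol=1e-6)
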