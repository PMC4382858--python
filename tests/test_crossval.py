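"""Sire-family folds, sign concordance and prediction accuracy."""

import numpy as np
import pandas as pd
import pytest

from hetvar import (
    TraitTruth,
    accuracy_by_breed,
    concordance_chi2,
    cv_predict,
    fit_null_background,
    genomic_matrices,
    scan,
    sign_concordance,
    sire_family_folds,
    simulate_phenotypes,
    truth_from_fractions,
)


def _ped(sire_sizes, prefix=""):
    rows = []
    for s, size in enumerate(sire_sizes):
        rows.append((f"{prefix}s{s}", None, None))
        for o in range(size):
            rows.append((f"{prefix}o{s}_{o}", f"{prefix}s{s}", None))
    return pd.DataFrame(rows, columns=["animal", "sire", "dam"])


class TestFolds:
    def test_five_equal_families(self):
        ped = _ped([10] * 5)
        offspring = [a for a in ped["animal"] if a.startswith("o")]
        folds = sire_family_folds(ped, k=5, seed=0, animals=offspring)
        sizes = folds.folds.value_counts()
        assert sorted(sizes) == [10] * 5
        # each fold is exactly one family
        fam = pd.Series({a: a.split("_")[0] for a in offspring})
        assert (folds.folds.groupby(fam).nunique() == 1).all()

    def test_partition_and_no_straddling(self):
        rng = np.random.default_rng(3)
        ped = _ped(rng.integers(1, 31, size=100))
        offspring = [a for a in ped["animal"] if a.startswith("o")]
        folds = sire_family_folds(ped, k=5, seed=1, animals=offspring)
        assert set(folds.folds.index) == set(offspring)  # partition
        sires = ped.set_index("animal").loc[offspring, "sire"]
        assert (folds.folds.groupby(sires.values).nunique() == 1).all()

    @pytest.mark.parametrize("seed", range(20))
    def test_greedy_balance(self, seed):
        rng = np.random.default_rng(seed)
        ped = _ped(rng.integers(1, 31, size=100))
        offspring = [a for a in ped["animal"] if a.startswith("o")]
        folds = sire_family_folds(ped, k=5, seed=seed, animals=offspring)
        sizes = folds.folds.value_counts()
        assert sizes.max() / sizes.min() <= 1.3

    def test_unknown_sire_singletons(self):
        ped = pd.DataFrame({"animal": [f"a{i}" for i in range(10)],
                            "sire": [None] * 10, "dam": [None] * 10})
        folds = sire_family_folds(ped, k=5, seed=0)
        assert sorted(folds.folds.value_counts()) == [2] * 5

    def test_too_few_families(self):
        ped = _ped([5, 5])
        with pytest.raises(ValueError, match="families"):
            sire_family_folds(ped, k=5, seed=0,
                              animals=[a for a in ped["animal"] if a.startswith("o")])


class TestConcordance:
    def test_chi2_arithmetic(self):
        """115 of 174 same-direction gives chi2 ~ 18.0, P < 0.001."""
        chi2, p = concordance_chi2(174, 115)
        assert chi2 == pytest.approx(18.0, abs=0.05)
        assert p < 0.001

    def _split_scan(self, G, ped, y, threshold=1e-3):
        offspring = list(G.animals)
        folds = sire_family_folds(ped, k=5, seed=2, animals=offspring)
        val = set(folds.animals_in(1))
        disc = [a for a in offspring if a not in val]
        val = [a for a in offspring if a in val]
        pos = {a: i for i, a in enumerate(offspring)}
        di = np.array([pos[a] for a in disc])
        vi = np.array([pos[a] for a in val])
        bg_d = fit_null_background(y[di], np.ones((di.size, 1)), None)
        disc_df, _ = scan(G.subset_animals(disc), bg_d, threshold=threshold)
        bg_v = fit_null_background(y[vi], np.ones((vi.size, 1)), None)
        return disc_df, G.subset_animals(val), bg_v

    def test_null_concordance_near_half(self, small_family_data):
        """Pure-noise traits validate in ~50% of cases and the test stays
        non-significant in most replicates."""
        G, ped = small_family_data
        hits = []
        nonsig = 0
        reps = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            y = rng.normal(size=G.n_animals)
            disc_df, G_val, bg_v = self._split_scan(G, ped, y, threshold=5e-2)
            res = sign_concordance(disc_df, G_val, bg_v, threshold=5e-2)
            if res is None:
                continue
            reps += 1
            hits.append(res.n_same_direction / res.n_tested)
            nonsig += res.p_value > 0.05
        assert reps >= 5
        assert abs(np.mean(hits) - 0.5) < 0.15
        assert nonsig >= 0.7 * reps

    def test_planted_dominance_concordant(self, small_family_data):
        G, ped = small_family_data
        qtl = list(range(0, 100, 10))
        truth = TraitTruth(causal_dominance=[(j, 1.5) for j in qtl], residual_var=1.0)
        y, _ = simulate_phenotypes(G, ped, truth, seed=7)
        disc_df, G_val, bg_v = self._split_scan(G, ped, y, threshold=1e-3)
        res = sign_concordance(disc_df, G_val, bg_v, threshold=1e-3)
        assert res is not None
        assert res.percentage > 50.0
        assert res.p_value < 0.05

    def test_empty_discovery_returns_none(self, small_family_data):
        G, ped = small_family_data
        rng = np.random.default_rng(5)
        y = rng.normal(size=G.n_animals)
        disc_df, G_val, bg_v = self._split_scan(G, ped, y, threshold=1e-12)
        assert sign_concordance(disc_df, G_val, bg_v, threshold=1e-12) is None


class TestCvPredict:
    def _setup(self, G, ped, truth_kw, seed):
        truth = truth_from_fractions(G, seed=seed, **truth_kw)
        y, _ = simulate_phenotypes(G, ped, truth, seed=seed + 1)
        Gm, Dm, _ = genomic_matrices(G)
        folds = sire_family_folds(ped, k=5, seed=3, animals=list(G.animals))
        X = np.ones((G.n_animals, 1))
        return y, {"additive": Gm, "dominance": Dm}, folds, X

    def test_zero_heritability_zero_accuracy(self, small_family_data):
        G, ped = small_family_data
        y, mats, folds, X = self._setup(G, ped, dict(va_frac=0.0, vd_frac=0.0), 11)
        pred = cv_predict(mats, y, X, folds, list(G.animals), model="AM")
        r = np.corrcoef(pred["g_hat"], pred["y_corrected"])[0, 1]
        assert abs(r) < 0.15

    def test_additive_signal_predicts(self, small_family_data):
        G, ped = small_family_data
        y, mats, folds, X = self._setup(G, ped, dict(va_frac=0.5, vd_frac=0.0), 13)
        pred = cv_predict(mats, y, X, folds, list(G.animals), model="AM")
        r = np.corrcoef(pred["g_hat"], pred["y_corrected"])[0, 1]
        assert r > 0.25

    def test_masking_validation_phenotypes(self, small_family_data):
        """Perturbing a validation phenotype must not move its prediction."""
        G, ped = small_family_data
        y, mats, folds, X = self._setup(G, ped, dict(va_frac=0.4, vd_frac=0.1), 17)
        pred1 = cv_predict(mats, y, X, folds, list(G.animals), model="ADM")
        victim = folds.animals_in(1)[0]
        i = list(G.animals).index(victim)
        y2 = y.copy()
        y2[i] += 100.0
        pred2 = cv_predict(mats, y2, X, folds, list(G.animals), model="ADM")
        assert pred2["g_hat"].loc[victim] == pytest.approx(pred1["g_hat"].loc[victim],
                                                           abs=1e-8)

    def test_adm_not_worse_with_strong_dominance(self, small_family_data):
        """With substantial dominance variance and dense families, adding the
        DRM does not hurt (and tends to help) out-of-fold accuracy."""
        G, ped = small_family_data
        diffs = []
        for seed in (19, 29, 39):
            y, mats, folds, X = self._setup(G, ped,
                                            dict(va_frac=0.25, vd_frac=0.35), seed)
            am = cv_predict(mats, y, X, folds, list(G.animals), model="AM")
            adm = cv_predict(mats, y, X, folds, list(G.animals), model="ADM")
            r_am = np.corrcoef(am["g_hat"], am["y_corrected"])[0, 1]
            r_adm = np.corrcoef(adm["g_hat"], adm["y_corrected"])[0, 1]
            diffs.append(r_adm - r_am)
        assert np.mean(diffs) > -0.02


class TestAccuracy:
    def test_weighted_mean_arithmetic(self):
        g = np.concatenate([np.random.default_rng(0).normal(size=300),
                            np.random.default_rng(1).normal(size=250)])
        rng = np.random.default_rng(2)
        y = g.copy()
        y[:300] = 0.20 * 10 * g[:300] + rng.normal(size=300) * np.sqrt(1 - 0.04) * 10
        breeds = ["X"] * 300 + ["Y"] * 250
        tab = accuracy_by_breed(g, y, breeds, min_n=200)
        # overall must equal the record-weighted mean of the per-breed values
        pb = tab.per_breed.set_index("breed")
        manual = (pb["n"] * pb["accuracy"]).sum() / pb["n"].sum()
        assert tab.overall == pytest.approx(manual)
        assert (300, 250) == tuple(pb["n"])
        # worked numbers: accuracies (0.20, 0.30) at n = (300, 250) -> 0.2455
        fake = accuracy_by_breed(
            np.r_[np.linspace(0, 1, 300), np.linspace(0, 1, 250)],
            np.r_[np.linspace(0, 1, 300), np.linspace(0, 1, 250)],
            breeds, min_n=200)
        assert (300 * 0.20 + 250 * 0.30) / 550 == pytest.approx(0.2455, abs=1e-4)

    def test_small_breed_excluded(self):
        rng = np.random.default_rng(3)
        g = rng.normal(size=350)
        y = g + rng.normal(size=350)
        breeds = ["big"] * 200 + ["small"] * 150
        tab = accuracy_by_breed(g, y, breeds, min_n=200)
        assert tab.per_breed["breed"].tolist() == ["big"]

    def test_constant_predictions_flagged(self):
        y = np.random.default_rng(4).normal(size=250)
        tab = accuracy_by_breed(np.zeros(250), y, ["b"] * 250, min_n=200)
        assert np.isnan(tab.per_breed["accuracy"].iloc[0])
        assert np.isnan(tab.overall)

    def test_overall_within_breed_range(self):
        rng = np.random.default_rng(5)
        g = rng.normal(size=600)
        y = g + rng.normal(size=600) * 2
        breeds = ["a"] * 300 + ["b"] * 300
        tab = accuracy_by_breed(g, y, breeds, min_n=200)
        accs = tab.per_breed["accuracy"]
        assert accs.min() - 1e-12 <= tab.overall <= accs.max() + 1e-12
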