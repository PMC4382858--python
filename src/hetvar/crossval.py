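"""Sire-family cross-validation, sign-concordance validation and accuracy.

Validation must be independent of discovery at the family level: paternal
half-sibs share half their sire's genome, so splitting a half-sib family
between reference and validation would leak information.  Folds are
therefore assigned to whole sire families.  Dominance-effect validation
re-estimates each discovery-significant SNP in the held-out animals and asks
whether the sign agrees more often than the 50% expected of pure noise;
prediction accuracy is the within-breed correlation between out-of-fold
predicted genetic values and fixed-effect-corrected phenotypes, averaged
over breeds with weights proportional to record counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeMatrix, RelationshipMatrix
from .gwas import BackgroundFit, fit_null_background, test_snp
from .reml import ModelSpec, blup_solve, reml_fit


@dataclass
class FoldAssignment:
    folds: pd.Series  # animal id -> fold in {1..k}
    k: int
    seed: int

    def animals_in(self, fold: int) -> list:
        return self.folds.index[self.folds == fold].tolist()


def sire_family_folds(ped: pd.DataFrame, k: int = 5, seed: int = 0, animals=None) -> FoldAssignment:
    """Assign whole paternal half-sib families to k folds of near-equal size.

    Greedy balancing: families in decreasing size (ties broken by a seeded
    shuffle) each go to the currently smallest fold.  Animals with an
    unknown sire count as singleton families, which preserves the guarantee
    that no paternal half-sib pair straddles a fold boundary.
    """
    if k < 2:
        raise ValueError("need k >= 2 folds")
    ped = ped.set_index("animal", drop=False) if "animal" in ped.columns else ped
    if animals is None:
        animals = ped["animal"].tolist()
    sires = ped.loc[animals, "sire"]
    fam_key = [s if pd.notna(s) else f"__singleton_{a}" for a, s in zip(animals, sires)]
    groups: dict = {}
    for a, f in zip(animals, fam_key):
        groups.setdefault(f, []).append(a)
    if len(groups) < k:
        raise ValueError(f"only {len(groups)} sire families for {k} folds")
    rng = np.random.default_rng(seed)
    fams = list(groups.items())
    rng.shuffle(fams)
    fams.sort(key=lambda kv: -len(kv[1]))  # stable: keeps the shuffled tie order
    sizes = np.zeros(k, dtype=int)
    assign = {}
    for fam, members in fams:
        tgt = int(np.argmin(sizes))
        sizes[tgt] += len(members)
        for a in members:
            assign[a] = tgt + 1
    return FoldAssignment(pd.Series({a: assign[a] for a in animals}, name="fold"), k, seed)


@dataclass
class ConcordanceResult:
    n_tested: int
    n_same_direction: int
    percentage: float
    chi2: float
    p_value: float
    by_sign: pd.DataFrame  # rows +/-: n tested, n same, percentage


def sign_concordance(
    discovery: pd.DataFrame,
    G_val: GenotypeMatrix,
    bg_val: BackgroundFit,
    threshold: float = 1e-4,
) -> ConcordanceResult | None:
    """Direction concordance of discovery-significant dominance effects.

    ``discovery`` is a GWAS record table from :func:`hetvar.gwas.scan`.
    SNPs significant at the threshold are re-estimated in the validation
    animals; SNPs lacking all three genotype classes there are dropped.  The
    chi-squared statistic tests the same-direction count against n/2.
    """
    sig = discovery[(discovery["p_dom"].notna()) & (discovery["p_dom"] < threshold)]
    if len(sig) == 0:
        return None
    ids = G_val.snps["snp"].tolist()
    rows = []
    for rec in sig.itertuples():
        if rec.snp not in ids:
            continue
        v = test_snp(G_val.genotypes[:, ids.index(rec.snp)], bg_val, rec.snp)
        if v is None or not np.isfinite(v.delta):
            continue
        rows.append((rec.snp, np.sign(rec.delta), np.sign(v.delta)))
    if not rows:
        return None
    tab = pd.DataFrame(rows, columns=["snp", "disc_sign", "val_sign"])
    same = tab["disc_sign"] == tab["val_sign"]
    n, k_same = len(tab), int(same.sum())
    chi2 = (2 * k_same - n) ** 2 / n
    p = float(stats.chi2.sf(chi2, df=1))
    by_sign = (
        tab.assign(same=same)
        .groupby(tab["disc_sign"].map({1.0: "+", -1.0: "-"}))
        .agg(n_tested=("snp", "size"), n_same=("same", "sum"))
    )
    by_sign["percentage"] = 100.0 * by_sign["n_same"] / by_sign["n_tested"]
    return ConcordanceResult(n, k_same, 100.0 * k_same / n, chi2, p, by_sign)


def concordance_chi2(n_tested: int, n_same: int) -> tuple[float, float]:
    """Chi-squared test of a same-direction count against the 50% null."""
    chi2 = (2 * n_same - n_tested) ** 2 / n_tested
    return chi2, float(stats.chi2.sf(chi2, df=1))


def cv_predict(
    matrices: dict,
    y: np.ndarray,
    X: np.ndarray,
    folds: FoldAssignment,
    animals: list,
    model: str = "ADM",
    correction: str = "training",
) -> pd.DataFrame:
    """Out-of-fold prediction of total genetic values g_hat.

    ``matrices`` maps term labels to RelationshipMatrix objects covering all
    animals (validation animals stay in the matrices; only their phenotypes
    are masked).  ``model`` is ``"AM"`` (first term only, g_hat = a_hat) or
    ``"ADM"`` (all terms, g_hat = a_hat + d_hat).  Returns a frame with the
    out-of-fold prediction and the fixed-effect-corrected phenotype per
    animal; the correction uses training-fold fixed-effect estimates by
    default (``correction="full"`` estimates them once from all data).
    """
    if model not in ("AM", "ADM"):
        raise ValueError("model must be 'AM' or 'ADM'")
    labels = list(matrices)
    if model == "AM":
        labels = labels[:1]
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    pos = {a: i for i, a in enumerate(animals)}
    g_hat = pd.Series(np.nan, index=pd.Index(animals, name="animal"))
    y_corr = pd.Series(np.nan, index=g_hat.index)
    full_beta = None
    if correction == "full":
        bg = fit_null_background(y, X, matrices[labels[0]].values)
        full_beta = bg.fit.beta if bg.fit is not None else np.linalg.lstsq(X, y, rcond=None)[0]
    for fold in range(1, folds.k + 1):
        val = [a for a in folds.animals_in(fold) if a in pos]
        train = [a for a in animals if folds.folds.get(a) != fold]
        vi = np.array([pos[a] for a in val], dtype=int)
        ti = np.array([pos[a] for a in train], dtype=int)
        if ti.size == 0 or vi.size == 0:
            continue
        terms = [(lab, matrices[lab].values[np.ix_(ti, ti)]) for lab in labels]
        fit = reml_fit(ModelSpec(y[ti], X[ti], terms))
        cross = {lab: matrices[lab].values[np.ix_(vi, ti)] for lab in labels}
        preds = blup_solve(fit, cross)
        g_hat.iloc[vi] = preds["total"]
        beta = full_beta if full_beta is not None else fit.beta
        Xv = X[vi][:, : beta.size] if X.shape[1] != beta.size else X[vi]
        y_corr.iloc[vi] = y[vi] - Xv @ beta
    return pd.DataFrame({"g_hat": g_hat, "y_corrected": y_corr})


@dataclass
class AccuracyTable:
    per_breed: pd.DataFrame  # breed, n, accuracy (NaN-flagged when degenerate)
    overall: float
    model: str


def accuracy_by_breed(
    g_hat, y_corrected, breeds, min_n: int = 200, model: str = "ADM"
) -> AccuracyTable:
    """Within-breed correlation of predictions with corrected phenotypes.

    Breeds with fewer than ``min_n`` records are excluded; a breed whose
    predictions are constant gets a NaN accuracy (flagged, not zeroed) and is
    left out of the record-weighted overall mean.
    """
    df = pd.DataFrame({
        "g_hat": np.asarray(g_hat, dtype=float),
        "y": np.asarray(y_corrected, dtype=float),
        "breed": list(breeds),
    }).dropna()
    rows = []
    for breed, grp in df.groupby("breed"):
        if len(grp) < min_n:
            continue
        if grp["g_hat"].std() == 0 or grp["y"].std() == 0:
            rows.append((breed, len(grp), np.nan))
            continue
        rows.append((breed, len(grp), float(np.corrcoef(grp["g_hat"], grp["y"])[0, 1])))
    per_breed = pd.DataFrame(rows, columns=["breed", "n", "accuracy"])
    usable = per_breed.dropna(subset=["accuracy"])
    overall = (
        float((usable["n"] * usable["accuracy"]).sum() / usable["n"].sum())
        if len(usable)
        else np.nan
    )
    return AccuracyTable(per_breed, overall, model)
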