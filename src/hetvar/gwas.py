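"""Single-SNP additive + dominance association scans with a polygenic background.

The scan follows the two-stage generalised-least-squares strategy that is
standard for mixed-linear-model association: variance components of the
no-SNP model (polygenic term against a pedigree A or a GRM, plus residual)
are estimated once by REML, the implied covariance V = sigma_a^2 K +
sigma_e^2 I is Cholesky-factored, and every SNP is tested by ordinary least
squares in the whitened space.  For each SNP the additive dosage s (0/1/2
B-allele counts) and the heterozygote indicator w (AB = 1) are fitted
jointly as covariates, so the Wald test on the dominance coefficient is
conditional on the additive effect.  An exact mode that re-estimates the
variance components for every SNP is available for small panels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .datatypes import MISSING, GenotypeMatrix
from .reml import ModelSpec, RemlResult, reml_fit


@dataclass
class BackgroundFit:
    """Null-model variance components plus the decorrelating transform."""

    fit: RemlResult | None
    L: np.ndarray       # lower Cholesky factor of V = sigma_a^2 K + sigma_e^2 I
    y_w: np.ndarray     # whitened response
    X_w: np.ndarray     # whitened fixed design
    Q: np.ndarray       # orthonormal basis for span(X_w)

    @property
    def n(self) -> int:
        return self.y_w.size

    def whiten(self, M: np.ndarray) -> np.ndarray:
        return linalg.solve_triangular(self.L, M, lower=True)


def fit_null_background(y, X, K=None) -> BackgroundFit:
    """REML fit of y = Xb + a + e with a ~ N(0, K sigma_a^2), factored once.

    With ``K=None`` (or a fitted sigma_a^2 of zero) the transform collapses
    to a scalar and the downstream tests are ordinary least squares.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if K is not None:
        Kv = np.asarray(K.values if hasattr(K, "values") else K, dtype=float)
        fit = reml_fit(ModelSpec(y, X, [("polygenic", Kv)]))
        V = fit.sigma2["polygenic"] * Kv + fit.sigma2["residual"] * np.eye(y.size)
    else:
        fit = None
        V = np.eye(y.size)
    L = linalg.cholesky(V, lower=True)
    y_w = linalg.solve_triangular(L, y, lower=True)
    X_w = linalg.solve_triangular(L, X, lower=True)
    Q, _ = np.linalg.qr(X_w)
    return BackgroundFit(fit=fit, L=L, y_w=y_w, X_w=X_w, Q=Q)


@dataclass
class GwasRecord:
    snp: str
    alpha: float
    alpha_se: float
    p_add: float
    delta: float
    delta_se: float
    p_dom: float
    n_classes: tuple  # (n_AA, n_AB, n_BB)
    note: str = ""


def _joint_gls(bg: BackgroundFit, covars: np.ndarray):
    """OLS of the whitened response on [X_w | whitened covars]; returns
    coefficients, SEs and two-sided t p-values for the extra covariates."""
    Cw = bg.whiten(covars)
    C_perp = Cw - bg.Q @ (bg.Q.T @ Cw)
    y_perp = bg.y_w - bg.Q @ (bg.Q.T @ bg.y_w)
    G = C_perp.T @ C_perp
    b = np.linalg.solve(G, C_perp.T @ y_perp)
    resid = y_perp - C_perp @ b
    df = bg.n - bg.Q.shape[1] - covars.shape[1]
    s2 = float(resid @ resid) / df
    cov = s2 * np.linalg.inv(G)
    se = np.sqrt(np.diag(cov))
    t = b / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return b, se, p, df


def test_snp(x, bg: BackgroundFit, snp_id: str = "", exact_refit=None) -> GwasRecord | None:
    """Additive + dominance test of one SNP against a fitted background.

    ``x`` is the 0/1/2 dosage vector (missing as -1, mean-imputed here).
    Returns ``None`` for a constant SNP.  With only two genotype classes the
    additive effect is still estimated but the dominance effect is marked
    inestimable (NaN).  ``exact_refit`` optionally supplies ``(y, X, K)`` to
    re-estimate the background variance components with this SNP's
    covariates absorbed into the fixed design first.
    """
    x = np.asarray(x, dtype=float).ravel()
    miss = x == MISSING
    if miss.any():
        x = x.copy()
        x[miss] = x[~miss].mean()
    counts = (int((x == 0).sum()), int((x == 1).sum()), int((x == 2).sum()))
    if np.ptp(x) == 0:
        return None
    w = (x == 1).astype(float)
    three_classes = all(c > 0 for c in counts)
    if exact_refit is not None:
        y0, X0, K0 = exact_refit
        covs = np.column_stack([x, w]) if three_classes else x[:, None]
        bg = fit_null_background(y0, np.column_stack([X0, covs]), K0)
        # rebuild without the SNP columns in X so _joint_gls tests them
        bg = BackgroundFit(bg.fit, bg.L,
                           linalg.solve_triangular(bg.L, y0, lower=True),
                           linalg.solve_triangular(bg.L, X0, lower=True),
                           np.linalg.qr(linalg.solve_triangular(bg.L, X0, lower=True))[0])
    if three_classes:
        b, se, p, _ = _joint_gls(bg, np.column_stack([x, w]))
        return GwasRecord(snp_id, b[0], se[0], p[0], b[1], se[1], p[1], counts)
    b, se, p, _ = _joint_gls(bg, x[:, None])
    return GwasRecord(snp_id, b[0], se[0], p[0], np.nan, np.nan, np.nan, counts,
                      note="dominance inestimable: not all three genotypes present")


test_snp.__test__ = False  # keep pytest from collecting the public name


@dataclass
class ScanSummary:
    threshold: float
    n_significant: int
    n_tested: int
    fdr: float
    n_positive: int
    n_negative: int


def scan(
    G: GenotypeMatrix,
    bg: BackgroundFit,
    threshold: float = 1e-4,
    exact_refit=None,
) -> tuple[pd.DataFrame, ScanSummary]:
    """Dominance GWAS over every SNP; returns per-SNP records and a summary.

    The summary counts SNPs with a significant dominance effect at the
    threshold, split by the sign of the estimated dominance deviation, and
    carries the expected-false-positive FDR statistic.
    """
    records = []
    ids = G.snps["snp"].tolist()
    x_all = G.genotypes
    if exact_refit is None and not np.any(x_all == MISSING):
        records = _scan_vectorised(x_all, ids, bg)
    else:
        for j in range(G.n_snps):
            rec = test_snp(x_all[:, j], bg, ids[j], exact_refit=exact_refit)
            if rec is not None:
                records.append(rec)
    df = pd.DataFrame([r.__dict__ for r in records])
    tested = df[df["p_dom"].notna()] if len(df) else df
    sig = tested[tested["p_dom"] < threshold] if len(tested) else tested
    a, t = len(sig), len(tested)
    summary = ScanSummary(
        threshold=threshold, n_significant=a, n_tested=t,
        fdr=fdr(threshold, a, t) if a > 0 else np.inf,
        n_positive=int((sig["delta"] > 0).sum()) if a else 0,
        n_negative=int((sig["delta"] < 0).sum()) if a else 0,
    )
    if len(df):
        df["neglog10_p_dom"] = -np.log10(df["p_dom"])
    return df, summary


def _scan_vectorised(x_all, ids, bg: BackgroundFit):
    """Blocked joint GLS over all SNPs at once (complete genotypes only)."""
    n, m = x_all.shape
    p_fixed = bg.Q.shape[1]
    y_perp = bg.y_w - bg.Q @ (bg.Q.T @ bg.y_w)
    Linv_apply = lambda M: linalg.solve_triangular(bg.L, M, lower=True)
    records = []
    for start in range(0, m, 2048):
        sl = slice(start, min(start + 2048, m))
        X = x_all[:, sl].astype(float)
        W = (X == 1).astype(float)
        Sw = Linv_apply(X)
        Ww = Linv_apply(W)
        Sp = Sw - bg.Q @ (bg.Q.T @ Sw)
        Wp = Ww - bg.Q @ (bg.Q.T @ Ww)
        ss = np.einsum("ij,ij->j", Sp, Sp)
        ww = np.einsum("ij,ij->j", Wp, Wp)
        sw = np.einsum("ij,ij->j", Sp, Wp)
        sy = Sp.T @ y_perp
        wy = Wp.T @ y_perp
        det = ss * ww - sw**2
        counts = np.stack([(X == g).sum(axis=0) for g in (0, 1, 2)])
        three = (counts > 0).all(axis=0)
        yy = float(y_perp @ y_perp)
        for jj in range(X.shape[1]):
            j = start + jj
            cts = (int(counts[0, jj]), int(counts[1, jj]), int(counts[2, jj]))
            if np.ptp(X[:, jj]) == 0:
                continue
            if three[jj] and det[jj] > 1e-12 * max(ss[jj] * ww[jj], 1e-300):
                a_hat = (ww[jj] * sy[j - start] - sw[jj] * wy[j - start]) / det[jj]
                d_hat = (ss[jj] * wy[j - start] - sw[jj] * sy[j - start]) / det[jj]
                df = n - p_fixed - 2
                rss = yy - a_hat * sy[j - start] - d_hat * wy[j - start]
                s2 = max(rss, 0.0) / df
                var_a = s2 * ww[jj] / det[jj]
                var_d = s2 * ss[jj] / det[jj]
                pa = 2 * stats.t.sf(abs(a_hat) / np.sqrt(var_a), df)
                pd_ = 2 * stats.t.sf(abs(d_hat) / np.sqrt(var_d), df)
                records.append(GwasRecord(ids[j], a_hat, float(np.sqrt(var_a)), float(pa),
                                          d_hat, float(np.sqrt(var_d)), float(pd_), cts))
            else:
                a_hat = sy[j - start] / ss[jj]
                df = n - p_fixed - 1
                rss = yy - a_hat * sy[j - start]
                s2 = max(rss, 0.0) / df
                var_a = s2 / ss[jj]
                pa = 2 * stats.t.sf(abs(a_hat) / np.sqrt(var_a), df)
                records.append(GwasRecord(ids[j], a_hat, float(np.sqrt(var_a)), float(pa),
                                          np.nan, np.nan, np.nan, cts,
                                          note="dominance inestimable: not all three genotypes present"))
    return records


def fdr(P: float, A: int, T: int) -> float:
    """Expected-false-positive FDR: P(1 - A/T) / [(A/T)(1 - P)].

    ``P`` is the significance threshold, ``A`` the number of effects declared
    significant, ``T`` the number tested.  The estimate can exceed 1, which
    reads as "everything declared significant is a false positive".
    """
    if not 0.0 < P < 1.0:
        raise ValueError("P must lie in (0, 1)")
    if T <= 0 or A < 0 or A > T:
        raise ValueError("need 0 <= A <= T with T > 0")
    if A == 0:
        warnings.warn("no significant effects: FDR undefined, returning inf")
        return np.inf
    frac = A / T
    return (P * (1.0 - frac)) / (frac * (1.0 - P))


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (labelled extra, not the default)."""
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p)
    ranked = p[order] * p.size / (np.arange(p.size) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1].clip(max=1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out
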