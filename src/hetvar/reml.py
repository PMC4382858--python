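"""Variance-component estimation and BLUP for relationship-matrix models.

Fits y = Xb + sum_k u_k + e with u_k ~ N(0, K_k sigma_k^2) and
e ~ N(0, I sigma_e^2) by average-information REML: Newton steps on the
restricted log-likelihood using the AI matrix, with step-halving and an
expectation-maximisation-style fallback step when an AI step fails to
improve the likelihood.  Components driven negative are pinned to zero and
the system re-solved, so boundary estimates are reported as exact zeros.

The restricted log-likelihood used throughout (constants dropped) is

    lR = -1/2 [ log|V| + log|X'V^{-1}X| + y'Py ],
    P  = V^{-1} - V^{-1}X (X'V^{-1}X)^{-1} X'V^{-1}.

All linear algebra is dense; problem sizes of a few thousand animals fit
comfortably.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats


@dataclass
class ModelSpec:
    """Response, fixed design and relationship-matrix random terms.

    ``X`` must include the intercept column.  ``het_index`` marks the column
    of ``X`` holding the (centred) mean-heterozygosity covariate, if any, so
    its regression coefficient can be reported with a t-value.
    """

    y: np.ndarray
    X: np.ndarray
    random_terms: list  # [(label, K ndarray n x n), ...]
    fixed_names: list = field(default_factory=list)
    het_index: int | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n = self.y.size
        if self.X.shape[0] != n:
            raise ValueError("fixed design rows do not match response length")
        if n < 2:
            raise ValueError("need at least 2 observations")
        for label, K in self.random_terms:
            K = np.asarray(K, dtype=float)
            if K.shape != (n, n):
                raise ValueError(f"random term {label!r} is not {n}x{n}")
        if not self.fixed_names:
            self.fixed_names = [f"b{j}" for j in range(self.X.shape[1])]
        # drop exactly collinear fixed columns, keeping the first of each group
        q, r = np.linalg.qr(self.X)
        keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
        if not keep.all():
            dropped = [self.fixed_names[j] for j in np.flatnonzero(~keep)]
            if self.het_index is not None and not keep[self.het_index]:
                raise ValueError("heterozygosity covariate is confounded with other fixed effects")
            if self.het_index is not None:
                self.het_index -= int((~keep[: self.het_index]).sum())
            self.X = self.X[:, keep]
            self.fixed_names = [nm for nm, k in zip(self.fixed_names, keep) if k]
            self.dropped_fixed = dropped
        else:
            self.dropped_fixed = []


def build_spec(
    y,
    covariates=None,
    factors=None,
    het=None,
    random_terms=(),
    center_het: bool = True,
) -> ModelSpec:
    """Assemble a ModelSpec from raw columns.

    ``covariates`` is a mapping name -> real vector, ``factors`` a mapping
    name -> label vector (dummy-coded dropping the first level), ``het`` the
    per-animal mean heterozygosity (centred by default so the intercept keeps
    its interpretation; centring leaves the regression slope untouched).
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    cols = [np.ones(n)]
    names = ["intercept"]
    for name, v in (factors or {}).items():
        v = np.asarray(v)
        levels = np.unique(v)
        for lev in levels[1:]:
            cols.append((v == lev).astype(float))
            names.append(f"{name}[{lev}]")
    for name, v in (covariates or {}).items():
        cols.append(np.asarray(v, dtype=float))
        names.append(name)
    het_index = None
    if het is not None:
        h = np.asarray(het, dtype=float)
        if center_het:
            h = h - h.mean()
        het_index = len(cols)
        cols.append(h)
        names.append("het")
    terms = [(label, np.asarray(K.values if hasattr(K, "values") else K, dtype=float))
             for label, K in random_terms]
    return ModelSpec(y, np.column_stack(cols), terms, names, het_index)


@dataclass
class RemlResult:
    """Fitted variance components and everything needed to reuse the fit."""

    sigma2: dict          # label -> variance (includes "residual")
    se: dict              # label -> asymptotic SE from the AI matrix
    loglik: float         # restricted log-likelihood (constants dropped)
    converged: bool
    n_iter: int
    beta: np.ndarray      # GLS fixed-effect estimates
    beta_se: np.ndarray
    fixed_names: list
    het_beta: float | None
    het_se: float | None
    het_t: float | None
    spec: ModelSpec
    Py: np.ndarray        # P y at the optimum (BLUP workhorse)
    chol_V: np.ndarray    # lower Cholesky factor of V at the optimum
    trajectory: list = field(default_factory=list)

    @property
    def vp(self) -> float:
        return float(sum(self.sigma2.values()))

    def ratio(self, label: str) -> float:
        return self.sigma2[label] / self.vp


class RemlError(RuntimeError):
    def __init__(self, msg, trajectory=None):
        super().__init__(msg)
        self.trajectory = trajectory or []


def _reml_quantities(y, X, Ks, theta):
    """Log-likelihood, Py, and per-term P K_k P y / traces for parameters theta."""
    n = y.size
    V = theta[-1] * np.eye(n)
    for K, th in zip(Ks, theta[:-1]):
        V += th * K
    try:
        L = linalg.cholesky(V, lower=True)
    except linalg.LinAlgError:
        return None
    Vinv = linalg.cho_solve((L, True), np.eye(n))
    VinvX = Vinv @ X
    XtVinvX = X.T @ VinvX
    sign, logdet_xtvx = np.linalg.slogdet(XtVinvX)
    if sign <= 0:
        return None
    C = np.linalg.inv(XtVinvX)
    logdet_v = 2.0 * np.log(np.diag(L)).sum()

    def project(t):
        return Vinv @ t - VinvX @ (C @ (VinvX.T @ t))

    Py = project(y)
    ll = -0.5 * (logdet_v + logdet_xtvx + float(y @ Py))
    all_K = list(Ks) + [np.eye(n)]
    t_vecs = [K @ Py for K in all_K]
    Pt = [project(t) for t in t_vecs]
    traces = []
    for K in all_K:
        tr = float(np.sum(Vinv * K)) - float(np.trace(C @ (VinvX.T @ (K @ VinvX))))
        traces.append(tr)
    score = np.array([-0.5 * (traces[k] - float(Py @ t_vecs[k])) for k in range(len(all_K))])
    AI = 0.5 * np.array([[float(t_vecs[k] @ Pt[l]) for l in range(len(all_K))]
                         for k in range(len(all_K))])
    return {"ll": ll, "Py": Py, "score": score, "AI": AI, "L": L, "C": C,
            "VinvX": VinvX, "Vinv": Vinv}


def reml_fit(
    spec: ModelSpec,
    max_iter: int = 200,
    ll_tol: float = 1e-6,
    par_tol: float = 1e-4,
    verbose: bool = False,
) -> RemlResult:
    """Average-information REML with EM fallback and zero-boundary handling."""
    y, X = spec.y, spec.X
    labels = [label for label, _ in spec.random_terms] + ["residual"]
    Ks = [K for _, K in spec.random_terms]
    n = y.size

    active = list(range(len(Ks)))  # genetic terms currently in the model
    while True:
        res = _fit_active(y, X, [Ks[i] for i in active], max_iter, ll_tol, par_tol)
        theta = res["theta"]
        # pin terms stuck at the zero boundary and re-solve without them
        floor = 1e-5 * (y.var(ddof=1) if n > 1 else 1.0)
        stuck = [j for j in range(len(active)) if theta[j] < floor]
        if not stuck:
            break
        active = [i for j, i in enumerate(active) if j not in stuck]

    sigma2 = {lab: 0.0 for lab in labels}
    se = {lab: 0.0 for lab in labels}
    for j, i in enumerate(active):
        sigma2[labels[i]] = float(res["theta"][j])
    sigma2["residual"] = float(res["theta"][-1])
    ai_se = res["se"]
    for j, i in enumerate(active):
        se[labels[i]] = float(ai_se[j])
    se["residual"] = float(ai_se[-1])

    q = res["quant"]
    C = q["C"]
    beta = C @ (q["VinvX"].T @ y)
    beta_se = np.sqrt(np.diag(C))
    het_beta = het_se = het_t = None
    if spec.het_index is not None:
        het_beta = float(beta[spec.het_index])
        het_se = float(beta_se[spec.het_index])
        het_t = het_beta / het_se if het_se > 0 else np.nan
    return RemlResult(
        sigma2=sigma2, se=se, loglik=res["ll"], converged=res["converged"],
        n_iter=res["n_iter"], beta=beta, beta_se=beta_se,
        fixed_names=spec.fixed_names, het_beta=het_beta, het_se=het_se, het_t=het_t,
        spec=spec, Py=q["Py"], chol_V=q["L"], trajectory=res["trajectory"],
    )


def _fit_active(y, X, Ks, max_iter, ll_tol, par_tol):
    n = y.size
    n_par = len(Ks) + 1
    # start from an equal split of the OLS residual variance
    b0, *_ = np.linalg.lstsq(X, y, rcond=None)
    v0 = float(np.var(y - X @ b0, ddof=X.shape[1])) or 1.0
    theta = np.full(n_par, v0 / n_par)
    floor = 1e-8 * v0
    trajectory = []
    quant = _reml_quantities(y, X, Ks, theta)
    if quant is None:
        raise RemlError("initial variance matrix not positive definite", trajectory)
    converged = False
    stall = 0  # consecutive iterations with negligible likelihood movement
    at_floor = np.zeros(n_par, dtype=int)
    it = 0
    for it in range(1, max_iter + 1):
        ll_old, theta_old = quant["ll"], theta.copy()
        trajectory.append((it, ll_old, theta.copy()))
        # AI (Newton) step with step-halving
        try:
            delta = np.linalg.solve(quant["AI"], quant["score"])
        except np.linalg.LinAlgError:
            delta = None
        stepped = False
        if delta is not None:
            step = 1.0
            for _ in range(8):
                cand = np.maximum(theta + step * delta, floor)
                q_new = _reml_quantities(y, X, Ks, cand)
                if q_new is not None and q_new["ll"] >= ll_old - 1e-10:
                    theta, quant, stepped = cand, q_new, True
                    break
                step *= 0.5
        if not stepped:
            # EM-flavoured scaled-gradient step (theta + 2 theta^2 score / n),
            # halved until uphill; if no step improves we are at the optimum
            step = 1.0
            for _ in range(8):
                cand = np.maximum(theta + step * 2.0 * theta**2 * quant["score"] / n, floor)
                q_new = _reml_quantities(y, X, Ks, cand)
                if q_new is not None and q_new["ll"] >= ll_old - 1e-10:
                    theta, quant, stepped = cand, q_new, True
                    break
                step *= 0.5
            if not stepped:
                converged = True
                break
        # measure change relative to a phenotypic-variance scale so that
        # components rattling at the zero floor still register as converged
        rel_change = np.max(np.abs(theta - theta_old) / np.maximum(theta_old, 1e-3 * v0))
        dll = abs(quant["ll"] - ll_old)
        stall = stall + 1 if dll < ll_tol else 0
        # genetic components crawling along the zero boundary stall EM badly;
        # hand them back early so the caller pins them at 0 and re-solves
        small = theta[:-1] < 1e-5 * v0
        at_floor[:-1] = np.where(small, at_floor[:-1] + 1, 0)
        if (dll < ll_tol and rel_change < par_tol) or stall >= 3 or at_floor.max() >= 4:
            # a persistent likelihood stall means a flat ridge (near-collinear
            # kernels): any point on it is a REML optimum
            converged = True
            break
    if not converged and it >= max_iter:
        raise RemlError(f"REML did not converge in {max_iter} iterations", trajectory)
    try:
        se = np.sqrt(np.diag(np.linalg.inv(quant["AI"])))
    except np.linalg.LinAlgError:
        se = np.full(n_par, np.nan)
    return {"theta": theta, "ll": quant["ll"], "converged": True, "n_iter": it,
            "quant": quant, "se": se, "trajectory": trajectory}


def lrt_dominance(fit_am: RemlResult, fit_adm: RemlResult) -> tuple[float, float]:
    """Likelihood-ratio test for the dominance variance component.

    Twice the restricted log-likelihood difference between the
    additive-plus-dominance and additive models, clipped at zero, referred to
    chi-squared with 1 degree of freedom.
    """
    if fit_am.spec.y.size != fit_adm.spec.y.size or not np.allclose(
        fit_am.spec.y, fit_adm.spec.y
    ):
        raise ValueError("fits are not on the same data")
    stat = max(0.0, 2.0 * (fit_adm.loglik - fit_am.loglik))
    return stat, float(stats.chi2.sf(stat, df=1))


def blup_solve(fit: RemlResult, cross: dict | None = None) -> dict:
    """BLUP solutions u_k = sigma_k^2 K_k P y for every random term.

    ``cross`` maps a term label to a rectangular relationship block
    K[target, fitted] to obtain predictions for animals outside the fitted
    set (e.g. validation animals carried in the genomic matrices but with
    masked phenotypes).  Returns label -> prediction vector; ``"total"`` is
    the sum over genetic terms (g_hat = a_hat + d_hat for an ADM fit).
    """
    out = {}
    Py = fit.Py
    for label, K in fit.spec.random_terms:
        block = cross[label] if cross is not None else K
        out[label] = fit.sigma2[label] * (np.asarray(block) @ Py)
    if out:
        out["total"] = np.sum(list(out.values()), axis=0)
    return out
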