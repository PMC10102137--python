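"""Manual three-step covariate analysis of latent trajectory classes.

Step 1 is the unconditional growth mixture (module ``trajectories``);
step 2 assigns each person to the modal class and quantifies the
classification error; step 3 regresses the latent class on covariates by
maximum likelihood with the class-measurement error fixed at the step-2
probabilities (Vermunt-style ML correction), together with a class-specific
Bernoulli model for the distal outcome and a two-stage regression of the
growth factors on the covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ThreeStepResult",
    "step2_classify",
    "step3_fit",
    "weighted_multinomial_logit",
    "odds_ratios",
    "class_descriptives",
]

_Q_FLOOR = 1e-4


@dataclass
class ThreeStepResult:
    error_matrix: np.ndarray          # Q[s, k] = P(W = s | C = k)
    fixed_logits: np.ndarray          # log(Q[s,k] / Q[ref,k]), floored
    coefficients: pd.DataFrame        # per non-reference class x covariate
    cov_params: np.ndarray
    distal: pd.DataFrame | None       # per-class outcome probability + SE
    growth_regression: pd.DataFrame | None
    reference_class: int
    loglik: float
    n_used: int
    converged: bool


def step2_classify(posterior: np.ndarray):
    """Modal assignment and the classification-error matrix.

    W_i = argmax_k p_ik (ties to the lowest index); Q[s, k] =
    sum_{i: W_i = s} p_ik / sum_i p_ik, so columns give P(W = s | C = k)
    and sum to one.
    """
    p = np.asarray(posterior, dtype=float)
    if p.ndim != 2 or not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("posterior rows must sum to 1")
    n, K = p.shape
    W = p.argmax(axis=1)
    Q = np.zeros((K, K))
    for s in range(K):
        Q[s] = p[W == s].sum(axis=0)
    col = p.sum(axis=0)
    Q = Q / np.where(col > 0, col, 1.0)
    if np.any(np.bincount(W, minlength=K) == 0):
        warnings.warn("a class is empty after modal assignment", stacklevel=2)
    return W, Q


def _softmax_probs(X, beta, ref):
    """Class probabilities under the multinomial logit; beta has K-1 rows."""
    n = len(X)
    K = beta.shape[0] + 1
    eta = np.zeros((n, K))
    free = [k for k in range(K) if k != ref]
    for r, k in enumerate(free):
        eta[:, k] = X @ beta[r]
    eta -= eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    return p / p.sum(axis=1, keepdims=True)


def weighted_multinomial_logit(X: np.ndarray, weights: np.ndarray, ref: int,
                               beta0: np.ndarray | None = None,
                               max_iter: int = 100, tol: float = 1e-12):
    """Newton-Raphson ML for a multinomial logit with soft (weighted) labels.

    ``weights`` is (n, K) with rows summing to 1 (responsibilities or
    one-hot labels); the reference class has its coefficient row fixed at
    zero.  Returns (beta (K-1, p), loglik, converged).
    """
    X = np.asarray(X, dtype=float)
    Wm = np.asarray(weights, dtype=float)
    n, p = X.shape
    K = Wm.shape[1]
    free = [k for k in range(K) if k != ref]
    nf = len(free)
    beta = np.zeros((nf, p)) if beta0 is None else beta0.copy()
    ll_prev = -np.inf
    for _ in range(max_iter):
        P = _softmax_probs(X, beta, ref)
        ll = float((Wm * np.log(np.maximum(P, 1e-300))).sum())
        grad = np.concatenate([X.T @ (Wm[:, k] - P[:, k]) for k in free])
        H = np.zeros((nf * p, nf * p))
        for a, ka in enumerate(free):
            for b, kb in enumerate(free):
                w = P[:, ka] * ((ka == kb) - P[:, kb])
                H[a * p:(a + 1) * p, b * p:(b + 1) * p] = -(X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(nf * p), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        new = beta - step.reshape(nf, p)
        # step-halving on the observed objective
        for _ in range(30):
            Pn = _softmax_probs(X, new, ref)
            ll_new = float((Wm * np.log(np.maximum(Pn, 1e-300))).sum())
            if ll_new >= ll - 1e-10:
                break
            new = (new + beta) / 2.0
        beta = new
        if abs(ll_new - ll_prev) < tol * (abs(ll_new) + 1.0):
            return beta, ll_new, True
        ll_prev = ll_new
    return beta, ll_prev, False


def _marginal_loglik(params, X, W, D, Qlog, ref, K, p):
    """Marginal log-likelihood of (W, distal) given covariates; params =
    flattened beta then distal logits."""
    nf = K - 1
    beta = params[: nf * p].reshape(nf, p)
    P = _softmax_probs(X, beta, ref)
    lik = P * np.exp(Qlog[W, :])  # (n, K): P(C=k|x) * Q[W_i, k]
    if D is not None:
        rho = 1.0 / (1.0 + np.exp(-params[nf * p:]))
        obs = ~np.isnan(D)
        bern = np.ones_like(lik)
        bern[obs] = np.where(D[obs, None] == 1, rho[None, :], 1 - rho[None, :])
        lik = lik * bern
    return float(np.log(np.maximum(lik.sum(axis=1), 1e-300)).sum())


def _fd_hessian(f, x, h=1e-5):
    n = len(x)
    H = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            xi = x.copy(); xi[i] += h; xi[j] += h; fpp = f(xi)
            xi = x.copy(); xi[i] += h; xi[j] -= h; fpm = f(xi)
            xi = x.copy(); xi[i] -= h; xi[j] += h; fmp = f(xi)
            xi = x.copy(); xi[i] -= h; xi[j] -= h; fmm = f(xi)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
    return H


def step3_fit(assignments: np.ndarray, Q: np.ndarray, covariates: pd.DataFrame,
              distal_outcome: np.ndarray | None = None,
              growth_estimates: np.ndarray | None = None,
              reference_class: int | None = None,
              max_iter: int = 500) -> ThreeStepResult:
    """ML three-step regression of latent class on covariates.

    The latent class C is measured by the modal assignment W through the
    fixed (epsilon-floored) step-2 error probabilities Q; estimation is EM
    with a weighted multinomial-logit Newton M-step.  Persons with any
    missing covariate are excluded.  The distal outcome, when given, is
    modelled as a class-specific Bernoulli inside the same likelihood.
    ``growth_estimates`` (n, 2) adds a two-stage OLS regression of the
    growth factors on the covariates.
    """
    W = np.asarray(assignments, dtype=int)
    Q = np.asarray(Q, dtype=float)
    K = Q.shape[0]
    X_df = covariates.copy()
    keep = ~X_df.isna().any(axis=1).to_numpy()
    if distal_outcome is not None:
        distal_outcome = np.asarray(distal_outcome, dtype=float)
    X = np.column_stack([np.ones(int(keep.sum())),
                         X_df.loc[keep].to_numpy(dtype=float)])
    names = ["intercept"] + list(X_df.columns)
    Wk = W[keep]
    Dk = distal_outcome[keep] if distal_outcome is not None else None
    n, p = X.shape
    if reference_class is None:
        reference_class = int(np.bincount(Wk, minlength=K).argmax())
    ref = reference_class

    # the likelihood uses Q exactly (zero cells are harmless there); the
    # epsilon floor only protects the reported measurement logits from -inf
    Qlog = np.log(np.maximum(Q, 1e-300))
    Qrep = np.log(np.maximum(Q, _Q_FLOOR))
    fixed_logits = Qrep - Qrep[ref][None, :]

    nf = K - 1
    beta = np.zeros((nf, p))
    rho = np.full(K, 0.5)
    ll_prev = -np.inf
    converged = False
    for _ in range(max_iter):
        P = _softmax_probs(X, beta, ref)
        lik = P * np.exp(Qlog[Wk, :])
        if Dk is not None:
            obs = ~np.isnan(Dk)
            bern = np.ones_like(lik)
            bern[obs] = np.where(Dk[obs, None] == 1, rho[None, :], 1 - rho[None, :])
            lik = lik * bern
        denom = lik.sum(axis=1)
        ll = float(np.log(np.maximum(denom, 1e-300)).sum())
        r = lik / np.maximum(denom[:, None], 1e-300)
        if abs(ll - ll_prev) < 1e-10 * (abs(ll) + 1.0):
            converged = True
            break
        ll_prev = ll
        beta, _, _ = weighted_multinomial_logit(X, r, ref, beta0=beta, max_iter=25)
        if Dk is not None:
            obs = ~np.isnan(Dk)
            num = (r[obs] * (Dk[obs, None] == 1)).sum(axis=0)
            den = r[obs].sum(axis=0)
            rho = np.clip(num / np.maximum(den, 1e-12), 1e-6, 1 - 1e-6)

    # observed-information SEs from the marginal likelihood
    rho_logit = np.log(rho / (1 - rho)) if Dk is not None else np.array([])
    params = np.concatenate([beta.ravel(), rho_logit])

    def negll(v):
        return -_marginal_loglik(v, X, Wk, Dk, Qlog, ref, K, p)

    H = _fd_hessian(negll, params)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    se_all = np.sqrt(np.maximum(np.diag(cov), 0.0))
    se_beta = se_all[: nf * p].reshape(nf, p)
    if np.any(se_beta > 10):
        warnings.warn("very large standard errors: possible separation in "
                      "the class-membership logit", stacklevel=2)

    free = [k for k in range(K) if k != ref]
    rows = []
    for rix, k in enumerate(free):
        for j, nm in enumerate(names):
            coef, se = beta[rix, j], se_beta[rix, j]
            orr, (lo, hi) = odds_ratios(coef, se) if se > 0 else (np.nan, (np.nan, np.nan))
            rows.append({"class": k, "covariate": nm, "coef": coef, "se": se,
                         "or": orr, "or_lo": lo, "or_hi": hi})
    coef_df = pd.DataFrame(rows)

    distal_df = None
    if Dk is not None:
        obs = ~np.isnan(Dk)
        P = _softmax_probs(X, beta, ref)
        lik = P * np.exp(Qlog[Wk, :])
        bern = np.ones_like(lik)
        bern[obs] = np.where(Dk[obs, None] == 1, rho[None, :], 1 - rho[None, :])
        r = lik * bern
        r /= r.sum(axis=1, keepdims=True)
        n_eff = r[obs].sum(axis=0)
        distal_df = pd.DataFrame({
            "class": np.arange(K), "probability": rho,
            "se": np.sqrt(rho * (1 - rho) / np.maximum(n_eff, 1.0)),
            "n_effective": n_eff,
        })

    growth_df = None
    if growth_estimates is not None:
        import statsmodels.api as sm
        g = np.asarray(growth_estimates, dtype=float)[keep]
        rows = []
        for fi, fname in enumerate(["intercept_factor", "slope_factor"][: g.shape[1]]):
            ok = ~np.isnan(g[:, fi])
            fit = sm.OLS(g[ok, fi], X[ok]).fit()
            for j, nm in enumerate(names):
                rows.append({"factor": fname, "covariate": nm,
                             "coef": fit.params[j], "se": fit.bse[j],
                             "p": fit.pvalues[j]})
        growth_df = pd.DataFrame(rows)

    return ThreeStepResult(
        error_matrix=Q, fixed_logits=fixed_logits, coefficients=coef_df,
        cov_params=cov, distal=distal_df, growth_regression=growth_df,
        reference_class=ref, loglik=ll_prev if not converged else ll,
        n_used=n, converged=converged,
    )


def odds_ratios(coef: float, se: float, z: float = 1.96):
    """Odds ratio with Wald 95% CI: exp(coef), exp(coef +- 1.96 se)."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    return float(np.exp(coef)), (float(np.exp(coef - z * se)),
                                 float(np.exp(coef + z * se)))


def class_descriptives(assignments: np.ndarray, covariates: pd.DataFrame,
                       categorical: list[str] | None = None,
                       continuous: list[str] | None = None) -> pd.DataFrame:
    """Per-class stratified table: count (%) for categorical covariates and
    mean (SD) for continuous ones; percentages are within class."""
    W = np.asarray(assignments, dtype=int)
    K = W.max() + 1
    if categorical is None:
        categorical = [c for c in covariates.columns
                       if covariates[c].nunique() <= 10 and c != "age"]
    if continuous is None:
        continuous = [c for c in covariates.columns if c not in categorical]
    rows = []
    for k in range(K):
        sel = covariates[W == k]
        if len(sel) == 0:
            warnings.warn(f"class {k} is empty", stacklevel=2)
        rows.append({"class": k, "variable": "n", "level": "", "value": float(len(sel))})
        for c in continuous:
            rows.append({"class": k, "variable": c, "level": "mean",
                         "value": float(sel[c].mean()) if len(sel) else np.nan})
            rows.append({"class": k, "variable": c, "level": "sd",
                         "value": float(sel[c].std()) if len(sel) else np.nan})
        for c in categorical:
            for lev in sorted(covariates[c].dropna().unique()):
                cnt = int((sel[c] == lev).sum())
                pct = 100.0 * cnt / len(sel) if len(sel) else 0.0
                rows.append({"class": k, "variable": c, "level": str(lev),
                             "value": float(cnt), "percent": pct})
    return pd.DataFrame(rows)
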