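"""Latent growth curve and growth mixture models.

Fits K-component mixtures of latent-basis (or linear/quadratic) growth
curves to a person x wave score matrix by EM under full-information maximum
likelihood over each person's observed waves (valid under MAR).  The
constraint set matches the analysis design: growth-factor covariance matrix
and wave residual variances shared across classes; basis loadings shared
across classes with lambda_1 = 0 and lambda_T = 1; LCGA fixes within-class
growth variances to zero.

Model, class k:
    eta_i ~ N(mu_k, Psi),   y_it = Lambda_t' eta_i + eps_it,
    eps_it ~ N(0, sigma2_t),  P(class k) = pi_k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "GrowthSpec",
    "GmmFit",
    "fit_lgcm",
    "fit_gmm",
    "refit_with_seed",
    "entropy",
    "information_criteria",
    "lmr_tests",
    "coverage_check",
    "select_K",
    "select_growth_shape",
]


@dataclass(frozen=True)
class GrowthSpec:
    """Configuration of one growth(-mixture) fit."""

    shape: str = "latent_basis"  # linear | quadratic | latent_basis
    K: int = 1
    lcga: bool = False  # fix within-class growth variances to zero
    residual: str = "wave"  # "wave": sigma2_t per wave; "single": one value
    n_starts: int = 50
    n_final: int = 10
    seed: int = 0
    max_iter: int = 500
    tol: float = 1e-7

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.shape not in ("linear", "quadratic", "latent_basis"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.n_starts < 1 or self.n_final < 1:
            raise ValueError("multistart counts must be positive")

    @property
    def q(self) -> int:
        return 3 if self.shape == "quadratic" else 2


@dataclass
class GmmFit:
    """One converged growth-mixture solution."""

    spec: GrowthSpec
    pi: np.ndarray
    mu: np.ndarray  # (K, q)
    psi: np.ndarray  # (q, q), zero matrix for LCGA
    sigma2: np.ndarray  # (T,)
    loadings: np.ndarray  # (T, q) full loading matrix
    loglik: float
    n_params: int
    n: int
    posterior: np.ndarray  # (n, K)
    assignments: np.ndarray
    fit: dict
    coverage: np.ndarray
    loglik_history: np.ndarray
    avg_posterior: np.ndarray  # mean posterior prob of each modal class
    class_counts: np.ndarray
    start_seeds: list  # seeds of starts ranked by final loglik (best first)
    converged: bool

    @property
    def basis(self) -> np.ndarray:
        """Time scores lambda_t (second loading column)."""
        return self.loadings[:, 1]


# ---------------------------------------------------------------------------
# internals


def _time_scores(T: int) -> np.ndarray:
    return np.arange(T) / (T - 1)


def _loading_matrix(spec: GrowthSpec, lam: np.ndarray) -> np.ndarray:
    T = len(lam)
    if spec.shape == "quadratic":
        s = _time_scores(T)
        return np.column_stack([np.ones(T), s, s * s])
    return np.column_stack([np.ones(T), lam])


def _patterns(Y: np.ndarray):
    """Group rows by missingness pattern; yields (pattern_bool, row_idx)."""
    obs = ~np.isnan(Y)
    keys = obs @ (1 << np.arange(Y.shape[1], dtype=np.int64))
    order = np.argsort(keys, kind="stable")
    keys_sorted = keys[order]
    bounds = np.flatnonzero(np.r_[True, np.diff(keys_sorted) != 0])
    groups = []
    for b0, b1 in zip(bounds, np.r_[bounds[1:], len(keys)]):
        rows = order[b0:b1]
        groups.append((obs[rows[0]], rows))
    return groups


class _Params:
    __slots__ = ("pi", "mu", "psi", "sigma2", "lam")

    def __init__(self, pi, mu, psi, sigma2, lam):
        self.pi, self.mu, self.psi, self.sigma2, self.lam = pi, mu, psi, sigma2, lam


def _e_step(Y, groups, spec: GrowthSpec, p: _Params):
    """Return loglik, responsibilities and conditional growth-factor moments."""
    n, T = Y.shape
    K, q = spec.K, spec.q
    L = _loading_matrix(spec, p.lam)
    logr = np.full((n, K), -np.inf)
    e_eta = np.zeros((n, K, q))
    cov_eta = np.zeros((n, q, q))
    for obs, rows in groups:
        m = int(obs.sum())
        if m == 0:
            logr[rows] = np.log(np.maximum(p.pi, 1e-300))
            continue
        Lo = L[obs]
        Do = p.sigma2[obs]
        S = Lo @ p.psi @ Lo.T + np.diag(Do)
        # robust inverse via Cholesky
        cf = np.linalg.cholesky(S)
        logdet = 2.0 * np.log(np.diag(cf)).sum()
        Yo = Y[np.ix_(rows, np.flatnonzero(obs))]
        A = p.psi @ Lo.T @ np.linalg.inv(S)  # q x m gain
        C = p.psi - A @ Lo @ p.psi
        cov_eta[rows] = C
        for k in range(K):
            d = Yo - (Lo @ p.mu[k])[None, :]
            z = np.linalg.solve(cf, d.T)
            quad = (z * z).sum(axis=0)
            logr[rows, k] = (
                np.log(max(p.pi[k], 1e-300))
                - 0.5 * (m * np.log(2 * np.pi) + logdet + quad)
            )
            e_eta[rows, k] = p.mu[k] + d @ A.T
    ll_i = logsumexp(logr, axis=1)
    r = np.exp(logr - ll_i[:, None])
    return float(ll_i.sum()), r, e_eta, cov_eta


def _e_step_lcga(Y, groups, spec: GrowthSpec, p: _Params):
    n, T = Y.shape
    K = spec.K
    L = _loading_matrix(spec, p.lam)
    logr = np.full((n, K), -np.inf)
    for obs, rows in groups:
        m = int(obs.sum())
        if m == 0:
            logr[rows] = np.log(np.maximum(p.pi, 1e-300))
            continue
        Lo = L[obs]
        Do = p.sigma2[obs]
        Yo = Y[np.ix_(rows, np.flatnonzero(obs))]
        for k in range(K):
            d = Yo - (Lo @ p.mu[k])[None, :]
            quad = ((d * d) / Do[None, :]).sum(axis=1)
            logr[rows, k] = (
                np.log(max(p.pi[k], 1e-300))
                - 0.5 * (m * np.log(2 * np.pi) + np.log(Do).sum() + quad)
            )
    ll_i = logsumexp(logr, axis=1)
    r = np.exp(logr - ll_i[:, None])
    return float(ll_i.sum()), r


def _m_step(Y, groups, spec: GrowthSpec, p: _Params, r, e_eta, cov_eta):
    n, T = Y.shape
    K, q = spec.K, spec.q
    nk = r.sum(axis=0)
    pi = nk / n
    mu = np.einsum("ik,ikq->kq", r, e_eta) / nk[:, None]
    # shared growth covariance
    dev = e_eta - mu[None, :, :]
    psi = np.einsum("ik,ikp,ikq->pq", r, dev, dev) / n + cov_eta.sum(axis=0) / n
    psi = 0.5 * (psi + psi.T)
    # basis loadings (interior waves only)
    lam = p.lam.copy()
    obs_mask = ~np.isnan(Y)
    if spec.shape == "latent_basis":
        e1 = e_eta[:, :, 1]
        e0 = e_eta[:, :, 0]
        e11 = cov_eta[:, 1, 1][:, None] + e1 * e1
        e01 = cov_eta[:, 0, 1][:, None] + e0 * e1
        for t in range(1, T - 1):
            o = obs_mask[:, t]
            if not o.any():
                continue
            num = (r[o] * (Y[o, t][:, None] * e1[o] - e01[o])).sum()
            den = (r[o] * e11[o]).sum()
            if den > 0:
                lam[t] = num / den
    L = _loading_matrix(spec, lam)
    # residual variances given the new loadings
    sigma2 = p.sigma2.copy()
    for t in range(T):
        o = obs_mask[:, t]
        if not o.any():
            continue
        pred = e_eta[o] @ L[t]  # (n_o, K)
        resid2 = (Y[o, t][:, None] - pred) ** 2
        extra = np.einsum("p,ipq,q->i", L[t], cov_eta[o], L[t])
        sigma2[t] = (r[o] * (resid2 + extra[:, None])).sum() / o.sum() + 0.0
    if spec.residual == "single":
        w = obs_mask.sum(axis=0)
        sigma2[:] = (sigma2 * w).sum() / w.sum()
    sigma2 = np.maximum(sigma2, 1e-6)
    return _Params(pi, mu, psi, sigma2, lam)


def _m_step_lcga(Y, groups, spec: GrowthSpec, p: _Params, r):
    n, T = Y.shape
    K, q = spec.K, spec.q
    nk = r.sum(axis=0)
    pi = nk / n
    obs_mask = ~np.isnan(Y)
    L = _loading_matrix(spec, p.lam)
    mu = p.mu.copy()
    for k in range(K):
        XtX = np.zeros((q, q))
        Xty = np.zeros(q)
        for obs, rows in groups:
            if not obs.any():
                continue
            Lo = L[obs] / p.sigma2[obs][:, None]
            w = r[rows, k].sum()
            XtX += w * (L[obs].T @ Lo)
            Yo = Y[np.ix_(rows, np.flatnonzero(obs))]
            Xty += Lo.T @ (r[rows, k] @ Yo)
        mu[k] = np.linalg.solve(XtX, Xty)
    lam = p.lam.copy()
    if spec.shape == "latent_basis":
        for t in range(1, T - 1):
            o = obs_mask[:, t]
            if not o.any():
                continue
            num = (r[o] * (Y[o, t][:, None] - mu[None, :, 0]) * mu[None, :, 1]).sum()
            den = (r[o] * (mu[None, :, 1] ** 2)).sum()
            if den > 0:
                lam[t] = num / den
    L = _loading_matrix(spec, lam)
    sigma2 = p.sigma2.copy()
    for t in range(T):
        o = obs_mask[:, t]
        if not o.any():
            continue
        resid2 = (Y[o, t][:, None] - (mu @ L[t])[None, :]) ** 2
        sigma2[t] = (r[o] * resid2).sum() / o.sum()
    if spec.residual == "single":
        w = obs_mask.sum(axis=0)
        sigma2[:] = (sigma2 * w).sum() / w.sum()
    sigma2 = np.maximum(sigma2, 1e-6)
    return _Params(pi, mu, np.zeros((q, q)), sigma2, lam)


def _initial_params(Y, spec: GrowthSpec, rng) -> _Params:
    """K-means-style seeding on (first observed level, last-first change),
    randomly perturbed; one draw per multistart replicate."""
    n, T = Y.shape
    obs = ~np.isnan(Y)
    first = np.array([Y[i, obs[i]][0] if obs[i].any() else np.nan for i in range(n)])
    last = np.array([Y[i, obs[i]][-1] if obs[i].any() else np.nan for i in range(n)])
    change = np.where(obs.sum(axis=1) > 1, last - first, 0.0)
    level = np.where(np.isnan(first), np.nanmean(first), first)
    feats = np.column_stack([level, change])
    sd = feats.std(axis=0)
    sd[sd == 0] = 1.0
    K, q = spec.K, spec.q
    centers = feats[rng.choice(n, size=K, replace=False)]
    centers = centers + rng.normal(0, 1.0, size=centers.shape) * sd
    mu = np.zeros((K, q))
    mu[:, 0] = centers[:, 0]
    mu[:, 1] = centers[:, 1]
    pi = rng.dirichlet(np.full(K, 5.0))
    var_level = max(np.nanvar(level), 1e-2)
    psi = np.diag([var_level / 2, max(np.nanvar(change) / 2, 1e-2), *([1e-2] * (q - 2))])
    sigma2 = np.full(T, max(np.nanvar(Y) / 4, 1e-2))
    lam = _time_scores(T).copy()
    if spec.lcga:
        psi = np.zeros((q, q))
    return _Params(pi, mu, psi, sigma2, lam)


def _run_em(Y, groups, spec: GrowthSpec, p: _Params, max_iter: int, tol: float):
    history = []
    ll_prev = -np.inf
    converged = False
    for it in range(max_iter):
        if spec.lcga:
            ll, r = _e_step_lcga(Y, groups, spec, p)
        else:
            ll, r, e_eta, cov_eta = _e_step(Y, groups, spec, p)
        history.append(ll)
        if np.isfinite(ll_prev) and abs(ll - ll_prev) < tol * (abs(ll_prev) + 1.0):
            converged = True
            break
        ll_prev = ll
        if spec.lcga:
            p = _m_step_lcga(Y, groups, spec, p, r)
        else:
            p = _m_step(Y, groups, spec, p, r, e_eta, cov_eta)
    if spec.lcga:
        ll, r = _e_step_lcga(Y, groups, spec, p)
    else:
        ll, r, _, _ = _e_step(Y, groups, spec, p)
    history.append(ll)
    return p, ll, r, np.asarray(history), converged


def n_parameters(spec: GrowthSpec, T: int) -> int:
    q = spec.q
    p = spec.K * q + (spec.K - 1)
    if not spec.lcga:
        p += q * (q + 1) // 2
    p += T if spec.residual == "wave" else 1
    if spec.shape == "latent_basis":
        p += T - 2
    return p


def _validate_scores(Y: np.ndarray) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("scores must be persons x waves")
    keep = ~np.all(np.isnan(Y), axis=1)
    Y = Y[keep]
    n_waves_obs = (~np.isnan(Y)).any(axis=0).sum()
    per_person = (~np.isnan(Y)).sum(axis=1)
    if n_waves_obs < 2 or per_person.max() < 2:
        raise ValueError("growth factors unidentified: fewer than two observed waves")
    return Y


def fit_gmm(scores: np.ndarray, spec: GrowthSpec) -> GmmFit:
    """Fit the K-class growth mixture by EM with multistart.

    ``scores`` is persons x waves with NaN for missing; persons with no
    observation are dropped.  Aborts if the pairwise covariance coverage
    falls below 0.10 for any wave pair observed at all.
    """
    Y = _validate_scores(scores)
    n, T = Y.shape
    cov_mat, cov_ok = coverage_check(Y)
    if not cov_ok:
        raise ValueError("covariance coverage below the 0.10 minimum threshold")
    groups = _patterns(Y)
    ss = np.random.SeedSequence([spec.seed, 29])
    start_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(spec.n_starts)]

    short = []
    for sd in start_seeds:
        rng = np.random.default_rng(sd)
        p0 = _initial_params(Y, spec, rng)
        try:
            p1, ll, _, _, _ = _run_em(Y, groups, spec, p0, max_iter=30, tol=spec.tol)
        except np.linalg.LinAlgError:
            ll, p1 = -np.inf, None
        short.append((ll, sd))
    short.sort(key=lambda x: -x[0])

    best = None
    ranked = []
    for ll0, sd in short[: spec.n_final]:
        if not np.isfinite(ll0):
            continue
        rng = np.random.default_rng(sd)
        p0 = _initial_params(Y, spec, rng)
        try:
            p1, ll, r, hist, conv = _run_em(Y, groups, spec, p0, spec.max_iter, spec.tol)
        except np.linalg.LinAlgError:
            continue
        if np.min(p1.pi) < 1e-6:  # degenerate class: discard this start
            continue
        ranked.append((ll, sd))
        if best is None or ll > best[0]:
            best = (ll, sd, p1, r, hist, conv)
    if best is None:
        raise RuntimeError("no multistart replicate converged to a proper solution")
    ll, sd_best, p1, r, hist, conv = best
    ranked.sort(key=lambda x: -x[0])

    assign = r.argmax(axis=1)
    counts = np.bincount(assign, minlength=spec.K)
    avg_post = np.array([
        r[assign == k, k].mean() if counts[k] else np.nan for k in range(spec.K)
    ])
    p_count = n_parameters(spec, T)
    aic, bic, ssabic = information_criteria(ll, p_count, n)
    fitstats = {"aic": aic, "bic": bic, "ssabic": ssabic,
                "entropy": entropy(r) if spec.K > 1 else np.nan}
    return GmmFit(
        spec=spec, pi=p1.pi, mu=p1.mu, psi=p1.psi, sigma2=p1.sigma2,
        loadings=_loading_matrix(spec, p1.lam), loglik=ll, n_params=p_count,
        n=n, posterior=r, assignments=assign, fit=fitstats, coverage=cov_mat,
        loglik_history=hist, avg_posterior=avg_post, class_counts=counts,
        start_seeds=[s for _, s in ranked], converged=conv,
    )


def refit_with_seed(scores: np.ndarray, spec: GrowthSpec, start_seed: int) -> GmmFit:
    """Re-run a single EM from the start generated by ``start_seed`` (the
    replication check on the stored seeds of the best solutions)."""
    one = replace(spec, n_starts=1, n_final=1)
    Y = _validate_scores(scores)
    groups = _patterns(Y)
    rng = np.random.default_rng(start_seed)
    p0 = _initial_params(Y, one, rng)
    p1, ll, r, hist, conv = _run_em(Y, groups, one, p0, one.max_iter, one.tol)
    assign = r.argmax(axis=1)
    counts = np.bincount(assign, minlength=one.K)
    p_count = n_parameters(one, Y.shape[1])
    aic, bic, ssabic = information_criteria(ll, p_count, len(Y))
    return GmmFit(
        spec=one, pi=p1.pi, mu=p1.mu, psi=p1.psi, sigma2=p1.sigma2,
        loadings=_loading_matrix(one, p1.lam), loglik=ll, n_params=p_count,
        n=len(Y), posterior=r, assignments=assign,
        fit={"aic": aic, "bic": bic, "ssabic": ssabic,
             "entropy": entropy(r) if one.K > 1 else np.nan},
        coverage=coverage_check(Y)[0], loglik_history=hist,
        avg_posterior=np.array([r[assign == k, k].mean() if counts[k] else np.nan
                                for k in range(one.K)]),
        class_counts=counts, start_seeds=[start_seed], converged=conv,
    )


def fit_lgcm(scores: np.ndarray, shape: str = "latent_basis",
             seed: int = 0, **kwargs) -> GmmFit:
    """Single-group latent growth curve model (K = 1)."""
    spec = GrowthSpec(shape=shape, K=1, seed=seed,
                      n_starts=kwargs.pop("n_starts", 10),
                      n_final=kwargs.pop("n_final", 3), **kwargs)
    return fit_gmm(scores, spec)


def select_growth_shape(scores: np.ndarray, seed: int = 0) -> tuple[str, dict]:
    """Compare linear / quadratic / latent-basis single-group curves by BIC."""
    report = {}
    for shape in ("linear", "quadratic", "latent_basis"):
        f = fit_lgcm(scores, shape=shape, seed=seed)
        report[shape] = {"loglik": f.loglik, "aic": f.fit["aic"], "bic": f.fit["bic"]}
    best = min(report, key=lambda s: report[s]["bic"])
    return best, report


# ---------------------------------------------------------------------------
# statistics


def entropy(posterior: np.ndarray) -> float:
    """Relative entropy E_K = 1 - sum(-p log p) / (n log K); 1 = perfect
    separation, 0 = uninformative posteriors."""
    p = np.asarray(posterior, dtype=float)
    if p.ndim != 2 or p.shape[1] < 2:
        raise ValueError("entropy requires a posterior with K >= 2 columns")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("posterior rows must sum to 1")
    n, K = p.shape
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, -p * np.log(p), 0.0)
    return float(1.0 - plogp.sum() / (n * np.log(K)))


def information_criteria(loglik: float, p: int, n: int) -> tuple[float, float, float]:
    """AIC, BIC and sample-size-adjusted BIC (penalty uses (n+2)/24)."""
    if n <= 0:
        raise ValueError("n must be positive")
    aic = -2.0 * loglik + 2.0 * p
    bic = -2.0 * loglik + p * np.log(n)
    ssabic = -2.0 * loglik + p * np.log((n + 2.0) / 24.0)
    return float(aic), float(bic), float(ssabic)


def _simulate_from_fit(fit: GmmFit, masks: np.ndarray, rng) -> np.ndarray:
    n = len(masks)
    K = fit.spec.K
    cls = rng.choice(K, size=n, p=fit.pi / fit.pi.sum())
    if fit.spec.lcga or not np.any(fit.psi):
        eta = fit.mu[cls]
    else:
        eta = fit.mu[cls] + rng.multivariate_normal(
            np.zeros(fit.spec.q), fit.psi, size=n)
    Y = eta @ fit.loadings.T + rng.normal(size=(n, len(fit.sigma2))) * np.sqrt(fit.sigma2)
    Y[~masks] = np.nan
    return Y


def lmr_tests(fit_K: GmmFit, fit_Km1: GmmFit, n: int | None = None,
              method: str = "lmr", n_boot: int = 49,
              seed: int = 0) -> tuple[float, float]:
    """Approximate likelihood-ratio tests of K classes against K-1.

    Returns (VLMR p, adjusted-LMR p) for the statistic 2(LL_K - LL_{K-1}).
    ``method="lmr"`` refers the statistic to the Wolfe-style chi-square
    approximation of the Lo-Mendell-Rubin limiting mixture (df = twice the
    number of extra non-mixing parameters); the adjusted version applies the
    small-sample correction (n - 1 - d - K/2)/n to the statistic, so its
    p-value is never smaller.  ``method="bootstrap"`` resimulates from the
    (K-1)-class fit, refits both models, and reports the empirical p twice.
    """
    if fit_K.spec.K <= 1 or fit_K.spec.K != fit_Km1.spec.K + 1:
        raise ValueError("fits must have K and K-1 classes, K >= 2")
    if n is None:
        n = fit_K.n
    stat = 2.0 * (fit_K.loglik - fit_Km1.loglik)
    stat = max(stat, 0.0)
    d = (fit_K.n_params - fit_Km1.n_params) - 1  # extra non-mixing parameters
    if method == "bootstrap":
        rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))
        # reuse the observed missingness frequencies
        masks = np.ones((n, len(fit_K.sigma2)), dtype=bool)
        count = 0
        spec_null = replace(fit_Km1.spec, n_starts=10, n_final=2)
        spec_alt = replace(fit_K.spec, n_starts=10, n_final=2)
        for b in range(n_boot):
            Yb = _simulate_from_fit(fit_Km1, masks, rng)
            try:
                f0 = fit_gmm(Yb, replace(spec_null, seed=int(rng.integers(2**31))))
                f1 = fit_gmm(Yb, replace(spec_alt, seed=int(rng.integers(2**31))))
            except (RuntimeError, np.linalg.LinAlgError):
                continue
            if 2.0 * (f1.loglik - f0.loglik) >= stat:
                count += 1
        p = (1.0 + count) / (n_boot + 1.0)
        return float(p), float(p)
    df = 2 * d
    p_vlmr = float(stats.chi2.sf(stat, df))
    c = (n - 1 - d - fit_K.spec.K / 2.0) / n
    p_adj = float(stats.chi2.sf(c * stat, df))
    return p_vlmr, max(p_adj, p_vlmr)


def coverage_check(scores: np.ndarray, threshold: float = 0.10):
    """Pairwise covariance coverage: fraction of persons observed on both
    waves of each pair; passes iff the minimum (over pairs with any joint
    design presence) is >= threshold."""
    Y = np.asarray(scores, dtype=float)
    obs = (~np.isnan(Y)).astype(float)
    n = len(Y)
    cov = (obs.T @ obs) / n
    ok = bool(cov.min() >= threshold)
    return cov, ok


def select_K(fits: dict[int, GmmFit], lcga_fits: dict[int, GmmFit] | None = None,
             min_class_frac: float = 0.05, min_avg_posterior: float = 0.70,
             alpha: float = 0.05) -> tuple[int, list[str]]:
    """Choose the class count.

    Walk K upward from the smallest fitted mixture; a step to K is accepted
    when the VLMR and adjusted-LMR tests reject the (K-1)-class model, the
    information criteria all decrease, no class is smaller than
    ``min_class_frac`` of the sample, and each class's average modal
    posterior probability is at least ``min_avg_posterior``.  The last
    accepted K wins; if no step is ever accepted, the smallest admissible K
    is returned with a warning in the log.
    """
    ks = sorted(fits)
    log: list[str] = []
    chosen = None
    for K in ks:
        f = fits[K]
        frac = f.class_counts / f.n
        admissible = frac.min() >= min_class_frac and np.nanmin(f.avg_posterior) >= min_avg_posterior
        if K - 1 in fits:
            p_v, p_a = lmr_tests(f, fits[K - 1])
            rejects = p_v <= alpha and p_a <= alpha
            prev = fits[K - 1].fit
            ic_down = all(f.fit[c] < prev[c] for c in ("aic", "bic", "ssabic"))
        else:
            rejects, ic_down = True, True
            p_v = p_a = np.nan
        log.append(
            f"K={K}: VLMR p={p_v:.4g}, aLMR p={p_a:.4g}, IC decrease={ic_down}, "
            f"min class frac={frac.min():.3f}, min avg posterior={np.nanmin(f.avg_posterior):.3f}"
        )
        if admissible and rejects and ic_down:
            chosen = K
        else:
            log.append(f"K={K} not accepted; stopping upward search")
            break
    if chosen is None:
        admissible_ks = [K for K in ks
                         if fits[K].class_counts.min() / fits[K].n >= min_class_frac]
        pool = admissible_ks or ks
        chosen = min(pool, key=lambda K: fits[K].fit["bic"])
        log.append(f"no K satisfied every rule; best-compromise K={chosen} by BIC")
        warnings.warn("select_K: no class count satisfied all criteria; "
                      "returning best compromise", stacklevel=2)
    if lcga_fits:
        log.append("LCGA (zero within-class growth variance) fits consulted as "
                   "preliminary evidence only")
    return chosen, log
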