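"""Dimensionality assessment of the item battery.

Two-stage factor-analytic workflow on ordinal items: polychoric
correlations (two-stage ML, pairwise-present), exploratory factor analysis
by minres extraction with Geomin oblique rotation on the development
sample, loading-based item retention, and a second-order confirmatory
factor analysis on the validation sample with conventional fit indices
(CFI/TLI/RMSEA with 90% CI).

The CFA discrepancy is normal-theory ML on the polychoric matrix; the
mean-and-variance chi-square adjustment of specialised categorical-data
estimators is deliberately not replicated — the fit-threshold logic
(adequate: CFI/TLI > 0.90, RMSEA < 0.08; good: > 0.95, < 0.06) operates on
the unadjusted statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import ndtri, owens_t

__all__ = [
    "FactorSolution",
    "FitIndices",
    "bvn_cdf",
    "polychoric_pair",
    "polychoric_matrix",
    "efa",
    "efa_fit_indices",
    "select_n_factors",
    "retain_items",
    "cfa_second_order",
    "fit_indices",
]


@dataclass
class FactorSolution:
    loadings: np.ndarray          # items x factors, Geomin-rotated
    factor_correlations: np.ndarray
    eigenvalues: np.ndarray       # of the input correlation matrix (scree)
    communalities: np.ndarray
    uniquenesses: np.ndarray
    n_factors: int
    criterion: float              # Geomin criterion value at the optimum
    converged: bool


@dataclass
class FitIndices:
    chi_square: float
    df: int
    cfi: float
    tli: float
    rmsea: float
    rmsea_ci: tuple[float, float]
    n_used: int
    chi_square_baseline: float = np.nan
    df_baseline: int = 0


# ---------------------------------------------------------------------------
# bivariate normal CDF and polychorics


def bvn_cdf(h, k, rho):
    """P(X <= h, Y <= k) for standard bivariate normal via Owen's T.

    Vectorised over h, k; scalar rho.  Handles infinite limits and
    |rho| -> 1 degeneracies.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    h, k = np.broadcast_arrays(h, k)
    Ph, Pk = stats.norm.cdf(h), stats.norm.cdf(k)
    if rho >= 0.9999:
        return np.minimum(Ph, Pk)
    if rho <= -0.9999:
        return np.maximum(Ph + Pk - 1.0, 0.0)
    denom = np.sqrt(1.0 - rho * rho)
    hs = np.where(np.isfinite(h), h, np.sign(h) * 40.0)
    ks = np.where(np.isfinite(k), k, np.sign(k) * 40.0)
    big = 1e12  # arctan saturates; exact limit of Owen's T slope
    with np.errstate(divide="ignore", invalid="ignore"):
        ah = (ks - rho * hs) / (hs * denom)
        ak = (hs - rho * ks) / (ks * denom)
    ah = np.nan_to_num(np.clip(ah, -big, big))
    ak = np.nan_to_num(np.clip(ak, -big, big))
    # T(0, a) limit: owens_t handles h = 0 for finite a; a is clipped above
    ah = np.where(hs == 0, np.sign(ks) * big, ah)
    ak = np.where(ks == 0, np.sign(hs) * big, ak)
    delta = np.where((hs * ks < 0) | ((hs * ks == 0) & (hs + ks < 0)), 0.5, 0.0)
    out = 0.5 * (Ph + Pk) - owens_t(hs, ah) - owens_t(ks, ak) - delta
    both_zero = (hs == 0) & (ks == 0)
    if np.any(both_zero):
        out = np.where(both_zero, 0.25 + np.arcsin(rho) / (2 * np.pi), out)
    return np.clip(out, 0.0, 1.0)


def _marginal_thresholds(x: np.ndarray, n_cat: int) -> np.ndarray:
    """Probit thresholds from the observed margin, with +-inf ends."""
    obs = x[~np.isnan(x)]
    cum = np.array([(obs < c).mean() for c in range(1, n_cat)])
    cum = np.clip(cum, 1e-6, 1 - 1e-6)
    tau = ndtri(cum)
    return np.concatenate([[-np.inf], np.maximum.accumulate(tau), [np.inf]])


def polychoric_pair(x: np.ndarray, y: np.ndarray, n_cat_x: int | None = None,
                    n_cat_y: int | None = None) -> float:
    """Two-stage ML polychoric correlation of two ordinal variables.

    Thresholds are fixed at the marginal probit quantiles of the pairwise-
    complete sample; rho maximises the bivariate cell likelihood.  Returns
    +-0.999 for degenerate perfectly concordant tables.
    """
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok].astype(int), y[ok].astype(int)
    if len(x) == 0:
        return np.nan
    cx = n_cat_x or int(x.max()) + 1
    cy = n_cat_y or int(y.max()) + 1
    counts = np.zeros((cx, cy))
    np.add.at(counts, (x, y), 1.0)
    taux = _marginal_thresholds(x.astype(float), cx)
    tauy = _marginal_thresholds(y.astype(float), cy)
    H, K = np.meshgrid(taux, tauy, indexing="ij")

    def negll(rho):
        F = bvn_cdf(H, K, rho)
        cell = F[1:, 1:] - F[:-1, 1:] - F[1:, :-1] + F[:-1, :-1]
        return -(counts * np.log(np.maximum(cell, 1e-12))).sum()

    res = optimize.minimize_scalar(negll, bounds=(-0.999, 0.999), method="bounded",
                                   options={"xatol": 1e-6})
    return float(np.clip(res.x, -0.999, 0.999))


def polychoric_matrix(responses: np.ndarray, n_categories=None):
    """Pairwise-present polychoric correlation matrix of an (n, J) ordinal
    table, eigenvalue-repaired to positive semi-definiteness.

    Items with fewer than two observed categories are flagged and excluded;
    returns (matrix over retained items, retained indices, dropped indices).
    """
    X = np.asarray(responses, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need an (n, J) table with J >= 2")
    J = X.shape[1]
    keep, dropped = [], []
    for j in range(J):
        obs = X[~np.isnan(X[:, j]), j]
        if len(np.unique(obs)) >= 2:
            keep.append(j)
        else:
            dropped.append(j)
    if len(keep) < 2:
        raise ValueError("fewer than two items with variation")
    if n_categories is None:
        ncat = [int(np.nanmax(X[:, j])) + 1 for j in keep]
    else:
        ncat = [int(n_categories[j]) for j in keep]
    p = len(keep)
    R = np.eye(p)
    for ai in range(p):
        for bi in range(ai + 1, p):
            r = polychoric_pair(X[:, keep[ai]], X[:, keep[bi]], ncat[ai], ncat[bi])
            R[ai, bi] = R[bi, ai] = 0.0 if np.isnan(r) else r
    # PSD repair: clip negative eigenvalues, renormalise the diagonal
    vals, vecs = np.linalg.eigh(R)
    if vals.min() < 1e-8:
        vals = np.maximum(vals, 1e-8)
        R = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
    return R, np.array(keep), np.array(dropped)


# ---------------------------------------------------------------------------
# EFA: minres extraction + Geomin oblique rotation


def _minres_loadings(R: np.ndarray, psi: np.ndarray, m: int) -> np.ndarray:
    vals, vecs = np.linalg.eigh(R - np.diag(psi))
    vals_m = np.maximum(vals[-m:], 0.0)
    return vecs[:, -m:] * np.sqrt(vals_m)


def _minres_objective(psi, R, m):
    L = _minres_loadings(R, psi, m)
    resid = R - L @ L.T
    np.fill_diagonal(resid, 0.0)
    return (resid ** 2).sum()


def _geomin_criterion(L: np.ndarray, eps: float):
    L2 = L * L + eps
    logs = np.log(L2)
    m = L.shape[1]
    g = np.exp(logs.mean(axis=1))  # geometric mean per item row
    Q = g.sum()
    Gq = (2.0 / m) * (L / L2) * g[:, None]
    return Q, Gq


def _gpa_oblique(A: np.ndarray, eps: float, T0: np.ndarray,
                 max_iter: int = 500, tol: float = 1e-6):
    """Gradient-projection algorithm for oblique rotation (Jennrich 2002)
    minimising the Geomin criterion.  Returns (loadings, Phi, Q, converged)."""
    T = T0.copy()
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = _geomin_criterion(L, eps)
    G = -(L.T @ Gq @ Ti).T
    al = 1.0
    converged = False
    for _ in range(max_iter):
        Gp = G - T * (T * G).sum(axis=0, keepdims=True)
        s = np.sqrt((Gp ** 2).sum())
        if s < tol:
            converged = True
            break
        al *= 2.0
        for _ in range(30):
            X = T - al * Gp
            X /= np.sqrt((X ** 2).sum(axis=0, keepdims=True))
            Ti = np.linalg.inv(X)
            Lt = A @ Ti.T
            ft, Gq = _geomin_criterion(Lt, eps)
            if ft < f - 0.5 * s * s * al:
                break
            al /= 2.0
        T, f, L = X, ft, Lt
        G = -(L.T @ Gq @ Ti).T
    Phi = T.T @ T
    return L, Phi, f, converged


def efa(corr: np.ndarray, n_factors: int, geomin_eps: float = 0.01,
        n_rotation_starts: int = 10, seed: int = 0) -> FactorSolution:
    """Minres factor extraction followed by Geomin oblique rotation.

    The rotation is restarted from several random orthonormal transforms
    (seeded, hence deterministic) and the lowest-criterion solution kept.
    Factors are sign-aligned so each column's dominant loadings are
    positive, and ordered by explained variance.
    """
    R = np.asarray(corr, dtype=float)
    p = R.shape[0]
    if n_factors >= p:
        raise ValueError("n_factors must be below the number of items")
    smc = 1.0 - 1.0 / np.maximum(np.diag(np.linalg.inv(R)), 1.0)
    psi0 = np.clip(1.0 - smc, 0.05, 0.95)
    res = optimize.minimize(
        _minres_objective, psi0, args=(R, n_factors), method="L-BFGS-B",
        bounds=[(0.001, 1.0)] * p, options={"maxiter": 1000, "ftol": 1e-12})
    if not res.success and res.fun > 1e-4:
        raise RuntimeError(f"minres extraction did not converge: {res.message}")
    A = _minres_loadings(R, res.x, n_factors)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 47]))
    best = None
    for s in range(n_rotation_starts):
        if s == 0:
            T0 = np.eye(n_factors)
        else:
            M = rng.normal(size=(n_factors, n_factors))
            Tq, _ = np.linalg.qr(M)
            T0 = Tq
        L, Phi, f, conv = _gpa_oblique(A, geomin_eps, T0)
        if best is None or f < best[2] - 1e-10:
            best = (L, Phi, f, conv)
    L, Phi, f, conv = best
    # sign alignment and ordering by explained variance
    signs = np.sign(np.where(np.abs(L).max(axis=0) > 0,
                             L[np.abs(L).argmax(axis=0), np.arange(n_factors)], 1.0))
    signs[signs == 0] = 1.0
    L = L * signs
    Phi = Phi * np.outer(signs, signs)
    order = np.argsort(-(L ** 2).sum(axis=0), kind="stable")
    L, Phi = L[:, order], Phi[np.ix_(order, order)]

    eigs = np.sort(np.linalg.eigvalsh(R))[::-1]
    comm = np.einsum("pm,mn,pn->p", L, Phi, L)
    return FactorSolution(
        loadings=L, factor_correlations=Phi, eigenvalues=eigs,
        communalities=comm, uniquenesses=1.0 - comm, n_factors=n_factors,
        criterion=float(f), converged=bool(conv),
    )


def efa_fit_indices(corr: np.ndarray, solution: FactorSolution, n: int) -> FitIndices:
    """ML-type discrepancy of the factor solution against the observed
    polychoric matrix, converted to conventional fit indices."""
    R = np.asarray(corr, dtype=float)
    p = R.shape[0]
    m = solution.n_factors
    sigma = solution.loadings @ solution.factor_correlations @ solution.loadings.T
    np.fill_diagonal(sigma, 1.0)
    chi2_m, df_m = _ml_chi2(R, sigma, n)
    df_m = ((p - m) ** 2 - p - m) // 2
    chi2_b, df_b = _baseline_chi2(R, n)
    return fit_indices(chi2_m, max(df_m, 0), chi2_b, df_b, n)


def select_n_factors(corr: np.ndarray, n: int, max_factors: int = 8,
                     cfi_cut: float = 0.95, rmsea_cut: float = 0.06,
                     seed: int = 0) -> tuple[int, list]:
    """Smallest factor count whose EFA reaches good fit (CFI > 0.95 and
    RMSEA < 0.06), reported together with the scree eigenvalues."""
    report = []
    chosen = None
    for m in range(1, max_factors + 1):
        sol = efa(corr, m, seed=seed)
        fi = efa_fit_indices(corr, sol, n)
        report.append((m, fi))
        if fi.df <= 0 or (fi.cfi > cfi_cut and fi.rmsea < rmsea_cut):
            chosen = m
            break
    if chosen is None:
        chosen = max_factors
    return chosen, report


def retain_items(solution: FactorSolution, cross_cut: float = 0.32,
                 floor_cut: float = 0.25):
    """Item retention: drop items with |loading| > 0.32 on two or more
    factors (cross-loaders) and items whose largest |loading| is below
    0.25; everything else is retained.  Returns (retained indices, drop log)."""
    L = np.abs(solution.loadings)
    retained, log = [], []
    for i in range(L.shape[0]):
        if (L[i] > cross_cut).sum() >= 2:
            log.append((i, "cross-loading"))
        elif L[i].max() < floor_cut:
            log.append((i, "no-factor"))
        else:
            retained.append(i)
    return np.array(retained, dtype=int), log


# ---------------------------------------------------------------------------
# second-order CFA


def _ml_chi2(S, sigma, n):
    sign, logdet_s = np.linalg.slogdet(S)
    sign2, logdet_m = np.linalg.slogdet(sigma)
    p = S.shape[0]
    F = logdet_m - logdet_s + np.trace(S @ np.linalg.inv(sigma)) - p
    return float(max(F, 0.0) * (n - 1)), p * (p - 1) // 2


def _baseline_chi2(S, n):
    sign, logdet_s = np.linalg.slogdet(S)
    p = S.shape[0]
    return float(max(-logdet_s, 0.0) * (n - 1)), p * (p - 1) // 2


def cfa_second_order(responses: np.ndarray, first_order_assignment,
                     n_categories=None):
    """Second-order CFA: items load on their assigned first-order factor,
    the first-order factors load on one general factor.

    Fits by ML on the pairwise-present polychoric matrix of ``responses``
    (all latent variances fixed at 1, so only correlations are modelled).
    Returns (FitIndices, item loadings, general-factor loadings,
    heywood_flag).
    """
    assign = np.asarray(first_order_assignment, dtype=int)
    R, keep, dropped = polychoric_matrix(responses, n_categories)
    if len(dropped):
        assign = assign[keep]
    p = R.shape[0]
    factors = np.unique(assign)
    m = len(factors)
    fmap = {f: i for i, f in enumerate(factors)}
    fa = np.array([fmap[f] for f in assign])
    n = int((~np.isnan(np.asarray(responses, dtype=float))).all(axis=1).sum())
    n = max(n, len(responses))

    def implied(params):
        lam = params[:p]
        gam = params[p:] if m > 1 else np.array([])
        if m > 1:
            g = np.tanh(gam)  # keep |gamma| < 1
            Phi = np.outer(g, g)
            np.fill_diagonal(Phi, 1.0)
        else:
            Phi = np.ones((1, 1))
        sigma = np.outer(lam, lam) * Phi[np.ix_(fa, fa)]
        np.fill_diagonal(sigma, 1.0)
        return sigma, lam, (np.tanh(gam) if m > 1 else np.ones(1))

    def obj(params):
        sigma, _, _ = implied(params)
        try:
            sign, logdet = np.linalg.slogdet(sigma)
            if sign <= 0:
                return 1e6
            return float(np.linalg.slogdet(sigma)[1]
                         + np.trace(np.linalg.solve(sigma, R)))
        except np.linalg.LinAlgError:
            return 1e6

    x0 = np.concatenate([np.full(p, 0.6), np.full(m if m > 1 else 0, 0.7)])
    res = optimize.minimize(obj, x0, method="L-BFGS-B",
                            options={"maxiter": 2000, "ftol": 1e-13})
    sigma, lam, gam = implied(res.x)
    heywood = bool(np.any(np.abs(lam) > 1.0))
    chi2_m, _ = _ml_chi2(R, sigma, n)
    n_par = p + (m if m > 1 else 0)
    df_m = p * (p - 1) // 2 - n_par
    chi2_b, df_b = _baseline_chi2(R, n)
    fi = fit_indices(chi2_m, max(df_m, 0), chi2_b, df_b, n)
    return fi, lam, gam, heywood


def fit_indices(chi2_model: float, df_model: int, chi2_baseline: float,
                df_baseline: int, n: int) -> FitIndices:
    """CFI, TLI and RMSEA (point + 90% CI by inverting the noncentral
    chi-square) from model and baseline chi-squares."""
    if df_baseline <= df_model:
        raise ValueError("baseline df must exceed model df")
    dm = max(chi2_model - df_model, 0.0)
    db = max(chi2_baseline - df_baseline, 0.0)
    cfi = 1.0 - dm / max(db, dm, np.finfo(float).tiny) if max(db, dm) > 0 else 1.0
    if df_model > 0 and df_baseline > 0 and chi2_baseline / df_baseline != 1.0:
        tli = ((chi2_baseline / df_baseline) - (chi2_model / df_model)) / \
              ((chi2_baseline / df_baseline) - 1.0)
    else:
        tli = 1.0
    if df_model > 0:
        rmsea = float(np.sqrt(dm / (df_model * (n - 1))))
        lo = _rmsea_ci_bound(chi2_model, df_model, n, 0.95)
        hi = _rmsea_ci_bound(chi2_model, df_model, n, 0.05)
    else:
        rmsea, lo, hi = 0.0, 0.0, 0.0
    return FitIndices(
        chi_square=float(chi2_model), df=int(df_model), cfi=float(min(cfi, 1.0)),
        tli=float(min(tli, 1.0)), rmsea=rmsea, rmsea_ci=(lo, hi), n_used=int(n),
        chi_square_baseline=float(chi2_baseline), df_baseline=int(df_baseline),
    )


def _rmsea_ci_bound(chi2, df, n, q):
    """Noncentrality bound: lambda with P(X2_{df,lambda} <= chi2) = q."""
    if stats.ncx2.cdf(chi2, df, 0.0) < q:
        lam = 0.0
    else:
        hi = max(chi2 * 2, df + 10.0)
        while stats.ncx2.cdf(chi2, df, hi) > q:
            hi *= 2
            if hi > 1e8:
                break
        lam = optimize.brentq(lambda l: stats.ncx2.cdf(chi2, df, l) - q, 0.0, hi)
    return float(np.sqrt(lam / (df * (n - 1))))
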