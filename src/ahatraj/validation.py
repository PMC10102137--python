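"""Sensitivity analyses for the trait metric.

Predictive validity: covariate-adjusted ROC/AUC of the baseline score for
a later binary quality-of-life outcome, using placement values (each case
score referred to the empirical control distribution within its sex
stratum) with a person-level cluster bootstrap CI.  Criterion validity:
linear mixed-effects models of lifestyle behaviours on the 0-100 scores
(random intercept, optional random slope on time), ML-fitted so nested
models are comparable by likelihood ratio test and AIC/BIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["RocResult", "LmmResult", "adjusted_auc", "fit_lmm", "lrt_nested"]


@dataclass
class RocResult:
    auc: float
    ci: tuple[float, float]
    n_cases: int
    n_controls: int
    stratum_variable: str
    n_boot: int


@dataclass
class LmmResult:
    fixed_effects: pd.DataFrame  # coef, ci_lo, ci_hi, z, p per term
    variance_components: dict    # intercept, slope (NaN if absent), residual
    loglik: float
    aic: float
    bic: float
    n_persons: int
    n_observations: int
    random_slope: bool
    converged: bool


def _placement_values(scores, outcome, stratum):
    """Mean placement of each case within its stratum's control scores
    (ties mid-ranked); strata without controls or cases are dropped."""
    placements = []
    dropped = []
    for g in np.unique(stratum):
        sel = stratum == g
        cases = scores[sel & (outcome == 1)]
        controls = scores[sel & (outcome == 0)]
        if len(controls) == 0 or len(cases) == 0:
            dropped.append(g)
            continue
        cs = np.sort(controls)
        below = np.searchsorted(cs, cases, side="left")
        upto = np.searchsorted(cs, cases, side="right")
        placements.append((below + 0.5 * (upto - below)) / len(cs))
    if dropped:
        warnings.warn(f"strata without both classes dropped: {dropped}",
                      stacklevel=3)
    if not placements:
        raise ValueError("no stratum contains both cases and controls")
    return np.concatenate(placements)


def adjusted_auc(score, outcome, stratum=None, cluster=None,
                 n_boot: int = 1000, seed: int = 0,
                 stratum_name: str = "sex") -> RocResult:
    """Covariate-adjusted AUC by placement values with a cluster bootstrap CI.

    Each case's score is ranked against the empirical control distribution
    of its own stratum; the AUC is the mean placement value.  The 95% CI is
    the percentile interval over ``n_boot`` resamples of clusters (persons).
    Rows with missing score or outcome are dropped.
    """
    score = np.asarray(score, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    n0 = len(score)
    if stratum is None:
        stratum = np.zeros(n0)
    stratum = np.asarray(stratum)
    if cluster is None:
        cluster = np.arange(n0)
    cluster = np.asarray(cluster)
    ok = ~(np.isnan(score) | np.isnan(outcome))
    score, outcome, stratum, cluster = score[ok], outcome[ok], stratum[ok], cluster[ok]
    auc = float(_placement_values(score, outcome, stratum).mean())

    rng = np.random.default_rng(np.random.SeedSequence([seed, 59]))
    uniq = np.unique(cluster)
    idx_by_cluster = {c: np.flatnonzero(cluster == c) for c in uniq}
    boots = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_boot):
            pick = rng.choice(uniq, size=len(uniq), replace=True)
            rows = np.concatenate([idx_by_cluster[c] for c in pick])
            try:
                boots.append(_placement_values(score[rows], outcome[rows],
                                               stratum[rows]).mean())
            except ValueError:
                continue
    if len(boots) >= 10:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = np.nan
    return RocResult(auc=auc, ci=(float(lo), float(hi)),
                     n_cases=int((outcome == 1).sum()),
                     n_controls=int((outcome == 0).sum()),
                     stratum_variable=stratum_name, n_boot=len(boots))


def fit_lmm(panel: pd.DataFrame, outcome: str = "aha",
            fixed: list[str] | None = None, time: str = "time",
            group: str = "person_id", random_slope: bool = False) -> LmmResult:
    """Linear mixed model of the score on behaviours and covariates.

    Complete-case ML fit (not REML, so nested random structures are
    LRT-comparable): random intercept per person, plus a random slope on
    the time variable when requested.  Falls back to a diagonal
    random-effects covariance if the unstructured one is not positive
    definite.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if fixed is None:
        fixed = [c for c in panel.columns if c not in (outcome, group)]
    cols = [outcome, group] + [c for c in fixed if c in panel.columns]
    data = panel[cols].dropna().copy()
    # fit on a unit-variance outcome for numerical conditioning, then map
    # estimates back to the reporting scale
    scale_y = float(data[outcome].std()) or 1.0
    data["_y_std"] = data[outcome] / scale_y
    rhs = " + ".join(fixed) if fixed else "1"
    re_formula = f"~{time}" if random_slope else "~1"
    md = smf.mixedlm(f"_y_std ~ {rhs}", data, groups=data[group],
                     re_formula=re_formula)
    def _try_fit(model, **kw):
        # some optimisers stop at points with a singular Hessian; cascade
        last = None
        for method in ("lbfgs", "bfgs", "cg", "powell"):
            try:
                return model.fit(reml=False, method=method, maxiter=500, **kw)
            except (np.linalg.LinAlgError, ValueError) as e:
                last = e
        raise last

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = _try_fit(md)
            cov_re0 = fit.cov_re.to_numpy()
            if random_slope and np.any(np.linalg.eigvalsh(cov_re0) < 0):
                raise np.linalg.LinAlgError
        except (np.linalg.LinAlgError, ValueError):
            # diagonal random-effects covariance as the structured fallback
            md = smf.mixedlm(f"_y_std ~ {rhs}", data, groups=data[group],
                             re_formula=re_formula)
            free = sm.regression.mixed_linear_model.MixedLMParams.from_components(
                fe_params=np.ones(md.k_fe),
                cov_re=np.eye(md.k_re))
            fit = _try_fit(md, free=free)

    fe = pd.DataFrame({
        "term": fit.fe_params.index,
        "coef": fit.fe_params.to_numpy() * scale_y,
        "se": fit.bse_fe.to_numpy() * scale_y,
    })
    fe["ci_lo"] = fe.coef - 1.96 * fe.se
    fe["ci_hi"] = fe.coef + 1.96 * fe.se
    fe["z"] = fe.coef / fe.se
    fe["p"] = 2 * stats.norm.sf(np.abs(fe.z))

    cov_re = fit.cov_re.to_numpy() * scale_y ** 2
    vc = {
        "intercept": float(cov_re[0, 0]),
        "slope": float(cov_re[1, 1]) if random_slope and cov_re.shape[0] > 1 else np.nan,
        "residual": float(fit.scale) * scale_y ** 2,
    }
    # log-likelihood on the original outcome scale (Jacobian of the
    # standardisation)
    ll = float(fit.llf) - len(data) * np.log(scale_y)
    k = len(fit.fe_params) + (3 if random_slope else 1) + 1
    n_obs = len(data)
    return LmmResult(
        fixed_effects=fe, variance_components=vc, loglik=ll,
        aic=-2 * ll + 2 * k, bic=-2 * ll + k * np.log(n_obs),
        n_persons=data[group].nunique(), n_observations=n_obs,
        random_slope=random_slope, converged=bool(fit.converged),
    )


def lrt_nested(fit0: LmmResult, fit1: LmmResult, df: int = 1):
    """Likelihood ratio test of nested ML fits: chi2 = 2(LL1 - LL0) on
    ``df`` degrees of freedom (plain chi-square; the boundary-corrected
    mixture halves the p-value for a single variance component)."""
    chi2 = 2.0 * (fit1.loglik - fit0.loglik)
    if chi2 < 0:
        warnings.warn("larger model has lower log-likelihood; statistic "
                      "floored at 0", stacklevel=2)
        chi2 = 0.0
    return float(chi2), float(stats.chi2.sf(chi2, df))
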