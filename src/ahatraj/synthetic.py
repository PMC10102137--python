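"""Synthetic longitudinal ageing cohort.

Generates panels with the statistical structure the downstream analysis
assumes: a three-class mixture of latent-basis growth trajectories of a
0-100 "Active and Healthy Ageing" (AHA) trait, mixed binary/ordinal items
driven by the trait through a probit graded response model, six raw
biomarkers and a handful of raw performance tests, socio-economic
covariates that predict class membership, monotone attrition, item-level
missingness, and a binary distal quality-of-life outcome.

Defaults emulate an eight-wave panel of ~14,755 adults aged 50+ with 45
anchor items plus 6 wave-varying items, class shares ~ (0.11, 0.79, 0.10)
and growth-factor means/covariances on the published 0-100 scale.  Truth
arrays (class labels, growth factors, per-wave traits) are always emitted;
they are recovery-test fixtures, never pipeline inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .utils import probit_inv

__all__ = [
    "ItemSpec",
    "SimConfig",
    "Cohort",
    "build_item_bank",
    "simulate_cohort",
    "apply_missingness",
    "write_panel",
    "read_panel",
    "simulate_ordinal_factor_data",
    "BIOMARKER_PANEL",
]

# name -> (population mean, SD, cut-off); direction of risk is handled by
# item_prep.dichotomize_biomarker, which knows the published cut-off rules.
BIOMARKER_PANEL = {
    "fibrinogen": (3.3, 0.7, 4.0),
    "hdl": (1.5, 0.4, 1.0),
    "triglycerides": (1.6, 0.8, 2.0),
    "ldl": (3.2, 1.0, 4.0),
    "crp": (2.2, 2.0, 3.0),
    "hba1c": (5.6, 0.8, 6.5),
}
# biomarkers where a LOW value is the risky side
_BIOMARKER_LOW_RISK = {"hdl"}


@dataclass(frozen=True)
class ItemSpec:
    """Measurement model of one item.

    ``kind`` is one of ``binary``, ``ordinal``, ``biomarker_raw``,
    ``measured_raw``.  For categorical kinds, ``thresholds`` are the
    strictly increasing category bounds b_c on the standardised latent
    scale, in the a*(theta - b) parameterisation; for raw kinds they are
    empty and ``discrimination`` controls the trait-value correlation.
    """

    item_id: str
    kind: str
    n_categories: int
    discrimination: float
    thresholds: tuple[float, ...]
    anchor: bool
    waves_available: tuple[int, ...]
    reverse_coded: bool = False

    def __post_init__(self):
        if self.kind in ("binary", "ordinal"):
            if len(self.thresholds) != self.n_categories - 1:
                raise ValueError(f"{self.item_id}: need C-1 thresholds")
            if np.any(np.diff(self.thresholds) <= 0):
                raise ValueError(f"{self.item_id}: thresholds must strictly increase")
        if self.discrimination <= 0:
            raise ValueError(f"{self.item_id}: discrimination must be positive")


@dataclass
class SimConfig:
    """Generator configuration; defaults are the emulated study conditions."""

    n_persons: int = 14755
    n_waves: int = 8
    seed: int = 0
    class_proportions: tuple[float, ...] = (0.111, 0.793, 0.096)
    # (intercept mean, slope mean) per class on the 0-100 trait scale;
    # classes: moderate-stable, high-stable, decliners
    class_growth_means: tuple[tuple[float, float], ...] = (
        (43.549, -3.269),
        (84.180, -6.577),
        (76.739, -50.017),
    )
    growth_cov: tuple[tuple[float, float], ...] = (
        (53.718, -2.456),
        (-2.456, 40.840),
    )
    # latent-basis time scores, lambda_1 = 0, lambda_T = 1, non-decreasing
    basis_loadings: tuple[float, ...] = (0.0, 0.18, 0.34, 0.48, 0.62, 0.75, 0.88, 1.0)
    residual_sd: float = 7.0
    # multinomial-logit coefficients of covariates on class (reference:
    # high-stable), keyed by dummy name; magnitudes follow the published
    # education/wealth gradients
    covariate_logits: dict | None = None
    item_bank_sizes: tuple[int, int] = (45, 6)  # (anchor, wave-varying)
    missing_rate: float = 0.05
    attrition_hazard: float = 0.10
    attrition_theta_coef: float = 0.0  # logit-linear dependence on current trait
    distal_probs: tuple[float, ...] = (0.151, 0.572, 0.097)
    # SDs of wave-level deviations of categorical item intercepts and
    # discriminations (0 = item parameters constant across waves)
    item_wave_sd: tuple[float, float] = (0.0, 0.0)

    def validate(self) -> None:
        p = np.asarray(self.class_proportions, dtype=float)
        if p.ndim != 1 or not np.isclose(p.sum(), 1.0) or np.any(p < 0):
            raise ValueError("class_proportions must be a probability vector")
        lam = np.asarray(self.basis_loadings, dtype=float)
        if len(lam) != self.n_waves:
            raise ValueError("basis_loadings must have one entry per wave")
        if lam[0] != 0.0 or lam[-1] != 1.0 or np.any(np.diff(lam) < 0):
            raise ValueError("basis loadings must be non-decreasing with endpoints 0 and 1")
        cov = np.asarray(self.growth_cov, dtype=float)
        if cov.shape != (2, 2) or np.any(np.linalg.eigvalsh(cov) < -1e-10):
            raise ValueError("growth_cov must be 2x2 positive semi-definite")
        if np.linalg.det(cov) <= 0:
            raise ValueError("growth_cov is singular")
        if not (0 <= self.missing_rate <= 1 and 0 <= self.attrition_hazard <= 1):
            raise ValueError("missing_rate and attrition_hazard must lie in [0, 1]")
        if self.n_persons <= 0 or self.n_waves <= 0:
            raise ValueError("n_persons and n_waves must be positive")
        if len(self.class_growth_means) != len(p) or len(self.distal_probs) != len(p):
            raise ValueError("per-class parameter lengths must match class count")


# default class-membership logits vs the high-stable reference; values are
# the published SES gradients (education/occupation/wealth) plus demographic
# effects backed out of the class-stratified descriptive table
_DEFAULT_LOGITS = {
    "moderate": {
        "edu_secondary": -0.297, "edu_higher": -0.460,
        "occ_intermediate": -0.132, "occ_higher": -0.178,
        "wealth_q2": -0.806, "wealth_q3": -1.353, "wealth_q4": -1.738, "wealth_q5": -2.500,
        "age_c": 0.07, "female": 0.43, "nonwhite": 0.34,
    },
    "decliner": {
        "edu_secondary": -0.150, "edu_higher": -0.314,
        "occ_intermediate": 0.022, "occ_higher": -0.074,
        "wealth_q2": -0.388, "wealth_q3": -0.861, "wealth_q4": -0.848, "wealth_q5": -1.240,
        "age_c": 0.08, "female": 0.16, "nonwhite": -0.14,
    },
}

_COVARIATE_DUMMIES = [
    "edu_secondary", "edu_higher", "occ_intermediate", "occ_higher",
    "wealth_q2", "wealth_q3", "wealth_q4", "wealth_q5",
    "age_c", "female", "nonwhite",
]


@dataclass
class Cohort:
    """Simulated truth plus observed responses.

    ``responses`` is (n_persons, n_waves, n_items) float with NaN for
    missing; categorical items hold categories 0..C-1, raw items hold
    continuous measurements.  ``observed`` is the companion boolean mask.
    """

    config: SimConfig
    bank: list[ItemSpec]
    true_class: np.ndarray
    growth_factors: np.ndarray  # (n, 2) eta0, eta1
    theta: np.ndarray  # (n, T) on 0-100 scale
    theta_std: np.ndarray  # standardised latent scale used by the items
    covariates: pd.DataFrame
    responses: np.ndarray
    observed: np.ndarray
    distal_outcome: np.ndarray  # float with NaN where unobserved
    in_panel: np.ndarray | None = None  # (n, T) bool, False after attrition
    behaviours: dict | None = None  # per-behaviour (n, T) category arrays

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_waves(self) -> int:
        return self.responses.shape[1]

    def item_index(self) -> dict[str, int]:
        return {spec.item_id: j for j, spec in enumerate(self.bank)}


def _draw_thresholds(rng, n_cat: int) -> tuple[float, ...]:
    """Strictly increasing thresholds with a minimum gap, centred near 0."""
    raw = np.sort(rng.normal(0.0, 1.0, size=n_cat - 1))
    gaps = np.maximum(np.diff(raw), 0.35) if n_cat > 2 else np.array([])
    out = np.concatenate([[raw[0]], raw[0] + np.cumsum(gaps)]) if n_cat > 2 else raw
    return tuple(out - out.mean() + rng.normal(0, 0.3))


def build_item_bank(config: SimConfig) -> list[ItemSpec]:
    """Deterministically (given seed) draw the mixed-type item bank.

    Anchor items are available at every wave; wave-varying items are
    available at baseline plus a random contiguous block of later waves.
    Kinds cycle through binary / 3-category / 4-category self-reports with
    a few raw performance tests and the six raw biomarkers mixed in.
    """
    n_anchor, n_varying = config.item_bank_sizes
    if n_anchor <= 0 or n_varying < 0:
        raise ValueError("item_bank_sizes must be positive (anchor) and non-negative")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 5]))
    all_waves = tuple(range(config.n_waves))
    bank: list[ItemSpec] = []

    biomarkers = list(BIOMARKER_PANEL) if n_anchor + n_varying >= 20 else []
    n_measured = 4 if n_anchor + n_varying >= 20 else 0
    kind_cycle = ["binary", "ordinal3", "binary", "ordinal4", "ordinal3"]

    def make(i: int, anchor: bool, waves: tuple[int, ...]) -> ItemSpec:
        a = float(np.exp(rng.normal(0.0, 0.3)))
        tag = "a" if anchor else "v"
        if biomarkers and anchor and i < len(biomarkers):
            name = biomarkers[i]
            return ItemSpec(f"bm_{name}", "biomarker_raw", 2, a, (), anchor, waves)
        if anchor and len(biomarkers) <= i < len(biomarkers) + n_measured:
            j = i - len(biomarkers)
            return ItemSpec(f"mt{j:02d}", "measured_raw", 3, a, (), anchor, waves)
        kind = kind_cycle[i % len(kind_cycle)]
        n_cat = {"binary": 2, "ordinal3": 3, "ordinal4": 4}[kind]
        thr = _draw_thresholds(rng, n_cat)
        reverse = bool(rng.uniform() < 0.3)  # negatively framed items, recoded in prep
        return ItemSpec(
            f"sr_{tag}{i:02d}", "binary" if n_cat == 2 else "ordinal",
            n_cat, a, thr, anchor, waves, reverse_coded=reverse,
        )

    for i in range(n_anchor):
        bank.append(make(i, True, all_waves))
    for i in range(n_varying):
        # baseline plus a contiguous later block, so every item appears in
        # at least two waves including baseline
        if config.n_waves > 2:
            start = int(rng.integers(1, config.n_waves - 1))
            stop = int(rng.integers(start + 1, config.n_waves + 1))
        else:
            start, stop = 1, config.n_waves
        waves = (0,) + tuple(range(start, stop))
        bank.append(make(i, False, waves))
    return bank


def _draw_covariates(rng, n: int) -> pd.DataFrame:
    edu = rng.choice(3, size=n, p=(0.35, 0.34, 0.31))
    occ = rng.choice(3, size=n, p=(0.42, 0.24, 0.34))
    wealth = rng.choice(5, size=n, p=(0.2,) * 5)
    age = np.clip(rng.normal(65.0, 9.5, size=n), 50, 90).round(1)
    female = (rng.uniform(size=n) < 0.53).astype(int)
    nonwhite = (rng.uniform(size=n) < 0.03).astype(int)
    return pd.DataFrame({
        "education": edu, "occupation": occ, "wealth": wealth,
        "age": age, "female": female, "nonwhite": nonwhite,
    })


def covariate_design(cov: pd.DataFrame) -> pd.DataFrame:
    """Dummy-coded design matrix (references: no qualifications, routine/
    manual occupations, 1st wealth quintile, male, White; age centred at 65)."""
    X = pd.DataFrame(index=cov.index)
    X["edu_secondary"] = (cov["education"] == 1).astype(float)
    X["edu_higher"] = (cov["education"] == 2).astype(float)
    X["occ_intermediate"] = (cov["occupation"] == 1).astype(float)
    X["occ_higher"] = (cov["occupation"] == 2).astype(float)
    for q in range(2, 6):
        X[f"wealth_q{q}"] = (cov["wealth"] == q - 1).astype(float)
    X["age_c"] = cov["age"] - 65.0
    X["female"] = cov["female"].astype(float)
    X["nonwhite"] = cov["nonwhite"].astype(float)
    return X


def class_membership_probs(config: SimConfig, cov: pd.DataFrame) -> np.ndarray:
    """P(class | covariates), calibrated so marginal shares match
    ``class_proportions`` over the realised covariate sample.

    The linear predictor is x'gamma_k for the non-reference classes; class
    intercepts c_k are solved by fixed-point iteration so that the mean of
    P(class=k|x) equals pi_k.  With zero covariate effects this reduces to
    the plain multinomial pi.
    """
    pi = np.asarray(config.class_proportions, dtype=float)
    K = len(pi)
    logits_cfg = config.covariate_logits
    if logits_cfg is None:
        logits_cfg = _DEFAULT_LOGITS if K == 3 else {}
    X = covariate_design(cov)
    eta = np.zeros((len(cov), K))
    class_names = ["moderate", "high", "decliner"] if K == 3 else [str(k) for k in range(K)]
    for k, name in enumerate(class_names):
        coefs = logits_cfg.get(name, {})
        for var, b in coefs.items():
            eta[:, k] += b * X[var].to_numpy()
    # calibrate intercepts to the target marginal shares
    c = np.log(np.maximum(pi, 1e-12))
    for _ in range(200):
        z = eta + c
        z -= z.max(axis=1, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=1, keepdims=True)
        share = p.mean(axis=0)
        if np.max(np.abs(share - pi)) < 1e-10:
            break
        with np.errstate(divide="ignore"):
            c += np.log(np.maximum(pi, 1e-300)) - np.log(np.maximum(share, 1e-300))
    p[:, pi == 0] = 0.0
    p /= p.sum(axis=1, keepdims=True)
    return p


def simulate_cohort(config: SimConfig, bank: Sequence[ItemSpec] | None = None) -> Cohort:
    """Draw a complete cohort (no missingness yet) from the generative model.

    Classes come from a multinomial logit of the covariates; growth factors
    from class-specific normals with the shared covariance; per-wave traits
    from the latent-basis model theta_pt = eta0 + lambda_t * eta1 + eps_pt;
    item responses from the probit graded response model on the
    standardised trait.
    """
    config.validate()
    if bank is None:
        bank = build_item_bank(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    n, T = config.n_persons, config.n_waves
    cov = _draw_covariates(rng, n)
    probs = class_membership_probs(config, cov)
    u = rng.uniform(size=n)
    true_class = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)

    means = np.asarray(config.class_growth_means, dtype=float)[true_class]
    growth = means + rng.multivariate_normal(
        np.zeros(2), np.asarray(config.growth_cov, dtype=float), size=n
    )
    lam = np.asarray(config.basis_loadings, dtype=float)
    theta = growth[:, [0]] + lam[None, :] * growth[:, [1]]
    theta = theta + rng.normal(0.0, config.residual_sd, size=(n, T))

    mu, sd = float(theta.mean()), float(theta.std())
    theta_std = (theta - mu) / sd

    n_items = len(bank)
    sd_int, sd_slope = config.item_wave_sd
    responses = np.full((n, T, n_items), np.nan)
    for j, spec in enumerate(bank):
        a = spec.discrimination
        if spec.kind in ("binary", "ordinal"):
            a_t = a + (rng.normal(0, sd_slope, size=T) if sd_slope > 0 else 0.0)
            a_t = np.maximum(np.broadcast_to(a_t, (T,)).copy(), 0.05)
            u_t = rng.normal(0, sd_int, size=T) if sd_int > 0 else np.zeros(T)
            u_t[0] = 0.0
            if sd_slope > 0:
                a_t[0] = a
            w = a_t[None, :] * theta_std + rng.normal(size=(n, T))
            thr = a * np.asarray(spec.thresholds)
            y = (w[:, :, None] > (thr[None, None, :] + u_t[None, :, None])).sum(axis=2).astype(float)
            if spec.reverse_coded:
                y = (spec.n_categories - 1) - y
            responses[:, :, j] = y
        elif spec.kind == "measured_raw":
            rho = a / np.sqrt(1 + a * a)
            responses[:, :, j] = rho * theta_std + np.sqrt(1 - rho * rho) * rng.normal(size=(n, T))
        elif spec.kind == "biomarker_raw":
            name = spec.item_id.removeprefix("bm_")
            m, s, _ = BIOMARKER_PANEL[name]
            rho = a / np.sqrt(1 + a * a)
            z = rho * theta_std + np.sqrt(1 - rho * rho) * rng.normal(size=(n, T))
            sign = -1.0 if name not in _BIOMARKER_LOW_RISK else 1.0
            responses[:, :, j] = np.maximum(m + s * sign * z, 0.01)
        else:
            raise ValueError(f"unknown item kind {spec.kind}")

    # item availability by design (wave-varying items absent off their waves)
    observed = np.ones((n, T, n_items), dtype=bool)
    for j, spec in enumerate(bank):
        off = [t for t in range(T) if t not in spec.waves_available]
        if off:
            observed[:, off, j] = False
    responses[~observed] = np.nan

    distal = rng.uniform(size=n) < np.asarray(config.distal_probs)[true_class]
    return Cohort(
        config=config, bank=list(bank), true_class=true_class,
        growth_factors=growth, theta=theta, theta_std=theta_std,
        covariates=cov, responses=responses, observed=observed,
        distal_outcome=distal.astype(float),
        in_panel=np.ones((n, T), dtype=bool),
        behaviours=_draw_behaviours(rng, theta_std),
    )


def _draw_behaviours(rng, theta_std: np.ndarray) -> dict[str, np.ndarray]:
    """Time-varying lifestyle behaviours correlated with the trait: ordinal
    probit draws so healthier people report more activity, less smoking."""
    def ordinal(a, thresholds):
        w = a * theta_std + rng.normal(size=theta_std.shape)
        thr = np.asarray(thresholds)
        return (w[:, :, None] > thr[None, None, :]).sum(axis=2)

    return {
        # 0 never, 1 former, 2 current (high trait -> lower category)
        "smoking": 2 - ordinal(0.5, (-0.8, 0.4)),
        # 0 none, 1 <= twice weekly, 2 > twice weekly
        "alcohol": ordinal(0.4, (-0.9, 0.6)),
        # 0 inactive, 1 mild, 2 moderate, 3 vigorous
        "activity": ordinal(0.9, (-1.3, -0.3, 0.7)),
    }


def apply_missingness(cohort: Cohort, config: SimConfig | None = None) -> Cohort:
    """Apply monotone attrition and item-level MAR holes.

    Attrition: from wave 2 onward each still-active person drops out with
    hazard sigma^-1(logit(h) + c * theta_std); once out, all later waves are
    absent and the distal outcome (collected at the final wave) is missing.
    Item holes are Bernoulli(missing_rate) on top.  Returns a new Cohort;
    the input must not already carry missingness.
    """
    if config is None:
        config = cohort.config
    if not (0 <= config.missing_rate <= 1 and 0 <= config.attrition_hazard <= 1):
        raise ValueError("rates must lie in [0, 1]")
    if cohort.in_panel is not None and not cohort.in_panel.all():
        raise ValueError("missingness already applied")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
    n, T = cohort.n_persons, cohort.n_waves

    in_panel = np.ones((n, T), dtype=bool)
    if config.attrition_hazard > 0 or config.attrition_theta_coef != 0:
        base = np.log(config.attrition_hazard / (1 - config.attrition_hazard)) \
            if 0 < config.attrition_hazard < 1 else (
                -np.inf if config.attrition_hazard == 0 else np.inf)
        active = np.ones(n, dtype=bool)
        for t in range(1, T):
            logit = base - config.attrition_theta_coef * cohort.theta_std[:, t]
            h = 1.0 / (1.0 + np.exp(-logit)) if np.isfinite(base) else (
                np.zeros(n) if base == -np.inf else np.ones(n))
            drop = active & (rng.uniform(size=n) < h)
            active &= ~drop
            in_panel[:, t] = active

    observed = cohort.observed & in_panel[:, :, None]
    if config.missing_rate > 0:
        holes = rng.uniform(size=observed.shape) < config.missing_rate
        observed &= ~holes
    responses = cohort.responses.copy()
    responses[~observed] = np.nan
    distal = cohort.distal_outcome.copy()
    distal[~in_panel[:, -1]] = np.nan
    return replace(
        cohort, responses=responses, observed=observed,
        distal_outcome=distal, in_panel=in_panel,
    )


def observed_wave_proportions(cohort: Cohort) -> np.ndarray:
    """Fraction of persons with at least one observed item per wave."""
    return cohort.observed.any(axis=2).mean(axis=0)


# ---------------------------------------------------------------------------
# file round-trip


def write_panel(cohort: Cohort, path: str | Path) -> dict[str, Path]:
    """Write the long response panel, covariates, item metadata and truth CSVs."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    n, T, J = cohort.responses.shape
    p, t, j = np.nonzero(cohort.observed)
    panel = pd.DataFrame({
        "person_id": p, "wave": t,
        "item_id": np.asarray([s.item_id for s in cohort.bank])[j],
        "value": cohort.responses[p, t, j],
    })
    files = {
        "panel": path / "panel.csv",
        "covariates": path / "covariates.csv",
        "items": path / "items.csv",
        "truth": path / "truth.csv",
    }
    panel.to_csv(files["panel"], index=False)
    cov = cohort.covariates.copy()
    cov.insert(0, "person_id", np.arange(n))
    cov["distal_outcome"] = cohort.distal_outcome
    cov.to_csv(files["covariates"], index=False)
    items = pd.DataFrame({
        "item_id": [s.item_id for s in cohort.bank],
        "kind": [s.kind for s in cohort.bank],
        "n_categories": [s.n_categories for s in cohort.bank],
        "discrimination": [s.discrimination for s in cohort.bank],
        "anchor": [s.anchor for s in cohort.bank],
        "reverse_coded": [s.reverse_coded for s in cohort.bank],
        "waves_available": [";".join(map(str, s.waves_available)) for s in cohort.bank],
        "thresholds": [";".join(f"{b:.6g}" for b in s.thresholds) for s in cohort.bank],
    })
    items.to_csv(files["items"], index=False)
    truth = pd.DataFrame({
        "person_id": np.arange(n),
        "true_class": cohort.true_class,
        "eta0": cohort.growth_factors[:, 0],
        "eta1": cohort.growth_factors[:, 1],
    })
    for w in range(T):
        truth[f"theta_w{w}"] = cohort.theta[:, w]
    truth.to_csv(files["truth"], index=False)
    return files


def read_panel(path: str | Path):
    """Read back (panel, covariates, items, truth) data frames written by write_panel."""
    path = Path(path)
    return (
        pd.read_csv(path / "panel.csv"),
        pd.read_csv(path / "covariates.csv"),
        pd.read_csv(path / "items.csv"),
        pd.read_csv(path / "truth.csv"),
    )


def panel_to_array(panel: pd.DataFrame, bank: Sequence[ItemSpec], n_persons: int,
                   n_waves: int) -> np.ndarray:
    """Long CSV panel back to the (n, T, J) response array (NaN = missing)."""
    idx = {s.item_id: j for j, s in enumerate(bank)}
    out = np.full((n_persons, n_waves, len(bank)), np.nan)
    out[
        panel["person_id"].to_numpy(),
        panel["wave"].to_numpy(),
        panel["item_id"].map(idx).to_numpy(),
    ] = panel["value"].to_numpy()
    return out


# ---------------------------------------------------------------------------
# auxiliary generator for the factor-analysis stage tests


def simulate_ordinal_factor_data(loadings: np.ndarray, n: int, rng,
                                 n_categories: int = 3,
                                 factor_corr: np.ndarray | None = None) -> np.ndarray:
    """Ordinal data from a linear factor model, discretised at fixed cuts.

    ``loadings`` is items x factors; unique variances are 1 - communality.
    Used to validate the EFA/CFA stage against a known structure.
    """
    loadings = np.asarray(loadings, dtype=float)
    p, m = loadings.shape
    if factor_corr is None:
        factor_corr = np.eye(m)
    f = rng.multivariate_normal(np.zeros(m), factor_corr, size=n)
    communality = np.einsum("pm,mn,pn->p", loadings, factor_corr, loadings)
    if np.any(communality >= 1):
        raise ValueError("communalities must be < 1")
    e = rng.normal(size=(n, p)) * np.sqrt(1 - communality)
    y = f @ loadings.T + e
    cuts = probit_inv(np.linspace(0, 1, n_categories + 1)[1:-1])
    return (y[:, :, None] > cuts[None, None, :]).sum(axis=2).astype(float)
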