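"""Item recoding and eligibility gates.

Turns the raw mixed-type panel into ordered categories with "higher =
better" orientation, applies the baseline 25%-missingness gate, the
half-of-battery person-wave gate for the IRT stage, and the 70/30
development/validation split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import BIOMARKER_PANEL, _BIOMARKER_LOW_RISK, Cohort, ItemSpec

__all__ = [
    "recode_direction",
    "dichotomize_biomarker",
    "trichotomize_measured",
    "code_orientation",
    "filter_baseline",
    "filter_half_items",
    "split_dev_validation",
    "prepare_panel",
    "PreparedPanel",
]

# non-strict comparison applies only to glycated haemoglobin (>= 6.5%)
_NON_STRICT = {"hba1c"}


def recode_direction(values: np.ndarray, n_categories: int, reverse: bool) -> np.ndarray:
    """Reverse the category order of an item so higher = better.

    Missing (NaN) entries are preserved; out-of-range categories raise.
    """
    v = np.asarray(values, dtype=float)
    obs = ~np.isnan(v)
    if np.any((v[obs] < 0) | (v[obs] > n_categories - 1)):
        raise ValueError("category outside the item's range")
    if not reverse:
        return v.copy()
    out = v.copy()
    out[obs] = (n_categories - 1) - v[obs]
    return out


def dichotomize_biomarker(name: str, value):
    """0 = higher-risk side of the published cut-off, 1 otherwise.

    Cut-offs: fibrinogen > 4.0 g/L, HDL < 1.0 mmol/L, triglycerides
    > 2.0 mmol/L, LDL > 4.0 mmol/L, CRP > 3 mg/L, HbA1c >= 6.5% — all
    strict comparisons except HbA1c.  NaN passes through.
    """
    if name not in BIOMARKER_PANEL:
        raise KeyError(f"unknown biomarker {name!r}")
    v = np.asarray(value, dtype=float)
    if np.any(v[~np.isnan(v)] < 0):
        raise ValueError("negative concentration")
    cut = BIOMARKER_PANEL[name][2]
    if name in _BIOMARKER_LOW_RISK:
        risky = v < cut
    elif name in _NON_STRICT:
        risky = v >= cut
    else:
        risky = v > cut
    out = np.where(risky, 0.0, 1.0)
    return np.where(np.isnan(v), np.nan, out)


def trichotomize_measured(values) -> np.ndarray:
    """SD-band scoring of a continuous test: 2 if > mean+SD, 0 if < mean-SD,
    else 1.  Mean/SD come from the non-missing values passed in (i.e. the
    estimation sample at that wave)."""
    v = np.asarray(values, dtype=float)
    obs = ~np.isnan(v)
    if obs.sum() < 2:
        raise ValueError("need at least two non-missing values")
    m, s = v[obs].mean(), v[obs].std(ddof=1)
    if s == 0:
        raise ValueError("degenerate distribution (SD = 0)")
    out = np.full_like(v, np.nan)
    out[obs] = 1.0
    out[obs & (v > m + s)] = 2.0
    out[obs & (v < m - s)] = 0.0
    return out


def code_orientation(answers) -> float:
    """Time-orientation score: 1 iff all four questions answered correctly;
    any missing answer makes the score missing."""
    a = np.asarray(answers, dtype=float)
    if a.shape[-1] != 4:
        raise ValueError("orientation requires exactly four answers")
    if np.any(np.isnan(a)):
        return np.nan
    return 1.0 if np.all(a == 1) else 0.0


def filter_baseline(responses_baseline: np.ndarray, max_missing: float = 0.25) -> np.ndarray:
    """Person is baseline-eligible iff their missing fraction over the
    baseline item battery is <= max_missing (inclusive boundary)."""
    r = np.asarray(responses_baseline, dtype=float)
    if r.ndim != 2 or r.shape[1] == 0:
        raise ValueError("need a person x item baseline matrix")
    frac = np.isnan(r).mean(axis=1)
    return frac <= max_missing


def filter_half_items(responses: np.ndarray, battery_size: int | None = None) -> np.ndarray:
    """Person-wave eligibility for the IRT stage: observed items >=
    ceil(battery/2).  ``responses`` is (n, T, J); returns (n, T) bool."""
    r = np.asarray(responses, dtype=float)
    if battery_size is None:
        battery_size = r.shape[-1]
    need = int(np.ceil(battery_size / 2))
    return (~np.isnan(r)).sum(axis=-1) >= need


def split_dev_validation(eligible_ids: np.ndarray, dev_fraction: float = 0.70,
                         seed: int = 0) -> pd.Series:
    """Simple random 70/30 split of the eligible persons; development size
    is round(dev_fraction * n)."""
    ids = np.asarray(eligible_ids)
    if len(ids) < 2:
        raise ValueError("need at least two eligible persons to split")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 17]))
    n_dev = int(round(dev_fraction * len(ids)))
    perm = rng.permutation(len(ids))
    labels = np.full(len(ids), "validation", dtype=object)
    labels[perm[:n_dev]] = "development"
    return pd.Series(labels, index=ids, name="split")


@dataclass
class PreparedPanel:
    """All-ordinal panel ready for the factor-analysis and IRT stages."""

    responses: np.ndarray  # (n, T, J) ordered categories, higher = better
    bank: list[ItemSpec]
    n_categories: np.ndarray
    baseline_missing_fraction: np.ndarray
    baseline_eligible: np.ndarray
    personwave_eligible: np.ndarray
    split: pd.Series  # over baseline-eligible person ids

    def baseline_matrix(self, subset: np.ndarray | None = None) -> np.ndarray:
        m = self.responses[:, 0, :]
        return m if subset is None else m[subset]


def prepare_panel(cohort: Cohort, seed: int | None = None,
                  max_missing: float = 0.25, dev_fraction: float = 0.70,
                  valid_ranges: dict | None = None) -> PreparedPanel:
    """Recode the cohort's raw panel into analysis categories and apply gates.

    Biomarkers are dichotomised at their published cut-offs; raw performance
    tests are SD-band trichotomised per wave on that wave's observed sample;
    reverse-coded self-reports are flipped so higher = better.
    ``valid_ranges`` maps item_id -> (lo, hi); raw values outside an item's
    valid range (outliers) are treated as missing before any recoding.
    """
    if seed is None:
        seed = cohort.config.seed
    n, T, J = cohort.responses.shape
    out = np.full((n, T, J), np.nan)
    n_cat = np.zeros(J, dtype=int)
    for j, spec in enumerate(cohort.bank):
        col = cohort.responses[:, :, j]
        if valid_ranges and spec.item_id in valid_ranges:
            lo, hi = valid_ranges[spec.item_id]
            col = np.where((col < lo) | (col > hi), np.nan, col)
        if spec.kind in ("binary", "ordinal"):
            out[:, :, j] = recode_direction(col, spec.n_categories, spec.reverse_coded)
            n_cat[j] = spec.n_categories
        elif spec.kind == "biomarker_raw":
            out[:, :, j] = dichotomize_biomarker(spec.item_id.removeprefix("bm_"), col)
            n_cat[j] = 2
        elif spec.kind == "measured_raw":
            for t in range(T):
                if (~np.isnan(col[:, t])).sum() >= 2 and np.nanstd(col[:, t]) > 0:
                    out[:, t, j] = trichotomize_measured(col[:, t])
            n_cat[j] = 3
        else:
            raise ValueError(spec.kind)

    baseline_frac = np.isnan(out[:, 0, :]).mean(axis=1)
    eligible = filter_baseline(out[:, 0, :], max_missing)
    pw = filter_half_items(out)
    split = split_dev_validation(np.nonzero(eligible)[0], dev_fraction, seed) \
        if eligible.sum() >= 2 else pd.Series(dtype=object)
    return PreparedPanel(
        responses=out, bank=list(cohort.bank), n_categories=n_cat,
        baseline_missing_fraction=baseline_frac, baseline_eligible=eligible,
        personwave_eligible=pw, split=split,
    )
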