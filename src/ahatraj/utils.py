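"""Shared numerical helpers: seed fan-out, link functions, small diagnostics."""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, ndtri

# Stable stage identifiers for counter-based seed fan-out.  Adding a stage
# appends a new id and never shifts the stream of an existing one.
STAGE_IDS = {
    "simulate": 11,
    "prep": 23,
    "dimensionality": 37,
    "mlirt": 41,
    "trajectories": 53,
    "covariates": 67,
    "validate": 79,
    "report": 97,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent generator for a named pipeline stage derived from one seed."""
    if stage not in STAGE_IDS:
        raise KeyError(f"unknown stage {stage!r}")
    return np.random.default_rng(np.random.SeedSequence([int(seed), STAGE_IDS[stage]]))


def probit(x):
    """Standard normal CDF (the probit link used throughout)."""
    return ndtr(x)


def probit_inv(p):
    return ndtri(p)


def split_rhat(chain: np.ndarray) -> float:
    """Split-R̂ of a single chain (Gelman et al.): halves treated as chains."""
    x = np.asarray(chain, dtype=float)
    n = (len(x) // 2) * 2
    if n < 4:
        return np.nan
    halves = x[:n].reshape(2, n // 2)
    w = halves.var(axis=1, ddof=1).mean()
    b = (n // 2) * halves.mean(axis=1).var(ddof=1)
    if w <= 0:
        return 1.0
    var_plus = (n // 2 - 1) / (n // 2) * w + b / (n // 2)
    return float(np.sqrt(var_plus / w))


def truncated_normal(rng, mean, lo, hi, sd=1.0):
    """Vectorised draw from N(mean, sd^2) truncated to (lo, hi) via inverse CDF."""
    mean = np.asarray(mean, dtype=float)
    a = ndtr((lo - mean) / sd)
    b = ndtr((hi - mean) / sd)
    # guard degenerate intervals deep in the tail
    a = np.clip(a, 0.0, 1.0 - 1e-12)
    b = np.clip(b, a + 1e-12, 1.0)
    u = rng.uniform(a, b)
    return mean + sd * ndtri(u)
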