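"""Empirical degree distribution and power-law fitting.

The degree distribution p(k) gives the fraction of nodes with degree k.
Scale-free networks follow p(k) ~ A k^(-gamma).  Two estimators of
gamma are provided:

``loglog_ols``
    Ordinary least squares of log p(k) on log k over the observed
    degrees k >= 1 with p(k) > 0 — the regression-on-the-scatter fit
    commonly applied to degree histograms.  Reports the slope's
    two-sided p-value and r².
``discrete_mle``
    Maximum-likelihood exponent of the discrete (zeta) power law with
    k_min = 1, the statistically preferred estimator; the OLS slope
    diagnostics (p-value, r²) are still attached as descriptive
    measures of log-log linearity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
from scipy import optimize, special, stats

from .errors import FitError

FitMethod = Literal["loglog_ols", "discrete_mle"]


@dataclass(frozen=True)
class DegreeDistribution:
    """Mapping degree k -> fraction of nodes with that degree.

    An empirical distribution sums to 1 over all observed degrees
    (degree 0 included); unnormalised weights are tolerated so that a
    rescaled distribution can still be fitted (rescaling changes the
    fitted amplitude only, never the exponent).
    """

    pk: dict[int, float]

    def __post_init__(self) -> None:
        if any(p < 0 for p in self.pk.values()):
            raise ValueError("degree fractions must be non-negative")


@dataclass(frozen=True)
class PowerLawFit:
    gamma: float
    amplitude: float
    p_value: float
    r_squared: float
    method: FitMethod


def empirical_pk(degrees: Mapping[str, int]) -> DegreeDistribution:
    """Fraction of nodes at each observed degree (k = 0 included)."""
    if not degrees:
        raise FitError("empty degree mapping")
    n = len(degrees)
    counts: dict[int, int] = {}
    for k in degrees.values():
        counts[k] = counts.get(k, 0) + 1
    return DegreeDistribution({k: counts[k] / n for k in sorted(counts)})


def _ols_points(dist: DegreeDistribution) -> tuple[np.ndarray, np.ndarray]:
    ks = np.array(sorted(k for k, p in dist.pk.items() if k >= 1 and p > 0), dtype=float)
    if ks.size < 3:
        raise FitError(
            f"power-law fit needs >= 3 degrees k >= 1 with p(k) > 0, got {ks.size}"
        )
    ps = np.array([dist.pk[int(k)] for k in ks])
    return ks, ps


def _mle_gamma(ks: np.ndarray, weights: np.ndarray) -> float:
    """Discrete power-law MLE with k_min = 1 (zeta normalisation)."""
    wsum = weights.sum()
    slogk = float(np.sum(weights * np.log(ks)))

    def nll(gamma: float) -> float:
        return gamma * slogk + wsum * math.log(special.zeta(gamma, 1.0))

    res = optimize.minimize_scalar(nll, bounds=(1.0 + 1e-6, 20.0), method="bounded")
    return float(res.x)


def fit_power_law(
    dist: DegreeDistribution, method: FitMethod = "loglog_ols"
) -> PowerLawFit:
    """Fit p(k) = A k^(-gamma) to a degree distribution.

    Degree-0 nodes are excluded (log k undefined); k_min is fixed at 1.
    """
    ks, ps = _ols_points(dist)
    ols = stats.linregress(np.log(ks), np.log(ps))
    if method == "loglog_ols":
        return PowerLawFit(
            gamma=float(-ols.slope),
            amplitude=float(math.exp(ols.intercept)),
            p_value=float(ols.pvalue),
            r_squared=float(ols.rvalue**2),
            method="loglog_ols",
        )
    if method == "discrete_mle":
        gamma = _mle_gamma(ks, ps)
        return PowerLawFit(
            gamma=gamma,
            amplitude=float(1.0 / special.zeta(gamma, 1.0)),
            p_value=float(ols.pvalue),
            r_squared=float(ols.rvalue**2),
            method="discrete_mle",
        )
    raise ValueError(f"unknown fit method {method!r}")


def fit_report(dist: DegreeDistribution, fit: PowerLawFit) -> dict:
    """JSON-ready report of a distribution plus its power-law fit."""
    return {
        "pk": {str(k): p for k, p in sorted(dist.pk.items())},
        "gamma": fit.gamma,
        "amplitude": fit.amplitude,
        "p_value": fit.p_value,
        "r_squared": fit.r_squared,
        "method": fit.method,
    }
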