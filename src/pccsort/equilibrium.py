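"""Stepwise association attributes from a formula distribution.

For the assembly step ``alpha_n beta_6 + alpha <-> alpha_{n+1} beta_6`` at
equilibrium, the product of the stepwise equilibrium constant and the free
ligand concentration is estimated by the particle-count ratio

    r_n = N_{n+1} / N_n,        n = 0..5,

since counts are proportional to concentrations and the free ligand
concentration is assumed constant.  The module fits an exponential decay
to r_n versus n and compares against the identical-independent-site
prediction r_n = ((6 - n) / (n + 1)) * theta, whose falling statistical
factor alone produces a decaying sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .sorting import FormulaDistribution
from .symmetry import N_SITES

__all__ = [
    "ExponentialFit",
    "ThetaEstimate",
    "EquilibriumResult",
    "stepwise_ratios",
    "fit_exponential_decay",
    "independent_site_ratios",
    "estimate_theta",
    "analyze_equilibrium",
]


@dataclass(frozen=True)
class ExponentialFit:
    """r_n ~ A * exp(-lambda * n), fitted by OLS on the log scale."""

    fit_A: float
    fit_lambda: float
    r_squared: float


@dataclass(frozen=True)
class ThetaEstimate:
    """Occupancy odds theta = p / (1 - p) under the independent-site model."""

    theta_hat: float
    ci_low: float
    ci_high: float

    def covers(self, theta: float) -> bool:
        return self.ci_low <= theta <= self.ci_high


@dataclass(frozen=True)
class EquilibriumResult:
    """Bundle of the stepwise ratios, decay fit and independent-site estimate.

    ``ratios[n]`` is NaN where N_n = 0 made the ratio undefined;
    ``defined[n]`` flags usable entries.
    """

    ratios: tuple[float, ...]
    defined: tuple[bool, ...]
    fit: ExponentialFit | None
    theta: ThetaEstimate | None
    pseudocount: float

    def to_dict(self) -> dict:
        out: dict = {
            "ratios": [
                {"n": n, "value": (r if d else None), "defined": d}
                for n, (r, d) in enumerate(zip(self.ratios, self.defined))
            ],
            "pseudocount": self.pseudocount,
        }
        if self.fit is not None:
            out["fit"] = {
                "A": self.fit.fit_A,
                "lambda": self.fit.fit_lambda,
                "r_squared": self.fit.r_squared,
            }
        if self.theta is not None:
            out["theta"] = {
                "theta_hat": self.theta.theta_hat,
                "ci_95": [self.theta.ci_low, self.theta.ci_high],
            }
        return out


def stepwise_ratios(
    dist: FormulaDistribution, pseudocount: float = 0.0
) -> np.ndarray:
    """Ratios r_n = (N_{n+1} + pseudocount) / (N_n + pseudocount) for n = 0..5.

    With pseudocount 0 the ratio is NaN (undefined) wherever N_n = 0;
    ratios are never silently fabricated.
    """
    if pseudocount < 0:
        raise ValueError(f"pseudocount must be nonnegative, got {pseudocount}")
    if dist.total <= 0:
        raise ValueError("distribution total must be positive")
    counts = dist.as_array() + pseudocount
    ratios = np.full(N_SITES, np.nan)
    nonzero = counts[:-1] > 0
    ratios[nonzero] = counts[1:][nonzero] / counts[:-1][nonzero]
    return ratios


def fit_exponential_decay(ratios: np.ndarray) -> ExponentialFit:
    """Fit r_n = A exp(-lambda n) by ordinary least squares of ln r_n on n.

    NaN entries (undefined ratios) are excluded; at least two defined,
    strictly positive ratios are required.  R^2 is reported on the log
    scale (defined as 1 for an exactly constant sequence).
    """
    ratios = np.asarray(ratios, dtype=float)
    if ratios.shape != (N_SITES,):
        raise ValueError(f"expected {N_SITES} ratio values, got shape {ratios.shape}")
    usable = ~np.isnan(ratios)
    if np.any(ratios[usable] <= 0):
        raise ValueError("defined ratios must be strictly positive for a log-scale fit")
    n = np.arange(N_SITES, dtype=float)[usable]
    if n.size < 2:
        raise ValueError(
            f"need at least 2 defined ratios to fit, got {n.size} "
            "(distribution too sparse)"
        )
    y = np.log(ratios[usable])
    slope, intercept = np.polyfit(n, y, 1)
    resid = y - (slope * n + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return ExponentialFit(
        fit_A=float(math.exp(intercept)), fit_lambda=float(-slope), r_squared=r2
    )


def independent_site_ratios(theta: float) -> np.ndarray:
    """Closed-form ratio sequence for six identical independent sites.

    With N_n proportional to C(6, n) * theta**n, the stepwise ratio is the
    statistical factor times the odds: r_n = ((6 - n) / (n + 1)) * theta,
    strictly decreasing in n for every theta > 0.
    """
    if theta <= 0:
        raise ValueError(f"theta must be positive, got {theta}")
    n = np.arange(N_SITES, dtype=float)
    return (N_SITES - n) / (n + 1.0) * theta


def estimate_theta(
    dist: FormulaDistribution, confidence: float = 0.95
) -> ThetaEstimate:
    """Maximum-likelihood occupancy odds under the independent-site model.

    p_hat = sum(n * N_n) / (6 * total) is the ML site-occupancy estimate
    when counts follow Binomial(6, p); theta_hat = p_hat / (1 - p_hat).
    The interval is a normal approximation on the logit scale.
    """
    counts = dist.as_array()
    total = dist.total
    if total <= 0:
        raise ValueError("distribution total must be positive")
    n = np.arange(N_SITES + 1, dtype=float)
    p_hat = float((n * counts).sum() / (N_SITES * total))
    if p_hat <= 0.0 or p_hat >= 1.0:
        raise ValueError(
            f"p_hat = {p_hat}: occupancy odds unbounded (all mass at n=0 or n=6)"
        )
    theta_hat = p_hat / (1.0 - p_hat)
    # delta method on logit(p) with 6 * total Bernoulli site observations
    se_logit = 1.0 / math.sqrt(N_SITES * total * p_hat * (1.0 - p_hat))
    z = norm.ppf(0.5 + confidence / 2.0)
    log_theta = math.log(theta_hat)
    return ThetaEstimate(
        theta_hat=theta_hat,
        ci_low=math.exp(log_theta - z * se_logit),
        ci_high=math.exp(log_theta + z * se_logit),
    )


def analyze_equilibrium(
    dist: FormulaDistribution, pseudocount: float = 0.0
) -> EquilibriumResult:
    """Full equilibrium report: ratios, decay fit and theta estimate.

    The fit and theta estimate are omitted (None) when the distribution is
    too sparse or degenerate to support them, rather than raising.
    """
    ratios = stepwise_ratios(dist, pseudocount=pseudocount)
    defined = tuple(bool(x) for x in ~np.isnan(ratios))
    try:
        fit = fit_exponential_decay(ratios)
    except ValueError:
        fit = None
    try:
        theta = estimate_theta(dist)
    except ValueError:
        theta = None
    return EquilibriumResult(
        ratios=tuple(float(r) for r in ratios),
        defined=defined,
        fit=fit,
        theta=theta,
        pseudocount=pseudocount,
    )
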