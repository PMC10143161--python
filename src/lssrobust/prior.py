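"""Discrete nonparametric (support-point) population distributions.

A nonparametric population pharmacokinetic analysis represents the
population parameter distribution as a finite set of support points:
parameter vectors theta_i = (CL, V, Vp, Q) each carrying a probability
p_i, with sum(p_i) = 1.  That discrete distribution serves directly as
the Bayesian prior for individual estimation, and weighted summaries of
it (weighted mean, weighted quantiles) describe the population.

The support points themselves are an input to this package -- estimating
them from raw concentration data is out of scope.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PARAM_NAMES",
    "DEFAULT_BOUNDS",
    "ParameterBounds",
    "SupportPointPrior",
    "read_prior",
    "write_prior",
    "compare_summaries",
    "PriorFormatError",
]

PARAM_NAMES = ("CL", "V", "Vp", "Q")

_PROB_TOL_STRICT = 1e-9   # invariant enforced on constructed priors
_PROB_TOL_READ = 1e-6     # renormalisation tolerance when reading files


class PriorFormatError(ValueError):
    """A support-point file or array violates the prior's contract."""


@dataclass(frozen=True)
class ParameterBounds:
    """Per-parameter box bounds (same units as the parameters)."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        if lower.shape != (len(PARAM_NAMES),) or upper.shape != lower.shape:
            raise ValueError("bounds must be length-4 vectors (CL, V, Vp, Q)")
        if np.any(lower <= 0) or np.any(lower >= upper):
            raise ValueError("bounds require 0 < lower < upper per parameter")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    def contains(self, theta) -> np.ndarray:
        """Boolean mask over rows of theta (n, 4) lying inside the box."""
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        return np.all((theta >= self.lower) & (theta <= self.upper), axis=1)


#: Physiologically wide default box used for the iohexol model: CL and Q in
#: L/h, V and Vp in L.  The CL range spans clearances corresponding to GFR
#: well below 15 and above 115 mL/min so the inclusion filter is exercised.
DEFAULT_BOUNDS = ParameterBounds(
    lower=np.array([0.5, 3.0, 1.0, 0.5]),
    upper=np.array([12.0, 30.0, 40.0, 60.0]),
)


@dataclass(frozen=True)
class SupportPointPrior:
    """A discrete population distribution over (CL, V, Vp, Q).

    Parameters
    ----------
    theta : ndarray, shape (K, 4)
        Support-point parameter vectors, columns ordered CL, V, Vp, Q.
    prob : ndarray, shape (K,)
        Point probabilities, all in (0, 1], summing to 1 within 1e-9.
    bounds : ParameterBounds
        Box bounds the points must respect (also used when sampling).
    """

    theta: np.ndarray
    prob: np.ndarray
    bounds: ParameterBounds = field(default=DEFAULT_BOUNDS)

    def __post_init__(self) -> None:
        theta = np.atleast_2d(np.asarray(self.theta, dtype=float))
        prob = np.asarray(self.prob, dtype=float)
        if theta.ndim != 2 or theta.shape[1] != len(PARAM_NAMES):
            raise PriorFormatError("theta must have shape (K, 4)")
        if prob.shape != (theta.shape[0],):
            raise PriorFormatError("prob must have one entry per support point")
        if theta.shape[0] < 1:
            raise PriorFormatError("at least one support point is required")
        if np.any(theta <= 0) or not np.all(np.isfinite(theta)):
            raise PriorFormatError("support-point parameters must be positive")
        if np.any(prob <= 0) or np.any(prob > 1):
            raise PriorFormatError("probabilities must lie in (0, 1]")
        if abs(prob.sum() - 1.0) > _PROB_TOL_STRICT:
            raise PriorFormatError(
                f"probabilities must sum to 1 within {_PROB_TOL_STRICT}, "
                f"got {prob.sum()!r}")
        if not np.all(self.bounds.contains(theta)):
            raise PriorFormatError("all support points must lie within bounds")
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "prob", prob)

    # -- basic accessors -------------------------------------------------

    @property
    def n_points(self) -> int:
        return self.theta.shape[0]

    def param_index(self, parameter: str) -> int:
        try:
            return PARAM_NAMES.index(parameter)
        except ValueError:
            raise KeyError(f"unknown parameter {parameter!r}; "
                           f"expected one of {PARAM_NAMES}") from None

    def values(self, parameter: str) -> np.ndarray:
        return self.theta[:, self.param_index(parameter)]

    def reweighted(self, prob) -> "SupportPointPrior":
        """Same support locations with new probabilities."""
        return SupportPointPrior(self.theta, np.asarray(prob, float),
                                 self.bounds)

    # -- weighted summaries ----------------------------------------------

    def weighted_mean(self, parameter: str) -> float:
        """Probability-weighted mean of one parameter."""
        return float(self.prob @ self.values(parameter))

    def weighted_quantile(self, parameter: str, q: float) -> float:
        """Left-continuous inverse of the weighted step CDF.

        Returns the smallest support value whose cumulative probability
        reaches ``q``; ``q`` in [0, 1].
        """
        if not 0.0 <= q <= 1.0:
            raise ValueError(f"quantile level must lie in [0, 1], got {q!r}")
        values = self.values(parameter)
        order = np.argsort(values, kind="stable")
        cum = np.cumsum(self.prob[order])
        idx = int(np.searchsorted(cum, q - 1e-12))
        idx = min(idx, len(values) - 1)
        return float(values[order][idx])

    def weighted_median(self, parameter: str) -> float:
        return self.weighted_quantile(parameter, 0.5)

    def credibility_interval(self, parameter: str,
                             level: float = 0.95) -> tuple[float, float]:
        """Central weighted-quantile interval of the discrete distribution."""
        if not 0.0 < level < 1.0:
            raise ValueError("level must lie in (0, 1)")
        tail = (1.0 - level) / 2.0
        return (self.weighted_quantile(parameter, tail),
                self.weighted_quantile(parameter, 1.0 - tail))

    def bootstrap_median_interval(self, parameter: str, level: float = 0.95,
                                  n_boot: int = 1000,
                                  seed: int | None = 0) -> tuple[float, float]:
        """Resampling interval for the weighted median itself.

        Support points are resampled with replacement by probability; the
        interval is the central ``level`` span of the bootstrap medians.
        This is narrower than the distribution's own quantile interval and
        quantifies uncertainty in the median, not population spread.
        """
        rng = np.random.default_rng(seed)
        values = self.values(parameter)
        medians = np.empty(n_boot)
        for b in range(n_boot):
            draw = rng.choice(values, size=self.n_points, p=self.prob)
            medians[b] = np.median(draw)
        tail = 100.0 * (1.0 - level) / 2.0
        lo, hi = np.percentile(medians, [tail, 100.0 - tail])
        return float(lo), float(hi)

    def summary(self) -> pd.DataFrame:
        """Weighted mean, median and 95% quantile interval per parameter."""
        rows = {}
        for name in PARAM_NAMES:
            lo, hi = self.credibility_interval(name)
            rows[name] = {
                "weighted_mean": self.weighted_mean(name),
                "weighted_median": self.weighted_median(name),
                "q2.5": lo,
                "q97.5": hi,
            }
        return pd.DataFrame(rows).T

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.theta, columns=list(PARAM_NAMES))
        df["prob"] = self.prob
        return df


def write_prior(prior: SupportPointPrior, path) -> None:
    """Write a prior to CSV (columns CL, V, Vp, Q, prob; full precision)."""
    df = prior.to_dataframe()
    buf = io.StringIO()
    df.to_csv(buf, index=False, float_format="%.17g")
    Path(path).write_text(buf.getvalue())


def read_prior(path, bounds: ParameterBounds = DEFAULT_BOUNDS) -> SupportPointPrior:
    """Read a support-point CSV written by :func:`write_prior`.

    Probabilities are renormalised only if their sum deviates from 1 by no
    more than 1e-6; larger deviations raise :class:`PriorFormatError`.
    Bounds are not part of the CSV; pass them from the run configuration.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in (*PARAM_NAMES, "prob") if c not in df.columns]
    if missing:
        raise PriorFormatError(f"support-point file missing columns {missing}")
    theta = df[list(PARAM_NAMES)].to_numpy(dtype=float)
    prob = df["prob"].to_numpy(dtype=float)
    if np.any(prob <= 0):
        raise PriorFormatError("probabilities must be strictly positive")
    total = prob.sum()
    if abs(total - 1.0) > _PROB_TOL_READ:
        raise PriorFormatError(
            f"probabilities sum to {total!r}; deviation from 1 exceeds "
            f"{_PROB_TOL_READ}")
    if abs(total - 1.0) > _PROB_TOL_STRICT:
        prob = prob / total  # renormalise only beyond float-sum noise
    return SupportPointPrior(theta, prob, bounds)


def compare_summaries(prior_a: SupportPointPrior,
                      prior_b: SupportPointPrior) -> dict[str, float]:
    """Relative difference (%) of weighted means, per parameter.

    Computed as 100 * |m_a - m_b| / m_a; used to check that a simulated
    population matches the source population (differences above 15% would
    flag a failed simulation).
    """
    out = {}
    for name in PARAM_NAMES:
        m_a = prior_a.weighted_mean(name)
        m_b = prior_b.weighted_mean(name)
        if m_a == 0:
            raise ZeroDivisionError(f"zero weighted mean for {name}")
        out[name] = 100.0 * abs(m_a - m_b) / m_a
    return out
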