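"""Closed-form two-compartment IV-bolus disposition model.

The model is parameterised in clearance from the central compartment (CL,
L/h), central and peripheral distribution volumes (V, Vp, L) and
inter-compartmental clearance (Q, L/h).  After an intravenous bolus the
serum concentration follows the bi-exponential solution

    C(t) = A * exp(-alpha * t) + B * exp(-beta * t)

where alpha > beta > 0 are the hybrid rate constants, i.e. the roots of
``s**2 - (k10 + k12 + k21) * s + k10 * k21 = 0`` with micro-constants
k10 = CL/V, k12 = Q/V, k21 = Q/Vp, and

    A = dose * (alpha - k21) / (V * (alpha - beta))
    B = dose * (k21  - beta) / (V * (alpha - beta))

With linear elimination from the central compartment the area under the
curve from zero to infinity is dose/CL exactly, and the iohexol plasma
clearance -- the measured glomerular filtration rate (mGFR) -- is
dose/AUC converted from L/h to mL/min.

Units are fixed throughout the package: mg, L and h internally; GFR is
reported in mL/min (absolute, no body-surface-area normalisation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PKParameters",
    "DoseEvent",
    "ConcentrationCurve",
    "micro_constants",
    "hybrid_rate_constants",
    "concentration",
    "two_compartment_bolus",
    "auc_inf",
    "gfr_from_auc",
    "LH_TO_ML_MIN",
    "InvalidParameterError",
]

#: Conversion factor from L/h to mL/min (1000 mL/L over 60 min/h).
LH_TO_ML_MIN = 1000.0 / 60.0

#: Relative alpha-beta gap below which the repeated-root limit is used.
_DEGENERATE_TOL = 1e-10


class InvalidParameterError(ValueError):
    """A pharmacokinetic parameter violates positivity or ordering."""


@dataclass(frozen=True)
class PKParameters:
    """One subject's structural parameters.

    Attributes
    ----------
    cl : float
        Clearance from the central compartment, L/h.
    v : float
        Central volume of distribution, L.
    vp : float
        Peripheral volume of distribution, L.
    q : float
        Inter-compartmental clearance, L/h.
    """

    cl: float
    v: float
    vp: float
    q: float

    def __post_init__(self) -> None:
        for name, value in (("cl", self.cl), ("v", self.v),
                            ("vp", self.vp), ("q", self.q)):
            if not np.isfinite(value) or value <= 0:
                raise InvalidParameterError(
                    f"{name.upper()} must be finite and > 0, got {value!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.cl, self.v, self.vp, self.q], dtype=float)

    @classmethod
    def from_array(cls, theta) -> "PKParameters":
        cl, v, vp, q = np.asarray(theta, dtype=float)
        return cls(cl, v, vp, q)


@dataclass(frozen=True)
class DoseEvent:
    """An intravenous bolus dose.

    amount is in mg; time in h (0 for a dose at the start of observation).
    """

    amount: float
    time: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.amount) or self.amount <= 0:
            raise ValueError(f"dose amount must be > 0, got {self.amount!r}")
        if not np.isfinite(self.time) or self.time < 0:
            raise ValueError(f"dose time must be >= 0, got {self.time!r}")


@dataclass(frozen=True)
class ConcentrationCurve:
    """A noiseless concentration-time profile on a fixed grid."""

    times: np.ndarray
    concentrations: np.ndarray
    dose: DoseEvent

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        conc = np.asarray(self.concentrations, dtype=float)
        if times.shape != conc.shape:
            raise ValueError("times and concentrations must have equal length")
        if times.size > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(conc)) or np.any(conc < 0):
            raise ValueError("concentrations must be finite and non-negative")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "concentrations", conc)


def micro_constants(params: PKParameters) -> tuple[float, float, float]:
    """Return the micro rate constants (k10, k12, k21) in 1/h."""
    return params.cl / params.v, params.q / params.v, params.q / params.vp


def hybrid_rate_constants(params: PKParameters) -> tuple[float, float]:
    """Return the hybrid rate constants (alpha, beta), alpha >= beta > 0."""
    k10, k12, k21 = micro_constants(params)
    a, b = _roots(np.asarray(k10), np.asarray(k12), np.asarray(k21))
    return float(a), float(b)


def _roots(k10, k12, k21):
    """Roots of s^2 - (k10+k12+k21) s + k10 k21, elementwise (alpha, beta)."""
    s = k10 + k12 + k21
    disc = s * s - 4.0 * k10 * k21
    root = np.sqrt(np.maximum(disc, 0.0))
    alpha = 0.5 * (s + root)
    beta = 0.5 * (s - root)
    return alpha, beta


def two_compartment_bolus(cl, v, vp, q, amount, t):
    """Vectorised bi-exponential concentration, broadcasting over all inputs.

    Parameters are in package units (L/h, L, mg, h); ``t`` is the time
    elapsed since the bolus and must be non-negative.  The repeated-root
    degeneracy (alpha == beta to within 1e-10 relative) is evaluated
    through its analytic limit ``(dose/V) * exp(-a t) * (1 + (k21-a) t)``.
    """
    cl, v, vp, q, t = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (cl, v, vp, q, t)))
    k10 = cl / v
    k12 = q / v
    k21 = q / vp
    alpha, beta = _roots(k10, k12, k21)
    gap = alpha - beta
    degen = gap <= _DEGENERATE_TOL * alpha
    safe_gap = np.where(degen, 1.0, gap)
    coef_a = (alpha - k21) / safe_gap
    coef_b = (k21 - beta) / safe_gap
    c = (amount / v) * (coef_a * np.exp(-alpha * t) + coef_b * np.exp(-beta * t))
    if np.any(degen):
        limit = (amount / v) * np.exp(-alpha * t) * (1.0 + (k21 - alpha) * t)
        c = np.where(degen, limit, c)
    return c


def concentration(params: PKParameters, dose: DoseEvent, t):
    """Concentration (mg/L) at time(s) ``t`` (h) after the dose event.

    Raises a domain error for any time preceding the dose.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < dose.time):
        raise ValueError("requested time precedes the dose event")
    out = two_compartment_bolus(params.cl, params.v, params.vp, params.q,
                                dose.amount, t - dose.time)
    return out if out.ndim else float(out)


def auc_inf(params: PKParameters, dose: DoseEvent) -> float:
    """AUC from the dose to infinity, mg*h/L; equals dose/CL exactly."""
    return dose.amount / params.cl


def gfr_from_auc(dose_mg: float, auc: float) -> float:
    """Convert dose (mg) over AUC (mg*h/L) to a clearance in mL/min.

    For iohexol this clearance is the measured GFR.
    """
    if not auc > 0:
        raise ValueError(f"AUC must be > 0, got {auc!r}")
    return dose_mg / auc * LH_TO_ML_MIN
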