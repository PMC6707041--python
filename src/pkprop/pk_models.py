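"""Closed-form compartmental pharmacokinetic models.

Two standard disposition models for a drug given as a single dose:

* **IV bolus, two-compartment open model** — the plasma concentration is a
  sum of two decaying exponentials,

  .. math:: C_P(t) = A e^{-\\alpha t} + B e^{-\\beta t},

  where :math:`\\alpha > \\beta > 0` are first-order rate constants for the
  fast *distribution* phase (blood into tissue) and the slow *elimination*
  phase, and :math:`A, B \\ge 0` are the corresponding amplitudes.

* **IM injection, one-compartment open model with first-order absorption**
  (the Bateman function) —

  .. math:: C_P(t) = a\\,(e^{-\\beta t} - e^{-\\gamma t}),

  where :math:`\\gamma > \\beta > 0` are the *uptake* (muscle into blood)
  and *elimination* rate constants and :math:`a > 0` is a scale amplitude.
  The curve is 0 at the dosing time, rises to a single maximum
  :math:`C_{max}` at :math:`t_{max}`, and decays back to 0.

All rate constants are in h⁻¹, times in hours, concentrations in μM.  Some
presentations quote phase *lifetimes* (1/rate, in hours) instead of rate
constants; the reciprocal converts between the two conventions.

The Bateman parameterization has an exact exchange symmetry: swapping
``gamma`` and ``beta`` while negating the amplitude leaves the curve
unchanged.  The canonical form enforced here (``gamma > beta``, positive
amplitude) makes the parameterization unique so that "beta" always names
the slow elimination phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

__all__ = [
    "PKParamsIV",
    "PKParamsIM",
    "PKProfile",
    "conc_iv",
    "conc_im",
    "tmax_im",
    "cmax_im",
    "auc_analytic",
    "auc_numeric",
    "ug_per_ml_to_uM",
    "canonicalize_im",
    "canonicalize_iv",
]

ArrayLike = Union[float, Sequence[float], np.ndarray]


@dataclass(frozen=True)
class PKParamsIV:
    """Two-compartment IV bolus parameters: C(t) = A·e^(−αt) + B·e^(−βt).

    Invariants: alpha > beta > 0 (distribution is the fast phase),
    A ≥ 0, B ≥ 0, A + B > 0.
    """

    A: float
    B: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > self.beta > 0):
            raise ValueError(
                f"require alpha > beta > 0, got alpha={self.alpha}, beta={self.beta}"
            )
        if self.A < 0 or self.B < 0:
            raise ValueError(f"amplitudes must be nonnegative, got A={self.A}, B={self.B}")
        if self.A + self.B <= 0:
            raise ValueError("A + B must be positive (empty model)")

    @property
    def lifetimes_h(self) -> tuple[float, float]:
        """Phase lifetimes (1/alpha, 1/beta) in hours, for readers used to
        the time-constant convention."""
        return (1.0 / self.alpha, 1.0 / self.beta)


@dataclass(frozen=True)
class PKParamsIM:
    """Bateman (one-compartment, first-order absorption) parameters:
    C(t) = amplitude·(e^(−βt) − e^(−γt)).

    Invariants: gamma > beta > 0 (uptake faster than elimination, the
    canonical branch of the exchange symmetry), amplitude > 0.
    """

    amplitude: float
    gamma: float
    beta: float

    def __post_init__(self) -> None:
        if self.gamma == self.beta:
            raise ValueError("degenerate Bateman case gamma == beta is not supported")
        if not (self.gamma > self.beta > 0):
            raise ValueError(
                f"require gamma > beta > 0, got gamma={self.gamma}, beta={self.beta}"
            )
        if self.amplitude <= 0:
            raise ValueError(f"amplitude must be positive, got {self.amplitude}")

    @property
    def lifetimes_h(self) -> tuple[float, float]:
        """Phase lifetimes (1/gamma, 1/beta) in hours."""
        return (1.0 / self.gamma, 1.0 / self.beta)


@dataclass(frozen=True)
class PKProfile:
    """A time–concentration series for one subject.

    Times are hours since drug administration (t = 0 at dosing), strictly
    increasing and nonnegative.  Concentrations are μM and may contain
    small negative values from measurement noise.
    """

    times: np.ndarray
    concentrations: np.ndarray
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)
        if t.ndim != 1 or c.ndim != 1:
            raise ValueError("times and concentrations must be 1-D")
        if t.size != c.size:
            raise ValueError(f"length mismatch: {t.size} times vs {c.size} concentrations")
        if t.size and t[0] < 0:
            raise ValueError("times must be >= 0 (t = 0 is drug administration)")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)


def _check_times(t: ArrayLike) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative times are not allowed (t = 0 is administration)")
    return t


def conc_iv(t: ArrayLike, p: PKParamsIV) -> np.ndarray | float:
    """Two-compartment IV concentration A·e^(−αt) + B·e^(−βt) at time t (h)."""
    t = _check_times(t)
    out = p.A * np.exp(-p.alpha * t) + p.B * np.exp(-p.beta * t)
    return out if out.ndim else float(out)


def conc_im(t: ArrayLike, p: PKParamsIM) -> np.ndarray | float:
    """Bateman concentration amplitude·(e^(−βt) − e^(−γt)) at time t (h)."""
    t = _check_times(t)
    out = p.amplitude * (np.exp(-p.beta * t) - np.exp(-p.gamma * t))
    return out if out.ndim else float(out)


def tmax_im(p: PKParamsIM) -> float:
    """Time of the Bateman maximum, ln(γ/β)/(γ−β) hours.

    The formula is symmetric under exchange of the two rates, so it is
    well defined on either branch of the parameterization.
    """
    return float(np.log(p.gamma / p.beta) / (p.gamma - p.beta))


def cmax_im(p: PKParamsIM) -> float:
    """Maximum plasma concentration C_MAX = C(t_max) of the Bateman curve, μM."""
    return float(conc_im(tmax_im(p), p))


def auc_analytic(p: PKParamsIV | PKParamsIM) -> float:
    """Total drug exposure ∫₀^∞ C_P(t) dt in μM·h.

    IV: A/α + B/β.  IM: amplitude·(1/β − 1/γ).
    """
    if isinstance(p, PKParamsIV):
        return p.A / p.alpha + p.B / p.beta
    if isinstance(p, PKParamsIM):
        return p.amplitude * (1.0 / p.beta - 1.0 / p.gamma)
    raise TypeError(f"unsupported parameter type {type(p).__name__}")


def auc_numeric(profile: PKProfile) -> float:
    """Model-free trapezoidal AUC over the observed window, μM·h."""
    if len(profile) < 2:
        raise ValueError("trapezoidal AUC needs at least 2 points")
    return float(np.trapezoid(profile.concentrations, profile.times))


def ug_per_ml_to_uM(c: ArrayLike, mw: float) -> np.ndarray | float:
    """Convert a mass concentration (μg/mL) to molarity (μM).

    ``mw`` is the molar mass in g/mol of the form actually weighed (free
    base vs. salt differ — e.g. tobramycin free base is 467.5 g/mol), which
    is why it is an explicit argument rather than a constant.
    """
    if mw <= 0:
        raise ValueError(f"molar mass must be positive, got {mw}")
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("mass concentration must be nonnegative")
    out = c * 1000.0 / mw
    return out if out.ndim else float(out)


def canonicalize_im(amplitude: float, gamma: float, beta: float) -> PKParamsIM:
    """Resolve the Bateman exchange symmetry to the canonical branch.

    a·(e^(−βt) − e^(−γt)) with β > γ equals (−a)·(e^(−β't) − e^(−γ't))
    with the rates relabelled so γ' > β'.  A parameter triple whose
    canonical amplitude is nonpositive describes a nonpositive curve and
    is rejected by the type invariant.
    """
    if gamma == beta:
        raise ValueError("degenerate Bateman case gamma == beta is not supported")
    if gamma < beta:
        gamma, beta = beta, gamma
        amplitude = -amplitude
    return PKParamsIM(amplitude=amplitude, gamma=gamma, beta=beta)


def canonicalize_iv(A: float, B: float, alpha: float, beta: float) -> PKParamsIV:
    """Order the two IV exponential phases so alpha (distribution) is the
    fast one; amplitudes travel with their rates."""
    if alpha == beta:
        raise ValueError("coincident IV rates alpha == beta are not supported")
    if alpha < beta:
        alpha, beta = beta, alpha
        A, B = B, A
    return PKParamsIV(A=A, B=B, alpha=alpha, beta=beta)
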