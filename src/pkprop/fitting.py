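"""Least-squares fitting of concentration profiles by the Nelder-Mead simplex.

The fit minimizes the unweighted sum of squared residuals between the
observed concentrations and the compartmental model curve.  The simplex
runs in *log-parameter space*: every rate constant and amplitude is
strictly positive, so optimizing the logarithms gives genuinely
unconstrained simplex moves while ruling out sign-flip pathologies of the
raw Bateman parameterization.  After optimization the parameters are
canonicalized (fast phase labelled first) so that "beta" consistently
names the slow elimination phase across replicates.

Initialization is automatic: the terminal log-linear tail of the profile
estimates the elimination rate, and the remaining parameters come from the
observed peak (IM, via the closed-form t_max relation) or from curve
peeling the early residual (IV).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import brentq, minimize

from .pk_models import (
    PKParamsIM,
    PKParamsIV,
    PKProfile,
    canonicalize_im,
    canonicalize_iv,
    conc_im,
    conc_iv,
)

__all__ = ["FitResult", "FitOptions", "initial_guess", "fit_profile", "rmse_of"]

ModelTag = Literal["IM", "IV"]

_MIN_POINTS = {"IM": 4, "IV": 5}


@dataclass(frozen=True)
class FitOptions:
    """Nelder-Mead convergence controls.

    ``xtol``/``ftol`` are relative simplex-size and function tolerances
    (applied in log-parameter space, where coordinates are O(1));
    ``max_restarts`` perturbed-initial-guess restarts (±20% multiplicative
    jitter) are attempted on non-convergence.
    """

    xtol: float = 1e-8
    ftol: float = 1e-8
    maxiter: int = 5000
    max_restarts: int = 3


@dataclass(frozen=True)
class FitResult:
    """Outcome of a least-squares fit of one profile."""

    model_tag: ModelTag
    params: PKParamsIV | PKParamsIM
    residuals: np.ndarray  # observed − model, μM
    rmse: float
    sse: float
    converged: bool
    n_points: int
    initial_guess: dict
    n_restarts: int = 0

    @property
    def dof(self) -> int:
        return self.n_points - (4 if self.model_tag == "IV" else 3)


def _model_curve(t: np.ndarray, params, model_tag: ModelTag) -> np.ndarray:
    return conc_iv(t, params) if model_tag == "IV" else conc_im(t, params)


def rmse_of(profile: PKProfile, params, model_tag: ModelTag) -> float:
    """Root-mean-square deviation (μM) between a profile and a model curve."""
    resid = profile.concentrations - _model_curve(profile.times, params, model_tag)
    return float(np.sqrt(np.mean(resid**2)))


def _terminal_loglinear(t: np.ndarray, c: np.ndarray) -> tuple[float, float]:
    """Log-linear fit to the terminal 30% of positive points.

    Returns (rate, amplitude) of c ≈ amplitude·e^(−rate·t) on the tail.
    """
    n_tail = max(3, int(np.ceil(0.3 * t.size)))
    t_tail, c_tail = t[-n_tail:], c[-n_tail:]
    keep = c_tail > 0
    if keep.sum() < 3:
        raise ValueError(
            "terminal phase not identifiable: fewer than 3 positive terminal points"
        )
    slope, intercept = np.polyfit(t_tail[keep], np.log(c_tail[keep]), 1)
    rate = max(-slope, 1e-6)
    return rate, float(np.exp(intercept))


def _gamma_from_tmax(beta: float, t_peak: float) -> float:
    """Invert t_max = ln(γ/β)/(γ−β) for γ at fixed β (t_max decreases in γ)."""
    lo, hi = beta * (1 + 1e-9), max(beta * 1e6, 1e3 / t_peak)
    f = lambda g: np.log(g / beta) / (g - beta) - t_peak
    # f(lo) → 1/β − t_peak; a peak later than 1/β is unreachable for any γ>β
    if 1.0 / beta <= t_peak:
        return 2.0 * beta
    if f(hi) > 0:
        return hi
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))


def initial_guess(profile: PKProfile, model_tag: ModelTag) -> dict:
    """Automatic starting values for the simplex, from the data's shape.

    IM: elimination rate β₀ from the terminal log-linear tail; uptake rate
    γ₀ by inverting the closed-form t_max relation at the observed peak
    time; amplitude from the peak height.  IV: β₀/B₀ from the terminal
    tail, α₀/A₀ by log-linear curve peeling of the early residual.
    All outputs are strictly positive and canonically ordered.
    """
    t, c = profile.times, profile.concentrations
    if t.size < _MIN_POINTS[model_tag]:
        raise ValueError(f"{model_tag} fit needs >= {_MIN_POINTS[model_tag]} points")
    if not np.any(c > 0):
        raise ValueError("profile has no positive concentrations")

    beta0, b_amp = _terminal_loglinear(t, c)

    if model_tag == "IM":
        i_peak = int(np.argmax(c))
        c_peak = float(c[i_peak])
        t_peak = float(t[i_peak])
        if t_peak <= 0:  # peak in the first sample: absorption faster than the grid
            t_peak = float(t[t > 0][0]) / 2 if np.any(t > 0) else 1e-3
        gamma0 = _gamma_from_tmax(beta0, t_peak)
        if gamma0 <= beta0:
            gamma0 = 2.0 * beta0
        bracket = np.exp(-beta0 * t_peak) - np.exp(-gamma0 * t_peak)
        amp0 = c_peak / bracket if bracket > 1e-12 else c_peak
        return {"amplitude": max(amp0, 1e-9), "gamma": gamma0, "beta": beta0}

    # IV: peel the fast phase out of the early residual
    resid = c - b_amp * np.exp(-beta0 * t)
    n_early = max(3, t.size // 4)
    te, re = t[:n_early], resid[:n_early]
    keep = re > 0
    if keep.sum() >= 3:
        slope, intercept = np.polyfit(te[keep], np.log(re[keep]), 1)
        alpha0, a_amp = max(-slope, 1e-6), float(np.exp(intercept))
    else:  # distribution phase invisible; seed a fast small component
        alpha0, a_amp = 5.0 * beta0, max(float(c[0]) - b_amp, 0.05 * b_amp)
    if alpha0 <= beta0:
        alpha0 = 5.0 * beta0
    return {
        "A": max(a_amp, 1e-9),
        "B": max(b_amp, 1e-9),
        "alpha": alpha0,
        "beta": beta0,
    }


_PARAM_ORDER = {"IM": ("amplitude", "gamma", "beta"), "IV": ("A", "B", "alpha", "beta")}


def _to_params(x: np.ndarray, model_tag: ModelTag):
    if model_tag == "IM":
        return canonicalize_im(x[0], x[1], x[2])
    return canonicalize_iv(x[0], x[1], x[2], x[3])


def _sse(logx: np.ndarray, t: np.ndarray, c: np.ndarray, model_tag: ModelTag) -> float:
    x = np.exp(logx)
    if model_tag == "IM":
        curve = x[0] * (np.exp(-x[2] * t) - np.exp(-x[1] * t))
    else:
        curve = x[0] * np.exp(-x[2] * t) + x[1] * np.exp(-x[3] * t)
    r = c - curve
    return float(r @ r)


def fit_profile(
    profile: PKProfile,
    model_tag: ModelTag,
    init: dict | None = None,
    options: FitOptions | None = None,
) -> FitResult:
    """Fit a profile to the IM or IV model by Nelder-Mead least squares.

    The returned parameters minimize the sum of squared residuals; the SSE
    at the optimum never exceeds the SSE at the initial guess (the simplex
    retains its best vertex).  Non-convergence after restarts is reported
    through ``converged=False``, never silently.
    """
    options = options or FitOptions()
    if len(profile) < _MIN_POINTS[model_tag]:
        raise ValueError(
            f"{model_tag} fit needs >= {_MIN_POINTS[model_tag]} points, got {len(profile)}"
        )
    guess = dict(init) if init is not None else initial_guess(profile, model_tag)
    order = _PARAM_ORDER[model_tag]
    missing = [k for k in order if k not in guess]
    if missing:
        raise ValueError(f"initial guess missing parameters {missing}")
    x0 = np.array([float(guess[k]) for k in order])
    if np.any(x0 <= 0):
        raise ValueError("initial guess must be strictly positive")

    t, c = profile.times, profile.concentrations
    f0 = _sse(np.log(x0), t, c, model_tag)
    ftol = options.ftol * max(1.0, f0)  # relative function tolerance

    rng = np.random.default_rng(0)  # deterministic restart jitter
    best = None
    n_restarts = 0
    start = np.log(x0)
    for attempt in range(options.max_restarts + 1):
        res = minimize(
            _sse,
            start,
            args=(t, c, model_tag),
            method="Nelder-Mead",
            options={
                "xatol": options.xtol,
                "fatol": ftol,
                "maxiter": options.maxiter,
                "maxfev": 4 * options.maxiter,
            },
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            break
        n_restarts = attempt + 1
        start = np.log(x0 * rng.uniform(0.8, 1.2, size=x0.size))

    x_opt = np.exp(best.x)
    params = _to_params(x_opt, model_tag)
    curve = _model_curve(t, params, model_tag)
    residuals = c - curve
    sse = float(residuals @ residuals)
    return FitResult(
        model_tag=model_tag,
        params=params,
        residuals=residuals,
        rmse=float(np.sqrt(sse / len(profile))),
        sse=sse,
        converged=bool(best.success),
        n_points=len(profile),
        initial_guess=guess,
        n_restarts=min(n_restarts, options.max_restarts),
    )
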