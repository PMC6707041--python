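"""Monte Carlo RMSE-propagation confidence intervals.

The uncertainty procedure is a parametric-bootstrap variant: on each
iteration, iid Gaussian noise with standard deviation equal to the point
fit's RMSE is added to the *observed* concentrations, the perturbed
profile is refit (initialized at the point estimate), and the
canonicalized parameters together with their analytic AUC are recorded.
Percentile confidence intervals are read off the empirical distribution
of the retained draws.  AUC (and C_MAX for the IM route) uncertainty is
full nonlinear propagation — the derived quantity is evaluated on every
parameter draw, not reconstructed from parameter intervals.

Quantile convention: linear interpolation between order statistics
(Hyndman–Fan type 7, numpy's default), fixed for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

import numpy as np
import pandas as pd

from .fitting import FitOptions, FitResult, fit_profile
from .pk_models import PKParamsIM, PKParamsIV, PKProfile, auc_analytic, cmax_im, tmax_im

__all__ = ["MCResult", "mc_propagate", "percentile_ci", "precision_fold"]


def percentile_ci(draws, level: float) -> tuple[float, float]:
    """Empirical percentile interval at the given confidence level (%).

    Uses linear interpolation between order statistics (type 7); invariant
    under permutation of the draws.  Requires at least 20 draws and
    0 < level < 100.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size < 20:
        raise ValueError(f"need >= 20 draws for a percentile interval, got {draws.size}")
    if not (0 < level < 100):
        raise ValueError(f"confidence level must be in (0, 100), got {level}")
    tail = (1 - level / 100) / 2
    lo, hi = np.quantile(draws, [tail, 1 - tail], method="linear")
    return float(lo), float(hi)


@dataclass(frozen=True)
class MCResult:
    """Monte Carlo parameter/AUC distributions and their percentile CIs."""

    point: FitResult
    draws: dict[str, np.ndarray]  # quantity -> retained per-iteration values
    ci: dict[str, tuple[float, float]]
    level: float
    n_iter: int
    n_failed: int
    seed: int | None

    @property
    def n_retained(self) -> int:
        return self.n_iter - self.n_failed

    def width(self, quantity: str) -> float:
        lo, hi = self.ci[quantity]
        return hi - lo

    def sd(self, quantity: str) -> float:
        """Standard deviation of the draw distribution (reported alongside
        the percentile CI; the two agree only for symmetric distributions)."""
        return float(np.std(self.draws[quantity], ddof=1))

    def point_value(self, quantity: str) -> float:
        return _quantities(self.point.params)[quantity]

    def to_frame(self) -> pd.DataFrame:
        """One row per quantity: point, lower, upper, sd, bookkeeping."""
        rows = []
        pt = _quantities(self.point.params)
        for q in self.draws:
            lo, hi = self.ci[q]
            rows.append(
                {
                    "quantity": q,
                    "point": pt[q],
                    "lower": lo,
                    "upper": hi,
                    "sd": self.sd(q),
                    "level_pct": self.level,
                    "n_iter": self.n_iter,
                    "n_failed": self.n_failed,
                    "seed": self.seed,
                }
            )
        return pd.DataFrame(rows)


def _quantities(params: PKParamsIV | PKParamsIM) -> dict[str, float]:
    """Scalar quantities tracked per draw for a parameter set."""
    if isinstance(params, PKParamsIM):
        return {
            "amplitude": params.amplitude,
            "gamma": params.gamma,
            "beta": params.beta,
            "cmax": cmax_im(params),
            "tmax": tmax_im(params),
            "auc": auc_analytic(params),
        }
    return {
        "A": params.A,
        "B": params.B,
        "alpha": params.alpha,
        "beta": params.beta,
        "auc": auc_analytic(params),
    }


def mc_propagate(
    profile: PKProfile,
    fit: FitResult,
    n_iter: int = 5000,
    level: float = 95.0,
    seed: int | None = None,
    fit_options: FitOptions | None = None,
) -> MCResult:
    """Propagate the fit RMSE through the data by refitting noisy replicas.

    Each iteration adds iid N(0, rmse²) noise to the observed
    concentrations and refits from the point-estimate parameters.  Failed
    or non-converged refits are dropped and counted; more than 20% failures
    raises.  Fully reproducible given ``seed``.
    """
    if not fit.converged:
        raise ValueError("cannot propagate uncertainty from a non-converged fit")
    if n_iter < 100:
        raise ValueError(f"n_iter must be >= 100, got {n_iter}")
    if not (0 < level < 100):
        raise ValueError(f"confidence level must be in (0, 100), got {level}")

    rng = np.random.default_rng(seed)
    init = {k: float(v) for k, v in _params_as_dict(fit.params).items()}
    # one restart is enough when starting at the optimum of the unperturbed fit
    opts = fit_options or FitOptions(max_restarts=1)

    keys = list(_quantities(fit.params))
    draws: dict[str, list[float]] = {k: [] for k in keys}
    n_failed = 0
    t, c = profile.times, profile.concentrations
    for _ in range(n_iter):
        noisy = c + rng.normal(0.0, fit.rmse, size=c.size) if fit.rmse > 0 else c
        try:
            refit = fit_profile(
                PKProfile(t, noisy, profile.subject_id), fit.model_tag, init=init, options=opts
            )
        except ValueError:
            n_failed += 1
            continue
        if not refit.converged:
            n_failed += 1
            continue
        for k, v in _quantities(refit.params).items():
            draws[k].append(v)

    if n_failed > 0.2 * n_iter:
        raise RuntimeError(
            f"Monte Carlo propagation unstable: {n_failed}/{n_iter} refits failed"
        )
    arr = {k: np.asarray(v) for k, v in draws.items()}
    ci = {k: percentile_ci(v, level) for k, v in arr.items()}
    return MCResult(
        point=fit, draws=arr, ci=ci, level=level, n_iter=n_iter, n_failed=n_failed, seed=seed
    )


def _params_as_dict(params: PKParamsIV | PKParamsIM) -> dict[str, float]:
    if isinstance(params, PKParamsIM):
        return {"amplitude": params.amplitude, "gamma": params.gamma, "beta": params.beta}
    return {"A": params.A, "B": params.B, "alpha": params.alpha, "beta": params.beta}


def precision_fold(mc_a: MCResult, mc_b: MCResult, quantity: str) -> float:
    """How many-fold narrower ``mc_a``'s interval is than ``mc_b``'s.

    Returns CI-width(b) / CI-width(a); > 1 means design *a* is the more
    precise one for this quantity.
    """
    if quantity not in mc_a.ci or quantity not in mc_b.ci:
        raise KeyError(f"quantity {quantity!r} not present in both results")
    wa = mc_a.width(quantity)
    if wa == 0:
        raise ZeroDivisionError(f"zero-width reference interval for {quantity!r}")
    return mc_b.width(quantity) / wa
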