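"""Sigmoid dose-response trajectory model.

A phenomenological surrogate for the score response to daily drug dose:

    dS/dt = beta * (Y(t)/Y_max) * S  +  alpha * S * (S_capacity - S)

The second term is logistic deterioration without treatment: the score grows
toward the carrying capacity ``S_capacity`` (an indicator of disease
severity) at rate ``alpha``. The first term is the drug effect at dose Y(t)
relative to the protocol ceiling ``Y_max``; with the sign convention used
here a beneficial drug has ``beta <= 0``, so dosing pulls the score down,
with |beta| setting how quickly the effect is observed. The model enforces
dose saturation (the drug term cannot exceed beta*S at Y = Y_max) but makes
no claim about the underlying autoimmune biology.

For constant dose y the fixed points are S = 0 and

    S* = S_capacity + (beta/alpha) * (y/Y_max),

stable when the local derivative of dS/dt is negative. (A commonly quoted
shorthand S_capacity - beta*y/Y_max coincides with S* only under an alpha=1
convention; :func:`equilibrium` reports both forms.)

Fitting follows the statsmodels pattern: build a
:class:`SigmoidDoseResponse` model from observed score and dose
trajectories, call :meth:`~SigmoidDoseResponse.fit`, and read estimates,
residuals and a summary table off the returned :class:`SigmoidFitResult`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import minimize

from .preprocess import GridSpec, UniformTrajectory

__all__ = ["SigmoidParams", "simulate", "equilibrium",
           "SigmoidDoseResponse", "SigmoidFitResult", "fit"]

RK4_STEP_WEEKS = 0.5


@dataclass(frozen=True)
class SigmoidParams:
    """(alpha, beta, S_capacity, Y_max); rates are per week, dose in mg/day."""

    alpha: float
    beta: float
    s_capacity: float
    y_max: float

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.s_capacity <= 0:
            raise ValueError("s_capacity must be positive")
        if self.y_max <= 0:
            raise ValueError("y_max must be positive")


def _rhs(p: SigmoidParams, s: float, y: float) -> float:
    return p.beta * (y / p.y_max) * s + p.alpha * s * (p.s_capacity - s)


def simulate(
    params: SigmoidParams,
    dose_fn: Callable[[float], float],
    s0: float,
    grid: GridSpec,
    step_weeks: float = RK4_STEP_WEEKS,
    patient_id: str = "sim",
) -> UniformTrajectory:
    """Integrate the ODE with fixed-step RK4 and sample onto ``grid``.

    Integration starts at the grid origin with S(start) = s0. Small negative
    undershoot (within 1e-9) is clipped to zero; anything worse, or a
    non-finite state, raises with advice to reduce the step.
    """
    if s0 < 0:
        raise ValueError("s0 must be nonnegative")
    t0, t1 = grid.start_week, grid.end_week
    n_steps = int(np.ceil((t1 - t0) / step_weeks))
    ts = t0 + np.arange(n_steps + 1) * step_weeks
    ts[-1] = t1
    ss = np.empty(n_steps + 1)
    ss[0] = s0
    s = s0
    for i in range(n_steps):
        t, h = ts[i], ts[i + 1] - ts[i]
        k1 = _rhs(params, s, dose_fn(t))
        k2 = _rhs(params, s + h / 2 * k1, dose_fn(t + h / 2))
        k3 = _rhs(params, s + h / 2 * k2, dose_fn(t + h / 2))
        k4 = _rhs(params, s + h * k3, dose_fn(t + h))
        s = s + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.isfinite(s):
            raise FloatingPointError(
                "integration diverged (non-finite state); reduce step_weeks"
            )
        if s < 0:
            if s < -1e-9:
                raise FloatingPointError(
                    "integration undershot zero; reduce step_weeks"
                )
            s = 0.0
        ss[i + 1] = s
    vals = np.interp(grid.weeks(), ts, ss)
    return UniformTrajectory(patient_id, "score_sim", grid, vals,
                             np.ones(grid.n_points, dtype=bool))


def equilibrium(params: SigmoidParams, y_const: float) -> dict:
    """Fixed points of the ODE at constant dose, with stability.

    Returns S = 0 and S* = S_capacity + (beta/alpha)*(y/Y_max), each tagged
    stable/unstable by the sign of d(dS/dt)/dS there, plus the alpha=1
    shorthand ``shorthand_equilibrium`` = S_capacity - beta*y/Y_max for
    comparison.
    """
    if y_const < 0:
        raise ValueError("dose must be nonnegative")
    p = params
    s_star = p.s_capacity + (p.beta / p.alpha) * (y_const / p.y_max)

    def dfds(s: float) -> float:
        return p.beta * y_const / p.y_max + p.alpha * (p.s_capacity - 2 * s)

    fixed_points = [
        {"s": 0.0, "stable": dfds(0.0) < 0},
        {"s": float(s_star), "stable": dfds(s_star) < 0},
    ]
    stable = [fp["s"] for fp in fixed_points if fp["stable"]]
    return {
        "fixed_points": fixed_points,
        "stable_point": stable[0] if stable else None,
        "shorthand_equilibrium": float(p.s_capacity - p.beta * y_const / p.y_max),
    }


class SigmoidDoseResponse:
    """Model: one observed score trajectory driven by one dose trajectory.

    ``y_max`` is fixed from the protocol ceiling, never fitted — it is a
    known property of the trial, and letting it float would trade off
    degenerately against beta.
    """

    def __init__(self, observed: UniformTrajectory, dose: UniformTrajectory,
                 y_max: float):
        if observed.grid != dose.grid:
            raise ValueError("observed and dose must share a grid")
        self.observed = observed
        self.dose = dose
        self.y_max = float(y_max)
        w = dose.grid.weeks()
        self.dose_fn = lambda t: float(np.interp(t, w, dose.values))

    def _predict(self, alpha: float, beta: float, s_cap: float) -> np.ndarray:
        p = SigmoidParams(alpha, beta, s_cap, self.y_max)
        return simulate(p, self.dose_fn, self.observed.values[0],
                        self.observed.grid).values

    def fit(
        self,
        init: SigmoidParams | None = None,
        bounds: dict | None = None,
        n_starts: int = 8,
        seed: int = 0,
    ) -> "SigmoidFitResult":
        """Bounded multi-start least squares over (alpha, beta, s_capacity).

        Starts are drawn log-uniform (rates) / uniform (capacity) inside the
        bounds, plus ``init`` when given; the best local optimum wins. A
        constant-zero observed series is flagged degenerate (the S = 0 orbit
        carries no parameter information) instead of being fitted.
        """
        obs = self.observed.values
        if np.allclose(obs, 0):
            return SigmoidFitResult(self, None, rss=0.0, degenerate=True,
                                    n_starts=0)
        b = {"alpha": (1e-4, 1.0), "beta": (-5.0, 0.0),
             "s_capacity": (1e-2, 60.0), **(bounds or {})}
        lo = np.array([b["alpha"][0], b["beta"][0], b["s_capacity"][0]])
        hi = np.array([b["alpha"][1], b["beta"][1], b["s_capacity"][1]])

        def objective(theta: np.ndarray) -> float:
            a, be, sc = theta
            try:
                pred = self._predict(a, be, sc)
            except FloatingPointError:
                return 1e12  # finite penalty keeps numeric gradients usable
            return float(np.sum((pred - obs) ** 2))

        rng = np.random.default_rng(seed)
        starts = []
        if init is not None:
            starts.append(np.array([init.alpha, init.beta, init.s_capacity]))
        while len(starts) < n_starts:
            # draw starts from the plausible (non-stiff) core of the box
            a = np.exp(rng.uniform(np.log(max(lo[0], 1e-3)),
                                   np.log(min(hi[0], 0.5))))
            be = rng.uniform(max(lo[1], -2.0), hi[1])
            sc = rng.uniform(max(lo[2], obs.max() * 0.5), max(hi[2], obs.max()))
            starts.append(np.array([a, be, min(sc, hi[2])]))

        best, best_obj = None, np.inf
        for x0 in starts:
            if objective(x0) >= 1e12:
                continue
            res = minimize(objective, x0, method="L-BFGS-B",
                           bounds=list(zip(lo, hi)))
            if res.fun < best_obj:
                best, best_obj = res.x, float(res.fun)
        if best is None:
            raise RuntimeError("no start produced a finite objective")
        params = SigmoidParams(best[0], best[1], best[2], self.y_max)
        return SigmoidFitResult(self, params, rss=best_obj,
                                degenerate=False, n_starts=len(starts))


@dataclass
class SigmoidFitResult:
    model: SigmoidDoseResponse
    params: SigmoidParams | None
    rss: float
    degenerate: bool
    n_starts: int

    def fittedvalues(self) -> np.ndarray:
        if self.params is None:
            return np.zeros_like(self.model.observed.values)
        return self.model._predict(self.params.alpha, self.params.beta,
                                   self.params.s_capacity)

    def resid(self) -> np.ndarray:
        return self.model.observed.values - self.fittedvalues()

    def summary(self) -> str:
        lines = ["Sigmoid dose-response fit", "=" * 34]
        if self.degenerate:
            lines.append("degenerate: observed score is identically zero "
                         "(S=0 orbit); no parameters estimated")
            return "\n".join(lines)
        p = self.params
        n = len(self.model.observed.values)
        lines += [
            f"alpha       {p.alpha:12.6f}  /week",
            f"beta        {p.beta:12.6f}  /week",
            f"s_capacity  {p.s_capacity:12.6f}  score units",
            f"y_max       {p.y_max:12.6f}  mg/day (fixed)",
            f"RSS         {self.rss:12.6f}  ({n} points, {self.n_starts} starts)",
        ]
        return "\n".join(lines)


def fit(
    observed: UniformTrajectory,
    dose: UniformTrajectory,
    init: SigmoidParams | None = None,
    bounds: dict | None = None,
    y_max: float | None = None,
    n_starts: int = 8,
    seed: int = 0,
) -> tuple[SigmoidParams | None, float]:
    """Functional wrapper: returns (params, rss). ``y_max`` defaults to the
    init's value and must come from the protocol, not the data."""
    if y_max is None:
        if init is None:
            raise ValueError("provide y_max or an init carrying it")
        y_max = init.y_max
    result = SigmoidDoseResponse(observed, dose, y_max).fit(
        init=init, bounds=bounds, n_starts=n_starts, seed=seed
    )
    return result.params, result.rss
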