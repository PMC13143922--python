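"""Projection of irregular visit series onto a uniform week grid.

Linear interpolation is used deliberately: it obeys a maximum principle (an
interpolated value is bounded by its two bracketing observations), so visit-
level scoring noise is never amplified. Patients whose records leave gaps too
wide to interpolate credibly are excluded rather than imputed. Optional
denoising is a centred moving average confined to segments between singular
events (hospitalisation or rescue therapy legitimately produces a step in the
trajectory, which the filter must not smear). Dose trajectories can be
normalised per patient by total cumulative dose so that subjects with very
different corticosteroid sensitivity become comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Cohort, WEEKS_PER_MONTH

__all__ = [
    "GridSpec", "UniformTrajectory", "ExclusionReport",
    "to_uniform_grid", "smooth", "normalize_control", "default_grid",
]


@dataclass(frozen=True)
class GridSpec:
    """Uniform time grid: [start_week, end_week] with step_weeks spacing."""

    start_week: float
    end_week: float
    step_weeks: float

    def __post_init__(self):
        if not self.start_week < self.end_week:
            raise ValueError("start_week must be < end_week")
        if self.step_weeks <= 0:
            raise ValueError("step_weeks must be positive")
        n = (self.end_week - self.start_week) / self.step_weeks
        if abs(n - round(n)) > 1e-8:
            raise ValueError("(end-start)/step must be integral")

    @property
    def n_points(self) -> int:
        return int(round((self.end_week - self.start_week) / self.step_weeks)) + 1

    def weeks(self) -> np.ndarray:
        return self.start_week + self.step_weeks * np.arange(self.n_points)


def default_grid() -> GridSpec:
    """Weeks 10 to 140 at monthly (13/3-week) spacing, 31 points.

    The first ten weeks of follow-up are the forced dose-escalation period and
    carry no patient-specific pattern, so analysis starts at week 10.
    """
    return GridSpec(10.0, 140.0, WEEKS_PER_MONTH)


@dataclass
class UniformTrajectory:
    """One patient's one variable resampled onto a uniform grid."""

    patient_id: str
    variable: str
    grid: GridSpec
    values: np.ndarray
    interpolated_mask: np.ndarray  # True where the grid point had no visit

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.interpolated_mask = np.asarray(self.interpolated_mask, dtype=bool)
        if len(self.values) != self.grid.n_points:
            raise ValueError("values length must match grid")
        if len(self.interpolated_mask) != self.grid.n_points:
            raise ValueError("mask length must match grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trajectory must be fully filled")


@dataclass
class ExclusionReport:
    excluded: list[tuple[str, str, float]] = field(default_factory=list)
    retained_count: int = 0


def to_uniform_grid(
    cohort: Cohort,
    variable: str,
    grid: GridSpec | None = None,
    max_gap_weeks: float = 26.0,
) -> tuple[list[UniformTrajectory], ExclusionReport]:
    """Linearly interpolate each patient's series onto ``grid``.

    A patient is excluded (with a reason) when observations do not cover the
    grid span or when any inter-visit gap intersecting the span exceeds
    ``max_gap_weeks`` (default: two missed quarterly visits). Raises if no
    patient survives.
    """
    if grid is None:
        grid = default_grid()
    gw = grid.weeks()
    report = ExclusionReport()
    out: list[UniformTrajectory] = []
    for p in cohort.patients:
        weeks, vals = p.weeks(variable), p.values(variable)
        if len(weeks) < 2:
            report.excluded.append((p.patient_id, "fewer than 2 observations", np.inf))
            continue
        if weeks[0] > grid.start_week + 1e-9 or weeks[-1] < grid.end_week - 1e-9:
            report.excluded.append((p.patient_id, "does not cover grid span",
                                    float(np.max(np.diff(weeks)))))
            continue
        gaps = np.diff(weeks)
        # only gaps that intersect the analysis window matter
        in_span = (weeks[1:] > grid.start_week + 1e-9) & (weeks[:-1] < grid.end_week - 1e-9)
        largest = float(gaps[in_span].max()) if in_span.any() else 0.0
        if largest > max_gap_weeks + 1e-9:
            report.excluded.append((p.patient_id, "gap exceeds max_gap_weeks", largest))
            continue
        interp = np.interp(gw, weeks, vals)
        observed = np.isclose(gw[:, None], weeks[None, :], rtol=0, atol=1e-9).any(axis=1)
        out.append(UniformTrajectory(p.patient_id, variable, grid, interp, ~observed))
    report.retained_count = len(out)
    if not out:
        raise ValueError(f"no analyzable patients for variable {variable!r}")
    return out, report


def smooth(
    traj: UniformTrajectory,
    window: int = 3,
    event_weeks: list[float] | None = None,
) -> UniformTrajectory:
    """Centred moving average that never crosses an event boundary.

    Events split the grid into segments; within each segment a centred window
    of ``window`` points is used, shrunk symmetrically near segment edges, so
    genuine steps at hospitalisation/rescue weeks are preserved.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    if window > traj.grid.n_points:
        raise ValueError("window exceeds trajectory length")
    gw = traj.grid.weeks()
    events = sorted(event_weeks or [])
    # segment id per grid point: increments at every event week
    seg = np.zeros(len(gw), dtype=int)
    for e in events:
        seg += gw >= e - 1e-9
    half = window // 2
    out = np.empty_like(traj.values)
    for s in np.unique(seg):
        idx = np.flatnonzero(seg == s)
        v = traj.values[idx]
        for i in range(len(v)):
            h = min(half, i, len(v) - 1 - i)  # shrink near edges
            out[idx[i]] = v[i - h : i + h + 1].mean()
    return UniformTrajectory(traj.patient_id, traj.variable, traj.grid,
                             out, traj.interpolated_mask.copy())


def normalize_control(traj: UniformTrajectory) -> UniformTrajectory:
    """Divide a dose trajectory by its cumulative total (trapezoid rule).

    Removes between-patient scale in drug exposure: the normalised trajectory
    integrates to one over the grid, so only the *shape* of dosing remains.
    """
    total = float(np.trapezoid(traj.values, traj.grid.weeks()))
    if total <= 0:
        raise ValueError("zero total control")
    return UniformTrajectory(traj.patient_id, traj.variable, traj.grid,
                             traj.values / total, traj.interpolated_mask.copy())


def trajectory_matrix(trajs: list[UniformTrajectory]) -> np.ndarray:
    """Stack trajectories (common grid required) into an (n, T) array."""
    if not trajs:
        raise ValueError("empty trajectory list")
    g0 = trajs[0].grid
    if any(t.grid != g0 for t in trajs):
        raise ValueError("trajectories are on mixed grids")
    return np.vstack([t.values for t in trajs])
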