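"""Trajectory predictability via greedy sphere covering.

Clustering assumes disease progression is not random; this module tests that
assumption directly. The transition operator that carries a patient's state
from one time block to the next is "continuous" when patients who start in
the same neighbourhood stay together. We therefore (1) slice trajectories
into overlapping temporal blocks (a block of k successive grid values, which
stabilises the comparison against visit-level fluctuation), (2) partition
each block's point cloud into spheres of radius D with a greedy
maximal-covering pass that always picks the densest remaining sphere
(patients in spheres below a minimum occupancy are "singular" — too rare to
support group prediction), and (3) measure the fraction of sphere members
that land inside the sphere of the same radius predicted at the next block.
That fraction, as a percentage pooled over all block transitions, is the
predictability index Ip: 100% means neighbourhoods map exactly onto
neighbourhoods (continuity modulus ~1); low values mean mean-trajectory
extrapolation is unreliable for this variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import UniformTrajectory, trajectory_matrix

__all__ = [
    "BlockSeries", "SphereCover", "PredictabilityReport",
    "make_blocks", "greedy_cover", "predictability_index",
    "partition_by_predictability", "default_sphere_radius",
]


@dataclass
class BlockSeries:
    """Sliding blocks of k successive grid values per patient."""

    block_length: int
    n_blocks: int
    ids: list[str]
    blocks: np.ndarray  # (n_patients, n_blocks, k)

    def at(self, j: int) -> dict[str, np.ndarray]:
        return {pid: self.blocks[i, j] for i, pid in enumerate(self.ids)}


@dataclass
class Sphere:
    center_id: str
    member_ids: list[str]


@dataclass
class SphereCover:
    spheres: list[Sphere]
    singular_ids: list[str]
    radius: float
    min_occupancy: int


@dataclass
class TransitionRecord:
    block_index: int
    center_id: str
    n_members: int
    n_retained: int
    escaped_ids: list[str]


@dataclass
class PredictabilityReport:
    ip: float  # percent in [0, 100]
    radius: float
    block_length: int
    min_occupancy: int
    transitions: list[TransitionRecord]
    singular_fraction: float
    escape_counts: dict[str, int] = field(default_factory=dict)
    transition_counts: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "Ip": self.ip,
            "D": self.radius,
            "k": self.block_length,
            "min_occupancy": self.min_occupancy,
            "singular_fraction": self.singular_fraction,
            "transitions": [
                {"block_index": t.block_index, "center": t.center_id,
                 "n_members": t.n_members, "n_retained": t.n_retained}
                for t in self.transitions
            ],
        }


def make_blocks(trajs: list[UniformTrajectory], k: int = 2) -> BlockSeries:
    """Overlapping length-k blocks; block distance is the Euclidean norm."""
    X = trajectory_matrix(trajs)
    T = X.shape[1]
    if not 1 <= k <= T:
        raise ValueError(f"block length {k} exceeds grid length {T}")
    n_blocks = T - k + 1
    blocks = np.stack([X[:, j : j + k] for j in range(n_blocks)], axis=1)
    return BlockSeries(block_length=k, n_blocks=n_blocks,
                       ids=[t.patient_id for t in trajs], blocks=blocks)


def greedy_cover(
    points: dict[str, np.ndarray], radius: float, min_occupancy: int = 1
) -> SphereCover:
    """Greedy maximal covering: repeatedly take the most populous D-ball.

    For every remaining point, count neighbours within ``radius``; the point
    with the largest count (ties: lexicographically smallest id) becomes a
    sphere centre and its ball is removed. Stops when the best remaining
    sphere would fall below ``min_occupancy``; leftovers are singular.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if min_occupancy < 1:
        raise ValueError("min_occupancy must be >= 1")
    ids = sorted(points)
    P = np.vstack([np.atleast_1d(np.asarray(points[i], dtype=float)) for i in ids])
    dist = np.linalg.norm(P[:, None, :] - P[None, :, :], axis=2)
    within = dist <= radius + 1e-12
    remaining = list(range(len(ids)))
    spheres: list[Sphere] = []
    while remaining:
        rem = np.array(remaining)
        counts = within[np.ix_(rem, rem)].sum(axis=1)
        best = int(counts.max())
        if best < min_occupancy:
            break
        # ties resolved by smallest id (ids are sorted, rem preserves order)
        center = rem[int(np.argmax(counts))]
        members = [i for i in remaining if within[center, i]]
        spheres.append(Sphere(center_id=ids[center],
                              member_ids=[ids[i] for i in members]))
        remaining = [i for i in remaining if i not in set(members)]
    spheres.sort(key=lambda s: (-len(s.member_ids), s.center_id))
    return SphereCover(spheres=spheres, singular_ids=[ids[i] for i in remaining],
                       radius=radius, min_occupancy=min_occupancy)


def default_sphere_radius(trajs: list[UniformTrajectory], block_length: int,
                          frac: float = 0.08) -> float:
    """Radius as a fraction of the variable's observed maximum.

    Scaled by sqrt(block length) so the per-coordinate tolerance stays the
    same when blocks widen. The 8%-of-maximum default mirrors the scale at
    which dose trajectories begin to form well-populated spheres.
    """
    vmax = max(float(np.max(np.abs(t.values))) for t in trajs)
    if vmax <= 0:
        raise ValueError("degenerate trajectories: zero maximum")
    return frac * vmax * np.sqrt(block_length)


def predictability_index(
    trajs: list[UniformTrajectory],
    radius: float | None = None,
    block_length: int = 2,
    min_occupancy: int = 10,
    predicted_center: str = "center",
) -> PredictabilityReport:
    """Compute the predictability index Ip over all block transitions.

    At each block index j the block vectors are covered greedily; each
    sphere's predicted position at j+1 is the ball of the same radius centred
    at the image of the sphere's centre trajectory (its next-block vector),
    and members falling inside it are "retained". Ip pools retained over
    members across every transition; singular patients enter neither
    numerator nor denominator.

    Centring the predicted sphere on the centre trajectory's image makes the
    index exact in the continuity-modulus-one limit: when the transition is
    an isometry (e.g. every trajectory constant in time), distances to the
    centre are preserved and Ip = 100 identically.
    ``predicted_center="mean"`` switches to the member-mean variant, which is
    more robust to an outlying centre but loses that exactness.
    """
    if predicted_center not in ("center", "mean"):
        raise ValueError("predicted_center must be 'center' or 'mean'")
    series = make_blocks(trajs, block_length)
    if series.n_blocks < 2:
        raise ValueError("need at least 2 block transitions")
    if radius is None:
        radius = default_sphere_radius(trajs, block_length)
    total_members = 0
    total_retained = 0
    n_singular = 0
    n_assignments = 0
    transitions: list[TransitionRecord] = []
    escape_counts = {pid: 0 for pid in series.ids}
    transition_counts = {pid: 0 for pid in series.ids}
    for j in range(series.n_blocks - 1):
        cover = greedy_cover(series.at(j), radius, min_occupancy)
        n_singular += len(cover.singular_ids)
        n_assignments += len(series.ids)
        nxt = series.at(j + 1)
        for sph in cover.spheres:
            next_vecs = np.vstack([nxt[m] for m in sph.member_ids])
            if predicted_center == "center":
                center = nxt[sph.center_id]
            else:
                center = next_vecs.mean(axis=0)
            inside = np.linalg.norm(next_vecs - center, axis=1) <= radius + 1e-12
            escaped = [m for m, ok in zip(sph.member_ids, inside) if not ok]
            for m in sph.member_ids:
                transition_counts[m] += 1
            for m in escaped:
                escape_counts[m] += 1
            transitions.append(TransitionRecord(
                block_index=j, center_id=sph.center_id,
                n_members=len(sph.member_ids), n_retained=int(inside.sum()),
                escaped_ids=escaped,
            ))
            total_members += len(sph.member_ids)
            total_retained += int(inside.sum())
    if total_members == 0:
        raise ValueError("cover too sparse; increase D or lower min_occupancy")
    return PredictabilityReport(
        ip=100.0 * total_retained / total_members,
        radius=float(radius), block_length=block_length,
        min_occupancy=min_occupancy, transitions=transitions,
        singular_fraction=n_singular / n_assignments,
        escape_counts=escape_counts, transition_counts=transition_counts,
    )


def partition_by_predictability(
    trajs: list[UniformTrajectory],
    report: PredictabilityReport,
    cohort=None,
    escape_frac: float = 0.5,
) -> tuple[list[str], list[str], "object"]:
    """Split patients into extrapolatable vs non-fitting.

    Non-fitting patients escape their predicted sphere in more than
    ``escape_frac`` of their counted transitions, or were singular at every
    transition. When a cohort is supplied, a covariate contrast table between
    the two groups is returned (else None), to mine for features that explain
    unpredictability.
    """
    non_fitting = []
    for pid in report.transition_counts:
        n_tr = report.transition_counts[pid]
        if n_tr == 0 or report.escape_counts[pid] > escape_frac * n_tr:
            non_fitting.append(pid)
    non_fitting = sorted(non_fitting)
    predictable = sorted(set(report.transition_counts) - set(non_fitting))
    contrast = None
    if cohort is not None:
        import pandas as pd

        rows = {}
        for name, ids in (("predictable", predictable), ("non_fitting", non_fitting)):
            recs = [cohort.get(p) for p in ids if p in cohort.patient_ids()]
            def _mean(vals):
                vals = [v for v in vals if v is not None]
                return float(np.mean(vals)) if vals else np.nan
            rows[name] = {
                "n": len(recs),
                "mean_age": _mean([r.age_years for r in recs]),
                "mean_bmi": _mean([r.bmi_kg_m2 for r in recs]),
                "pct_female": 100 * _mean([r.sex == "F" if r.sex else None for r in recs]),
                "pct_smokers": 100 * _mean([r.smoker for r in recs]),
                "pct_thymectomy": 100 * _mean([r.thymectomy for r in recs]),
            }
        contrast = pd.DataFrame(rows).T
    return predictable, non_fitting, contrast
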