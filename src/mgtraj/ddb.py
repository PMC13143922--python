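"""Drug-dosage boosts (DDBs) and cluster-specific score-response maps.

A DDB is a discrete escalation of the prednisone dose made in response to
clinical worsening. Isolating each boost and the score change that follows
it yields dynamic response samples — the "basic atoms" from which
cluster-specific dose-response maps are assembled. Ideally the score drops
after a boost; how often and by how much varies across the severity clusters,
and a new patient's observed responses can be checked for consistency with
their assigned cluster's map.

No causal claim is made: clinicians boosted doses *because* scores worsened,
so the maps are descriptive response summaries, not treatment effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import UniformTrajectory, smooth

__all__ = [
    "DoseBoost", "ResponseSample", "ClusterResponseMap", "SaturationMetrics",
    "detect_boosts", "score_response", "build_response_map",
    "saturation_metrics", "check_cluster_consistency", "patient_max_dose",
]


@dataclass
class DoseBoost:
    patient_id: str
    start_week: float
    magnitude: float  # mg/day increase over the pre-boost dose
    pre_dose: float
    sustained: bool
    step_weeks: list[float] = field(default_factory=list)  # contributing steps


@dataclass
class ResponseSample:
    boost: DoseBoost
    delta_s: float
    window_weeks: float


@dataclass
class ClusterResponseMap:
    samples: dict[int, list[ResponseSample]]
    summary: pd.DataFrame


@dataclass
class SaturationMetrics:
    per_patient: pd.DataFrame  # boost_count, fraction_near_max
    per_cluster: pd.DataFrame | None


def detect_boosts(
    dose_traj: UniformTrajectory,
    threshold_mg_day: float = 5.0,
    refractory_weeks: float = 4.0,
    sustain_weeks: float = 2.0,
) -> list[DoseBoost]:
    """Scan a uniform dose trajectory for step increases >= threshold.

    A step within ``refractory_weeks`` of the previous accepted boost is
    merged into it (its magnitude then measures the full rise above the
    original pre-boost dose). ``sustained`` records whether the dose stayed
    at least ``threshold`` above the pre-boost level for ``sustain_weeks``
    after onset. The default 5 mg/day threshold is one protocol escalation
    step (10 mg alternate-day).
    """
    v = dose_traj.values
    w = dose_traj.grid.weeks()
    boosts: list[DoseBoost] = []
    for i in range(1, len(v)):
        rise = v[i] - v[i - 1]
        if rise < threshold_mg_day - 1e-12:
            continue
        week = float(w[i])
        if boosts and week - boosts[-1].start_week <= refractory_weeks + 1e-12:
            b = boosts[-1]
            b.magnitude = float(v[i] - b.pre_dose)
            b.step_weeks.append(week)
            continue
        boosts.append(DoseBoost(
            patient_id=dose_traj.patient_id, start_week=week,
            magnitude=float(rise), pre_dose=float(v[i - 1]),
            sustained=False, step_weeks=[week],
        ))
    for b in boosts:
        hold = (w >= b.start_week - 1e-9) & (w <= b.start_week + sustain_weeks + 1e-9)
        b.sustained = bool(np.all(v[hold] >= b.pre_dose + threshold_mg_day - 1e-9))
    return boosts


def score_response(
    boost: DoseBoost,
    score_traj: UniformTrajectory,
    window_weeks: float = 8.0,
    use_smoothed: bool = True,
) -> ResponseSample | None:
    """Score change over the response window: S(start+window) - S(start).

    Negative delta_s means improvement. Uses the lightly smoothed score by
    default to damp visit-level noise. Returns None (a dropped sample) when
    the window overruns the grid.
    """
    traj = smooth(score_traj, 3) if use_smoothed else score_traj
    w = traj.grid.weeks()
    t_end = boost.start_week + window_weeks
    if t_end > w[-1] + 1e-9 or boost.start_week < w[0] - 1e-9:
        return None
    s0 = float(np.interp(boost.start_week, w, traj.values))
    s1 = float(np.interp(t_end, w, traj.values))
    return ResponseSample(boost=boost, delta_s=s1 - s0, window_weeks=window_weeks)


def build_response_map(
    samples: list[ResponseSample], labels: dict[str, int]
) -> ClusterResponseMap:
    """Group response samples by cluster and summarise each group."""
    by_cluster: dict[int, list[ResponseSample]] = {
        tag: [] for tag in sorted(set(labels.values()))
    }
    for s in samples:
        pid = s.boost.patient_id
        if pid not in labels:
            raise KeyError(f"sample patient {pid} has no cluster label")
        by_cluster.setdefault(labels[pid], []).append(s)
    rows = []
    for tag in sorted(by_cluster):
        ds = np.array([s.delta_s for s in by_cluster[tag]])
        rows.append({
            "cluster": tag,
            "n": len(ds),
            "mean_delta_s": float(ds.mean()) if len(ds) else 0.0,
            "sd_delta_s": float(ds.std(ddof=1)) if len(ds) > 1 else 0.0,
            "frac_improved": float((ds < 0).mean()) if len(ds) else 0.0,
        })
    return ClusterResponseMap(
        samples=by_cluster, summary=pd.DataFrame(rows).set_index("cluster")
    )


def patient_max_dose(weight_kg: float | None, prior_prednisone: bool | None) -> float:
    """Protocol ceiling in daily-equivalent mg/day.

    Alternate-day cap is min(100 mg, 1.5 mg/kg bodyweight), raised to 120 mg
    for patients already on prednisone at entry; daily-equivalent is half.
    """
    if prior_prednisone:
        return 120.0 / 2.0
    if weight_kg is None:
        return 100.0 / 2.0
    return min(100.0, 1.5 * weight_kg) / 2.0


def saturation_metrics(
    dose_trajs: list[UniformTrajectory],
    max_dose: dict[str, float],
    near_fraction: float = 0.9,
    labels: dict[str, int] | None = None,
    threshold_mg_day: float = 5.0,
) -> SaturationMetrics:
    """Boost counts and fraction of the timeline spent near the dose ceiling.

    "Near" means dose >= near_fraction * the patient's protocol maximum. A
    patient pinned at the ceiling has little room left for further boosts, so
    a high fraction flags saturation of the dosing strategy.
    """
    rows = []
    for t in dose_trajs:
        cap = max_dose[t.patient_id]
        if cap <= 0:
            raise ValueError(f"max dose must be positive for {t.patient_id}")
        frac = float(np.mean(t.values >= near_fraction * cap - 1e-12))
        rows.append({
            "patient_id": t.patient_id,
            "boost_count": len(detect_boosts(t, threshold_mg_day)),
            "fraction_near_max": frac,
        })
    per_patient = pd.DataFrame(rows).set_index("patient_id")
    per_cluster = None
    if labels is not None:
        per_patient["cluster"] = [labels[p] for p in per_patient.index]
        per_cluster = per_patient.groupby("cluster")[
            ["boost_count", "fraction_near_max"]
        ].mean()
    return SaturationMetrics(per_patient=per_patient, per_cluster=per_cluster)


def check_cluster_consistency(
    patient_samples: list[ResponseSample],
    response_map: ClusterResponseMap,
    cluster: int,
    z_bound: float = 2.0,
) -> tuple[bool | None, list[float]]:
    """Are a patient's boost responses compatible with a cluster's map?

    Each delta_s becomes a z-score against the cluster summary; consistent
    iff every |z| <= z_bound (closed bound). Returns (None, []) when the
    cluster summary is degenerate (n < 3 or zero SD) — indeterminate.
    """
    row = response_map.summary.loc[cluster]
    if row["n"] < 3 or row["sd_delta_s"] <= 0:
        return None, []
    z = [(s.delta_s - row["mean_delta_s"]) / row["sd_delta_s"]
         for s in patient_samples]
    return all(abs(zi) <= z_bound + 1e-12 for zi in z), z
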