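"""K-Medoids (PAM) clustering of trajectories on a DTW distance matrix.

PAM is used rather than K-means because the cluster centre is an actual
patient trajectory (the medoid), which keeps the result interpretable and
robust to outliers, and because it only needs a distance matrix — so DTW can
drive it directly. The implementation is the classical deterministic
BUILD + SWAP algorithm: identical inputs always give identical labels.

Validation helpers (silhouette, Davies-Bouldin, Dunn, Calinski-Harabasz),
outcome-ordered relabelling, mean +/- SD cluster strips, cross-tabulations,
covariate profiles, new-patient assignment and treatment-failure summaries
round out the module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import calinski_harabasz_score, silhouette_samples

from .distance import DistanceMatrix, dtw_distance
from .io import Cohort
from .preprocess import UniformTrajectory, trajectory_matrix

__all__ = [
    "ClusterModel", "SilhouetteReport", "SeparationIndices", "ClusterStrip",
    "pam_cluster", "silhouette", "separation_indices", "select_k",
    "order_clusters_by_outcome", "cluster_strips", "cross_tab",
    "assign_new_patient", "cluster_covariate_profile",
    "treatment_failure_summary",
]


@dataclass
class ClusterModel:
    """A k-medoids partition; tags run 1..k."""

    k: int
    medoid_ids: list[str]
    labels: dict[str, int]
    objective: float

    def __post_init__(self):
        tags = set(self.labels.values())
        if tags != set(range(1, self.k + 1)):
            raise ValueError("cluster tags must be exactly 1..k, all non-empty")
        for tag, mid in enumerate(self.medoid_ids, start=1):
            if self.labels[mid] != tag:
                raise ValueError(f"medoid {mid} not labelled with its own cluster")

    def members(self, tag: int) -> list[str]:
        return [pid for pid, t in self.labels.items() if t == tag]

    def sizes(self) -> dict[int, int]:
        return {t: len(self.members(t)) for t in range(1, self.k + 1)}


@dataclass
class SilhouetteReport:
    values: dict[str, float]
    per_cluster_mean: dict[int, float]
    overall_mean: float
    negative_ids: list[str]


@dataclass
class SeparationIndices:
    davies_bouldin: float
    calinski_harabasz: float
    dunn: float


@dataclass
class ClusterStrip:
    tag: int
    mean: np.ndarray
    sd: np.ndarray


def _check_matrix(D: DistanceMatrix) -> np.ndarray:
    M = np.asarray(D.values, dtype=float)
    if not np.allclose(M, M.T):
        raise ValueError("distance matrix must be symmetric")
    return M


def _assign(M: np.ndarray, medoids: list[int]) -> tuple[np.ndarray, float]:
    sub = M[:, medoids]
    nearest = np.argmin(sub, axis=1)
    return nearest, float(sub[np.arange(len(M)), nearest].sum())


def _swap_descent(M: np.ndarray, medoids: list[int]) -> tuple[list[int], float]:
    """SWAP phase: repeat the single best improving exchange to convergence.

    The objective is asserted non-increasing at every accepted swap.
    """
    n = len(M)
    medoids = list(medoids)
    _, obj = _assign(M, medoids)
    improved = True
    while improved:
        improved = False
        best = (0.0, None)
        for mi, _m in enumerate(medoids):
            for c in range(n):
                if c in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = c
                _, t_obj = _assign(M, trial)
                delta = t_obj - obj
                if delta < best[0] - 1e-12:
                    best = (delta, (mi, c))
        if best[1] is not None:
            mi, c = best[1]
            medoids[mi] = c
            _, new_obj = _assign(M, medoids)
            assert new_obj <= obj + 1e-9, "SWAP must not increase the objective"
            obj = new_obj
            improved = True
    return medoids, obj


def pam_cluster(D: DistanceMatrix, k: int, seed: int = 0,
                n_restarts: int = 4) -> ClusterModel:
    """Partitioning Around Medoids: greedy BUILD then best-improvement SWAP.

    The deterministic BUILD start is supplemented by ``n_restarts`` seeded
    random medoid initialisations (SWAP descent escapes most, but not all,
    local optima from a single start); the best objective wins. The result is
    fully deterministic given (D, k, seed), so repeated runs reproduce the
    same partition.
    """
    M = _check_matrix(D)
    n = len(M)
    if not 2 <= k < n:
        raise ValueError(f"need 2 <= k < n, got k={k}, n={n}")

    # BUILD: first medoid minimises total distance; then greedy additions
    medoids = [int(np.argmin(M.sum(axis=1)))]
    while len(medoids) < k:
        current = M[:, medoids].min(axis=1)
        gains = np.array([
            np.maximum(current - M[:, c], 0.0).sum() if c not in medoids else -np.inf
            for c in range(n)
        ])
        medoids.append(int(np.argmax(gains)))

    medoids, obj = _swap_descent(M, medoids)
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        start = rng.choice(n, size=k, replace=False).tolist()
        cand, cand_obj = _swap_descent(M, start)
        if cand_obj < obj - 1e-12:
            medoids, obj = cand, cand_obj

    medoids = sorted(medoids)
    nearest, obj = _assign(M, medoids)
    labels = {D.ids[i]: int(nearest[i]) + 1 for i in range(n)}
    # medoids always belong to their own cluster (distance 0, ties broken by
    # argmin order); enforce explicitly for zero-distance duplicate medoids
    for tag, m in enumerate(medoids, start=1):
        labels[D.ids[m]] = tag
    return ClusterModel(k=k, medoid_ids=[D.ids[m] for m in medoids],
                        labels=labels, objective=obj)


def silhouette(D: DistanceMatrix, labels: dict[str, int]) -> SilhouetteReport:
    """Silhouette widths computed from the (DTW) distance matrix."""
    M = _check_matrix(D)
    lab = np.array([labels[i] for i in D.ids])
    if len(set(lab)) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    s = silhouette_samples(M, lab, metric="precomputed")
    values = {pid: float(si) for pid, si in zip(D.ids, s)}
    per_cluster = {int(t): float(s[lab == t].mean()) for t in np.unique(lab)}
    return SilhouetteReport(
        values=values,
        per_cluster_mean=per_cluster,
        overall_mean=float(s.mean()),
        negative_ids=[pid for pid, si in values.items() if si < 0],
    )


def separation_indices(
    trajs: list[UniformTrajectory], D: DistanceMatrix, labels: dict[str, int]
) -> SeparationIndices:
    """Davies-Bouldin and Dunn from the DTW matrix (medoid centres);
    Calinski-Harabasz on grid-aligned value vectors (needs centroids)."""
    M = _check_matrix(D)
    lab = np.array([labels[i] for i in D.ids])
    tags = np.unique(lab)
    if len(tags) < 2:
        raise ValueError("need at least 2 clusters")

    # medoid of each cluster: member minimising total within-cluster distance
    medoid_idx, scatter = {}, {}
    for t in tags:
        idx = np.flatnonzero(lab == t)
        within = M[np.ix_(idx, idx)]
        m = idx[int(np.argmin(within.sum(axis=1)))]
        medoid_idx[t] = m
        scatter[t] = float(M[idx, m].mean())

    db_terms = []
    for t in tags:
        ratios = [
            (scatter[t] + scatter[u]) / M[medoid_idx[t], medoid_idx[u]]
            for u in tags if u != t and M[medoid_idx[t], medoid_idx[u]] > 0
        ]
        db_terms.append(max(ratios) if ratios else 0.0)
    davies_bouldin = float(np.mean(db_terms))

    inter = np.inf
    intra = 0.0
    for t in tags:
        idx = np.flatnonzero(lab == t)
        if len(idx) > 1:
            intra = max(intra, float(M[np.ix_(idx, idx)].max()))
        for u in tags:
            if u > t:
                jdx = np.flatnonzero(lab == u)
                inter = min(inter, float(M[np.ix_(idx, jdx)].min()))
    dunn = float(np.inf) if intra == 0 else float(inter / intra)

    order = {pid: i for i, pid in enumerate(D.ids)}
    X = trajectory_matrix(sorted(trajs, key=lambda t: order[t.patient_id]))
    ch = float(calinski_harabasz_score(X, lab))
    return SeparationIndices(davies_bouldin, ch, dunn)


def select_k(
    D: DistanceMatrix,
    k_range: range | list[int],
    seed: int = 0,
    negative_cap_frac: float = 0.05,
    sil_tolerance: float = 0.1,
) -> tuple[int, pd.DataFrame]:
    """Choose the largest k that still separates well.

    A candidate k qualifies when its negative-silhouette count is at most
    ``negative_cap_frac`` of n and its mean silhouette is within
    ``sil_tolerance`` of the best mean over the range; the largest qualifying
    k wins. The full per-k table is returned for transparency, with a
    ``warning`` flag set when nothing separates (all mean silhouettes weak).
    """
    n = len(D)
    rows = []
    for k in k_range:
        model = pam_cluster(D, k, seed)
        rep = silhouette(D, model.labels)
        rows.append({"k": k, "mean_silhouette": rep.overall_mean,
                     "n_negative": len(rep.negative_ids),
                     "objective": model.objective})
    table = pd.DataFrame(rows)
    best_sil = table["mean_silhouette"].max()
    ok = (table["n_negative"] <= negative_cap_frac * n) & (
        table["mean_silhouette"] >= best_sil - sil_tolerance
    )
    table["qualifies"] = ok
    table["warning"] = best_sil < 0.25  # no real separation anywhere
    if ok.any():
        k_best = int(table.loc[ok, "k"].max())
    else:
        k_best = int(table.loc[table["mean_silhouette"].idxmax(), "k"])
    return k_best, table


def order_clusters_by_outcome(
    model: ClusterModel, trajs: list[UniformTrajectory]
) -> ClusterModel:
    """Permute tags so cluster 1 has the lowest time-averaged trajectory.

    Lower dose or lower score means a better outcome, so tag 1 is the best
    performing group, ascending to the worst. Ties break by size descending.
    """
    by_id = {t.patient_id: t for t in trajs}
    stats = []
    for tag in range(1, model.k + 1):
        members = model.members(tag)
        means = [float(np.mean(by_id[m].values)) for m in members]
        stats.append((float(np.mean(means)), -len(members), tag))
    old_order = [tag for _, _, tag in sorted(stats)]
    remap = {old: new for new, old in enumerate(old_order, start=1)}
    new_labels = {pid: remap[t] for pid, t in model.labels.items()}
    new_medoids = [None] * model.k
    for old_tag, mid in enumerate(model.medoid_ids, start=1):
        new_medoids[remap[old_tag] - 1] = mid
    return ClusterModel(k=model.k, medoid_ids=new_medoids,
                        labels=new_labels, objective=model.objective)


def cluster_strips(
    trajs: list[UniformTrajectory], labels: dict[str, int]
) -> list[ClusterStrip]:
    """Pointwise mean and sample SD per cluster (singletons report SD 0)."""
    by_id = {t.patient_id: t for t in trajs}
    strips = []
    for tag in sorted(set(labels.values())):
        members = [by_id[p] for p in labels if labels[p] == tag and p in by_id]
        X = trajectory_matrix(members)
        sd = X.std(axis=0, ddof=1) if len(members) > 1 else np.zeros(X.shape[1])
        strips.append(ClusterStrip(tag=tag, mean=X.mean(axis=0), sd=sd))
    return strips


def cross_tab(labelsA: dict[str, int], labelsB: dict[str, int]) -> pd.DataFrame:
    """Patient counts at intersections of two labelings (common ids only)."""
    common = sorted(set(labelsA) & set(labelsB))
    if not common:
        raise ValueError("labelings share no patients")
    a = pd.Series({p: labelsA[p] for p in common}, name="A")
    b = pd.Series({p: labelsB[p] for p in common}, name="B")
    return pd.crosstab(a, b)


def assign_new_patient(
    prefix_traj: UniformTrajectory,
    model: ClusterModel,
    reference_trajs: list[UniformTrajectory],
    min_points: int = 6,
) -> tuple[int, dict[int, float]]:
    """Assign from an initial (prefix) trajectory by DTW to medoid prefixes.

    The prefix must span at least ``min_points`` grid points; ties go to the
    lower (better-outcome) tag.
    """
    m = len(prefix_traj.values)
    if m < min_points:
        raise ValueError(f"prefix has {m} points; need at least {min_points}")
    by_id = {t.patient_id: t for t in reference_trajs}
    dists: dict[int, float] = {}
    for tag, mid in enumerate(model.medoid_ids, start=1):
        ref = by_id[mid].values[:m]
        d, _ = dtw_distance(prefix_traj.values, ref)
        dists[tag] = d
    best = min(dists, key=lambda t: (dists[t], t))
    return best, dists


def cluster_covariate_profile(
    model: ClusterModel,
    cohort: Cohort,
    silhouette_report: SilhouetteReport | None = None,
) -> pd.DataFrame:
    """Per-cluster covariate summary (age, BMI, sex, smoking, thymectomy,
    azathioprine dose-days).

    Patients with negative silhouette are excluded here — they are not
    reliably classified, so they would blur the covariate contrast — but they
    are never removed from the clustering itself. Patients with missing
    covariates are skipped per covariate.
    """
    drop = set(silhouette_report.negative_ids) if silhouette_report else set()
    rows = []
    for tag in range(1, model.k + 1):
        members = [cohort.get(p) for p in model.members(tag) if p not in drop]
        aza_days = [
            sum(1 for _, v in p.series.get("azathioprine_daily_mg", []) if v > 0)
            for p in members
        ]
        def _mean(vals):
            vals = [v for v in vals if v is not None]
            return float(np.mean(vals)) if vals else np.nan
        rows.append({
            "cluster": tag,
            "n": len(members),
            "mean_age": _mean([p.age_years for p in members]),
            "mean_bmi": _mean([p.bmi_kg_m2 for p in members]),
            "pct_female": 100 * _mean([p.sex == "F" if p.sex else None for p in members]),
            "pct_smokers": 100 * _mean([p.smoker for p in members]),
            "pct_thymectomy": 100 * _mean([p.thymectomy for p in members]),
            "mean_aza_dose_days": float(np.mean(aza_days)) if aza_days else np.nan,
        })
    return pd.DataFrame(rows).set_index("cluster")


def treatment_failure_summary(cohort: Cohort) -> pd.DataFrame:
    """Failure week (first azathioprine dose) and prednisone accumulated by then.

    Failure of the steroid regimen is operationalised as the start of
    azathioprine; accumulated prednisone is the trapezoidal integral of the
    daily-equivalent dose from week 0 to the failure week, in mg
    (mg/day x 7 days/week). Patients never dosed get a missing failure week.
    """
    rows = []
    for p in cohort.patients:
        aza = p.series.get("azathioprine_daily_mg", [])
        start = next((w for w, v in aza if v > 0), None)
        if start is None:
            rows.append({"patient_id": p.patient_id, "failure_week": np.nan,
                         "accumulated_prednisone_mg": np.nan})
            continue
        weeks, vals = p.weeks("prednisone_daily_mg"), p.values("prednisone_daily_mg")
        if len(weeks) == 0 or start <= weeks[0]:
            acc = 0.0
        else:
            stop = min(start, weeks[-1])
            sub_w = np.concatenate([weeks[weeks < stop], [stop]])
            sub_v = np.concatenate([vals[weeks < stop],
                                    [np.interp(stop, weeks, vals)]])
            acc = float(np.trapezoid(sub_v, sub_w)) * 7.0  # mg/day x days
        rows.append({"patient_id": p.patient_id, "failure_week": float(start),
                     "accumulated_prednisone_mg": acc})
    return pd.DataFrame(rows).set_index("patient_id")
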