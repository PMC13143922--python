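"""PAM clustering, validation indices, and cluster summary operations."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from mgtraj import (
    DistanceMatrix, assign_new_patient, cluster_covariate_profile,
    cluster_strips, cross_tab, order_clusters_by_outcome, pairwise_matrix,
    pam_cluster, select_k, separation_indices, silhouette,
    treatment_failure_summary,
)
from mgtraj.io import Cohort, PatientRecord
from mgtraj.synth import noise_trajectories, separated_trajectories
from conftest import make_traj


def _dmat(points, ids=None):
    points = np.asarray(points, dtype=float)
    ids = ids or [f"p{i}" for i in range(len(points))]
    D = np.abs(points[:, None] - points[None, :])
    return DistanceMatrix(D, ids)


def _exhaustive_pam(D, k):
    """Best objective over every medoid subset (oracle, tiny n)."""
    M, n = D.values, len(D)
    best = np.inf
    for subset in combinations(range(n), k):
        obj = M[:, subset].min(axis=1).sum()
        best = min(best, obj)
    return best


def test_two_tight_groups_recovered_with_optimal_medoids():
    pts = [0.0, 0.1, 0.2, 10.0, 10.1, 10.2]
    D = _dmat(pts)
    model = pam_cluster(D, 2)
    groups = {tuple(sorted(model.members(t))) for t in (1, 2)}
    assert groups == {("p0", "p1", "p2"), ("p3", "p4", "p5")}
    assert model.objective == pytest.approx(_exhaustive_pam(D, 2))


def test_k_equals_n_minus_1_matches_brute_force():
    D = _dmat([0.0, 1.0, 3.0, 7.0, 15.0])
    model = pam_cluster(D, 4)
    assert model.objective == pytest.approx(_exhaustive_pam(D, 4))


def test_duplicated_points_split_cleanly():
    D = _dmat([1.0, 1.0, 9.0, 9.0])
    model = pam_cluster(D, 2)
    assert model.labels["p0"] == model.labels["p1"]
    assert model.labels["p2"] == model.labels["p3"]
    assert model.labels["p0"] != model.labels["p2"]


def test_pam_rejects_bad_k():
    D = _dmat([0.0, 1.0, 2.0])
    with pytest.raises(ValueError):
        pam_cluster(D, 3)
    with pytest.raises(ValueError):
        pam_cluster(D, 1)


def test_pam_deterministic(small_cohort):
    from mgtraj import to_uniform_grid
    from mgtraj.preprocess import default_grid
    cohort, _ = small_cohort
    trajs, _ = to_uniform_grid(cohort, "prednisone_daily_mg",
                               default_grid(), 30)
    D = pairwise_matrix(trajs)
    m1 = pam_cluster(D, 3, seed=0)
    m2 = pam_cluster(D, 3, seed=0)
    assert m1.labels == m2.labels and m1.objective == m2.objective


def test_silhouette_hand_computed_four_points():
    D = _dmat([0.0, 1.0, 10.0, 11.0])
    labels = {"p0": 1, "p1": 1, "p2": 2, "p3": 2}
    rep = silhouette(D, labels)
    assert rep.values["p0"] == pytest.approx(19 / 21, abs=1e-12)
    assert rep.values["p1"] == pytest.approx(17 / 19, abs=1e-12)
    assert rep.values["p2"] == pytest.approx(17 / 19, abs=1e-12)
    assert rep.values["p3"] == pytest.approx(19 / 21, abs=1e-12)
    assert rep.negative_ids == []
    assert all(-1 <= s <= 1 for s in rep.values.values())


def test_silhouette_equidistant_point_is_zero():
    # p2 sits exactly between the two clusters: a == b
    D = _dmat([0.0, 0.0, 1.0, 2.0, 2.0])
    labels = {"p0": 1, "p1": 1, "p2": 1, "p3": 2, "p4": 2}
    rep = silhouette(D, labels)
    assert rep.values["p2"] == pytest.approx(0.0, abs=1e-12)


def test_silhouette_single_cluster_rejected():
    D = _dmat([0.0, 1.0])
    with pytest.raises(ValueError):
        silhouette(D, {"p0": 1, "p1": 1})


def test_separation_indices_hand_computed():
    pts = [0.0, 1.0, 10.0, 11.0]
    D = _dmat(pts)
    labels = {"p0": 1, "p1": 1, "p2": 2, "p3": 2}
    trajs = [make_traj(f"p{i}", [pts[i], pts[i]]) for i in range(4)]
    idx = separation_indices(trajs, D, labels)
    # medoid scatter 0.5 each, medoid gap 10 -> DB = 0.1
    assert idx.davies_bouldin == pytest.approx(0.1, abs=1e-12)
    # min inter-cluster 9, max intra 1 -> Dunn = 9
    assert idx.dunn == pytest.approx(9.0, abs=1e-12)
    # 1-D CH: B=100, W=1, (B/1)/(W/2) = 200
    assert idx.calinski_harabasz == pytest.approx(200.0, abs=1e-9)


def test_separation_indices_limits():
    D = _dmat([0.0, 0.0, 100.0, 100.0])
    labels = {"p0": 1, "p1": 1, "p2": 2, "p3": 2}
    trajs = [make_traj(f"p{i}", [v, v]) for i, v in enumerate([0, 0, 100, 100])]
    idx = separation_indices(trajs, D, labels)
    assert idx.davies_bouldin == 0.0          # duplicate-point clusters
    assert idx.dunn == np.inf                  # zero intra-cluster diameter


def test_select_k_recovers_four_separated_clusters():
    trajs, _ = separated_trajectories(n=80, n_clusters=4, seed=1)
    D = pairwise_matrix(trajs)
    k_best, table = select_k(D, range(2, 7), seed=0)
    assert k_best == 4
    assert not table["warning"].any()


def test_select_k_two_duplicate_groups():
    trajs = [make_traj(f"a{i}", [0, 0, 0]) for i in range(4)] + \
            [make_traj(f"b{i}", [9, 9, 9]) for i in range(4)]
    D = pairwise_matrix(trajs)
    k_best, _ = select_k(D, range(2, 5), seed=0)
    assert k_best == 2


def test_select_k_flags_homogeneous_noise():
    trajs = noise_trajectories(n=30, sd=1.0, seed=5)
    D = pairwise_matrix(trajs)
    _, table = select_k(D, range(2, 6), seed=0)
    assert table["warning"].all()


def test_order_clusters_by_outcome():
    trajs = [make_traj("hi1", [50, 50]), make_traj("hi2", [52, 52]),
             make_traj("lo1", [5, 5]), make_traj("lo2", [6, 6])]
    D = pairwise_matrix(trajs)
    model = pam_cluster(D, 2)
    ordered = order_clusters_by_outcome(model, trajs)
    assert {ordered.labels["lo1"], ordered.labels["lo2"]} == {1}
    assert {ordered.labels["hi1"], ordered.labels["hi2"]} == {2}
    # idempotent: already ordered stays unchanged; partition is preserved
    again = order_clusters_by_outcome(ordered, trajs)
    assert again.labels == ordered.labels
    assert {frozenset(model.members(t)) for t in (1, 2)} == \
           {frozenset(ordered.members(t)) for t in (1, 2)}


def test_cluster_strips_closed_form():
    a = 3.0
    trajs = [make_traj("x", [a, a, a]), make_traj("y", [a + 2, a + 2, a + 2]),
             make_traj("z", [0, 0, 0])]
    labels = {"x": 1, "y": 1, "z": 2}
    strips = cluster_strips(trajs, labels)
    s1 = next(s for s in strips if s.tag == 1)
    np.testing.assert_allclose(s1.mean, a + 1)
    np.testing.assert_allclose(s1.sd, np.sqrt(2))  # sample SD of {a, a+2}
    s2 = next(s for s in strips if s.tag == 2)
    np.testing.assert_allclose(s2.sd, 0.0)         # singleton cluster
    assert len(s1.mean) == len(s1.sd) == 3


def test_cross_tab_hand_counted():
    A = {"a": 1, "b": 1, "c": 2, "d": 2, "e": 3, "f": 3}
    B = {"a": 1, "b": 2, "c": 2, "d": 2, "e": 3, "f": 1}
    tab = cross_tab(A, B)
    assert tab.loc[1, 1] == 1 and tab.loc[1, 2] == 1
    assert tab.loc[2, 2] == 2 and tab.loc[3, 3] == 1 and tab.loc[3, 1] == 1
    assert tab.to_numpy().sum() == 6
    # identical labelings give a diagonal matrix
    diag = cross_tab(A, A)
    assert (diag.to_numpy() == np.diag([2, 2, 2])).all()


def test_cross_tab_disjoint_rejected():
    with pytest.raises(ValueError):
        cross_tab({"a": 1}, {"b": 1})


def test_assign_new_patient_prefix_and_ties():
    trajs, labels = separated_trajectories(n=40, n_clusters=2, seed=3)
    D = pairwise_matrix(trajs)
    model = pam_cluster(D, 2)
    medoid = next(t for t in trajs if t.patient_id == model.medoid_ids[0])
    from mgtraj.preprocess import GridSpec, UniformTrajectory
    m = 8
    g = GridSpec(0, float(m - 1), 1.0)
    prefix = UniformTrajectory("new", "x", g, medoid.values[:m],
                               np.zeros(m, dtype=bool))
    tag, dists = assign_new_patient(prefix, model, trajs, min_points=6)
    assert tag == 1 and dists[1] == 0.0
    with pytest.raises(ValueError, match="prefix"):
        short = UniformTrajectory("new", "x", GridSpec(0, 2, 1),
                                  medoid.values[:3], np.zeros(3, dtype=bool))
        assign_new_patient(short, model, trajs, min_points=6)


def test_assign_new_patient_from_generator_cluster():
    trajs, labels = separated_trajectories(n=60, n_clusters=3, seed=11)
    D = pairwise_matrix(trajs)
    model = pam_cluster(D, 3)
    # draw fresh members of each true cluster; assignment should match the
    # cluster holding that template's patients
    fresh, fresh_labels = separated_trajectories(n=9, n_clusters=3, seed=99)
    from mgtraj.preprocess import GridSpec, UniformTrajectory
    m = 12
    g = GridSpec(trajs[0].grid.start_week,
                 trajs[0].grid.start_week + (m - 1) * trajs[0].grid.step_weeks,
                 trajs[0].grid.step_weeks)
    hits = 0
    for t in fresh:
        prefix = UniformTrajectory(t.patient_id, "x", g, t.values[:m],
                                   np.zeros(m, dtype=bool))
        tag, _ = assign_new_patient(prefix, model, trajs, min_points=6)
        true_tag = model.labels[
            next(p for p in labels if labels[p] == fresh_labels[t.patient_id])
        ]
        hits += tag == true_tag
    assert hits >= 8  # 3-SD separation: near-perfect assignment


def _profile_cohort():
    patients = []
    for i, (smoker, cl) in enumerate([(False, 1), (False, 1), (False, 2),
                                      (False, 2), (True, 3), (True, 3)]):
        p = PatientRecord(f"p{i}", age_years=40.0 + 5 * cl, sex="F",
                          bmi_kg_m2=25.0, weight_kg=70.0, smoker=smoker,
                          thymectomy=cl == 1, prior_prednisone=False)
        p.series["azathioprine_daily_mg"] = [(0.0, 0.0), (52.0, 100.0 if cl == 3 else 0.0)]
        patients.append(p)
    labels = {f"p{i}": cl for i, cl in enumerate([1, 1, 2, 2, 3, 3])}
    from mgtraj.cluster import ClusterModel
    model = ClusterModel(k=3, medoid_ids=["p0", "p2", "p4"], labels=labels,
                         objective=0.0)
    return Cohort(patients=patients), model


def test_covariate_profile_constructed_smokers():
    cohort, model = _profile_cohort()
    prof = cluster_covariate_profile(model, cohort)
    assert prof.loc[3, "pct_smokers"] == 100.0
    assert prof.loc[1, "pct_smokers"] == 0.0
    assert prof.loc[2, "pct_smokers"] == 0.0
    # planted age gradient is monotone
    assert prof["mean_age"].is_monotonic_increasing
    assert prof.loc[3, "mean_aza_dose_days"] == 1.0


def test_covariate_profile_negative_silhouette_exclusion():
    cohort, model = _profile_cohort()
    from mgtraj.cluster import SilhouetteReport
    rep = SilhouetteReport(values={}, per_cluster_mean={}, overall_mean=0.5,
                           negative_ids=["p4"])
    full = cluster_covariate_profile(model, cohort)
    drop = cluster_covariate_profile(model, cohort, rep)
    assert drop.loc[3, "n"] == full.loc[3, "n"] - 1
    pd.testing.assert_frame_equal(drop.loc[[1, 2]], full.loc[[1, 2]])


def test_treatment_failure_summary():
    p1 = PatientRecord("p1")  # never dosed
    p1.series["azathioprine_daily_mg"] = [(0.0, 0.0), (52.0, 0.0)]
    p1.series["prednisone_daily_mg"] = [(0.0, 20.0), (52.0, 20.0)]
    p2 = PatientRecord("p2")  # azathioprine from week 10, constant 20 mg/day
    p2.series["azathioprine_daily_mg"] = [(0.0, 0.0), (10.0, 150.0)]
    p2.series["prednisone_daily_mg"] = [(0.0, 20.0), (52.0, 20.0)]
    p3 = PatientRecord("p3")  # dosed at entry
    p3.series["azathioprine_daily_mg"] = [(0.0, 150.0)]
    p3.series["prednisone_daily_mg"] = [(0.0, 20.0), (52.0, 20.0)]
    out = treatment_failure_summary(Cohort(patients=[p1, p2, p3]))
    assert np.isnan(out.loc["p1", "failure_week"])
    assert out.loc["p2", "failure_week"] == 10.0
    # 20 mg/day for 70 days = 1400 mg
    assert out.loc["p2", "accumulated_prednisone_mg"] == pytest.approx(1400.0)
    assert out.loc["p3", "accumulated_prednisone_mg"] == 0.0
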