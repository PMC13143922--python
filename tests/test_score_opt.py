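"""Composite score construction and predictability-driven weight search."""

import numpy as np
import pytest

from mgtraj import GAParams, GammaMix, IpParams, WeightVector
from mgtraj.score_opt import composite_score, optimize_adl_weights, optimize_gamma
from mgtraj.predictability import predictability_index, default_sphere_radius
from mgtraj.synth import noise_trajectories, separated_trajectories
from conftest import make_traj


def test_weight_vector_constraints():
    with pytest.raises(ValueError):
        WeightVector(np.ones(7))
    with pytest.raises(ValueError):
        WeightVector(np.array([9.0, -1, 0, 0, 0, 0, 0, 0]) + 0.0)
    w = WeightVector.uniform()
    assert w.alpha.sum() == pytest.approx(8.0)
    with pytest.raises(ValueError):
        GammaMix(2.5)


def _item_cohort(n=12, signal_items=(0, 1), seed=0, grid_len=12):
    """Patients whose items in ``signal_items`` carry smooth cluster signal
    and whose remaining items are iid noise."""
    rng = np.random.default_rng(seed)
    smooth_trajs, _ = separated_trajectories(
        n=n, n_clusters=2, seed=seed,
        grid=make_traj("x", np.zeros(grid_len)).grid)
    items = {}
    for i, base in enumerate(smooth_trajs):
        pid = f"q{i:02d}"
        per_item = []
        for j in range(8):
            if j in signal_items:
                vals = base.values + rng.normal(0, 0.05, grid_len)
            else:
                vals = rng.normal(1.5, 1.0, grid_len)
            per_item.append(make_traj(pid, vals))
        items[pid] = per_item
    return items


def test_composite_uniform_is_standard_total():
    items = _item_cohort(n=4)
    comps = composite_score(items, WeightVector.uniform())
    pid = comps[0].patient_id
    expect = np.sum([t.values for t in items[pid]], axis=0)
    np.testing.assert_allclose(comps[0].values, expect)


def test_composite_zero_and_linearity():
    grid_len = 6
    items = {"p": [make_traj("p", np.zeros(grid_len)) for _ in range(8)]}
    comp = composite_score(items, WeightVector.uniform())
    np.testing.assert_allclose(comp[0].values, 0.0)
    # alpha-linearity, hand-checked on a 2-point series
    items = {"p": [make_traj("p", [float(j), float(j + 1)]) for j in range(8)]}
    w = np.ones(8)
    w[0], w[1] = 2.0, 0.0 + 1e-3
    w = w * (8.0 / w.sum())
    comp_w = composite_score(items, WeightVector(w))[0].values
    expect = np.sum([w[j] * np.array([j, j + 1]) for j in range(8)], axis=0)
    np.testing.assert_allclose(comp_w, expect)


def test_identical_items_make_ip_weight_invariant():
    base = np.linspace(0, 3, 10)
    items = {f"p{i}": [make_traj(f"p{i}", base + i % 3) for _ in range(8)]
             for i in range(9)}
    ipp = IpParams(min_occupancy=2, radius_frac=0.15)
    res = optimize_adl_weights(items, ipp,
                               GAParams(population=8, generations=3), seed=0)
    assert res.achieved_ip == pytest.approx(res.baseline_ip)


def test_ga_concentrates_weight_on_signal_items():
    items = _item_cohort(n=14, signal_items=(0, 1), seed=2)
    ipp = IpParams(min_occupancy=3, radius_frac=0.08)
    res = optimize_adl_weights(items, ipp,
                               GAParams(population=20, generations=10), seed=1)
    assert res.achieved_ip >= res.baseline_ip
    w = res.best.alpha
    assert w.sum() == pytest.approx(8.0) and np.all(w > 0)
    assert w[:2].mean() > w[2:].mean()
    # elitism: best fitness never decreases across generations
    assert all(b <= a for b, a in zip(res.history, res.history[1:]))


def test_ip_scale_equivariance():
    """Scaling every item by c > 0 leaves Ip unchanged when the radius is a
    fraction of the composite's own maximum."""
    items = _item_cohort(n=10, seed=4)
    ipp = IpParams(min_occupancy=3)
    w = WeightVector.uniform()

    def ip_of(scale):
        comps = composite_score(
            {p: [make_traj(p, scale * t.values) for t in ts]
             for p, ts in items.items()}, w)
        radius = default_sphere_radius(comps, ipp.block_length, ipp.radius_frac)
        return predictability_index(comps, radius, ipp.block_length,
                                    ipp.min_occupancy).ip

    assert ip_of(1.0) == pytest.approx(ip_of(7.3))


def test_gamma_symmetric_scores_return_one():
    trajs, _ = separated_trajectories(n=10, n_clusters=2, seed=5,
                                      grid=make_traj("x", np.zeros(10)).grid)
    res = optimize_gamma(trajs, trajs, IpParams(min_occupancy=2))
    assert res.best.gamma == pytest.approx(1.0)
    assert res.achieved_ip == pytest.approx(res.baseline_ip)


def test_gamma_prefers_predictable_score_over_noise():
    from mgtraj.synth import constant_trajectories
    grid = make_traj("x", np.zeros(12)).grid
    adl = [make_traj(f"m{i:02d}", t.values, grid) for i, t in
           enumerate(constant_trajectories(12, grid=grid, low=0, high=10, seed=6))]
    qmg = [make_traj(f"m{i:02d}", v.values, grid)
           for i, v in enumerate(noise_trajectories(12, grid=grid, sd=8.0, seed=7))]
    res = optimize_gamma(adl, qmg, IpParams(min_occupancy=3), grid_step=0.25)
    # pure-ADL mixture is exactly predictable (Ip = 100); any noise admixture
    # is not, so the search lands on the gamma = 2 endpoint
    assert res.best.gamma == pytest.approx(2.0)
    assert res.achieved_ip == pytest.approx(100.0)
    assert res.achieved_ip >= res.baseline_ip


def test_gamma_endpoints_reduce_to_single_score():
    grid = make_traj("x", np.zeros(10)).grid
    adl, _ = separated_trajectories(n=10, n_clusters=2, seed=8, grid=grid)
    adl = [make_traj(f"m{i}", t.values, grid) for i, t in enumerate(adl)]
    qmg = [make_traj(f"m{i}", t.values[::-1].copy(), grid)
           for i, t in enumerate(adl)]
    ipp = IpParams(min_occupancy=2)
    res = optimize_gamma(adl, qmg, ipp, grid_step=1.0)  # gammas 0, 1, 2

    def single_ip(trajs):
        r = default_sphere_radius(trajs, ipp.block_length, ipp.radius_frac)
        return predictability_index(trajs, r, ipp.block_length,
                                    ipp.min_occupancy).ip

    # endpoint gamma=2 is 2*ADL, scale-invariant => equals ADL-only Ip
    assert res.history[2] == pytest.approx(single_ip(adl))
    assert res.history[0] == pytest.approx(single_ip(qmg))
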