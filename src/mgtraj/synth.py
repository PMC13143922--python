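"""Synthetic corticosteroid-trial cohort generator with known ground truth.

The real thymectomy-vs-prednisone trial dataset this toolkit is designed for
is access-restricted, so every pipeline stage is exercised on synthetic
cohorts that emulate its structure: ~126 patients followed 36 months, visits
at months 0, 3, 4, 6 and then quarterly, alternate-day prednisone titrated
by a protocol decision tree against the quantitative severity score (QMG),
item-level ADL scores in 0..3, azathioprine rescue for poor responders after
month 12, missing visits and dropout.

The generator couples two mechanisms per patient:

* a protocol engine (:func:`protocol_step`) reproducing the published dosing
  rules — escalate 10 mg alternate-day steps from 10 mg up to
  min(100, 1.5 mg/kg) (120 mg ceiling for patients already on prednisone
  without minimal-manifestation status by month 4); hold from month 4 until
  MMS with QMG < 14 and at least 1 point under baseline; taper 10 mg every
  2 weeks down to 40 mg, then 5 mg per month; on MMS loss re-escalate 10 mg
  every 2 weeks and resume tapering 4 weeks after MMS returns;

* sigmoid dose-response dynamics (module :mod:`mgtraj.dynamics`) with
  cluster-profile parameters, which produce the latent severity score the
  protocol reacts to.

Cluster profiles differ in disease severity (carrying capacity) and drug
responsiveness, which yields the well-separated dose-trajectory clusters the
analysis modules are meant to recover. Everything is reproducible by seed,
and :class:`GroundTruth` exposes true labels, true parameters, every
escalation event and the weekly latent traces for auditing.

Minimal-manifestation status has no numeric definition in the clinic; here
it is synthesised as latent QMG below a threshold (default 8) sustained for
4 weeks. Pyridostigmine and rescue therapy appear only as event flags with a
transient score dip, not as pharmacology.

Helper generators (:func:`separated_trajectories`,
:func:`constant_trajectories`, :func:`noise_trajectories`) provide directly
controlled trajectory sets for calibration and recovery studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dynamics import SigmoidParams
from .io import Cohort, PatientRecord, WEEKS_PER_MONTH
from .preprocess import GridSpec, UniformTrajectory

__all__ = [
    "ClusterProfile", "ProtocolState", "SynthConfig", "GroundTruth",
    "protocol_step", "generate_cohort", "ground_truth", "audit_protocol",
    "default_profiles", "separated_trajectories", "constant_trajectories",
    "noise_trajectories",
]

MONTH4_WEEK = int(round(4 * WEEKS_PER_MONTH))  # 17
MONTH12_WEEK = int(round(12 * WEEKS_PER_MONTH))  # 52
HORIZON_WEEKS = int(round(36 * WEEKS_PER_MONTH))  # 156
VISIT_MONTHS = (0, 3, 4, 6, 9, 12, 15, 18, 21, 24, 27, 30, 33, 36)
MMS_SUSTAIN_WEEKS = 4
QMG_MAX = 39.0
ADL_ITEM_MAX = 3


@dataclass
class ClusterProfile:
    """One latent response phenotype and its covariate mix."""

    label: int
    prevalence: float
    params: SigmoidParams
    jitter_sd: float = 0.1        # relative jitter on beta per patient
    item_loading: np.ndarray = field(
        default_factory=lambda: np.full(8, 1 / 8)
    )                             # how the ADL total spreads over 8 items
    smoker_prob: float = 0.2
    thymectomy_prob: float = 0.5
    age_mean: float = 45.0
    age_sd: float = 12.0
    bmi_mean: float = 27.0
    bmi_sd: float = 4.0

    def __post_init__(self):
        self.item_loading = np.asarray(self.item_loading, dtype=float)
        if self.item_loading.shape != (8,) or np.any(self.item_loading < 0):
            raise ValueError("item_loading must be 8 nonnegative reals")
        if abs(self.item_loading.sum() - 1.0) > 1e-9:
            raise ValueError("item_loading must sum to 1")


def default_profiles() -> list[ClusterProfile]:
    """Four phenotypes from best (fast responder, mild) to worst (refractory).

    alpha = 0.02/week gives an untreated worsening timescale of a few weeks;
    capacities span mild to severe disease and beta spans strong to nearly
    absent drug effect, which is what spreads the dose trajectories apart.
    """
    mk = lambda c, b: SigmoidParams(alpha=0.02, beta=b, s_capacity=c, y_max=50.0)
    loads = [
        np.array([3, 3, 2, 2, 2, 2, 1, 1]) / 16,
        np.array([1, 1, 2, 2, 2, 2, 3, 3]) / 16,
        np.full(8, 1 / 8),
        np.array([2, 2, 2, 2, 1, 1, 3, 3]) / 16,
    ]
    return [
        ClusterProfile(1, 0.40, mk(12.0, -1.2), item_loading=loads[0],
                       thymectomy_prob=0.7, age_mean=38, bmi_mean=25,
                       smoker_prob=0.10),
        ClusterProfile(2, 0.25, mk(16.0, -0.8), item_loading=loads[1],
                       thymectomy_prob=0.55, age_mean=44, bmi_mean=27,
                       smoker_prob=0.15),
        ClusterProfile(3, 0.20, mk(20.0, -0.5), item_loading=loads[2],
                       thymectomy_prob=0.45, age_mean=50, bmi_mean=29,
                       smoker_prob=0.25),
        ClusterProfile(4, 0.15, mk(26.0, -0.15), item_loading=loads[3],
                       thymectomy_prob=0.30, age_mean=55, bmi_mean=31,
                       smoker_prob=0.35),
    ]


@dataclass
class ProtocolState:
    """Dosing state advanced weekly by :func:`protocol_step`."""

    alt_day_dose_mg: float
    phase: str  # escalation | hold | taper_fast | taper_slow | re_escalation
    mms: bool
    weeks_in_phase: int
    baseline_qmg: float
    weight_kg: float
    prior_prednisone: bool
    low_qmg_weeks: int = 0
    weeks_since_change: int = 99
    post_mms_wait: int = 0
    mms_threshold: float = 8.0

    @property
    def cap(self) -> float:
        base = min(100.0, 1.5 * self.weight_kg)
        if self.prior_prednisone:
            return max(base, 120.0)
        return base

    @property
    def daily_dose_mg(self) -> float:
        return self.alt_day_dose_mg / 2.0


def initial_state(weight_kg: float, prior_prednisone: bool,
                  baseline_qmg: float, mms_threshold: float = 8.0) -> ProtocolState:
    start = 30.0 if prior_prednisone else 10.0
    return ProtocolState(
        alt_day_dose_mg=start, phase="escalation", mms=False,
        weeks_in_phase=0, baseline_qmg=baseline_qmg, weight_kg=weight_kg,
        prior_prednisone=prior_prednisone, mms_threshold=mms_threshold,
    )


def protocol_step(state: ProtocolState, qmg: float, week: float) -> ProtocolState:
    """Advance the dosing decision tree by one week.

    The engine runs on a weekly clock; escalation and fast-taper steps fire
    every 2 weeks, the slow taper every 4 weeks (the protocol's "monthly"
    cadence discretised to whole weeks). Dose changes are always whole
    protocol steps: +10, -10, or -5 mg alternate-day.
    """
    s = replace(state)
    # MMS bookkeeping: sustained low severity
    s.low_qmg_weeks = s.low_qmg_weeks + 1 if qmg < s.mms_threshold else 0
    s.mms = s.low_qmg_weeks >= MMS_SUSTAIN_WEEKS
    s.weeks_in_phase += 1
    s.weeks_since_change += 1

    def change(delta: float, cap: float | None = None) -> None:
        new = s.alt_day_dose_mg + delta
        if cap is not None and new > cap:
            return  # whole steps only: a step past the cap is not taken
        s.alt_day_dose_mg = max(new, 0.0)
        if s.alt_day_dose_mg != state.alt_day_dose_mg:
            s.weeks_since_change = 0

    def enter(phase: str) -> None:
        s.phase = phase
        s.weeks_in_phase = 0

    if s.phase == "escalation":
        if week >= MONTH4_WEEK:
            enter("hold")
        elif not s.mms and s.weeks_since_change >= 2:
            change(+10.0, cap=min(100.0, 1.5 * s.weight_kg))
    elif s.phase == "hold":
        if s.mms and qmg < 14.0 and qmg <= s.baseline_qmg - 1.0:
            enter("taper_fast")
        elif s.prior_prednisone and not s.mms and s.weeks_since_change >= 2:
            change(+10.0, cap=120.0)
    elif s.phase == "taper_fast":
        if not s.mms:
            enter("re_escalation")
            s.post_mms_wait = 0
        elif s.weeks_since_change >= 2:
            # fast taper stops AT 40 mg: a re-escalated 45 mg dose steps -5
            delta = max(-10.0, 40.0 - s.alt_day_dose_mg)
            change(delta)
            if s.alt_day_dose_mg <= 40.0:
                enter("taper_slow")
    elif s.phase == "taper_slow":
        if not s.mms:
            enter("re_escalation")
            s.post_mms_wait = 0
        elif s.weeks_since_change >= 4:
            change(-5.0)
    elif s.phase == "re_escalation":
        if s.mms:
            s.post_mms_wait += 1
            if s.post_mms_wait >= MMS_SUSTAIN_WEEKS:
                enter("taper_fast" if s.alt_day_dose_mg > 40.0 else "taper_slow")
                s.post_mms_wait = 0
        else:
            s.post_mms_wait = 0
            if s.weeks_since_change >= 2:
                change(+10.0, cap=s.cap)
    else:
        raise ValueError(f"unknown phase {s.phase!r}")
    return s


@dataclass
class SynthConfig:
    n_patients: int = 126
    profiles: list[ClusterProfile] = field(default_factory=default_profiles)
    baseline_qmg_mean: float = 16.0
    baseline_qmg_sd: float = 3.0
    weight_mean_kg: float = 75.0
    weight_sd_kg: float = 14.0
    score_noise_sd: float = 1.5
    adl_qmg_correlation: float = 0.6
    missing_visit_prob: float = 0.05
    dropout_hazard: float = 0.008  # per visit, ~10% cumulative over the trial
    prior_prednisone_prob: float = 0.15
    rescue_prob: float = 0.05      # per patient, one transient rescue event
    mms_threshold: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        total = sum(p.prevalence for p in self.profiles)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("profile prevalences must sum to 1")
        for prob in (self.missing_visit_prob, self.dropout_hazard,
                     self.prior_prednisone_prob, self.rescue_prob):
            if not 0.0 <= prob <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class GroundTruth:
    labels: dict[str, int]
    params: dict[str, SigmoidParams]
    escalations: dict[str, list[tuple[float, float]]]  # (week, new alt-day dose)
    azathioprine_start: dict[str, float | None]
    weekly_dose_alt_mg: dict[str, np.ndarray]
    weekly_qmg: dict[str, np.ndarray]
    caps_alt_mg: dict[str, float]


def _simulate_patient(pid, profile, cfg, rng):
    weight = float(np.clip(rng.normal(cfg.weight_mean_kg, cfg.weight_sd_kg),
                           45, 120))
    prior = bool(rng.random() < cfg.prior_prednisone_prob)
    s0 = float(np.clip(rng.normal(cfg.baseline_qmg_mean, cfg.baseline_qmg_sd),
                       10, 30))
    beta = profile.params.beta * float(
        np.clip(1 + rng.normal(0, profile.jitter_sd), 0.3, 2.0)
    )
    y_max = min(100.0, 1.5 * weight) / 2.0 if not prior else 60.0
    params = SigmoidParams(profile.params.alpha, beta,
                           profile.params.s_capacity, y_max)
    rescue_week = (
        int(rng.integers(20, HORIZON_WEEKS - 20))
        if rng.random() < cfg.rescue_prob else None
    )

    state = initial_state(weight, prior, s0, cfg.mms_threshold)
    qmg = s0
    weeks = np.arange(HORIZON_WEEKS + 1)
    dose_trace = np.empty(len(weeks))
    qmg_trace = np.empty(len(weeks))
    escalations: list[tuple[float, float]] = []
    mms_at_month12 = False
    for t in weeks:
        dose_trace[t] = state.alt_day_dose_mg
        qmg_trace[t] = qmg
        if t == MONTH12_WEEK:
            mms_at_month12 = state.mms
        if t == weeks[-1]:
            break  # the horizon: no further dosing decision to record
        prev_dose = state.alt_day_dose_mg
        state = protocol_step(state, qmg, float(t))
        if state.alt_day_dose_mg > prev_dose:
            escalations.append((float(t), state.alt_day_dose_mg))
        # latent severity: weekly Euler of the sigmoid ODE (2 half-week steps)
        y = state.daily_dose_mg
        for _ in range(2):
            ds = (params.beta * (y / params.y_max) * qmg
                  + params.alpha * qmg * (params.s_capacity - qmg))
            qmg = max(qmg + 0.5 * ds, 0.0)
        if rescue_week is not None and t == rescue_week:
            qmg = max(qmg - 4.0, 0.0)  # transient rescue-therapy dip
    aza_start = None
    if not mms_at_month12:
        aza_start = float(min(
            m * WEEKS_PER_MONTH for m in VISIT_MONTHS
            if m * WEEKS_PER_MONTH >= MONTH12_WEEK
        ))
    return (weight, prior, s0, params, dose_trace, qmg_trace, escalations,
            aza_start, rescue_week, mms_at_month12)


def generate_cohort(config: SynthConfig) -> tuple[Cohort, GroundTruth]:
    """Generate a full synthetic cohort plus its ground truth (same seed)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    prevalences = np.array([p.prevalence for p in cfg.profiles])
    patients: list[PatientRecord] = []
    gt = GroundTruth({}, {}, {}, {}, {}, {}, {})
    visit_weeks = [m * WEEKS_PER_MONTH for m in VISIT_MONTHS]

    for i in range(cfg.n_patients):
        pid = f"P{i:03d}"
        profile = cfg.profiles[int(rng.choice(len(cfg.profiles), p=prevalences))]
        (weight, prior, s0, params, dose_trace, qmg_trace, escalations,
         aza_start, rescue_week, _) = _simulate_patient(pid, profile, cfg, rng)

        # dropout: geometric over visits, truncates the record
        last_week = HORIZON_WEEKS + 1.0
        for j in range(1, len(visit_weeks)):
            if rng.random() < cfg.dropout_hazard:
                last_week = visit_weeks[j]
                break

        rec = PatientRecord(
            patient_id=pid,
            age_years=float(np.clip(rng.normal(profile.age_mean, profile.age_sd), 18, 65)),
            sex="F" if rng.random() < 0.71 else "M",
            bmi_kg_m2=float(np.clip(rng.normal(profile.bmi_mean, profile.bmi_sd), 16, 45)),
            weight_kg=weight,
            smoker=bool(rng.random() < profile.smoker_prob),
            thymectomy=bool(rng.random() < profile.thymectomy_prob),
            prior_prednisone=prior,
        )
        if rescue_week is not None and rescue_week < last_week:
            rec.event_weeks = [float(rescue_week)]

        pred, qmg_obs, aza_obs, adl_obs = [], [], [], {j: [] for j in range(1, 9)}
        for vi, vw in enumerate(visit_weeks):
            if vw >= last_week:
                break
            if vi > 0 and rng.random() < cfg.missing_visit_prob:
                continue
            wt = int(round(vw))
            pred.append((vw, dose_trace[wt] / 2.0))
            q_seen = float(np.clip(
                round(qmg_trace[wt] + rng.normal(0, cfg.score_noise_sd)), 0, QMG_MAX
            ))
            qmg_obs.append((vw, q_seen))
            aza_dose = (2.5 * weight if aza_start is not None and vw >= aza_start
                        else 0.0)
            aza_obs.append((vw, aza_dose))
            # ADL total tracks QMG with moderate correlation, spread over items
            latent_adl = (cfg.adl_qmg_correlation * qmg_trace[wt] * (24.0 / QMG_MAX)
                          + (1 - cfg.adl_qmg_correlation) * rng.normal(6, 2))
            latent_adl = float(np.clip(latent_adl, 0, 24))
            for j in range(1, 9):
                item = latent_adl * profile.item_loading[j - 1] + rng.normal(0, 0.4)
                adl_obs[j].append((vw, float(np.clip(round(item), 0, ADL_ITEM_MAX))))

        rec.series["prednisone_daily_mg"] = pred
        rec.series["qmg_total"] = qmg_obs
        rec.series["azathioprine_daily_mg"] = aza_obs
        for j in range(1, 9):
            rec.series[f"adl_item_{j}"] = adl_obs[j]
        patients.append(rec)

        gt.labels[pid] = profile.label
        gt.params[pid] = params
        gt.escalations[pid] = escalations
        gt.azathioprine_start[pid] = aza_start if (
            aza_start is not None and aza_start < last_week) else None
        gt.weekly_dose_alt_mg[pid] = dose_trace
        gt.weekly_qmg[pid] = qmg_trace
        gt.caps_alt_mg[pid] = 120.0 if prior else min(100.0, 1.5 * weight)

    return Cohort(patients=patients), gt


def ground_truth(config: SynthConfig) -> GroundTruth:
    """Ground truth for the cohort ``generate_cohort(config)`` would emit."""
    return generate_cohort(config)[1]


def audit_protocol(gt: GroundTruth, patient_id: str) -> list[str]:
    """Check a weekly dose trace against the protocol's step/cap/floor rules.

    Violations: a change other than +10/-10/-5 mg alternate-day, dose outside
    [0, cap], a -10 step taken below the 40 mg fast-taper floor, or two
    changes closer than 2 weeks apart.
    """
    trace = gt.weekly_dose_alt_mg[patient_id]
    cap = gt.caps_alt_mg[patient_id]
    violations = []
    last_change_week = -10
    for t in range(1, len(trace)):
        d = trace[t] - trace[t - 1]
        if d == 0:
            continue
        if d not in (10.0, -10.0, -5.0):
            violations.append(f"week {t}: step {d:+g} not a protocol step")
        if d == -10.0 and trace[t] < 40.0 - 1e-9:
            violations.append(f"week {t}: fast taper below 40 mg")
        if t - last_change_week < 2:
            violations.append(f"week {t}: changes closer than 2 weeks")
        last_change_week = t
    if np.any(trace < -1e-9) or np.any(trace > cap + 1e-9):
        violations.append(f"dose outside [0, {cap}]")
    return violations


# ---------------------------------------------------------------------------
# controlled trajectory sets for calibration and recovery studies


def _grid(n_points: int = 12) -> GridSpec:
    return GridSpec(0.0, float(n_points - 1), 1.0)


def separated_trajectories(
    n: int = 120,
    n_clusters: int = 4,
    separation: float = 3.0,
    within_sd: float = 1.0,
    grid: GridSpec | None = None,
    seed: int = 0,
) -> tuple[list[UniformTrajectory], dict[str, int]]:
    """Cluster-structured trajectories with controlled mean separation.

    Adjacent cluster templates sit ``separation * within_sd`` apart pointwise
    (plus mild per-cluster shape differences); members add a patient-level
    offset and iid noise of SD ``within_sd``. With separation >= 3 the
    clusters are recoverable essentially perfectly, which makes this the
    reference setting for cluster-recovery studies.
    """
    rng = np.random.default_rng(seed)
    grid = grid or GridSpec(10.0, 140.0, WEEKS_PER_MONTH)
    t = np.linspace(0, 1, grid.n_points)
    trajs, labels = [], {}
    for i in range(n):
        c = i % n_clusters
        template = (
            c * separation * within_sd
            + within_sd * np.sin(2 * np.pi * t + c * np.pi / n_clusters)
            + c * 0.5 * within_sd * t
        )
        values = (template + rng.normal(0, 0.5 * within_sd)
                  + rng.normal(0, within_sd, grid.n_points))
        pid = f"S{i:03d}"
        trajs.append(UniformTrajectory(pid, "synthetic", grid, values,
                                       np.zeros(grid.n_points, dtype=bool)))
        labels[pid] = c + 1
    return trajs, labels


def constant_trajectories(
    n: int = 30,
    grid: GridSpec | None = None,
    low: float = 0.0,
    high: float = 50.0,
    seed: int = 0,
) -> list[UniformTrajectory]:
    """n trajectories, each constant in time at a random level in [low, high]."""
    rng = np.random.default_rng(seed)
    grid = grid or _grid()
    levels = rng.uniform(low, high, n)
    return [
        UniformTrajectory(f"C{i:03d}", "constant", grid,
                          np.full(grid.n_points, levels[i]),
                          np.zeros(grid.n_points, dtype=bool))
        for i in range(n)
    ]


def noise_trajectories(
    n: int = 30,
    grid: GridSpec | None = None,
    sd: float = 1.0,
    seed: int = 0,
) -> list[UniformTrajectory]:
    """n trajectories of iid Gaussian noise — the unpredictable extreme."""
    rng = np.random.default_rng(seed)
    grid = grid or _grid()
    return [
        UniformTrajectory(f"N{i:03d}", "noise", grid,
                          rng.normal(0, sd, grid.n_points),
                          np.zeros(grid.n_points, dtype=bool))
        for i in range(n)
    ]
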