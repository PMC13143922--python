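"""Raw trial data model and long-format CSV input/output.

Visit-level observations live in a long table (patient_id, week, variable,
value); static covariates (age, sex, BMI, weight, smoking, thymectomy arm,
prior corticosteroid use) live in a companion one-row-per-patient table.
Time is real-valued weeks from baseline; month M converts as 13/3 * M weeks.
Prednisone is stored as its daily-equivalent dose in mg/day (the alternate-day
protocol dose divided by two).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

WEEKS_PER_MONTH = 13.0 / 3.0

#: default variable registry: units and plausible ranges used for validation
DEFAULT_REGISTRY: dict[str, dict] = {
    "prednisone_daily_mg": {"units": "mg/day", "min": 0.0, "max": 80.0},
    "azathioprine_daily_mg": {"units": "mg/day", "min": 0.0, "max": 400.0},
    "qmg_total": {"units": "points", "min": 0.0, "max": 39.0},
    **{f"qmg_item_{j}": {"units": "points", "min": 0.0, "max": 3.0} for j in range(1, 14)},
    "adl_total": {"units": "points", "min": 0.0, "max": 24.0},
    **{f"adl_item_{j}": {"units": "points", "min": 0.0, "max": 3.0} for j in range(1, 9)},
    "rescue_event": {"units": "flag", "min": 0.0, "max": 1.0},
}

STATIC_COLUMNS = [
    "patient_id", "age_years", "sex", "bmi_kg_m2", "weight_kg",
    "smoker", "thymectomy", "prior_prednisone",
]


class CohortValidationError(ValueError):
    """Raised when a cohort violates a structural invariant."""


@dataclass
class PatientRecord:
    """One subject: static covariates plus per-variable irregular time series."""

    patient_id: str
    age_years: float | None = None
    sex: str | None = None  # "F" or "M"
    bmi_kg_m2: float | None = None
    weight_kg: float | None = None
    smoker: bool | None = None
    thymectomy: bool | None = None
    prior_prednisone: bool | None = None
    series: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    event_weeks: list[float] = field(default_factory=list)

    def weeks(self, variable: str) -> np.ndarray:
        return np.array([w for w, _ in self.series.get(variable, [])], dtype=float)

    def values(self, variable: str) -> np.ndarray:
        return np.array([v for _, v in self.series.get(variable, [])], dtype=float)

    def has_missing_covariates(self) -> bool:
        return any(
            getattr(self, c) is None
            for c in ("age_years", "sex", "bmi_kg_m2", "smoker", "thymectomy")
        )


@dataclass
class Cohort:
    """A trial dataset: patients plus the registry of observed variables."""

    patients: list[PatientRecord]
    variable_registry: dict[str, dict] = field(default_factory=lambda: dict(DEFAULT_REGISTRY))

    def __len__(self) -> int:
        return len(self.patients)

    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    def get(self, patient_id: str) -> PatientRecord:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)

    def variables(self) -> set[str]:
        out: set[str] = set()
        for p in self.patients:
            out.update(p.series)
        return out


def load_registry(path: str | Path) -> dict[str, dict]:
    """Load a variable registry from a JSON or YAML file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _coerce_bool(x) -> bool | None:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return None
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in ("true", "1", "yes", "y"):
        return True
    if s in ("false", "0", "no", "n"):
        return False
    return None


def read_long_csv(
    path: str | Path,
    registry: dict[str, dict] | None = None,
    static_path: str | Path | None = None,
) -> Cohort:
    """Read a long-format visit table (and optional static-covariate table).

    Duplicate (patient_id, week, variable) triples raise
    :class:`CohortValidationError`; values outside a registered range are kept
    (range findings are reported by :func:`validate_cohort`, not here).
    When 13 QMG items are supplied without a total, ``qmg_total`` is derived
    as their per-week sum.
    """
    registry = dict(registry) if registry is not None else dict(DEFAULT_REGISTRY)
    df = pd.read_csv(path)
    required = {"patient_id", "week", "variable", "value"}
    if not required.issubset(df.columns):
        raise CohortValidationError(
            f"long table must have columns {sorted(required)}, got {list(df.columns)}"
        )
    bad = pd.to_numeric(df["value"], errors="coerce").isna() & df["value"].notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # header is line 1
        raise CohortValidationError(f"unparseable numeric value at line {line}")
    df["value"] = pd.to_numeric(df["value"])
    df["week"] = pd.to_numeric(df["week"])

    dup = df.duplicated(subset=["patient_id", "week", "variable"], keep=False)
    if dup.any():
        r = df[dup].iloc[0]
        raise CohortValidationError(
            f"duplicate observation ({r['patient_id']}, {r['week']}, {r['variable']})"
        )

    static: dict[str, dict] = {}
    if static_path is not None:
        sdf = pd.read_csv(static_path)
        for _, row in sdf.iterrows():
            static[str(row["patient_id"])] = row.to_dict()

    patients: list[PatientRecord] = []
    for pid, grp in df.groupby("patient_id", sort=True):
        rec = PatientRecord(patient_id=str(pid))
        for var, sub in grp.groupby("variable", sort=True):
            sub = sub.sort_values("week")
            if var == "rescue_event":
                rec.event_weeks = [float(w) for w in sub["week"]]
                continue
            rec.series[str(var)] = list(
                zip(sub["week"].astype(float), sub["value"].astype(float))
            )
        _derive_qmg_total(rec)
        s = static.get(str(pid))
        if s is not None:
            rec.age_years = None if pd.isna(s.get("age_years")) else float(s["age_years"])
            rec.sex = None if pd.isna(s.get("sex")) else str(s["sex"])
            rec.bmi_kg_m2 = None if pd.isna(s.get("bmi_kg_m2")) else float(s["bmi_kg_m2"])
            rec.weight_kg = None if pd.isna(s.get("weight_kg")) else float(s["weight_kg"])
            rec.smoker = _coerce_bool(s.get("smoker"))
            rec.thymectomy = _coerce_bool(s.get("thymectomy"))
            rec.prior_prednisone = _coerce_bool(s.get("prior_prednisone"))
        patients.append(rec)
    return Cohort(patients=patients, variable_registry=registry)


def _derive_qmg_total(rec: PatientRecord) -> None:
    items = [f"qmg_item_{j}" for j in range(1, 14)]
    if "qmg_total" in rec.series or not all(v in rec.series for v in items):
        return
    weeks = rec.weeks(items[0])
    if any(not np.array_equal(rec.weeks(v), weeks) for v in items[1:]):
        return
    total = np.sum([rec.values(v) for v in items], axis=0)
    rec.series["qmg_total"] = list(zip(weeks.tolist(), total.tolist()))


def write_long_csv(
    cohort: Cohort, path: str | Path, static_path: str | Path | None = None
) -> None:
    """Write the long table (rows sorted by patient_id, variable, week)."""
    rows = []
    for p in cohort.patients:
        for var in sorted(p.series):
            for w, v in p.series[var]:
                rows.append((p.patient_id, w, var, v))
        for w in p.event_weeks:
            rows.append((p.patient_id, w, "rescue_event", 1.0))
    df = pd.DataFrame(rows, columns=["patient_id", "week", "variable", "value"])
    df = df.sort_values(["patient_id", "variable", "week"], kind="stable")
    df.to_csv(path, index=False, float_format="%.12g")
    if static_path is not None:
        write_static_csv(cohort, static_path)


def write_static_csv(cohort: Cohort, path: str | Path) -> None:
    rows = []
    for p in cohort.patients:
        rows.append({
            "patient_id": p.patient_id, "age_years": p.age_years, "sex": p.sex,
            "bmi_kg_m2": p.bmi_kg_m2, "weight_kg": p.weight_kg, "smoker": p.smoker,
            "thymectomy": p.thymectomy, "prior_prednisone": p.prior_prednisone,
        })
    pd.DataFrame(rows, columns=STATIC_COLUMNS).sort_values("patient_id").to_csv(
        path, index=False, float_format="%.12g"
    )


def validate_cohort(cohort: Cohort) -> list[str]:
    """Enumerate invariant violations and range warnings; empty list iff clean.

    Findings are sorted, hence stable under patient reordering.
    """
    findings: list[str] = []
    ids = cohort.patient_ids()
    for pid in sorted({i for i in ids if ids.count(i) > 1}):
        findings.append(f"violation: duplicate patient_id {pid}")
    for p in cohort.patients:
        for var, obs in p.series.items():
            weeks = np.array([w for w, _ in obs])
            if len(weeks) and weeks.min() < 0:
                findings.append(f"violation: {p.patient_id}/{var} has negative week")
            if np.any(np.diff(weeks) <= 0):
                findings.append(
                    f"violation: {p.patient_id}/{var} weeks not strictly increasing"
                )
            reg = cohort.variable_registry.get(var)
            if reg is None:
                findings.append(f"violation: unregistered variable {var} ({p.patient_id})")
                continue
            vals = np.array([v for _, v in obs])
            lo, hi = reg.get("min", -np.inf), reg.get("max", np.inf)
            n_out = int(np.sum((vals < lo) | (vals > hi)))
            if n_out:
                findings.append(
                    f"warning: {p.patient_id}/{var} has {n_out} value(s) outside "
                    f"[{lo}, {hi}]"
                )
        if p.has_missing_covariates():
            findings.append(f"warning: {p.patient_id} has missing static covariates")
    return sorted(findings)


def cohort_equal(a: Cohort, b: Cohort) -> bool:
    """Field-by-field equality of two cohorts (used by round-trip tests)."""
    if sorted(a.patient_ids()) != sorted(b.patient_ids()):
        return False
    for pid in a.patient_ids():
        pa, pb = a.get(pid), b.get(pid)
        if set(pa.series) != set(pb.series):
            return False
        for var in pa.series:
            if not np.allclose(pa.series[var], pb.series[var], rtol=0, atol=1e-9):
                return False
        if not np.allclose(pa.event_weeks, pb.event_weeks):
            return False
        for c in STATIC_COLUMNS[1:]:
            va, vb = getattr(pa, c), getattr(pb, c)
            if isinstance(va, float) and isinstance(vb, float):
                if not np.isclose(va, vb, rtol=0, atol=1e-9):
                    return False
            elif va != vb:
                return False
    return True
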