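"""Delimited-text readers and writers for the shared file formats.

Conventions shared by every format: grade is stored as percent in files
(human-facing) and as a fraction in memory; speed columns carry their unit
as a header suffix (``speed_m_s``, ``speed_mph``, ``speed_km_h``,
``speed_m_min``) or as a plain ``speed`` column whose unit is declared by
the caller.  Floats are written at full precision so write-then-read
round-trips to 1e-9.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from . import stats
from .metabolic import Workload
from .translation import GxtRecord, Prescription, SessionPlan, Subject
from .units import canonical_unit, from_m_per_min, to_m_per_min

_SUFFIX_UNITS = {"m_s": "m/s", "mph": "mph", "km_h": "km/h", "m_min": "m/min"}


def _find_speed_column(columns, declared_unit):
    for col in columns:
        if col == "speed":
            return col, canonical_unit(declared_unit)
        if col.startswith("speed_"):
            suffix = col[len("speed_"):]
            if suffix in _SUFFIX_UNITS:
                return col, _SUFFIX_UNITS[suffix]
    raise ValueError(
        "no speed column found (expected 'speed' or a unit-suffixed "
        "'speed_m_s' / 'speed_mph' / 'speed_km_h' / 'speed_m_min')"
    )


def read_gxt(
    path,
    *,
    speed_unit: str = "m/s",
    subject: Subject | None = None,
    delimiter: str = ",",
) -> GxtRecord:
    """Read a stage-end GXT table into a :class:`GxtRecord`.

    Expected columns: ``time_s``, a speed column, ``grade_pct``, ``hr_bpm``,
    ``rpe`` — one row per stage end, including the pre-test standing row at
    time 0 if present.  When ``subject`` is omitted, resting HR is taken from
    the first row and maximal HR from the highest measurement (the observed
    test-end value).
    """
    df = pd.read_csv(path, sep=delimiter)
    if df.empty:
        raise ValueError(f"{path}: GXT file has no stages")
    required = {"time_s", "grade_pct", "hr_bpm", "rpe"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    speed_col, unit = _find_speed_column(df.columns, speed_unit)
    stages, hr_series, rpe_series = [], [], []
    for row in df.itertuples(index=False):
        t = float(getattr(row, "time_s"))
        w = Workload(to_m_per_min(float(getattr(row, speed_col)), unit),
                     float(getattr(row, "grade_pct")) / 100.0)
        stages.append((t, w))
        hr_series.append((t, float(getattr(row, "hr_bpm"))))
        rpe_series.append((t, float(getattr(row, "rpe"))))
    if subject is None:
        subject = Subject(
            hr_rest=hr_series[0][1],
            hr_max=max(h for _, h in hr_series),
            rpe_max=max(r for _, r in rpe_series),
            id=Path(path).stem,
        )
    return GxtRecord(
        subject=subject,
        stages=tuple(stages),
        hr_series=tuple(hr_series),
        rpe_series=tuple(rpe_series),
        protocol_name=Path(path).stem,
    )


def write_gxt(record: GxtRecord, path, *, speed_unit: str = "m/s") -> None:
    """Write a GXT record in the stage-end table format."""
    unit = canonical_unit(speed_unit)
    suffix = {v: k for k, v in _SUFFIX_UNITS.items()}[unit]
    hr = dict(record.hr_series)
    rpe = dict(record.rpe_series)
    rows = [
        {
            "time_s": t,
            f"speed_{suffix}": from_m_per_min(w.speed, unit),
            "grade_pct": w.grade * 100.0,
            "hr_bpm": hr[t],
            "rpe": rpe[t],
        }
        for t, w in record.stages
        if t in hr
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_example_gxt() -> GxtRecord:
    """The worked-example Balke-type GXT that ships with the package
    (standing rest 70 bpm to maximum 160 bpm over six 2-min stages)."""
    src = resources.files("gxtrans").joinpath("data/balke_example_gxt.csv")
    with resources.as_file(src) as p:
        return read_gxt(p, speed_unit="m/s")


# ---------------------------------------------------------------------------
# prescriptions

def prescriptions_to_frame(prescriptions: dict, subject_id: str = "anon") -> pd.DataFrame:
    """Tidy table of prescriptions keyed by HRR fraction."""
    rows = []
    for fraction, rx in sorted(prescriptions.items()):
        rows.append(
            {
                "subject_id": subject_id,
                "hrr_fraction": fraction,
                "thr_bpm": rx.target.thr,
                "gxt_mets": rx.target.gxt_mets,
                "training_mets": rx.training_mets,
                "speed_m_s": rx.workload.speed_m_s,
                "grade_pct": rx.workload.grade_pct,
                "predicted_hr": rx.predicted_hr,
                "predicted_rpe": rx.predicted_rpe,
            }
        )
    return pd.DataFrame(rows)


def write_prescriptions(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_prescriptions(path, delimiter: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter)
    required = {"subject_id", "hrr_fraction", "thr_bpm", "training_mets",
                "grade_pct", "predicted_rpe"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def format_session_plan(
    plan: SessionPlan, *, label: str = "", grade_resolution_pct: float = 1.0
) -> str:
    """Human-readable session block; grade displayed at whole- or
    half-percent resolution."""

    def pct(g):
        q = grade_resolution_pct
        return f"{round(g * 100.0 / q) * q:g}%"

    def line(name, phase):
        return (
            f"  {name:<9} {phase.duration / 60.0:4.0f} min at "
            f"{phase.workload.speed_m_s:.2f} m/s, grade {pct(phase.workload.grade)}"
        )

    header = f"session {label}".strip()
    return "\n".join(
        [
            f"{header} (total {plan.total_duration / 60.0:.0f} min)",
            line("warm-up", plan.warmup),
            line("work", plan.work),
            line("cool-down", plan.cooldown),
        ]
    )


# ---------------------------------------------------------------------------
# bout logs

def bout_logs_to_frame(logs) -> pd.DataFrame:
    """Long table of bout samples: subject_id, intensity, time_s, hr_bpm, rpe."""
    rows = []
    for log in logs:
        for t, hr, rpe in log.samples:
            rows.append(
                {
                    "subject_id": log.subject.id,
                    "intensity": log.prescription.target.hrr_fraction,
                    "time_s": t,
                    "hr_bpm": hr,
                    "rpe": rpe,
                }
            )
    return pd.DataFrame(rows)


def write_bout_logs(logs_or_frame, path) -> None:
    df = (
        logs_or_frame
        if isinstance(logs_or_frame, pd.DataFrame)
        else bout_logs_to_frame(logs_or_frame)
    )
    df.to_csv(path, index=False)


def read_bout_logs(path, delimiter: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter)
    required = {"subject_id", "intensity", "time_s", "hr_bpm", "rpe"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def summarize_bout_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Steady-state (15/20/25-min mean) achieved HR/RPE per subject × intensity."""
    rows = []
    for (sid, intensity), g in df.groupby(["subject_id", "intensity"]):
        s = stats.summarize_window(
            g["time_s"].to_numpy(float),
            g["hr_bpm"].to_numpy(float),
            g["rpe"].to_numpy(float),
        )
        rows.append(
            {
                "subject_id": sid,
                "intensity": intensity,
                "achieved_hr": s.achieved_hr,
                "achieved_rpe": s.achieved_rpe,
                "complete_window": s.complete,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohorts

def cohort_to_frame(cohort) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": m.subject_id,
                "hr_rest": m.hr_rest,
                "hr_max": m.hr_max,
                "max_mets": m.max_mets,
                "true_kappa": m.true_kappa,
                "hr_noise_sd": m.hr_noise_sd,
                "rpe_noise_sd": m.rpe_noise_sd,
                "seed": m.seed,
            }
            for m in cohort
        ]
    )


def write_cohort(cohort, path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def read_cohort(path):
    from .simulate import PhysiologyModel

    df = pd.read_csv(path)
    return [
        PhysiologyModel(
            hr_rest=float(r.hr_rest),
            hr_max=float(r.hr_max),
            max_mets=float(r.max_mets),
            true_kappa=float(r.true_kappa),
            hr_noise_sd=float(r.hr_noise_sd),
            rpe_noise_sd=float(r.rpe_noise_sd),
            seed=int(r.seed),
            subject_id=str(r.subject_id),
        )
        for r in df.itertuples(index=False)
    ]
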