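"""Translate a graded exercise test into first-session training prescriptions.

The exercise intensity a subject experiences at a workload during a brief GXT
stage is *not* what they experience sustaining that workload for 20–30 min:
cardiovascular drift makes the sustained internal load (heart rate, perceived
exertion) substantially higher.  The generalized functional translation model
corrects for this by prescribing the training workload at a fixed fraction
(default 0.72) of the MET cost of the GXT stage at which the target heart
rate was reached, so that sustained training elicits the internal load the
GXT produced transiently.

Pipeline: pick a %HRR intensity (Karvonen target heart rate), locate the
moment the GXT heart-rate curve crosses it, take the belt speed/grade in
effect at that moment, compute its MET cost, scale by the translation factor,
and solve the metabolic equations backwards for a speed/grade combination —
avoiding the awkward 1.79–2.23 m/s band — that elicits the translated cost.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field

import numpy as np

from . import metabolic
from .errors import PreTestTargetError, TargetUnreachedError
from .metabolic import Workload

DEFAULT_TRANSLATION_FACTOR = 0.72
DEFAULT_FRACTIONS = (0.6, 0.7, 0.8)

WALK_SPEED = 1.34 * 60.0
"""Conventional prescription walking speed, m/min (1.34 m/s, 3 mph)."""

RUN_SPEED = 2.68 * 60.0
"""Conventional prescription running speed, m/min (2.68 m/s, 6 mph)."""

WARMUP_SPEED = 1.33 * 60.0
"""Warm-up / cool-down belt speed, m/min (1.33 m/s)."""


@dataclass(frozen=True)
class Subject:
    """Resting and maximal heart rate defining the heart-rate reserve.

    ``hr_rest`` is taken standing immediately pre-test; ``hr_max`` is the
    observed heart rate at test end.
    """

    hr_rest: float
    hr_max: float
    rpe_max: float | None = None
    id: str = "anon"

    def __post_init__(self):
        if not (20 <= self.hr_rest < self.hr_max <= 230):
            raise ValueError(
                f"require 20 <= hr_rest < hr_max <= 230, got "
                f"hr_rest={self.hr_rest}, hr_max={self.hr_max}"
            )
        if self.rpe_max is not None and not (6 <= self.rpe_max <= 20):
            raise ValueError(f"rpe_max {self.rpe_max} outside the 6–20 scale")

    @property
    def hrr(self) -> float:
        """Heart-rate reserve, hr_max − hr_rest (bpm)."""
        return self.hr_max - self.hr_rest


@dataclass(frozen=True)
class GxtRecord:
    """An incremental treadmill test: stages plus stage-end HR/RPE series.

    ``stages`` is an ordered tuple of ``(end_time_s, Workload)``; the belt is
    piecewise-constant, stage *k* occupying the interval from the previous
    stage's end (exclusive) to its own end (inclusive).  HR and RPE are
    measured at stage ends, so their sample times must be stage end times.
    """

    subject: Subject
    stages: tuple
    hr_series: tuple
    rpe_series: tuple
    protocol_name: str = ""
    submaximal: bool = False

    def __post_init__(self):
        object.__setattr__(self, "stages", tuple(tuple(s) for s in self.stages))
        object.__setattr__(self, "hr_series", tuple(tuple(s) for s in self.hr_series))
        object.__setattr__(self, "rpe_series", tuple(tuple(s) for s in self.rpe_series))
        ends = [t for t, _ in self.stages]
        if any(b <= a for a, b in zip(ends, ends[1:])):
            raise ValueError("stage end times must be strictly increasing")
        end_set = set(ends)
        for name, series in (("hr", self.hr_series), ("rpe", self.rpe_series)):
            times = [t for t, _ in series]
            if any(b <= a for a, b in zip(times, times[1:])):
                raise ValueError(f"{name}_series times must be strictly increasing")
            if not set(times) <= end_set:
                raise ValueError(f"{name}_series times must be stage end times")
        if any(not (6 <= r <= 20) for _, r in self.rpe_series):
            raise ValueError("RPE values must lie on the 6–20 scale")

    @property
    def stage_end_times(self) -> list[float]:
        return [t for t, _ in self.stages]

    def stage_at(self, time: float) -> Workload:
        """Belt workload in effect at ``time``.

        A time exactly on a stage boundary belongs to the stage just
        completed: the measurement made at a stage end reflects that stage.
        """
        ends = self.stage_end_times
        i = bisect.bisect_left(ends, time)
        if i >= len(ends):
            raise ValueError(f"time {time} beyond the end of the test")
        return self.stages[i][1]


@dataclass(frozen=True)
class IntensityTarget:
    """A %HRR level resolved against a specific GXT.

    ``gxt_workload``/``gxt_mets`` are the belt state and MET cost at the
    moment the heart rate reached the target; ``gxt_rpe`` is the perceived
    exertion interpolated at that moment.
    """

    hrr_fraction: float
    thr: float
    crossing_time: float
    gxt_workload: Workload
    gxt_mets: float
    gxt_rpe: float

    def __post_init__(self):
        if self.gxt_mets < 1:
            raise ValueError(f"gxt_mets {self.gxt_mets} below rest (1 MET)")


@dataclass(frozen=True)
class Prescription:
    """A translated training workload with its expected internal load."""

    target: IntensityTarget
    translation_factor: float
    training_mets: float
    workload: Workload
    predicted_hr: float
    predicted_rpe: float

    def __post_init__(self):
        expected = self.translation_factor * self.target.gxt_mets
        if not math.isclose(self.training_mets, expected, abs_tol=1e-9):
            raise ValueError(
                f"training_mets {self.training_mets} != "
                f"factor × gxt_mets = {expected}"
            )


@dataclass(frozen=True)
class Phase:
    """One session phase: duration in seconds at a fixed workload."""

    duration: float
    workload: Workload


@dataclass(frozen=True)
class SessionPlan:
    """Warm-up / work / cool-down structure of one training bout."""

    warmup: Phase
    work: Phase
    cooldown: Phase

    def __post_init__(self):
        if self.total_duration <= 0:
            raise ValueError("session plan must have positive total duration")

    @property
    def total_duration(self) -> float:
        return self.warmup.duration + self.work.duration + self.cooldown.duration


def target_hr(subject: Subject, fraction: float) -> float:
    """Karvonen target heart rate: hr_rest + fraction × (hr_max − hr_rest)."""
    if not (0 <= fraction <= 1):
        raise ValueError(f"HRR fraction must lie in [0, 1], got {fraction}")
    return subject.hr_rest + fraction * subject.hrr


def locate_target(record: GxtRecord, fraction: float) -> IntensityTarget:
    """Find where the GXT heart-rate curve first reaches a %HRR target.

    The stage-end HR series is regularized to be non-decreasing (cumulative
    maximum, absorbing measurement noise) and the first crossing of the
    target HR is found by linear interpolation in time.  The workload
    attributed to the crossing is the belt state in effect at that instant
    (piecewise-constant; a crossing exactly at a stage end belongs to the
    completed stage).  RPE is linearly interpolated at the crossing time.
    """
    thr = target_hr(record.subject, fraction)
    times = np.asarray([t for t, _ in record.hr_series], dtype=float)
    hrs = np.maximum.accumulate(np.asarray([h for _, h in record.hr_series], dtype=float))
    if thr > hrs[-1]:
        raise TargetUnreachedError(thr, float(hrs[-1]))
    if thr < hrs[0]:
        raise PreTestTargetError(
            f"target HR {thr:.1f} bpm below the first measurement "
            f"({hrs[0]:.1f} bpm at t={times[0]:g} s)"
        )
    i = int(np.argmax(hrs >= thr))
    if hrs[i] == thr or i == 0:
        t_cross = float(times[i])
    else:
        t_cross = float(
            times[i - 1]
            + (thr - hrs[i - 1]) / (hrs[i] - hrs[i - 1]) * (times[i] - times[i - 1])
        )
    workload = record.stage_at(t_cross)
    gxt_mets = metabolic.workload_mets(workload)
    rpe_t = np.asarray([t for t, _ in record.rpe_series], dtype=float)
    rpe_v = np.asarray([r for _, r in record.rpe_series], dtype=float)
    gxt_rpe = float(np.interp(t_cross, rpe_t, rpe_v))
    return IntensityTarget(
        hrr_fraction=fraction,
        thr=thr,
        crossing_time=t_cross,
        gxt_workload=workload,
        gxt_mets=gxt_mets,
        gxt_rpe=gxt_rpe,
    )


def default_speed_grid(record: GxtRecord | None = None) -> list[float]:
    """Candidate speeds: the GXT's own stage speeds plus the conventional
    walking (1.34 m/s) and running (2.68 m/s) prescription speeds."""
    speeds = {WALK_SPEED, RUN_SPEED}
    if record is not None:
        speeds.update(w.speed for _, w in record.stages if w.speed > 0)
    return sorted(speeds)


def translate(
    target: IntensityTarget,
    factor: float = DEFAULT_TRANSLATION_FACTOR,
    *,
    speed_grid=None,
    avoid_band: tuple = metabolic.AVOID_BAND,
    record: GxtRecord | None = None,
) -> Prescription:
    """Apply the functional translation model to one intensity target.

    ``training_mets = factor × gxt_mets``; the workload is the flattest
    feasible candidate on the speed grid outside the avoided band.  The
    prescription predicts the target heart rate and the GXT RPE as the
    sustained training response.
    """
    if not (0 < factor <= 1):
        raise ValueError(f"translation factor must lie in (0, 1], got {factor}")
    if speed_grid is None:
        speed_grid = default_speed_grid(record)
    training_mets = factor * target.gxt_mets
    candidates = metabolic.candidate_prescriptions(
        training_mets, speed_grid, avoid_band
    )
    return Prescription(
        target=target,
        translation_factor=factor,
        training_mets=training_mets,
        workload=candidates[0],
        predicted_hr=target.thr,
        predicted_rpe=target.gxt_rpe,
    )


def prescribe(
    record: GxtRecord,
    fractions=DEFAULT_FRACTIONS,
    factor: float = DEFAULT_TRANSLATION_FACTOR,
    *,
    speed_grid=None,
    avoid_band: tuple = metabolic.AVOID_BAND,
) -> dict[float, Prescription]:
    """Locate and translate every requested %HRR fraction of a GXT record."""
    out = {}
    for f in fractions:
        target = locate_target(record, f)
        out[f] = translate(
            target, factor, speed_grid=speed_grid, avoid_band=avoid_band,
            record=record,
        )
    return out


def build_session(
    prescription: Prescription,
    *,
    warmup_speed: float = WARMUP_SPEED,
    warmup_duration: float = 300.0,
    work_duration: float = 1200.0,
    cooldown_duration: float = 300.0,
) -> SessionPlan:
    """Assemble the 30-min bout: 5 min warm-up at 1.33 m/s and 0% grade,
    20 min at the prescribed workload, 5 min cool-down (defaults)."""
    easy = Workload(warmup_speed, 0.0)
    return SessionPlan(
        warmup=Phase(warmup_duration, easy),
        work=Phase(work_duration, prescription.workload),
        cooldown=Phase(cooldown_duration, easy),
    )
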