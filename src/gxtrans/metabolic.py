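"""Forward and inverse evaluation of the conventional treadmill metabolic equations.

The walking equation predicts steady-state oxygen uptake (mL·kg⁻¹·min⁻¹) as

    VO2 = 0.1·speed + 1.8·speed·grade + 3.5

and the running equation as

    VO2 = 0.2·speed + 0.9·speed·grade + 3.5

with speed in m/min and grade a dimensionless fraction (0.04 = 4%).  The 3.5
term is the resting component, so 1 MET = 3.5 mL·kg⁻¹·min⁻¹.  The walking
equation is nominally valid up to ~107 m/min (≈4 mph, 1.78 m/s) and the
running equation from ~134 m/min (≈5 mph, 2.23 m/s); in between, solely
walking or solely running is awkward, which is why prescriptions avoid the
1.79–2.23 m/s band.  Both equations are linear in speed at fixed grade and in
grade at fixed speed, so the inverse problems (solve for grade at a given
speed, or for speed at a given grade) have closed forms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .errors import (
    AvoidBandWarning,
    InfeasibleGradeError,
    InfeasiblePrescriptionError,
    ValidityError,
    ValidityWarning,
)
from .units import from_m_per_min, to_m_per_min

REST_VO2 = 3.5
"""Resting oxygen uptake, mL·kg⁻¹·min⁻¹ (1 MET)."""

GRADE_MIN = -0.20
GRADE_MAX = 0.30

WALK_MAX_SPEED = 107.0
"""Upper validity bound of the walking equation, m/min (≈4 mph)."""

RUN_MIN_SPEED = 134.0
"""Lower validity bound of the running equation, m/min (≈5 mph)."""

AVOID_BAND = (1.79 * 60.0, 2.23 * 60.0)
"""Speed band (m/min) avoided in prescriptions: 1.79–2.23 m/s, 4–5 mph."""

#: walking above this speed is treated as running when a cost must be
#: computed inside the avoided band (midpoint of the band, 2.0 m/s)
_EQUATION_SPLIT_SPEED = 120.0

_COEFFS = {
    "walking": (0.1, 1.8),
    "running": (0.2, 0.9),
}


@dataclass(frozen=True)
class Workload:
    """A treadmill belt state: speed in m/min and fractional grade.

    Use :meth:`of` to construct from other speed units.  Grade is restricted
    to the mechanical range of common treadmills, −20% to +30%.
    """

    speed: float
    grade: float

    def __post_init__(self):
        if not math.isfinite(self.speed) or self.speed < 0:
            raise ValueError(f"speed must be finite and >= 0, got {self.speed}")
        if not (GRADE_MIN <= self.grade <= GRADE_MAX):
            raise ValueError(
                f"grade {self.grade} outside [{GRADE_MIN}, {GRADE_MAX}]"
            )

    @classmethod
    def of(cls, speed: float, grade: float, unit: str = "m/min") -> "Workload":
        """Build a workload from a speed in any supported unit."""
        return cls(to_m_per_min(speed, unit), grade)

    def speed_in(self, unit: str) -> float:
        return from_m_per_min(self.speed, unit)

    @property
    def speed_m_s(self) -> float:
        return self.speed / 60.0

    @property
    def grade_pct(self) -> float:
        return self.grade * 100.0


@dataclass(frozen=True)
class MetabolicCost:
    """Oxygen uptake and its MET equivalent (vo2 / 3.5)."""

    vo2: float

    def __post_init__(self):
        if self.vo2 < 0:
            raise ValueError(f"vo2 must be >= 0, got {self.vo2}")

    @property
    def mets(self) -> float:
        return self.vo2 / REST_VO2


def _check_validity(ok: bool, message: str, strict: bool) -> None:
    if ok:
        return
    if strict:
        raise ValidityError(message)
    warnings.warn(message, ValidityWarning, stacklevel=3)


def vo2_walking(
    speed: float,
    grade: float,
    *,
    max_speed: float = WALK_MAX_SPEED,
    strict: bool = False,
) -> float:
    """Walking-equation oxygen cost, mL·kg⁻¹·min⁻¹.

    Parameters
    ----------
    speed : float
        Belt speed in m/min; nominal validity 0–``max_speed``.
    grade : float
        Fractional grade.
    strict : bool
        If True, speeds outside the validity range raise ``ValidityError``
        instead of warning.
    """
    _check_validity(
        0 <= speed <= max_speed,
        f"walking equation valid for 0–{max_speed:g} m/min, got {speed:g}",
        strict,
    )
    return 0.1 * speed + 1.8 * speed * grade + REST_VO2


def vo2_running(
    speed: float,
    grade: float,
    *,
    jogging: bool = False,
    min_speed: float = RUN_MIN_SPEED,
    strict: bool = False,
) -> float:
    """Running-equation oxygen cost, mL·kg⁻¹·min⁻¹.

    ``jogging=True`` acknowledges a true running gait below the nominal
    ``min_speed`` validity bound and suppresses the validity check.
    """
    if not jogging:
        _check_validity(
            speed >= min_speed,
            f"running equation valid above {min_speed:g} m/min, got {speed:g}"
            " (pass jogging=True for a slow running gait)",
            strict,
        )
    return 0.2 * speed + 0.9 * speed * grade + REST_VO2


def mets(vo2: float) -> float:
    """Convert oxygen uptake (mL·kg⁻¹·min⁻¹) to METs (÷ 3.5), exact."""
    if vo2 < 0:
        raise ValueError(f"vo2 must be >= 0, got {vo2}")
    return vo2 / REST_VO2


def mets_to_vo2(m: float) -> float:
    """Convert METs to oxygen uptake (× 3.5)."""
    if m < 0:
        raise ValueError(f"METs must be >= 0, got {m}")
    return m * REST_VO2


def display_mets(vo2: float, ndigits: int = 1) -> float:
    """MET value at reporting precision.

    VO2 is conventionally reported to 0.1 mL·kg⁻¹·min⁻¹ and MET tables are
    derived from the reported VO2, so the displayed value rounds VO2 first
    and then the quotient.  (Exact conversion stays in :func:`mets`.)
    """
    return round(round(vo2, ndigits) / REST_VO2, ndigits)


def equation_for_speed(speed: float, avoid_band: tuple = AVOID_BAND) -> str:
    """Pick walking vs running for a cost computation at ``speed`` (m/min).

    Below the band the gait is a walk, above it a run.  Inside the avoided
    band (where either gait is awkward) the band midpoint splits the choice
    and a warning is emitted, since such speeds occur in GXT protocols even
    though prescriptions never use them.
    """
    if avoid_band is not None and avoid_band[0] <= speed <= avoid_band[1]:
        warnings.warn(
            f"speed {speed:g} m/min lies inside the avoided walk/run band "
            f"({avoid_band[0]:g}–{avoid_band[1]:g} m/min); using the "
            f"{'walking' if speed <= _EQUATION_SPLIT_SPEED else 'running'} equation",
            AvoidBandWarning,
            stacklevel=2,
        )
    return "walking" if speed <= _EQUATION_SPLIT_SPEED else "running"


def workload_vo2(workload: Workload, *, strict: bool = False) -> float:
    """Oxygen cost of a workload, selecting the gait equation by speed."""
    eq = equation_for_speed(workload.speed)
    if eq == "walking":
        return vo2_walking(workload.speed, workload.grade, strict=strict)
    return vo2_running(workload.speed, workload.grade, strict=strict)


def workload_mets(workload: Workload, *, strict: bool = False) -> float:
    """MET cost of a workload (exact, not display-rounded)."""
    return mets(workload_vo2(workload, strict=strict))


def solve_grade(
    target_vo2: float,
    speed: float,
    equation: str = "walking",
    *,
    strict: bool = False,
) -> float:
    """Grade at which ``equation`` yields ``target_vo2`` at the given speed.

    Closed form: grade = (VO2 − 3.5 − h·speed) / (v·speed) with (h, v) the
    horizontal/vertical coefficients.  Raises ``InfeasibleGradeError``
    (carrying the unclamped value) when the solution falls outside treadmill
    grade limits.
    """
    if speed <= 0:
        raise ValueError("speed must be > 0 to solve for grade")
    h, v = _COEFFS[equation]
    if equation == "walking":
        _check_validity(
            speed <= WALK_MAX_SPEED,
            f"walking equation valid for 0–{WALK_MAX_SPEED:g} m/min, got {speed:g}",
            strict,
        )
    else:
        _check_validity(
            speed >= RUN_MIN_SPEED,
            f"running equation valid above {RUN_MIN_SPEED:g} m/min, got {speed:g}",
            strict,
        )
    grade = (target_vo2 - REST_VO2 - h * speed) / (v * speed)
    if not (GRADE_MIN <= grade <= GRADE_MAX):
        raise InfeasibleGradeError(grade)
    return grade


def solve_speed(
    target_vo2: float,
    grade: float,
    equation: str = "walking",
    *,
    strict: bool = False,
) -> float:
    """Speed at which ``equation`` yields ``target_vo2`` at the given grade.

    Closed form: speed = (VO2 − 3.5) / (h + v·grade).  The resulting speed is
    checked against the equation's validity range; outside it a warning (or
    error, in strict mode) suggests the other equation.
    """
    if target_vo2 < REST_VO2:
        raise ValueError(
            f"target VO2 {target_vo2:g} below the resting component {REST_VO2}"
        )
    h, v = _COEFFS[equation]
    denom = h + v * grade
    if denom <= 0:
        raise ValueError(
            f"non-positive speed coefficient (h + v·grade = {denom:g}); "
            "grade too steeply negative for this equation"
        )
    speed = (target_vo2 - REST_VO2) / denom
    if equation == "walking":
        _check_validity(
            speed <= WALK_MAX_SPEED,
            f"solution {speed:g} m/min above walking validity "
            f"({WALK_MAX_SPEED:g} m/min); consider the running equation",
            strict,
        )
    elif speed > 0:
        _check_validity(
            speed >= RUN_MIN_SPEED,
            f"solution {speed:g} m/min below running validity "
            f"({RUN_MIN_SPEED:g} m/min); consider the walking equation",
            strict,
        )
    return speed


def candidate_prescriptions(
    target_mets: float,
    speed_grid,
    avoid_band: tuple = AVOID_BAND,
    *,
    strict: bool = False,
) -> list[Workload]:
    """Feasible workloads eliciting ``target_mets`` on a grid of speeds.

    For each grid speed (m/min) outside the avoided band, solves the
    gait-appropriate equation for the grade that yields the target cost.
    Results are ordered by \\|grade\\| ascending (flattest first) and then by
    speed; an empty result raises ``InfeasiblePrescriptionError`` listing the
    per-speed reasons.
    """
    if target_mets <= 1:
        raise ValueError(f"target METs must exceed 1 (rest), got {target_mets}")
    speed_grid = list(speed_grid)
    if not speed_grid:
        raise ValueError("speed grid is empty")
    target_vo2 = mets_to_vo2(target_mets)
    out: list[Workload] = []
    reasons: dict[float, str] = {}
    seen: set[float] = set()
    for speed in speed_grid:
        if speed in seen:
            continue
        seen.add(speed)
        if speed <= 0:
            reasons[speed] = "non-positive speed"
            continue
        if avoid_band is not None and avoid_band[0] <= speed <= avoid_band[1]:
            reasons[speed] = (
                f"inside avoided band {avoid_band[0]:g}–{avoid_band[1]:g} m/min"
            )
            continue
        equation = "walking" if speed <= _EQUATION_SPLIT_SPEED else "running"
        try:
            grade = solve_grade(target_vo2, speed, equation, strict=strict)
        except InfeasibleGradeError as err:
            reasons[speed] = f"required grade {err.grade:.3f} outside limits"
            continue
        except ValidityError as err:
            reasons[speed] = str(err)
            continue
        out.append(Workload(speed, grade))
    if not out:
        raise InfeasiblePrescriptionError(reasons)
    out.sort(key=lambda w: (abs(w.grade), w.speed))
    return out
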