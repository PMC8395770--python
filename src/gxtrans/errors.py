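"""Exception and warning types shared across the package."""


class GxtransError(Exception):
    """Base class for all package-specific errors."""


class ValidityError(GxtransError, ValueError):
    """A treadmill metabolic equation was used outside its validity range."""


class ValidityWarning(UserWarning):
    """Equation used outside its nominal validity range (non-strict mode)."""


class AvoidBandWarning(UserWarning):
    """MET cost computed at a speed inside the avoided walk/run speed band."""


class SupramaximalWarning(UserWarning):
    """A simulated sustained load demands more than the subject's capacity."""


class InfeasibleGradeError(GxtransError):
    """The grade required to hit a target cost falls outside treadmill limits.

    Carries the unclamped value in ``grade``.
    """

    def __init__(self, grade: float, message: str | None = None):
        self.grade = grade
        super().__init__(
            message or f"required grade {grade:.4f} outside treadmill limits"
        )


class InfeasiblePrescriptionError(GxtransError):
    """No speed on the grid yields a feasible workload for the target METs.

    ``reasons`` maps each rejected speed (m/min) to a short explanation.
    """

    def __init__(self, reasons: dict):
        self.reasons = dict(reasons)
        detail = "; ".join(f"{s:g} m/min: {r}" for s, r in self.reasons.items())
        super().__init__(f"no feasible workload ({detail})")


class TargetUnreachedError(GxtransError):
    """The target heart rate was never reached during the test."""

    def __init__(self, thr: float, max_hr: float):
        self.thr = thr
        self.max_hr = max_hr
        super().__init__(
            f"target HR {thr:.1f} bpm never reached (max observed {max_hr:.1f} bpm)"
        )


class PreTestTargetError(GxtransError):
    """The target heart rate lies below the first measured heart rate."""


class MissingWindowError(GxtransError):
    """No steady-state window sample (15/20/25 min) is present in a bout log."""
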