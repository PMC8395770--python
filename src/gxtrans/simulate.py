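"""Synthetic subjects, graded exercise tests and training bouts.

The generator gives every other module a closed loop to test against.  Each
synthetic subject carries an affine internal-load model: heart rate rises
linearly with MET demand from ``hr_rest`` at 1 MET to ``hr_max`` at the
subject's capacity ``max_mets``, and RPE rises linearly with %HRR from 6 at
rest to 20 at maximum.  Cardiovascular drift is encoded by a sustained-load
equivalence factor ``true_kappa``: holding a workload of M METs for many
minutes produces the internal load the incremental test showed transiently
at M / kappa METs.  A translation factor equal to ``true_kappa`` therefore
makes sustained training land exactly on the targeted internal load — the
premise of the functional translation model.

Measurement noise is additive, independent, zero-mean Gaussian, clipped to
physiologic bounds.  A maximal test ends at the first stage whose MET demand
reaches the subject's capacity; the heart rate observed at that moment *is*
the subject's recorded ``hr_max`` (the reserve is defined from the observed
test-end value), so every %HRR target is reachable on a maximal record.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import metabolic, stats, translation
from .errors import SupramaximalWarning
from .metabolic import Workload
from .translation import GxtRecord, Prescription, SessionPlan, Subject


@dataclass(frozen=True)
class PhysiologyModel:
    """Ground-truth parameters of one synthetic subject."""

    hr_rest: float
    hr_max: float
    max_mets: float
    true_kappa: float = 0.72
    hr_noise_sd: float = 5.0
    rpe_noise_sd: float = 0.5
    seed: int | None = None
    subject_id: str = "sim"

    def __post_init__(self):
        if not self.hr_rest < self.hr_max:
            raise ValueError("hr_rest must be below hr_max")
        if self.max_mets <= 1:
            raise ValueError("max_mets must exceed 1 (rest)")
        if not (0 < self.true_kappa <= 1):
            raise ValueError("true_kappa must lie in (0, 1]")
        if self.hr_noise_sd < 0 or self.rpe_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")

    @property
    def curve(self) -> "ResponseCurve":
        return ResponseCurve(self.hr_rest, self.hr_max, self.max_mets)

    def subject(self) -> Subject:
        return Subject(self.hr_rest, self.hr_max, rpe_max=20.0, id=self.subject_id)


@dataclass(frozen=True)
class ResponseCurve:
    """Affine internal-load maps of a synthetic subject.

    HR(M) = hr_rest + (hr_max − hr_rest)·(M − 1)/(max_mets − 1);
    RPE(%HRR) = 6 + 14·%HRR.
    """

    hr_rest: float
    hr_max: float
    max_mets: float

    def hr_of_mets(self, m: float) -> float:
        return self.hr_rest + (self.hr_max - self.hr_rest) * (m - 1.0) / (
            self.max_mets - 1.0
        )

    def mets_of_hr(self, hr: float) -> float:
        return 1.0 + (self.max_mets - 1.0) * (hr - self.hr_rest) / (
            self.hr_max - self.hr_rest
        )

    def hrr_of_hr(self, hr: float) -> float:
        return (hr - self.hr_rest) / (self.hr_max - self.hr_rest)

    @staticmethod
    def rpe_of_hrr(hrr: float) -> float:
        return 6.0 + 14.0 * hrr

    def rpe_of_mets(self, m: float) -> float:
        return self.rpe_of_hrr(self.hrr_of_hr(self.hr_of_mets(m)))


# ---------------------------------------------------------------------------
# protocols

def load_protocol(name_or_path) -> list[tuple[float, Workload]]:
    """Load a stage schedule: CSV with duration_s, speed_m_s, grade_pct.

    ``balke`` (1.34 m/s constant, +2% every 2 min) and ``modified_bruce``
    (1-min stages ramping speed and grade) ship with the package; both are
    editable conventions, not authoritative protocol definitions.
    """
    name = str(name_or_path)
    if name in ("balke", "modified_bruce"):
        src = resources.files("gxtrans").joinpath(f"data/protocols/{name}.csv")
        text = src.read_text()
    else:
        text = Path(name_or_path).read_text()
    out = []
    for row in csv.DictReader(text.splitlines()):
        out.append(
            (
                float(row["duration_s"]),
                Workload.of(float(row["speed_m_s"]), float(row["grade_pct"]) / 100.0, "m/s"),
            )
        )
    if not out:
        raise ValueError(f"protocol {name!r} has no stages")
    return out


def protocol_met_ceiling(protocol) -> float:
    """Highest stage MET demand of a protocol."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return max(metabolic.workload_mets(w) for _, w in protocol)


# ---------------------------------------------------------------------------
# cohort generation

DEFAULT_RANGES = {
    "hr_rest": (60.0, 80.0),
    "hr_max": (180.0, 194.0),
    "max_mets": (11.5, 15.2),
}


def _draw(rng, spec):
    if isinstance(spec, (tuple, list)):
        lo, hi = spec
        if hi < lo:
            raise ValueError(f"invalid range ({lo}, {hi})")
        return float(rng.uniform(lo, hi))
    return float(spec)


def make_cohort(
    n: int,
    *,
    seed: int,
    hr_rest=DEFAULT_RANGES["hr_rest"],
    hr_max=DEFAULT_RANGES["hr_max"],
    max_mets=DEFAULT_RANGES["max_mets"],
    true_kappa: float = 0.72,
    hr_noise_sd: float = 5.0,
    rpe_noise_sd: float = 0.5,
) -> list[PhysiologyModel]:
    """Draw ``n`` synthetic subjects, parameters uniform within ranges.

    Scalar values pin a parameter exactly; ``(lo, hi)`` tuples draw
    uniformly.  Reproducible for a fixed seed: every subject receives a
    child seed spawned from the cohort seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    child_seeds = [int(c.generate_state(1)[0]) for c in ss.spawn(n)]
    cohort = []
    for i in range(n):
        cohort.append(
            PhysiologyModel(
                hr_rest=_draw(rng, hr_rest),
                hr_max=_draw(rng, hr_max),
                max_mets=_draw(rng, max_mets),
                true_kappa=_draw(rng, true_kappa),
                hr_noise_sd=_draw(rng, hr_noise_sd),
                rpe_noise_sd=_draw(rng, rpe_noise_sd),
                seed=child_seeds[i],
                subject_id=f"S{i + 1:03d}",
            )
        )
    return cohort


# ---------------------------------------------------------------------------
# simulation

def _clip(x, lo, hi):
    return float(min(max(x, lo), hi))


def simulate_gxt(
    model: PhysiologyModel,
    protocol=None,
    *,
    rng: np.random.Generator | None = None,
) -> GxtRecord:
    """Run one incremental test to volitional fatigue.

    Stage-end HR is the affine response plus Gaussian noise, clipped to
    [hr_rest, hr_max] and cumulative-max regularized; RPE analogously on
    [6, 20].  The test ends at the first stage demanding the subject's full
    capacity; that stage's HR is recorded as exactly hr_max and its RPE as
    maximal, since the observed test-end values define the reserve.  A
    protocol whose ceiling never reaches capacity yields a record flagged
    ``submaximal`` rather than an error.
    """
    if protocol is None:
        protocol = load_protocol("balke")
    protocol_name = "custom" if not isinstance(protocol, str) else protocol
    if rng is None:
        rng = np.random.default_rng(model.seed)
    curve = model.curve
    stages = [(0.0, Workload(0.0, 0.0))]
    hr_series = [(0.0, model.hr_rest)]
    rpe_series = [(0.0, 6.0)]
    t = 0.0
    maximal = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # GXT stages may cross the avoid band
        stage_mets = [metabolic.workload_mets(w) for _, w in protocol]
    for (duration, w), m in zip(protocol, stage_mets):
        t += duration
        stages.append((t, w))
        if m >= model.max_mets:
            hr = model.hr_max
            rpe = _clip(20.0 + rng.normal(0.0, model.rpe_noise_sd), 6.0, 20.0)
            hr_series.append((t, hr))
            rpe_series.append((t, rpe))
            maximal = True
            break
        clean_hr = curve.hr_of_mets(m)
        hr = _clip(
            clean_hr + rng.normal(0.0, model.hr_noise_sd),
            model.hr_rest,
            model.hr_max,
        )
        rpe = _clip(
            curve.rpe_of_hrr(curve.hrr_of_hr(clean_hr))
            + rng.normal(0.0, model.rpe_noise_sd),
            6.0,
            20.0,
        )
        hr_series.append((t, hr))
        rpe_series.append((t, rpe))
    hrs = np.maximum.accumulate([h for _, h in hr_series])
    rpes = np.maximum.accumulate([r for _, r in rpe_series])
    return GxtRecord(
        subject=model.subject(),
        stages=tuple(stages),
        hr_series=tuple((t_, float(h)) for (t_, _), h in zip(hr_series, hrs)),
        rpe_series=tuple((t_, float(r)) for (t_, _), r in zip(rpe_series, rpes)),
        protocol_name=str(protocol_name),
        submaximal=not maximal,
    )


def simulate_bout(
    model: PhysiologyModel,
    prescription: Prescription,
    plan: SessionPlan | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> stats.TrainingBoutLog:
    """Run one constant-load training bout under the drift model.

    The steady-state internal load of sustained work at M METs equals the
    incremental-test load at M / true_kappa METs; HR ramps linearly from rest
    across the warm-up and back toward the cool-down level at the end.
    Samples are taken at 5-min intervals.  A sustained demand exceeding the
    subject's capacity triggers a supramaximal warning and clips at hr_max.
    """
    if plan is None:
        plan = translation.build_session(prescription)
    if rng is None:
        rng = np.random.default_rng(model.seed)
    curve = model.curve
    work_m = metabolic.workload_mets(plan.work.workload)
    m_eff = work_m / model.true_kappa
    if m_eff > model.max_mets:
        warnings.warn(
            f"sustained demand {m_eff:.2f} METs exceeds capacity "
            f"{model.max_mets:.2f}; HR clipped at hr_max",
            SupramaximalWarning,
            stacklevel=2,
        )
    steady = min(curve.hr_of_mets(m_eff), model.hr_max)
    cool_m = metabolic.workload_mets(plan.cooldown.workload) / model.true_kappa
    cool = min(curve.hr_of_mets(cool_m), model.hr_max)
    wu, wk, cd = plan.warmup.duration, plan.work.duration, plan.cooldown.duration

    def clean_hr(t: float) -> float:
        if t <= wu:
            return model.hr_rest + (steady - model.hr_rest) * (t / wu if wu else 1.0)
        if t <= wu + wk:
            return steady
        return steady + (cool - steady) * ((t - wu - wk) / cd if cd else 1.0)

    samples = []
    n_samples = int(plan.total_duration // 300.0)
    for k in range(1, n_samples + 1):
        t = 300.0 * k
        c = clean_hr(t)
        hr = _clip(
            c + rng.normal(0.0, model.hr_noise_sd), model.hr_rest, model.hr_max
        )
        rpe = _clip(
            curve.rpe_of_hrr(curve.hrr_of_hr(c))
            + rng.normal(0.0, model.rpe_noise_sd),
            6.0,
            20.0,
        )
        samples.append((t, hr, rpe))
    return stats.TrainingBoutLog(
        subject=model.subject(), prescription=prescription, samples=tuple(samples)
    )


# ---------------------------------------------------------------------------
# parameter recovery

@dataclass(frozen=True)
class KappaRecovery:
    """Estimate of the sustained-load equivalence factor from bouts."""

    kappa: float
    per_bout: tuple
    n_unrecoverable: int

    def __float__(self) -> float:
        return self.kappa


def recover_kappa(gxt: GxtRecord, bouts) -> KappaRecovery:
    """Estimate kappa by inverting achieved bout HR on the GXT curve.

    For each bout, the achieved steady-state HR is mapped back to the MET
    level M* at which the GXT produced that HR (piecewise-linear
    interpolation of the stage-end HR-vs-METs curve, first crossing), and
    kappa is estimated as work METs / M*; the mean across recoverable bouts
    is returned.  Bouts whose achieved HR falls outside the observed GXT HR
    range are flagged unrecoverable and excluded.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pts = [
            (metabolic.workload_mets(gxt.stage_at(t)), h) for t, h in gxt.hr_series
        ]
    hrs_reg = np.maximum.accumulate([h for _, h in pts])
    mets_keep, hr_keep = [], []
    for (m, _), h in zip(pts, hrs_reg):
        if not hr_keep or h > hr_keep[-1]:
            mets_keep.append(m)
            hr_keep.append(float(h))
    hr_keep = np.asarray(hr_keep)
    mets_keep = np.asarray(mets_keep)
    estimates = []
    n_bad = 0
    for bout in bouts:
        achieved = stats.summarize_bout(bout).achieved_hr
        if achieved < hr_keep[0] or achieved > hr_keep[-1]:
            n_bad += 1
            continue
        m_star = float(np.interp(achieved, hr_keep, mets_keep))
        if m_star <= 0:
            n_bad += 1
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            work_m = metabolic.workload_mets(bout.prescription.workload)
        estimates.append(work_m / m_star)
    if not estimates:
        raise ValueError("no recoverable bout (achieved HR outside GXT range)")
    return KappaRecovery(
        kappa=float(np.mean(estimates)),
        per_bout=tuple(estimates),
        n_unrecoverable=n_bad,
    )


# ---------------------------------------------------------------------------
# end-to-end experiment

def run_subject(
    model: PhysiologyModel,
    *,
    factor: float = 0.72,
    fractions=translation.DEFAULT_FRACTIONS,
    protocol=None,
    rng: np.random.Generator | None = None,
):
    """GXT → locate → translate → bout → summary for one subject.

    Returns ``(record, results)`` where ``results`` maps each HRR fraction to
    a dict with the target, prescription, bout log and bout summary.
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    record = simulate_gxt(model, protocol, rng=rng)
    results = {}
    for f in fractions:
        target = translation.locate_target(record, f)
        rx = translation.translate(target, factor, record=record)
        log = simulate_bout(model, rx, rng=rng)
        results[f] = {
            "target": target,
            "prescription": rx,
            "log": log,
            "summary": stats.summarize_bout(log),
        }
    return record, results


def simulate_experiment(
    n: int = 20,
    *,
    seed: int,
    true_kappa: float = 0.72,
    factor: float = 0.72,
    fractions=translation.DEFAULT_FRACTIONS,
    hr_noise_sd: float = 5.0,
    rpe_noise_sd: float = 0.5,
    protocol=None,
    **cohort_ranges,
) -> pd.DataFrame:
    """Full cohort study: one tidy row per subject × intensity.

    Columns: subject_id, intensity, predicted/achieved HR and RPE, plus the
    located GXT METs and the translated training METs.
    """
    cohort = make_cohort(
        n,
        seed=seed,
        true_kappa=true_kappa,
        hr_noise_sd=hr_noise_sd,
        rpe_noise_sd=rpe_noise_sd,
        **cohort_ranges,
    )
    rows = []
    for model in cohort:
        _, results = run_subject(
            model, factor=factor, fractions=fractions, protocol=protocol
        )
        for f, r in results.items():
            rows.append(
                {
                    "subject_id": model.subject_id,
                    "intensity": f,
                    "predicted_hr": r["prescription"].predicted_hr,
                    "achieved_hr": r["summary"].achieved_hr,
                    "predicted_rpe": r["prescription"].predicted_rpe,
                    "achieved_rpe": r["summary"].achieved_rpe,
                    "gxt_mets": r["target"].gxt_mets,
                    "training_mets": r["prescription"].training_mets,
                }
            )
    return pd.DataFrame(rows)
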