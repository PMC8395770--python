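"""Predicted-vs-achieved agreement statistics for training bouts.

A training bout is summarized by averaging the HR and RPE samples at 15, 20
and 25 min (the steady-state window of a 30-min bout).  Achieved values are
then compared with the model's predictions per intensity via paired tests, a
repeated-measures decomposition, Pearson correlations, within-band
proportions (±10 bpm for HR, ±1 unit for RPE, closed intervals) and
Bland–Altman limits of agreement.

Sign conventions, fixed and stated in every report header:
paired difference = predicted − achieved; Bland–Altman bias = mean of
(achieved − predicted), i.e. the negative of the paired difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import MissingWindowError

STEADY_STATE_WINDOW = (900.0, 1200.0, 1500.0)
"""Bout sample times (s) averaged into the achieved response: 15/20/25 min."""

HR_BAND = 10.0
RPE_BAND = 1.0

SIGN_CONVENTION = (
    "paired difference = predicted - achieved; "
    "Bland-Altman bias = mean(achieved - predicted)"
)


@dataclass(frozen=True)
class BoutSummary:
    """Steady-state HR/RPE of one bout: mean over the 15/20/25-min samples."""

    achieved_hr: float
    achieved_rpe: float
    window: tuple
    complete: bool


@dataclass(frozen=True)
class TrainingBoutLog:
    """HR/RPE sampled at 5-min intervals during one prescribed bout."""

    subject: object
    prescription: object
    samples: tuple  # (time_s, hr, rpe)

    def __post_init__(self):
        object.__setattr__(self, "samples", tuple(tuple(s) for s in self.samples))
        allowed = {300.0 * k for k in range(1, 7)}
        for t, _, rpe in self.samples:
            if float(t) not in allowed:
                raise ValueError(
                    f"sample time {t} s not on the 5-min grid (300–1800 s)"
                )
            if not (6 <= rpe <= 20):
                raise ValueError(f"RPE {rpe} outside the 6–20 scale")


def summarize_window(times, hrs, rpes, window=STEADY_STATE_WINDOW) -> BoutSummary:
    """Average HR/RPE over the samples falling in the steady-state window."""
    times = np.asarray(times, dtype=float)
    mask = np.isin(times, np.asarray(window, dtype=float))
    if not mask.any():
        raise MissingWindowError(
            f"no sample at any of the window times {tuple(window)} s"
        )
    used = tuple(times[mask])
    return BoutSummary(
        achieved_hr=float(np.mean(np.asarray(hrs, dtype=float)[mask])),
        achieved_rpe=float(np.mean(np.asarray(rpes, dtype=float)[mask])),
        window=used,
        complete=len(used) == len(window),
    )


def summarize_bout(log: TrainingBoutLog, window=STEADY_STATE_WINDOW) -> BoutSummary:
    """Steady-state summary of a bout log (15/20/25-min mean by default)."""
    t = [s[0] for s in log.samples]
    hr = [s[1] for s in log.samples]
    rpe = [s[2] for s in log.samples]
    return summarize_window(t, hr, rpe, window)


@dataclass(frozen=True)
class PairedComparison:
    """Paired predicted-vs-achieved comparison for one intensity."""

    n: int
    mean_diff: float  # predicted − achieved
    sd_diff: float
    t_stat: float
    p_value: float
    degenerate: bool  # zero variance of the paired differences


def paired_comparison(predicted, achieved) -> PairedComparison:
    """Paired t-test of predicted − achieved (n ≥ 3, equal lengths).

    Zero variance of the differences is a degenerate case: the t statistic is
    undefined, so the comparison is flagged and the mean difference still
    reported (p = 1 when the difference is identically zero).
    """
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(achieved, dtype=float)
    if p.shape != a.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {a.shape}")
    n = p.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    d = p - a
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    if sd_diff == 0.0:
        return PairedComparison(
            n=n,
            mean_diff=mean_diff,
            sd_diff=0.0,
            t_stat=math.nan,
            p_value=1.0 if mean_diff == 0.0 else math.nan,
            degenerate=True,
        )
    t_stat, p_value = sps.ttest_rel(p, a)
    return PairedComparison(
        n=n,
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        t_stat=float(t_stat),
        p_value=float(p_value),
        degenerate=False,
    )


def repeated_measures_anova(df: pd.DataFrame) -> pd.DataFrame:
    """Two-way repeated-measures ANOVA table.

    ``df`` must be long-format with columns ``subject``, ``measurement``
    (predicted/achieved), ``intensity`` and ``value``; every subject must
    have all measurement × intensity cells (balanced design).
    """
    from statsmodels.stats.anova import AnovaRM

    res = AnovaRM(
        df, depvar="value", subject="subject", within=["measurement", "intensity"]
    ).fit()
    return res.anova_table


def tukey_cell_comparisons(df: pd.DataFrame):
    """Tukey HSD across the measurement × intensity cell means."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    cells = df["measurement"].astype(str) + "@" + df["intensity"].astype(str)
    return pairwise_tukeyhsd(df["value"].to_numpy(float), cells.to_numpy())


def within_band_proportion(predicted, achieved, band: float) -> float:
    """Fraction of pairs with |predicted − achieved| ≤ band (closed)."""
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(achieved, dtype=float)
    if p.shape != a.shape or p.size == 0:
        raise ValueError("predicted/achieved must be equal-length, non-empty")
    return float(np.mean(np.abs(p - a) <= band))


def pearson_r(predicted, achieved) -> float | None:
    """Pearson correlation; None when either vector has zero variance."""
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(achieved, dtype=float)
    if np.ptp(p) == 0 or np.ptp(a) == 0:
        return None
    return float(sps.pearsonr(p, a)[0])


@dataclass(frozen=True)
class BlandAltman:
    """Bias = mean(achieved − predicted) with ±1.96·SD limits of agreement."""

    bias: float
    loa_low: float
    loa_high: float


def bland_altman(predicted, achieved) -> BlandAltman:
    d = np.asarray(achieved, dtype=float) - np.asarray(predicted, dtype=float)
    bias = float(d.mean())
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return BlandAltman(bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd)


@dataclass(frozen=True)
class AgreementStats:
    """Agreement of one predicted/achieved vector pair."""

    n: int
    r: float | None
    within_band: float
    band: float
    bland_altman: BlandAltman


def agreement(predicted, achieved, band: float) -> AgreementStats:
    """Pearson r, within-band proportion and Bland–Altman for one pair of
    vectors (n ≥ 2).  Band bounds are inclusive."""
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(achieved, dtype=float)
    if p.shape != a.shape or p.size < 2:
        raise ValueError("need paired vectors with n >= 2")
    return AgreementStats(
        n=p.size,
        r=pearson_r(p, a),
        within_band=within_band_proportion(p, a, band),
        band=band,
        bland_altman=bland_altman(p, a),
    )


@dataclass
class AgreementReport:
    """Per-intensity and pooled predicted-vs-achieved agreement.

    ``per_intensity`` maps intensity label → dict with predicted/achieved
    mean ± SD, n, the paired comparison, and per-intensity r for HR and RPE.
    """

    per_intensity: dict
    pooled_hr: AgreementStats
    pooled_rpe: AgreementStats
    hr_band: float
    rpe_band: float
    sign_convention: str = SIGN_CONVENTION


def compare_predictions(
    df: pd.DataFrame,
    hr_band: float = HR_BAND,
    rpe_band: float = RPE_BAND,
) -> AgreementReport:
    """Build the full agreement report from a tidy predicted/achieved table.

    ``df`` columns: ``subject_id``, ``intensity``, ``predicted_hr``,
    ``achieved_hr``, ``predicted_rpe``, ``achieved_rpe`` — one row per
    subject × intensity.
    """
    required = {
        "subject_id", "intensity",
        "predicted_hr", "achieved_hr", "predicted_rpe", "achieved_rpe",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if len(df) < 2:
        raise ValueError("need at least two subject × intensity observations")
    per = {}
    for intensity, g in df.groupby("intensity"):
        entry = {"n": len(g)}
        for var, band in (("hr", hr_band), ("rpe", rpe_band)):
            p = g[f"predicted_{var}"].to_numpy(float)
            a = g[f"achieved_{var}"].to_numpy(float)
            entry[f"predicted_{var}_mean"] = float(p.mean())
            entry[f"predicted_{var}_sd"] = float(p.std(ddof=1)) if len(g) > 1 else 0.0
            entry[f"achieved_{var}_mean"] = float(a.mean())
            entry[f"achieved_{var}_sd"] = float(a.std(ddof=1)) if len(g) > 1 else 0.0
            entry[f"{var}_r"] = pearson_r(p, a) if len(g) > 1 else None
            entry[f"{var}_within_band"] = within_band_proportion(p, a, band)
            entry[f"{var}_comparison"] = (
                paired_comparison(p, a) if len(g) >= 3 else None
            )
        per[intensity] = entry
    pooled_hr = agreement(df["predicted_hr"], df["achieved_hr"], hr_band)
    pooled_rpe = agreement(df["predicted_rpe"], df["achieved_rpe"], rpe_band)
    return AgreementReport(
        per_intensity=per,
        pooled_hr=pooled_hr,
        pooled_rpe=pooled_rpe,
        hr_band=hr_band,
        rpe_band=rpe_band,
    )


def format_report(report: AgreementReport) -> str:
    """Plain-text summary table: predicted/achieved mean ± SD per intensity
    (significance of the paired test flagged with *), then pooled agreement."""
    lines = [
        "Predicted vs achieved training responses",
        f"  ({report.sign_convention})",
        "",
        f"{'intensity':>10} {'pred HR':>13} {'achieved HR':>15} "
        f"{'pred RPE':>12} {'achieved RPE':>14}",
    ]
    for intensity in sorted(report.per_intensity):
        e = report.per_intensity[intensity]
        def cell(var, side):
            m = e[f"{side}_{var}_mean"]
            s = e[f"{side}_{var}_sd"]
            comp = e[f"{var}_comparison"]
            star = (
                " *"
                if side == "achieved"
                and comp is not None
                and not comp.degenerate
                and comp.p_value < 0.05
                else ""
            )
            return f"{m:.1f} ± {s:.1f}{star}"
        lines.append(
            f"{str(intensity):>10} {cell('hr', 'predicted'):>13} "
            f"{cell('hr', 'achieved'):>15} {cell('rpe', 'predicted'):>12} "
            f"{cell('rpe', 'achieved'):>14}"
        )
    lines += [
        "",
        "* paired p < 0.05 vs predicted",
        "",
        f"pooled HR : n={report.pooled_hr.n}, r="
        + (f"{report.pooled_hr.r:.2f}" if report.pooled_hr.r is not None else "n/a")
        + f", within ±{report.hr_band:g} bpm: {100 * report.pooled_hr.within_band:.0f}%"
        + f", bias {report.pooled_hr.bland_altman.bias:+.1f} bpm"
        + f" (LoA {report.pooled_hr.bland_altman.loa_low:+.1f}"
        + f" to {report.pooled_hr.bland_altman.loa_high:+.1f})",
        f"pooled RPE: n={report.pooled_rpe.n}, r="
        + (f"{report.pooled_rpe.r:.2f}" if report.pooled_rpe.r is not None else "n/a")
        + f", within ±{report.rpe_band:g} units: {100 * report.pooled_rpe.within_band:.0f}%"
        + f", bias {report.pooled_rpe.bland_altman.bias:+.2f}"
        + f" (LoA {report.pooled_rpe.bland_altman.loa_low:+.2f}"
        + f" to {report.pooled_rpe.bland_altman.loa_high:+.2f})",
    ]
    return "\n".join(lines)
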