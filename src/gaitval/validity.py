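"""Concurrent-validity metrics between paired measurement systems.

Metrics are computed cycle by cycle on matched curve pairs, then averaged
across cycles and sides within each subject, then across subjects within
each group.  RMSE decomposes exactly as
``rmse**2 == centered_rmse**2 + mean_difference**2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from gaitval.datamodel_io import (
    GROUPS,
    OUTCOMES,
    AngleCycle,
    CohortTable,
    GaitvalError,
    PairingError,
    ValidationError,
    get_logger,
)

logger = get_logger("gaitval.validity")

ALTMAN_BANDS: Tuple[Tuple[float, str], ...] = (
    (0.80, "very good"),
    (0.60, "good"),
    (0.40, "moderate"),
    (0.20, "fair"),
    (-1.0, "poor"),
)


class UndefinedCorrelationError(GaitvalError):
    """Correlation undefined because a curve is constant."""


class DegenerateAmplitudeError(GaitvalError):
    """Reference curve amplitude too small for a relative metric."""


@dataclass
class ValidityMetrics:
    rmse: float
    centered_rmse: float
    cc: float
    delta_rom: float
    relative_rmse: float


def _check_pair(a: AngleCycle, b: AngleCycle) -> None:
    if a.outcome != b.outcome:
        raise PairingError(f"outcome mismatch: {a.outcome} vs {b.outcome}")
    if a.side != b.side:
        raise PairingError(f"side mismatch: {a.side} vs {b.side}")


def rmse(a: AngleCycle, b: AngleCycle) -> float:
    """Root mean square of the pointwise differences, in degrees."""
    _check_pair(a, b)
    d = a.samples - b.samples
    return float(np.sqrt(np.mean(d * d)))


def centered_rmse(a: AngleCycle, b: AngleCycle) -> float:
    """RMSE after removing each curve's own mean (offset-free waveform error)."""
    _check_pair(a, b)
    d = (a.samples - a.samples.mean()) - (b.samples - b.samples.mean())
    return float(np.sqrt(np.mean(d * d)))


def pearson_cc(a: AngleCycle, b: AngleCycle) -> float:
    """Pearson correlation over the 101 points of a curve pair."""
    _check_pair(a, b)
    if np.ptp(a.samples) == 0 or np.ptp(b.samples) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant curve")
    r = np.corrcoef(a.samples, b.samples)[0, 1]
    return float(r)


def delta_rom(a: AngleCycle, b: AngleCycle) -> float:
    """Absolute difference in range of motion, degrees."""
    _check_pair(a, b)
    return float(abs(np.ptp(a.samples) - np.ptp(b.samples)))


def relative_rmse(a: AngleCycle, b: AngleCycle) -> float:
    """RMSE as percent of the reference (first) curve's amplitude."""
    _check_pair(a, b)
    amp = float(np.ptp(a.samples))
    if amp <= 1.0:
        raise DegenerateAmplitudeError(
            f"reference amplitude {amp:.3f} deg too small for relative RMSE"
        )
    return 100.0 * rmse(a, b) / amp


def pair_metrics(opto: AngleCycle, imu: AngleCycle) -> ValidityMetrics:
    """All validity metrics for one matched (reference, test) cycle pair.

    Correlation is NaN (pair excluded from CC averaging, logged) when a
    curve is constant; relative RMSE is NaN for degenerate amplitudes.
    """
    try:
        cc = pearson_cc(opto, imu)
    except UndefinedCorrelationError:
        logger.info("constant curve in %s pair: CC excluded", opto.outcome)
        cc = np.nan
    try:
        rel = relative_rmse(opto, imu)
    except DegenerateAmplitudeError:
        rel = np.nan
    return ValidityMetrics(
        rmse=rmse(opto, imu),
        centered_rmse=centered_rmse(opto, imu),
        cc=cc,
        delta_rom=delta_rom(opto, imu),
        relative_rmse=rel,
    )


METRIC_NAMES = ("rmse", "centered_rmse", "cc", "delta_rom", "relative_rmse")


@dataclass
class ValiditySummary:
    """Aggregated validity results.

    ``per_subject``: one row per (subject, group, outcome) with cycle/side
    averaged metrics.  ``per_group``: mean and 95% CI half-width across
    subjects per (group, outcome), with the clinical-acceptability flag on
    RMSE.  ``overall``: per-group means across all outcomes.
    """

    per_subject: pd.DataFrame
    per_group: pd.DataFrame
    overall: pd.DataFrame


def subject_metric_table(table: CohortTable, session: int = 1) -> pd.DataFrame:
    """Per-pair metrics reduced to subject level (mean over cycles and sides)."""
    rows = []
    for key, opto, imu in table.iter_pairs():
        if key.session != session:
            continue
        m = pair_metrics(opto, imu)
        rows.append(
            {
                "subject_id": key.subject_id,
                "group": key.group,
                "outcome": opto.outcome,
                **{name: getattr(m, name) for name in METRIC_NAMES},
            }
        )
    if not rows:
        raise PairingError("no matched OPTO/IMU cycle pairs found")
    df = pd.DataFrame(rows)
    return (
        df.groupby(["subject_id", "group", "outcome"], as_index=False)[list(METRIC_NAMES)]
        .mean()
    )


def summarize_validity(
    table: CohortTable,
    clinical_threshold: float = 5.0,
    session: int = 1,
) -> ValiditySummary:
    """Aggregate pairwise metrics: cycles/sides -> subject -> group.

    The 95% CI half-width is a t-interval across subjects; it is NaN (with a
    warning) for groups with fewer than 2 subjects.
    """
    per_subject = subject_metric_table(table, session=session)

    def _ci_half(x: pd.Series) -> float:
        x = x.dropna()
        if len(x) < 2:
            return np.nan
        return float(
            stats.t.ppf(0.975, len(x) - 1) * x.std(ddof=1) / np.sqrt(len(x))
        )

    group_rows = []
    for (group, outcome), sub in per_subject.groupby(["group", "outcome"]):
        if len(sub) < 2:
            logger.warning("group %s has <2 subjects: CI omitted", group)
        row = {"group": group, "outcome": outcome, "n_subjects": len(sub)}
        for name in METRIC_NAMES:
            row[f"{name}_mean"] = float(sub[name].mean())
            row[f"{name}_ci95"] = _ci_half(sub[name])
        row["rmse_acceptable"] = bool(row["rmse_mean"] < clinical_threshold)
        group_rows.append(row)
    per_group = pd.DataFrame(group_rows).sort_values(["group", "outcome"]).reset_index(drop=True)

    overall = (
        per_group.groupby("group", as_index=False)[[f"{n}_mean" for n in METRIC_NAMES]]
        .mean()
    )
    return ValiditySummary(per_subject=per_subject, per_group=per_group, overall=overall)


def interpret_cc_altman(cc: float) -> str:
    """Correlation band with inclusive lower bounds at .20/.40/.60/.80."""
    if not (-1.0 <= cc <= 1.0):
        raise ValidationError(f"correlation {cc} outside [-1, 1]")
    for bound, label in ALTMAN_BANDS:
        if cc >= bound:
            return label
    return "poor"


def rmse_vs_gps_correlation(
    table: CohortTable,
    gps_opto: Dict[str, float],
    session: int = 1,
) -> pd.DataFrame:
    """Per-outcome correlation between subject RMSE and reference gait profile
    score, with band label and two-sided p-value."""
    per_subject = subject_metric_table(table, session=session)
    rows = []
    for outcome, sub in per_subject.groupby("outcome"):
        sub = sub[sub["subject_id"].isin(gps_opto)]
        if len(sub) < 3:
            raise ValidationError("need at least 3 subjects for RMSE-GPS correlation")
        x = sub["rmse"].to_numpy()
        y = np.array([gps_opto[s] for s in sub["subject_id"]])
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise UndefinedCorrelationError(
                f"constant RMSE or GPS vector for outcome {outcome}"
            )
        r, p = stats.pearsonr(x, y)
        rows.append(
            {
                "outcome": outcome,
                "cc": float(r),
                "p_value": float(p),
                "band": interpret_cc_altman(float(r)),
                "n": len(sub),
            }
        )
    return pd.DataFrame(rows)
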