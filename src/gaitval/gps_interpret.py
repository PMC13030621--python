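"""Gait profile scores and interpretability statistics.

The gait variable score (GVS) of one outcome is the RMS distance between a
subject's curve and the normative mean curve over the gait cycle; the gait
profile score (GPS) of one side is the RMS of the nine GVS values.  Each
measurement system gets its own normative bank (mean asymptomatic-group
kinematics measured by that system), so banks and scores never mix systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from gaitval.datamodel_io import (
    GPS_OUTCOMES,
    N_SAMPLES,
    AnalysisConfig,
    AngleCycle,
    CohortTable,
    CoverageError,
    PairingError,
    ValidationError,
    get_logger,
)

logger = get_logger("gaitval.gps")


@dataclass
class NormativeBank:
    """Per-outcome normative mean curves for one measurement system."""

    system: str
    curves: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if set(self.curves) != set(GPS_OUTCOMES):
            raise CoverageError(
                "normative bank must contain exactly the 9 profile-score outcomes"
            )


@dataclass
class GpsResult:
    """Per-side scores for one subject and system."""

    subject_id: str
    system: str
    side: str
    gvs: Dict[str, float]
    gps: float


def build_normative_bank(
    table: CohortTable, system: str, session: int = 1
) -> NormativeBank:
    """Pointwise mean across all asymptomatic-group cycles (sides pooled)."""
    sums: Dict[str, np.ndarray] = {o: np.zeros(N_SAMPLES) for o in GPS_OUTCOMES}
    counts: Dict[str, int] = {o: 0 for o in GPS_OUTCOMES}
    for key, cycle in table.iter_all():
        if key.group != "AS" or key.session != session:
            continue
        if cycle.system != system or cycle.outcome not in sums:
            continue
        sums[cycle.outcome] += cycle.samples
        counts[cycle.outcome] += 1
    missing = [o for o in GPS_OUTCOMES if counts[o] == 0]
    if missing:
        raise CoverageError(
            f"no asymptomatic {system} cycles for outcome(s): {', '.join(missing)}"
        )
    return NormativeBank(
        system=system, curves={o: sums[o] / counts[o] for o in GPS_OUTCOMES}
    )


def gait_variable_score(
    cycle: AngleCycle,
    reference: np.ndarray,
    reference_outcome: Optional[str] = None,
) -> float:
    """RMS distance (degrees) between a curve and a normative mean curve."""
    if reference_outcome is not None and reference_outcome != cycle.outcome:
        raise PairingError(
            f"outcome mismatch: {cycle.outcome} vs reference {reference_outcome}"
        )
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (N_SAMPLES,):
        raise ValidationError(f"reference curve must have {N_SAMPLES} samples")
    d = cycle.samples - reference
    return float(np.sqrt(np.mean(d * d)))


def gps_for_side(
    cycles: Sequence[AngleCycle],
    bank: NormativeBank,
    subject_id: str = "",
    side: Optional[str] = None,
) -> GpsResult:
    """Scores for one subject-side from its (cycle-averaged) outcome curves.

    ``cycles`` may hold several cycles per outcome; the subject curve per
    outcome is their pointwise mean.  All 9 profile-score outcomes must be
    present.
    """
    by_outcome: Dict[str, List[np.ndarray]] = {}
    sides = set()
    for c in cycles:
        if c.outcome in bank.curves:
            by_outcome.setdefault(c.outcome, []).append(c.samples)
            sides.add(c.side)
    missing = [o for o in GPS_OUTCOMES if o not in by_outcome]
    if missing:
        raise CoverageError(f"missing outcome(s) for scoring: {', '.join(missing)}")
    if side is None:
        side = sides.pop() if len(sides) == 1 else "both"
    gvs: Dict[str, float] = {}
    for outcome in GPS_OUTCOMES:
        mean_curve = np.mean(by_outcome[outcome], axis=0)
        subject_cycle = AngleCycle(outcome, "left", 0, bank.system, mean_curve)
        gvs[outcome] = gait_variable_score(subject_cycle, bank.curves[outcome], outcome)
    gps = float(np.sqrt(np.mean(np.array([gvs[o] for o in GPS_OUTCOMES]) ** 2)))
    return GpsResult(subject_id=subject_id, system=bank.system, side=side, gvs=gvs, gps=gps)


def gps_table(
    table: CohortTable,
    banks: Dict[str, NormativeBank],
    session: int = 1,
) -> pd.DataFrame:
    """Side-mean GPS per subject and system.

    Columns: subject_id, group, gps_<system> per system in ``banks`` plus
    gps_<system>_left/right.
    """
    rows: Dict[str, Dict[str, object]] = {}
    for key in table.subject_keys():
        if key.session != session:
            continue
        cycles = table.cycles(key)
        row = rows.setdefault(
            key.subject_id, {"subject_id": key.subject_id, "group": key.group}
        )
        for system, bank in banks.items():
            side_vals = []
            for side in ("left", "right"):
                subset = [c for c in cycles if c.system == system and c.side == side]
                if not subset:
                    continue
                res = gps_for_side(subset, bank, key.subject_id, side)
                row[f"gps_{system.lower()}_{side}"] = res.gps
                side_vals.append(res.gps)
            if side_vals:
                row[f"gps_{system.lower()}"] = float(np.mean(side_vals))
    return pd.DataFrame(list(rows.values())).sort_values("subject_id").reset_index(drop=True)


def mdc_flag(delta_gps: float, group: str, config: AnalysisConfig) -> bool:
    """True iff |delta| strictly exceeds the group's minimal detectable change."""
    return abs(delta_gps) > config.mdc_for_group(group)


def find_outliers(gps_values) -> List:
    """Tukey rule: values beyond 1.5 x IQR outside the quartiles.

    Accepts a mapping (subject -> value) or a sequence; returns the flagged
    keys (or indices).
    """
    if isinstance(gps_values, dict):
        keys = list(gps_values.keys())
        vals = np.array([gps_values[k] for k in keys], dtype=float)
    else:
        vals = np.asarray(gps_values, dtype=float)
        keys = list(range(vals.size))
    if vals.size < 4:
        raise ValidationError("need at least 4 values for outlier detection")
    q1, q3 = np.percentile(vals, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return [k for k, v in zip(keys, vals) if v < lo or v > hi]


def _is_normal(x: np.ndarray, alpha: float) -> bool:
    if x.size < 3 or np.ptp(x) == 0:
        return False
    return stats.shapiro(x).pvalue >= alpha


def _paired_test(a: np.ndarray, b: np.ndarray, parametric: bool) -> Tuple[float, str]:
    d = a - b
    if np.allclose(d, 0.0):
        return 1.0, "degenerate"
    if parametric:
        return float(stats.ttest_rel(a, b).pvalue), "paired t"
    return float(stats.wilcoxon(a, b).pvalue), "paired wilcoxon"


@dataclass
class InterpretReport:
    """Interpretability statistics comparing the two systems' GPS."""

    gps: pd.DataFrame  # per-subject side-mean GPS for both systems
    group_summary: pd.DataFrame  # group x system mean/SD
    paired_overall: Dict[str, object]
    paired_by_group: pd.DataFrame
    correlation: Dict[str, object]
    group_comparison: pd.DataFrame  # per system: omnibus + pairwise vs AS
    mdc_flags: pd.DataFrame
    outliers: Dict[str, List[str]]


def compare_gps_systems(
    table: CohortTable,
    banks: Dict[str, NormativeBank],
    config: AnalysisConfig,
    session: int = 1,
) -> InterpretReport:
    """Full interpretability comparison between GPS of the two systems.

    Normality is decided by Shapiro-Wilk at ``config.alpha`` unless
    ``config.nonparametric`` forces the nonparametric branch.  Per-group
    paired comparisons are Wilcoxon tests with Bonferroni correction; group
    comparisons use Kruskal-Wallis with pairwise rank tests against the
    asymptomatic group (Bonferroni-adjusted).
    """
    df = gps_table(table, banks, session=session)
    if "gps_opto" not in df or "gps_imu" not in df:
        raise CoverageError("both systems' GPS required for comparison")
    df = df.dropna(subset=["gps_opto", "gps_imu"]).reset_index(drop=True)
    a = df["gps_opto"].to_numpy()
    b = df["gps_imu"].to_numpy()

    parametric = (
        not config.nonparametric
        and _is_normal(a, config.alpha)
        and _is_normal(b, config.alpha)
    )
    if config.nonparametric:
        logger.debug("nonparametric branch forced by configuration")

    # headline paired comparison: pathological groups only (asymptomatic
    # subjects define the normative banks, which couples their scores)
    patho_mask = df["group"] != "AS"
    if patho_mask.sum() >= 2:
        p_overall, test_name = _paired_test(
            a[patho_mask.to_numpy()], b[patho_mask.to_numpy()], parametric
        )
        n_overall = int(patho_mask.sum())
    else:
        p_overall, test_name = _paired_test(a, b, parametric)
        n_overall = int(len(df))
    paired_overall = {"p_value": p_overall, "test": test_name, "n": n_overall}

    if parametric:
        cc, p_cc = stats.pearsonr(a, b)
        corr_method = "pearson"
    else:
        cc, p_cc = stats.spearmanr(a, b)
        corr_method = "spearman"
    correlation = {"cc": float(cc), "p_value": float(p_cc), "method": corr_method}

    groups_present = [g for g in ("AS", "CP", "OMD") if (df["group"] == g).sum() >= 2]
    skipped = sorted(set(df["group"]) - set(groups_present))
    for g in skipped:
        logger.warning("group %s too small: excluded from group tests", g)

    rows = []
    n_tests = max(len(groups_present), 1)
    for g in groups_present:
        sub = df[df["group"] == g]
        p_raw, tname = _paired_test(
            sub["gps_opto"].to_numpy(), sub["gps_imu"].to_numpy(), parametric=False
        )
        rows.append(
            {
                "group": g,
                "n": len(sub),
                "p_raw": p_raw,
                "p_adj": min(p_raw * n_tests, 1.0),
                "test": tname,
            }
        )
    paired_by_group = pd.DataFrame(rows)

    summary_rows = []
    for g in ("AS", "CP", "OMD"):
        sub = df[df["group"] == g]
        if not len(sub):
            continue
        for system in ("opto", "imu"):
            summary_rows.append(
                {
                    "group": g,
                    "system": system.upper(),
                    "n": len(sub),
                    "mean": float(sub[f"gps_{system}"].mean()),
                    "sd": float(sub[f"gps_{system}"].std(ddof=1)) if len(sub) > 1 else np.nan,
                }
            )
    group_summary = pd.DataFrame(summary_rows)

    comp_rows = []
    for system in ("opto", "imu"):
        col = f"gps_{system}"
        samples = [df.loc[df["group"] == g, col].to_numpy() for g in groups_present]
        if len(samples) >= 2:
            p_omni = float(stats.kruskal(*samples).pvalue)
        else:
            p_omni = np.nan
        comp_rows.append(
            {
                "system": system.upper(),
                "comparison": "omnibus",
                "p_value": p_omni,
                "test": "kruskal-wallis",
            }
        )
        patho = [g for g in groups_present if g != "AS"]
        if "AS" in groups_present:
            ref = df.loc[df["group"] == "AS", col].to_numpy()
            for g in patho:
                other = df.loc[df["group"] == g, col].to_numpy()
                p_pair = float(
                    stats.mannwhitneyu(other, ref, alternative="two-sided").pvalue
                )
                comp_rows.append(
                    {
                        "system": system.upper(),
                        "comparison": f"{g} vs AS",
                        "p_value": min(p_pair * max(len(patho), 1), 1.0),
                        "test": "rank-sum (bonferroni)",
                    }
                )
    group_comparison = pd.DataFrame(comp_rows)

    mdc_rows = []
    for g in ("AS", "CP", "OMD"):
        sub = df[df["group"] == g]
        if not len(sub):
            continue
        delta = float((sub["gps_imu"] - sub["gps_opto"]).mean())
        mdc_rows.append(
            {
                "group": g,
                "delta_gps": delta,
                "mdc": config.mdc_for_group(g),
                "exceeds_mdc": mdc_flag(delta, g, config),
            }
        )
    mdc_flags = pd.DataFrame(mdc_rows)

    outliers = {}
    for system in ("opto", "imu"):
        vals = dict(zip(df["subject_id"], df[f"gps_{system}"]))
        outliers[system.upper()] = find_outliers(vals) if len(vals) >= 4 else []

    return InterpretReport(
        gps=df,
        group_summary=group_summary,
        paired_overall=paired_overall,
        paired_by_group=paired_by_group,
        correlation=correlation,
        group_comparison=group_comparison,
        mdc_flags=mdc_flags,
        outliers=outliers,
    )
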