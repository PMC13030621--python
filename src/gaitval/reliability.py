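"""Test-retest reliability: discrete curve parameters and intraclass
correlation from variance components of a linear two-way mixed effects model.

The class component is the session (intra-operator mode: session 1 vs 2,
operator A) or the operator (inter-operator mode: operators A vs B within
session 2).  ICC = var_subject / (var_subject + var_class + var_residual),
i.e. two-way, absolute agreement, single measurement.  Variance components
are estimated by REML (statsmodels MixedLM with crossed subject/condition
components); a balanced-ANOVA method-of-moments estimator is the fallback
when REML does not converge.  Negative estimates are truncated at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from gaitval.datamodel_io import (
    OUTCOMES,
    SYSTEMS,
    AngleCycle,
    CohortTable,
    DesignError,
    ValidationError,
    get_logger,
)

logger = get_logger("gaitval.reliability")

PARAMETERS = ("max", "min", "rom", "mean")

KOO_LI_BANDS: Tuple[Tuple[float, str], ...] = (
    (0.90, "excellent"),
    (0.75, "good"),
    (0.50, "moderate"),
    (0.0, "poor"),
)


@dataclass
class DiscreteParams:
    """Clinically read discrete parameters of one angle curve (degrees)."""

    max: float
    min: float
    rom: float
    mean: float


def discrete_params(cycle: AngleCycle) -> DiscreteParams:
    s = cycle.samples
    return DiscreteParams(
        max=float(s.max()),
        min=float(s.min()),
        rom=float(s.max() - s.min()),
        mean=float(s.mean()),
    )


@dataclass
class ReliabilityResult:
    var_subject: float
    var_class: float
    var_residual: float
    icc: float
    mode: str
    band: str
    method: str  # "reml" or "moments"


def interpret_icc_koo(icc: float) -> str:
    """Reliability band with inclusive lower bounds at .50/.75/.90."""
    if not (0.0 <= icc <= 1.0):
        raise ValidationError(f"ICC {icc} outside [0, 1]")
    for bound, label in KOO_LI_BANDS:
        if icc >= bound:
            return label
    return "poor"


# Conditions defining each reliability mode: (session, operator) pairs.
_MODE_CONDITIONS: Dict[str, List[Tuple[int, str]]] = {
    "intra": [(1, "A"), (2, "A")],
    "inter": [(2, "A"), (2, "B")],
}


def reliability_table(table: CohortTable, mode: str) -> pd.DataFrame:
    """One cycle- and side-averaged value per subject per condition.

    Returns a long DataFrame with columns subject_id, group, outcome,
    parameter, system, condition (0/1) and value.  Subjects missing either
    condition are dropped and logged.
    """
    if mode not in _MODE_CONDITIONS:
        raise ValidationError("mode must be 'intra' or 'inter'")
    conditions = _MODE_CONDITIONS[mode]

    # accumulate per (subject, outcome, parameter, system, condition)
    values: Dict[Tuple, List[float]] = {}
    groups: Dict[str, str] = {}
    for key, cycle in table.iter_all():
        try:
            cond = conditions.index((key.session, key.operator))
        except ValueError:
            continue
        groups[key.subject_id] = key.group
        p = discrete_params(cycle)
        for name in PARAMETERS:
            values.setdefault(
                (key.subject_id, cycle.outcome, name, cycle.system, cond), []
            ).append(getattr(p, name))

    present = {(s, o, n, sys) for (s, o, n, sys, _) in values}
    rows = []
    dropped = set()
    for s, o, n, sysname in present:
        if any((s, o, n, sysname, c) not in values for c in range(len(conditions))):
            dropped.add(s)
            continue
        for c in range(len(conditions)):
            rows.append(
                {
                    "subject_id": s,
                    "group": groups[s],
                    "outcome": o,
                    "parameter": n,
                    "system": sysname,
                    "condition": c,
                    "value": float(np.mean(values[(s, o, n, sysname, c)])),
                }
            )
    for s in sorted(dropped):
        logger.info("subject %s missing a %s-mode condition: excluded", s, mode)
    if not rows:
        raise DesignError(
            f"no subjects with both conditions for mode '{mode}' "
            f"(requires sessions/operators {conditions})"
        )
    df = pd.DataFrame(rows).sort_values(
        ["outcome", "parameter", "system", "subject_id", "condition"]
    )
    return df.reset_index(drop=True)


def _as_matrix(measurements) -> np.ndarray:
    """Coerce a subject x condition table to a 2D float array."""
    if isinstance(measurements, pd.DataFrame):
        if {"subject_id", "condition", "value"}.issubset(measurements.columns):
            wide = measurements.pivot(
                index="subject_id", columns="condition", values="value"
            )
            return wide.to_numpy(dtype=float)
        return measurements.to_numpy(dtype=float)
    return np.asarray(measurements, dtype=float)


def _moments_components(y: np.ndarray) -> Tuple[float, float, float]:
    """Balanced two-way ANOVA variance components (truncated at zero)."""
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((y - grand) ** 2)
    sse = max(sst - ssr - ssc, 0.0)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    var_e = mse
    var_s = max((msr - mse) / k, 0.0)
    var_c = max((msc - mse) / n, 0.0)
    return var_s, var_c, var_e


def _reml_components(y: np.ndarray) -> Tuple[float, float, float]:
    """Exact REML variance components for a balanced two-way layout.

    For a balanced crossed design with one observation per cell the REML
    likelihood factors over the three independent sums of squares (rows,
    columns, residual), so REML reduces to maximizing over the expected
    mean squares ``lam_s = k*var_s + var_e``, ``lam_c = n*var_c + var_e``,
    ``lam_e = var_e`` subject to ``lam_s, lam_c >= lam_e``.  In the interior
    this equals the ANOVA estimator; at the boundary the relevant sums of
    squares are pooled.  (Cross-checked against statsmodels MixedLM in the
    test suite.)
    """
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ssr = k * float(np.sum((row_means - grand) ** 2))
    ssc = n * float(np.sum((col_means - grand) ** 2))
    sst = float(np.sum((y - grand) ** 2))
    sse = max(sst - ssr - ssc, 0.0)
    df_r, df_c, df_e = n - 1, k - 1, (n - 1) * (k - 1)

    tiny = 1e-12

    def loglik(lam_s: float, lam_c: float, lam_e: float) -> float:
        ll = 0.0
        for ss, df_, lam in ((ssr, df_r, lam_s), (ssc, df_c, lam_c), (sse, df_e, lam_e)):
            lam = max(lam, tiny)
            ll -= 0.5 * (df_ * np.log(lam) + ss / lam)
        return ll

    candidates = []
    # interior: each lambda at its own mean square
    lam_e = sse / df_e
    lam_s, lam_c = ssr / df_r, ssc / df_c
    if lam_s >= lam_e and lam_c >= lam_e:
        candidates.append((lam_s, lam_c, lam_e))
    # row variance on boundary: pool rows with residual
    pooled_se = (ssr + sse) / (df_r + df_e)
    if ssc / df_c >= pooled_se:
        candidates.append((pooled_se, ssc / df_c, pooled_se))
    # column variance on boundary: pool columns with residual
    pooled_ce = (ssc + sse) / (df_c + df_e)
    if ssr / df_r >= pooled_ce:
        candidates.append((ssr / df_r, pooled_ce, pooled_ce))
    # both on boundary
    pooled_all = sst / (df_r + df_c + df_e)
    candidates.append((pooled_all, pooled_all, pooled_all))

    lam_s, lam_c, lam_e = max(candidates, key=lambda c: loglik(*c))
    return (
        max((lam_s - lam_e) / k, 0.0),
        max((lam_c - lam_e) / n, 0.0),
        max(lam_e, 0.0),
    )


def _reml_components_mixedlm(y: np.ndarray) -> Tuple[float, float, float]:
    """REML via statsmodels MixedLM with crossed components (slow; used as
    an independent cross-check of the closed form)."""
    from statsmodels.regression.mixed_linear_model import MixedLM

    n, k = y.shape
    df = pd.DataFrame(
        {
            "value": y.ravel(),
            "subject": np.repeat(np.arange(n), k).astype(str),
            "condition": np.tile(np.arange(k), n).astype(str),
        }
    )
    df["one"] = 1
    model = MixedLM.from_formula(
        "value ~ 1",
        groups="one",
        vc_formula={"subject": "0 + C(subject)", "condition": "0 + C(condition)"},
        re_formula="0",
        data=df,
    )
    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # gradient optimizers can stall near the boundary; keep the
        # converged fit with the best restricted likelihood
        for opt in ("nm", "powell", "bfgs"):
            fit = model.fit(reml=True, method=opt, maxiter=2000)
            if fit.converged and (result is None or fit.llf > result.llf):
                result = fit
    if result is None:
        raise RuntimeError("REML did not converge")
    comp = dict(zip(model.exog_vc.names, result.vcomp))
    return (
        max(float(comp["subject"]), 0.0),
        max(float(comp["condition"]), 0.0),
        max(float(result.scale), 0.0),
    )


def fit_icc(measurements, mode: str = "intra") -> ReliabilityResult:
    """ICC from variance components of a subject x condition table.

    REML first; method-of-moments (balanced ANOVA) on non-convergence.
    """
    y = _as_matrix(measurements)
    if y.ndim != 2 or y.shape[1] < 2:
        raise DesignError("need a 2D subject x condition table with >= 2 conditions")
    if y.shape[0] < 5:
        raise DesignError("need at least 5 subjects for ICC estimation")
    if np.isnan(y).any():
        raise ValidationError("measurement table contains missing values")

    method = "reml"
    try:
        var_s, var_c, var_e = _reml_components(y)
    except Exception as exc:  # non-convergence or singular fit
        logger.info("REML failed (%s): falling back to method of moments", exc)
        var_s, var_c, var_e = _moments_components(y)
        method = "moments"

    denom = var_s + var_c + var_e
    icc = float(var_s / denom) if denom > 0 else 0.0
    icc = min(max(icc, 0.0), 1.0)
    return ReliabilityResult(
        var_subject=var_s,
        var_class=var_c,
        var_residual=var_e,
        icc=icc,
        mode=mode,
        band=interpret_icc_koo(icc),
        method=method,
    )


def fit_icc_moments(measurements, mode: str = "intra") -> ReliabilityResult:
    """Method-of-moments ICC (balanced ANOVA components), no REML."""
    y = _as_matrix(measurements)
    if y.ndim != 2 or y.shape[1] < 2:
        raise DesignError("need a 2D subject x condition table with >= 2 conditions")
    var_s, var_c, var_e = _moments_components(y)
    denom = var_s + var_c + var_e
    icc = float(var_s / denom) if denom > 0 else 0.0
    icc = min(max(icc, 0.0), 1.0)
    return ReliabilityResult(
        var_subject=var_s,
        var_class=var_c,
        var_residual=var_e,
        icc=icc,
        mode=mode,
        band=interpret_icc_koo(icc),
        method="moments",
    )


def compute_reliability(
    table: CohortTable,
    mode: str,
    use_reml: bool = True,
) -> pd.DataFrame:
    """ICC per (outcome, parameter, system) for one reliability mode."""
    long = reliability_table(table, mode)
    rows = []
    for (outcome, parameter, system), sub in long.groupby(
        ["outcome", "parameter", "system"]
    ):
        wide = sub.pivot(index="subject_id", columns="condition", values="value")
        try:
            res = fit_icc(wide, mode) if use_reml else fit_icc_moments(wide, mode)
        except DesignError as exc:
            logger.warning(
                "skipping %s/%s/%s: %s", outcome, parameter, system, exc
            )
            continue
        rows.append(
            {
                "outcome": outcome,
                "parameter": parameter,
                "system": system,
                "mode": mode,
                "n_subjects": wide.shape[0],
                "var_subject": res.var_subject,
                "var_class": res.var_class,
                "var_residual": res.var_residual,
                "icc": res.icc,
                "band": res.band,
                "method": res.method,
            }
        )
    return pd.DataFrame(rows)
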