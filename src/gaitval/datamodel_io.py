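"""Core domain types, long-format cycles CSV I/O, JSON configuration.

An :class:`AngleCycle` is one time-normalized joint-angle curve: 101 samples
(0–100% of the gait cycle, inclusive) in degrees, for one kinematic outcome,
one side, one cycle and one measurement system.  A :class:`CohortTable`
collects cycles keyed by subject/session/operator, and is the unit of exchange
between the simulation, signal-preparation and analysis stages.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

N_SAMPLES = 101  # 0..100% inclusive, integral percent indices

#: The 11 kinematic outcomes analysed throughout.
OUTCOMES: Tuple[str, ...] = (
    "pelvis_tilt",
    "pelvis_obliquity",
    "pelvis_rotation",
    "hip_flexion",
    "hip_abduction",
    "hip_rotation",
    "knee_flexion",
    "knee_abduction",
    "knee_rotation",
    "ankle_flexion",
    "foot_progression",
)

#: The 9 outcomes entering the Gait Profile Score (pelvis and hip in all
#: three planes, knee and ankle sagittal only, foot progression).
GPS_OUTCOMES: Tuple[str, ...] = tuple(
    o for o in OUTCOMES if o not in ("knee_abduction", "knee_rotation")
)

#: Anatomical plane of each outcome (used for report layout only).
PLANES: Dict[str, str] = {
    "pelvis_tilt": "sagittal",
    "pelvis_obliquity": "frontal",
    "pelvis_rotation": "transverse",
    "hip_flexion": "sagittal",
    "hip_abduction": "frontal",
    "hip_rotation": "transverse",
    "knee_flexion": "sagittal",
    "knee_abduction": "frontal",
    "knee_rotation": "transverse",
    "ankle_flexion": "sagittal",
    "foot_progression": "transverse",
}

GROUPS = ("AS", "CP", "OMD")
AGE_GROUPS = ("child", "teen", "adult")
SYSTEMS = ("OPTO", "IMU")
SIDES = ("left", "right")

SAMPLE_COLUMNS = [f"s{i:03d}" for i in range(N_SAMPLES)]
KEY_COLUMNS = [
    "subject_id",
    "group",
    "age_group",
    "session",
    "operator",
    "system",
    "side",
    "cycle_index",
    "outcome",
]


class GaitvalError(Exception):
    """Base class for all package errors."""


class FormatError(GaitvalError):
    """File does not match the expected schema."""


class ParseError(GaitvalError):
    """A value in an input file could not be parsed."""


class IntegrityError(GaitvalError):
    """Duplicate or inconsistent keys in a table."""


class PairingError(GaitvalError):
    """Curves that should be compared do not match."""


class CoverageError(GaitvalError):
    """Required outcomes/conditions are missing."""


class DesignError(GaitvalError):
    """The measurement design does not support the requested analysis."""


class ValidationError(GaitvalError):
    """A domain invariant was violated."""


def get_logger(name: str = "gaitval") -> logging.Logger:
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


@contextmanager
def stage_timer(stage: str, logger: Optional[logging.Logger] = None):
    """Log wall-clock duration of a pipeline stage to stderr."""
    log = logger or get_logger()
    t0 = time.perf_counter()
    log.info("stage %s: start", stage)
    try:
        yield
    finally:
        log.info("stage %s: done in %.3f s", stage, time.perf_counter() - t0)


@dataclass
class AngleCycle:
    """One time-normalized joint-angle curve (101 samples, degrees)."""

    outcome: str
    side: str
    cycle_index: int
    system: str
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValidationError(f"unknown outcome {self.outcome!r}")
        if self.side not in SIDES:
            raise ValidationError(f"side must be left|right, got {self.side!r}")
        if self.system not in SYSTEMS:
            raise ValidationError(f"system must be OPTO|IMU, got {self.system!r}")
        if self.cycle_index < 0:
            raise ValidationError("cycle_index must be >= 0")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.shape != (N_SAMPLES,):
            raise ValidationError(
                f"cycle must have exactly {N_SAMPLES} samples, "
                f"got shape {self.samples.shape}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("cycle samples must all be finite")

    def key(self) -> Tuple[str, str, int, str]:
        return (self.system, self.side, self.cycle_index, self.outcome)


@dataclass(frozen=True)
class SubjectKey:
    """Identifies one subject under one measurement condition."""

    subject_id: str
    group: str
    age_group: str
    session: int
    operator: str

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.age_group not in AGE_GROUPS:
            raise ValidationError(
                f"age_group must be one of {AGE_GROUPS}, got {self.age_group!r}"
            )
        if self.session not in (1, 2):
            raise ValidationError("session must be 1 or 2")
        if self.operator not in ("A", "B"):
            raise ValidationError("operator must be A or B")
        # protocol: session 1 is always led by operator A
        if self.session == 1 and self.operator != "A":
            raise ValidationError("session 1 implies operator A")


class CohortTable:
    """Collection of AngleCycles keyed by subject condition.

    Every (subject condition, system, side, cycle_index, outcome) key is
    unique; :meth:`add` enforces this.
    """

    def __init__(self) -> None:
        self._records: Dict[SubjectKey, Dict[Tuple[str, str, int, str], AngleCycle]] = {}

    @property
    def records(self) -> Dict[SubjectKey, List[AngleCycle]]:
        return {k: list(v.values()) for k, v in self._records.items()}

    def add(self, key: SubjectKey, cycle: AngleCycle) -> None:
        bucket = self._records.setdefault(key, {})
        ck = cycle.key()
        if ck in bucket:
            raise IntegrityError(f"duplicate cycle key {key} / {ck}")
        bucket[ck] = cycle

    def subject_keys(self) -> List[SubjectKey]:
        return list(self._records.keys())

    def cycles(self, key: SubjectKey) -> List[AngleCycle]:
        return list(self._records.get(key, {}).values())

    def get(
        self, key: SubjectKey, system: str, side: str, cycle_index: int, outcome: str
    ) -> Optional[AngleCycle]:
        return self._records.get(key, {}).get((system, side, cycle_index, outcome))

    def iter_all(self) -> Iterator[Tuple[SubjectKey, AngleCycle]]:
        for key, bucket in self._records.items():
            for cycle in bucket.values():
                yield key, cycle

    def __len__(self) -> int:
        return sum(len(b) for b in self._records.values())

    def subjects(self) -> List[str]:
        return sorted({k.subject_id for k in self._records})

    def filter(
        self,
        group: Optional[str] = None,
        session: Optional[int] = None,
        operator: Optional[str] = None,
    ) -> "CohortTable":
        out = CohortTable()
        for key, bucket in self._records.items():
            if group is not None and key.group != group:
                continue
            if session is not None and key.session != session:
                continue
            if operator is not None and key.operator != operator:
                continue
            for cycle in bucket.values():
                out.add(key, cycle)
        return out

    def iter_pairs(self) -> Iterator[Tuple[SubjectKey, AngleCycle, AngleCycle]]:
        """Yield matched (OPTO, IMU) cycle pairs with identical keys."""
        for key, bucket in self._records.items():
            for ck, cyc in bucket.items():
                if ck[0] != "OPTO":
                    continue
                partner = bucket.get(("IMU",) + ck[1:])
                if partner is not None:
                    yield key, cyc, partner

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortTable):
            return NotImplemented
        if set(self._records) != set(other._records):
            return False
        for key, bucket in self._records.items():
            ob = other._records[key]
            if set(bucket) != set(ob):
                return False
            for ck, cyc in bucket.items():
                if not np.array_equal(cyc.samples, ob[ck].samples):
                    return False
        return True


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _table_to_frame(table: CohortTable) -> pd.DataFrame:
    rows = []
    for key, cycle in table.iter_all():
        row = {
            "subject_id": key.subject_id,
            "group": key.group,
            "age_group": key.age_group,
            "session": key.session,
            "operator": key.operator,
            "system": cycle.system,
            "side": cycle.side,
            "cycle_index": cycle.cycle_index,
            "outcome": cycle.outcome,
        }
        row.update(zip(SAMPLE_COLUMNS, cycle.samples))
        rows.append(row)
    df = pd.DataFrame(rows, columns=KEY_COLUMNS + SAMPLE_COLUMNS)
    if len(df):
        df = df.sort_values(KEY_COLUMNS, kind="mergesort").reset_index(drop=True)
    return df


def write_cycles_csv(table: CohortTable, path) -> Path:
    """Write a CohortTable as long-format CSV with deterministic row order."""
    path = Path(path)
    df = _table_to_frame(table)
    try:
        df.to_csv(path, index=False)
    except OSError as exc:
        raise GaitvalError(f"cannot write {path}: {exc}") from exc
    return path


def read_cycles_csv(path) -> CohortTable:
    """Read a long-format cycles CSV into a CohortTable."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    except OSError as exc:
        raise GaitvalError(f"cannot read {path}: {exc}") from exc
    missing = [c for c in KEY_COLUMNS + SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing column(s): {', '.join(missing)}")
    extra = [
        c
        for c in df.columns
        if c not in KEY_COLUMNS and c.startswith("s") and c not in SAMPLE_COLUMNS
    ]
    if extra:
        raise FormatError(f"unexpected sample column(s): {', '.join(extra)}")
    table = CohortTable()
    sample_block = df[SAMPLE_COLUMNS]
    numeric = sample_block.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & sample_block.notna()
    if bad.to_numpy().any():
        row = int(np.argwhere(bad.to_numpy().any(axis=1))[0][0])
        raise ParseError(f"non-numeric sample value in data row {row}")
    if numeric.isna().to_numpy().any():
        row = int(np.argwhere(numeric.isna().to_numpy().any(axis=1))[0][0])
        raise ParseError(f"missing sample value in data row {row}")
    values = numeric.to_numpy(dtype=float)
    for i, rec in enumerate(df[KEY_COLUMNS].to_dict("records")):
        try:
            key = SubjectKey(
                subject_id=str(rec["subject_id"]),
                group=str(rec["group"]),
                age_group=str(rec["age_group"]),
                session=int(rec["session"]),
                operator=str(rec["operator"]),
            )
            cycle = AngleCycle(
                outcome=str(rec["outcome"]),
                side=str(rec["side"]),
                cycle_index=int(rec["cycle_index"]),
                system=str(rec["system"]),
                samples=values[i],
            )
        except (ValueError, ValidationError) as exc:
            raise ParseError(f"invalid record in data row {i}: {exc}") from exc
        table.add(key, cycle)
    return table


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

class AnalysisConfig(BaseModel):
    """Analysis thresholds and options with study defaults."""

    mdc_patho: float = Field(default=1.7, gt=0.0)
    mdc_as: float = Field(default=0.7, gt=0.0)
    clinical_threshold: float = Field(default=5.0, gt=0.0)
    gps_outcomes: List[str] = Field(default_factory=lambda: list(GPS_OUTCOMES))
    alpha: float = Field(default=0.05, gt=0.0, lt=1.0)
    seed: int = 0
    nonparametric: bool = False

    @field_validator("gps_outcomes")
    @classmethod
    def _check_gps_outcomes(cls, v: List[str]) -> List[str]:
        unknown = [o for o in v if o not in OUTCOMES]
        if unknown:
            raise ValueError(f"unknown outcome id(s): {unknown}")
        if set(v) != set(GPS_OUTCOMES):
            raise ValueError(
                "gps_outcomes must be exactly the 9 profile-score outcomes"
            )
        return v

    def mdc_for_group(self, group: str) -> float:
        return self.mdc_as if group == "AS" else self.mdc_patho


def load_config(path) -> AnalysisConfig:
    """Load an AnalysisConfig from a JSON file, applying defaults."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        data = json.load(fh)
    if not isinstance(data, dict):
        raise FormatError("config must be a JSON object")
    return AnalysisConfig(**data)
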