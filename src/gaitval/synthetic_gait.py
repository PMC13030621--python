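"""Seeded synthetic gait data: paired two-system cycle cohorts with a
controlled error structure, raw walking trials with known ground-truth events,
and synchronization ("wand drop") trials.

All generators draw from a single ``numpy.random.default_rng(seed)`` stream
per call, so identical seeds and parameters give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from gaitval.datamodel_io import (
    GPS_OUTCOMES,
    N_SAMPLES,
    OUTCOMES,
    PLANES,
    AngleCycle,
    CohortTable,
    SubjectKey,
    ValidationError,
)

_PHASE = np.arange(N_SAMPLES) / 100.0  # 0..1 inclusive

MARKER_RATE = 100.0  # Hz, camera system
IMU_RATE = 256.0  # Hz, inertial system
GRAVITY = 9.80665  # m/s^2
ACCEL_RANGE_G = 16.0
GYRO_RANGE_DPS = 2000.0


def _harmonic(mean: float, terms: List[Tuple[int, float, float]]) -> np.ndarray:
    """Sum of cosine harmonics: exactly periodic on the 0..100% grid."""
    curve = np.full(N_SAMPLES, mean, dtype=float)
    for k, amp, phase in terms:
        curve += amp * np.cos(2.0 * np.pi * (k * _PHASE - phase))
    return curve


# Base waveform shapes per outcome: (mean, [(harmonic, amplitude, phase)]).
# Amplitudes chosen so nominal ROMs sit in physiological ranges (knee
# flexion 50-70 deg; pelvis curves low amplitude).
_TEMPLATE_SPEC: Dict[str, Tuple[float, List[Tuple[int, float, float]]]] = {
    "pelvis_tilt": (10.0, [(2, 1.5, 0.05), (1, 0.5, 0.3)]),
    "pelvis_obliquity": (0.0, [(1, 3.0, 0.12), (2, 1.0, 0.4)]),
    "pelvis_rotation": (0.0, [(1, 5.0, 0.0), (2, 0.8, 0.2)]),
    "hip_flexion": (12.0, [(1, 20.0, 0.92), (2, 3.0, 0.25)]),
    "hip_abduction": (-1.0, [(1, 4.5, 0.55), (2, 1.5, 0.1)]),
    "hip_rotation": (4.0, [(1, 5.0, 0.35), (2, 1.2, 0.6)]),
    "knee_flexion": (27.0, [(1, 24.0, 0.72), (2, 8.0, 0.30)]),
    "knee_abduction": (2.0, [(1, 3.0, 0.5), (2, 1.0, 0.15)]),
    "knee_rotation": (5.0, [(1, 5.0, 0.45), (2, 1.5, 0.7)]),
    "ankle_flexion": (2.0, [(1, 8.0, 0.48), (2, 6.0, 0.85)]),
    "foot_progression": (-8.0, [(1, 4.0, 0.25), (2, 1.2, 0.55)]),
}


@dataclass
class TemplateBank:
    """Per-outcome mean waveform (101 samples, degrees) and nominal ROM."""

    templates: Dict[str, np.ndarray]

    def rom(self, outcome: str) -> float:
        t = self.templates[outcome]
        return float(t.max() - t.min())


def make_template_bank(seed: int = 0) -> TemplateBank:
    """Deterministic gait-like waveform templates with small seeded variation.

    The seeded jitter is built from integer harmonics only, so periodicity
    (sample 0 == sample 100) is preserved exactly.
    """
    rng = np.random.default_rng(seed)
    templates: Dict[str, np.ndarray] = {}
    for outcome in OUTCOMES:
        mean, terms = _TEMPLATE_SPEC[outcome]
        curve = _harmonic(mean, terms)
        for k in (1, 2, 3):
            amp = rng.uniform(0.0, 0.25)
            phase = rng.uniform(0.0, 1.0)
            curve += amp * np.cos(2.0 * np.pi * (k * _PHASE - phase))
        templates[outcome] = curve
    return TemplateBank(templates=templates)


@dataclass
class ErrorModel:
    """Between-system error: constant per-outcome offset plus waveform noise.

    The dominant error mode is a constant offset per (subject, outcome),
    with per-cycle jitter; waveform noise is white; an optional smooth
    per-plane component degrades correlation without adding offset.
    """

    offset_mean: Dict[str, float] = field(default_factory=dict)
    offset_subject_sd: float = 1.0
    offset_cycle_sd: float = 0.3
    noise_sd: float = 1.0
    corr_degradation: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.offset_subject_sd < 0 or self.offset_cycle_sd < 0 or self.noise_sd < 0:
            raise ValidationError("error-model SDs must be >= 0")
        if any(v < 0 for v in self.corr_degradation.values()):
            raise ValidationError("correlation-degradation amplitudes must be >= 0")

    @classmethod
    def default(cls) -> "ErrorModel":
        offsets = {o: 2.0 for o in OUTCOMES}
        offsets["pelvis_tilt"] = 15.0  # dominant constant offset
        return cls(
            offset_mean=offsets,
            offset_subject_sd=1.0,
            offset_cycle_sd=0.3,
            noise_sd=1.0,
            corr_degradation={"sagittal": 0.0, "frontal": 0.5, "transverse": 1.0},
        )

    @classmethod
    def null(cls) -> "ErrorModel":
        return cls(
            offset_mean={o: 0.0 for o in OUTCOMES},
            offset_subject_sd=0.0,
            offset_cycle_sd=0.0,
            noise_sd=0.0,
        )

    def offset_for(self, outcome: str) -> float:
        return float(self.offset_mean.get(outcome, 0.0))

    def degradation_for(self, outcome: str) -> float:
        return float(self.corr_degradation.get(PLANES[outcome], 0.0))


@dataclass
class VarianceSpec:
    """Variance components (degrees^2) for discrete-parameter generation."""

    var_subject: float = 16.0
    var_session: float = 1.0
    var_operator: float = 1.0
    var_cycle: float = 0.25
    var_residual: float = 0.25

    def __post_init__(self) -> None:
        for name in ("var_subject", "var_session", "var_operator", "var_cycle", "var_residual"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


# Group-level deviation patterns (relative weight per outcome; each vector is
# normalized to unit RMS over the nine profile-score outcomes before scaling
# by subject severity).  CP: crouch-like knee/hip flexion excess with
# equinus-like ankle offset.
_CP_PATTERN: Dict[str, float] = {
    "pelvis_tilt": 0.8,
    "pelvis_obliquity": 0.4,
    "pelvis_rotation": 0.7,
    "hip_flexion": 1.3,
    "hip_abduction": 0.5,
    "hip_rotation": 1.2,
    "knee_flexion": 1.6,
    "knee_abduction": 0.5,
    "knee_rotation": 0.6,
    "ankle_flexion": -1.3,
    "foot_progression": 1.0,
}


def _unit_rms(pattern: Dict[str, float]) -> Dict[str, float]:
    vals = np.array([pattern[o] for o in GPS_OUTCOMES])
    scale = float(np.sqrt(np.mean(vals**2)))
    return {o: v / scale for o, v in pattern.items()}


def _smooth_field(rng: np.random.Generator, sd: float, n_harm: int = 3) -> np.ndarray:
    """Zero-mean smooth periodic waveform with RMS amplitude ~= sd."""
    curve = np.zeros(N_SAMPLES)
    if sd <= 0:
        # keep the stream position independent of sd
        rng.normal(size=2 * n_harm)
        rng.uniform(size=n_harm)
        return curve
    amps = rng.normal(size=n_harm) * sd / np.sqrt(n_harm)
    _ = rng.normal(size=n_harm)  # reserved draws (stream stability)
    phases = rng.uniform(size=n_harm)
    for k in range(1, n_harm + 1):
        curve += amps[k - 1] * np.sqrt(2.0) * np.cos(2 * np.pi * (k * _PHASE - phases[k - 1]))
    return curve


def simulate_cohort(
    n_as: int = 15,
    n_cp: int = 15,
    n_omd: int = 25,
    cycles_per_subject: int = 3,
    error: Optional[ErrorModel] = None,
    variance: Optional[VarianceSpec] = None,
    seed: int = 0,
    design: str = "full",
    subject_waveform_sd: float = 2.5,
    side_asymmetry_sd: float = 0.5,
    cp_severity: Tuple[float, float] = (6.4, 1.5),
    omd_severity: Tuple[float, float] = (4.8, 1.5),
) -> CohortTable:
    """Generate a paired two-system cohort table.

    Camera-system (OPTO) curves are template + per-subject individuality +
    group deviation + session/operator/cycle perturbations; inertial (IMU)
    curves are the matched OPTO curve plus a constant offset draw, per-cycle
    offset jitter and waveform noise.

    ``design='full'`` emits conditions (session 1 / operator A,
    session 2 / A, session 2 / B) for every subject; ``design='validity'``
    emits session 1 only.
    """
    if min(n_as, n_cp, n_omd) < 1 or cycles_per_subject < 1:
        raise ValidationError("subject and cycle counts must be >= 1")
    if design not in ("full", "validity"):
        raise ValidationError("design must be 'full' or 'validity'")
    error = error if error is not None else ErrorModel.default()
    variance = variance if variance is not None else VarianceSpec()

    rng = np.random.default_rng(seed)
    bank = make_template_bank(seed)
    cp_pattern = _unit_rms(_CP_PATTERN)

    conditions = [(1, "A")] if design == "validity" else [(1, "A"), (2, "A"), (2, "B")]
    age_cycle = ("child", "teen", "adult")

    table = CohortTable()
    groups = [("AS", n_as), ("CP", n_cp), ("OMD", n_omd)]
    sd = {
        "subject": np.sqrt(variance.var_subject),
        "session": np.sqrt(variance.var_session),
        "operator": np.sqrt(variance.var_operator),
        "cycle": np.sqrt(variance.var_cycle),
        "residual": np.sqrt(variance.var_residual),
    }

    idx = 0
    for group, n_sub in groups:
        for j in range(n_sub):
            subject_id = f"{group}{j + 1:03d}"
            age_group = age_cycle[idx % 3]
            idx += 1

            # group deviation field, scaled by per-subject severity
            if group == "CP":
                severity = max(0.0, rng.normal(*cp_severity))
                pattern = dict(cp_pattern)
            elif group == "OMD":
                severity = max(0.0, rng.normal(*omd_severity))
                raw = {o: rng.normal() for o in OUTCOMES}
                pattern = _unit_rms(raw)
            else:
                severity = 0.0
                pattern = {o: 0.0 for o in OUTCOMES}

            per_outcome: Dict[str, Dict[str, np.ndarray]] = {}
            for outcome in OUTCOMES:
                subj_offset = rng.normal(0.0, sd["subject"])
                subj_wave = _smooth_field(rng, subject_waveform_sd)
                # deviation: mostly constant with a smooth waveform part
                dev_shape = 0.85 + _smooth_field(rng, 0.5)
                deviation = severity * pattern[outcome] * dev_shape
                sess_off = {s: rng.normal(0.0, sd["session"]) for s in (1, 2)}
                op_off = {op: rng.normal(0.0, sd["operator"]) for op in ("A", "B")}
                side_off = {s: rng.normal(0.0, side_asymmetry_sd) for s in ("left", "right")}
                imu_offset = rng.normal(error.offset_for(outcome), error.offset_subject_sd)
                per_outcome[outcome] = {
                    "base": bank.templates[outcome] + subj_offset + subj_wave + deviation,
                    "sess": sess_off,
                    "op": op_off,
                    "side": side_off,
                    "imu_offset": imu_offset,
                }

            for session, operator in conditions:
                key = SubjectKey(
                    subject_id=subject_id,
                    group=group,
                    age_group=age_group,
                    session=session,
                    operator=operator,
                )
                for side in ("left", "right"):
                    for c in range(cycles_per_subject):
                        cyc_off = {o: rng.normal(0.0, sd["cycle"]) for o in OUTCOMES}
                        for outcome in OUTCOMES:
                            info = per_outcome[outcome]
                            opto = (
                                info["base"]
                                + info["sess"][session]
                                + info["op"][operator]
                                + info["side"][side]
                                + cyc_off[outcome]
                                + rng.normal(0.0, sd["residual"], N_SAMPLES)
                            )
                            imu = (
                                opto
                                + info["imu_offset"]
                                + rng.normal(0.0, error.offset_cycle_sd)
                                + rng.normal(0.0, error.noise_sd, N_SAMPLES)
                                + _smooth_field(rng, error.degradation_for(outcome))
                            )
                            table.add(
                                key,
                                AngleCycle(outcome, side, c, "OPTO", opto),
                            )
                            table.add(
                                key,
                                AngleCycle(outcome, side, c, "IMU", imu),
                            )
    return table


# ---------------------------------------------------------------------------
# Raw walking trials
# ---------------------------------------------------------------------------

@dataclass
class SyntheticWalk:
    """A straight-line walking pass with ground-truth events.

    Marker trajectories are (n, 3) positions in meters at 100 Hz on the
    camera clock; inertial streams are at 256 Hz on the IMU clock, which is
    shifted by ``clock_offset`` relative to the camera clock.
    """

    marker_time: np.ndarray
    markers: Dict[str, np.ndarray]  # sacrum, {left,right}_{heel,toe}
    imu_time: np.ndarray
    gyro_sagittal: Dict[str, np.ndarray]  # per side, deg/s
    accel: Dict[str, np.ndarray]  # per side, (n, 3) in g
    events: Dict[str, Dict[str, np.ndarray]]  # marker-clock ground truth
    clock_offset: float
    marker_rate: float = MARKER_RATE
    imu_rate: float = IMU_RATE

    def imu_events(self) -> Dict[str, Dict[str, np.ndarray]]:
        """Ground-truth events expressed on the IMU clock."""
        return {
            side: {kind: times + self.clock_offset for kind, times in ev.items()}
            for side, ev in self.events.items()
        }


def _gauss_bumps(t: np.ndarray, centers: np.ndarray, amp: float, width: float) -> np.ndarray:
    out = np.zeros_like(t)
    for c in centers:
        out += amp * np.exp(-0.5 * ((t - c) / width) ** 2)
    return out


def simulate_walk(
    n_strides: int = 10,
    cadence: float = 50.0,
    clock_offset: float = 0.0,
    seed: int = 0,
    stride_length: float = 1.2,
    marker_noise_sd: float = 0.0005,  # sub-millimeter, typical of camera systems
    gyro_noise_sd: float = 5.0,
) -> SyntheticWalk:
    """Simulate one straight walking pass with known events.

    ``cadence`` is in strides/min (per side).  Heel/toe trajectories are
    sinusoids superposed on the sacrum progression so that maxima of
    (heel - sacrum) coincide with foot strikes and minima of (toe - sacrum)
    with foot offs.  The sagittal foot gyro has one dominant positive
    mid-swing peak per stride with negative minima at foot off and strike.
    """
    if n_strides < 2:
        raise ValidationError("n_strides must be >= 2")
    if cadence <= 0:
        raise ValidationError("cadence must be > 0")
    rng = np.random.default_rng(seed)

    period = 60.0 / cadence
    lead_in = period  # events kept away from stream edges
    duration = lead_in + n_strides * period + lead_in
    speed = stride_length / period

    marker_time = np.arange(0.0, duration, 1.0 / MARKER_RATE)
    imu_time_true = np.arange(0.0, duration, 1.0 / IMU_RATE)

    sacrum_x = speed * marker_time
    sacrum = np.column_stack(
        [sacrum_x, 0.02 * np.sin(2 * np.pi * marker_time / period), np.full_like(marker_time, 1.0)]
    )

    events: Dict[str, Dict[str, np.ndarray]] = {}
    markers: Dict[str, np.ndarray] = {"sacrum": sacrum}
    gyro: Dict[str, np.ndarray] = {}
    accel: Dict[str, np.ndarray] = {}

    for side, phase_shift in (("left", 0.5), ("right", 0.0)):
        first_strike = lead_in + phase_shift * period
        strikes = first_strike + period * np.arange(n_strides)
        offs = strikes - 0.4 * period  # foot off precedes the next strike by 40%
        offs = offs[offs > 0.1]
        mids = strikes - 0.2 * period

        # taper the foot oscillation outside the stride window so detected
        # and ground-truth event counts agree
        t_lo = offs[0] - 0.05 * period if offs.size else strikes[0] - 0.05 * period
        t_hi = strikes[-1] + 0.05 * period
        ramp = 0.4 * period
        env = np.clip(
            np.minimum((marker_time - (t_lo - ramp)) / ramp, ((t_hi + ramp) - marker_time) / ramp),
            0.0,
            1.0,
        )
        env = 0.5 - 0.5 * np.cos(np.pi * env)  # smooth cosine ramps

        heel_rel = env * 0.35 * np.cos(2 * np.pi * (marker_time - first_strike) / period)
        toe_rel = 0.30 - env * 0.30 * np.cos(2 * np.pi * (marker_time - (first_strike - 0.4 * period)) / period)
        heel = sacrum.copy()
        heel[:, 0] += heel_rel + rng.normal(0.0, marker_noise_sd, marker_time.size)
        heel[:, 2] = 0.05 + 0.04 * np.clip(np.sin(2 * np.pi * (marker_time - first_strike) / period), 0, None)
        toe = sacrum.copy()
        toe[:, 0] += toe_rel + rng.normal(0.0, marker_noise_sd, marker_time.size)
        toe[:, 2] = 0.02
        markers[f"{side}_heel"] = heel
        markers[f"{side}_toe"] = toe

        w = _gauss_bumps(imu_time_true, mids, 350.0, 0.05 * period)
        w -= _gauss_bumps(imu_time_true, strikes, 150.0, 0.03 * period)
        w -= _gauss_bumps(imu_time_true, offs, 120.0, 0.03 * period)
        w += rng.normal(0.0, gyro_noise_sd, imu_time_true.size)
        np.clip(w, -GYRO_RANGE_DPS, GYRO_RANGE_DPS, out=w)
        gyro[side] = w
        acc = np.column_stack(
            [
                rng.normal(0.0, 0.02, imu_time_true.size),
                rng.normal(0.0, 0.02, imu_time_true.size),
                1.0 + rng.normal(0.0, 0.02, imu_time_true.size),
            ]
        )
        accel[side] = acc

        events[side] = {"strikes": strikes, "offs": offs}

    return SyntheticWalk(
        marker_time=marker_time,
        markers=markers,
        imu_time=imu_time_true + clock_offset,
        gyro_sagittal=gyro,
        accel=accel,
        events=events,
        clock_offset=clock_offset,
    )


# ---------------------------------------------------------------------------
# Synchronization trials
# ---------------------------------------------------------------------------

@dataclass
class SyncTrial:
    """Wand-drop trial: accel stream with an impact peak and the marker's
    vertical trajectory contacting the floor at the same true instant."""

    imu_time: np.ndarray
    accel: np.ndarray  # (n, 3) in g
    marker_time: np.ndarray
    marker_z: np.ndarray  # meters
    true_impact_time: float


def simulate_sync_trial(
    impact_time: float,
    seed: int = 0,
    duration: Optional[float] = None,
    accel_noise_sd: float = 0.02,
    marker_noise_sd: float = 0.0005,
    impact_amplitude_g: float = 9.0,
    drop_height: float = 0.8,
) -> SyncTrial:
    """Simulate a wand-drop synchronization trial.

    The impact produces a sharp acceleration peak at ``impact_time`` on top
    of gravity-plus-noise; the marker's vertical coordinate free-falls from
    ``drop_height`` and stays on the floor after contact.
    """
    if duration is None:
        duration = impact_time + 2.0
    if not (0.0 < impact_time < duration):
        raise ValidationError("impact_time must lie within the trial duration")
    rng = np.random.default_rng(seed)

    imu_time = np.arange(0.0, duration, 1.0 / IMU_RATE)
    accel = np.column_stack(
        [
            rng.normal(0.0, accel_noise_sd, imu_time.size),
            rng.normal(0.0, accel_noise_sd, imu_time.size),
            1.0 + rng.normal(0.0, accel_noise_sd, imu_time.size),
        ]
    )
    accel[:, 2] += impact_amplitude_g * np.exp(
        -0.5 * ((imu_time - impact_time) / 0.005) ** 2
    )
    np.clip(accel, -ACCEL_RANGE_G, ACCEL_RANGE_G, out=accel)

    marker_time = np.arange(0.0, duration, 1.0 / MARKER_RATE)
    fall_time = np.sqrt(2.0 * drop_height / GRAVITY)
    release = impact_time - fall_time
    z = np.full(marker_time.size, drop_height)
    falling = (marker_time >= release) & (marker_time < impact_time)
    z[falling] = drop_height - 0.5 * GRAVITY * (marker_time[falling] - release) ** 2
    z[marker_time >= impact_time] = 0.0
    z += rng.normal(0.0, marker_noise_sd, marker_time.size)

    return SyncTrial(
        imu_time=imu_time,
        accel=accel,
        marker_time=marker_time,
        marker_z=z,
        true_impact_time=impact_time,
    )
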