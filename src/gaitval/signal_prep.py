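"""Signal preparation: inter-system synchronization from wand-drop trials,
gait event detection from marker trajectories (coordinate-based) and from raw
foot angular velocity, and segmentation of angle streams into 101-point
time-normalized cycles.

Filtering defaults: zero-phase 2nd-order Butterworth, 10 Hz for marker
trajectories and 17 Hz for gyro streams (standard gait bandwidths).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from gaitval.datamodel_io import (
    N_SAMPLES,
    AngleCycle,
    GaitvalError,
    PairingError,
    ValidationError,
    get_logger,
)

MARKER_FILTER_HZ = 10.0
GYRO_FILTER_HZ = 17.0

logger = get_logger("gaitval.signal_prep")


class NoImpactError(GaitvalError):
    """No impact found in the acceleration stream."""


class NoDropError(GaitvalError):
    """No drop found in the marker trajectory."""


class NoProgressionError(GaitvalError):
    """Sacrum displacement too small to estimate walking direction."""


class InsufficientStridesError(GaitvalError):
    """Fewer than two mid-swing peaks in the gyro stream."""


class NoCompleteCycleError(GaitvalError):
    """Fewer than two foot strikes: no complete gait cycle."""


@dataclass
class EventSet:
    """Detected gait events per side, in seconds, strictly increasing."""

    strikes: Dict[str, np.ndarray] = field(default_factory=dict)
    offs: Dict[str, np.ndarray] = field(default_factory=dict)
    source: str = "marker"

    def __post_init__(self) -> None:
        for d in (self.strikes, self.offs):
            for side, times in d.items():
                arr = np.asarray(times, dtype=float)
                if np.any(np.diff(arr) <= 0):
                    raise ValidationError(f"{side} event times must be strictly increasing")
                d[side] = arr

    def merge(self, other: "EventSet") -> "EventSet":
        out = EventSet(source=self.source)
        for d_out, d_a, d_b in (
            (out.strikes, self.strikes, other.strikes),
            (out.offs, self.offs, other.offs),
        ):
            for side in set(d_a) | set(d_b):
                parts = [d for d in (d_a.get(side), d_b.get(side)) if d is not None]
                d_out[side] = np.sort(np.concatenate(parts))
        return out

    def shifted(self, dt: float) -> "EventSet":
        return EventSet(
            strikes={s: t + dt for s, t in self.strikes.items()},
            offs={s: t + dt for s, t in self.offs.items()},
            source=self.source,
        )


@dataclass
class SyncResult:
    """Clock alignment: IMU time = marker time + offset + drift * marker time."""

    offset: float
    drift: Optional[float]
    residual: float

    def imu_to_marker(self, t_imu: np.ndarray) -> np.ndarray:
        drift = self.drift or 0.0
        return (np.asarray(t_imu, dtype=float) - self.offset) / (1.0 + drift)


def _lowpass(x: np.ndarray, rate: float, cutoff: float) -> np.ndarray:
    if x.size < 12 or cutoff >= rate / 2:
        return np.asarray(x, dtype=float)
    sos = sps.butter(2, cutoff, btype="low", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, x)


def fill_gaps(values: np.ndarray, rate: float, max_gap: float = 0.2) -> np.ndarray:
    """Linearly interpolate NaN runs up to ``max_gap`` seconds.

    Longer gaps invalidate the trajectory (error), matching the pipeline's
    simple interpolation policy.
    """
    values = np.asarray(values, dtype=float).copy()
    isnan = np.isnan(values)
    if not isnan.any():
        return values
    if isnan.all():
        raise GaitvalError("trajectory contains no valid samples")
    # locate NaN runs
    idx = np.flatnonzero(np.diff(np.concatenate(([0], isnan.view(np.int8), [0]))))
    starts, ends = idx[::2], idx[1::2]
    max_run = int(round(max_gap * rate))
    for s, e in zip(starts, ends):
        if e - s > max_run:
            raise GaitvalError(f"marker gap of {(e - s) / rate:.3f} s exceeds {max_gap} s")
    good = ~isnan
    values[isnan] = np.interp(
        np.flatnonzero(isnan), np.flatnonzero(good), values[good]
    )
    return values


# ---------------------------------------------------------------------------
# Synchronization
# ---------------------------------------------------------------------------

def detect_impact_time(
    accel: np.ndarray,
    rate: float = 256.0,
    threshold_g: float = 4.0,
) -> float:
    """Time of the wand-drop impact peak in an acceleration stream (g).

    The impact is the global maximum of the smoothed deviation of the
    acceleration norm from 1 g; it must exceed ``threshold_g``.
    """
    accel = np.atleast_2d(np.asarray(accel, dtype=float))
    if accel.shape[0] < int(0.5 * rate):
        raise ValidationError("acceleration stream must cover at least 0.5 s")
    mag = np.abs(np.linalg.norm(accel, axis=1) - 1.0)
    # light smoothing only: the impact peak is a few samples wide
    kernel = np.ones(3) / 3.0
    smooth = np.convolve(mag, kernel, mode="same")
    i = int(np.argmax(smooth))
    if smooth[i] < threshold_g:
        raise NoImpactError(
            f"no impact found: peak {smooth[i]:.2f} g below threshold {threshold_g} g"
        )
    return i / rate


def detect_drop_event(marker_z: np.ndarray, rate: float = 100.0) -> float:
    """Time of floor contact in a wand marker's vertical trajectory (m).

    Returns the peak of downward velocity magnitude immediately before the
    height minimum, from forward differences timestamped at interval
    midpoints.
    """
    # no low-pass here: filtering smears the floor-contact corner and
    # biases the velocity peak early; marker noise is sub-millimeter
    z = np.asarray(marker_z, dtype=float)
    if z.size < 3 or (z.max() - z.min()) < 0.05:
        raise NoDropError("no drop found: trajectory flat or too short")
    v = np.diff(z) * rate  # m/s at midpoints
    i_floor = int(np.argmin(z))
    search_end = max(i_floor, 1)
    segment = v[:search_end]
    if segment.size == 0 or segment.min() > -0.2:
        raise NoDropError("no drop found: no descending phase before minimum")
    i = int(np.argmin(segment))
    estimate = (i + 0.5) / rate
    # sub-sample refinement: the descent is ballistic (quadratic in time), so
    # extrapolate a parabola through the last falling samples to the resting
    # level and take the crossing nearest the coarse estimate
    lo = i - 3
    post = z[i + 2 : i + 2 + int(0.2 * rate)]
    if lo >= 0 and post.size >= 3:
        floor_level = float(np.median(post))
        t_fit = np.arange(lo, i + 1) / rate
        coeffs = np.polyfit(t_fit, z[lo : i + 1] - floor_level, 2)
        roots = np.roots(coeffs)
        roots = roots[np.isreal(roots)].real
        near = roots[np.abs(roots - estimate) <= 2.0 / rate]
        if near.size:
            return float(near[np.argmin(np.abs(near - estimate))])
    return estimate


def synchronize(
    sync_events_imu: Sequence[float],
    sync_events_marker: Sequence[float],
) -> SyncResult:
    """Estimate the inter-clock offset (and drift, if two event pairs).

    Offset is the IMU-minus-marker time difference extrapolated to marker
    time zero; drift is its rate of change per second of marker time.
    """
    imu = np.asarray(sync_events_imu, dtype=float)
    marker = np.asarray(sync_events_marker, dtype=float)
    if imu.shape != marker.shape or imu.ndim != 1 or imu.size not in (1, 2):
        raise PairingError("expected 1 or 2 matched sync event pairs")
    diff = imu - marker
    if imu.size == 1:
        return SyncResult(offset=float(diff[0]), drift=None, residual=0.0)
    dt = marker[1] - marker[0]
    if dt == 0:
        raise PairingError("sync events must be distinct in time")
    drift = float((diff[1] - diff[0]) / dt)
    offset = float(diff[0] - drift * marker[0])
    return SyncResult(offset=offset, drift=drift, residual=0.0)


# ---------------------------------------------------------------------------
# Gait event detection
# ---------------------------------------------------------------------------

def detect_events_zeni(
    heel: np.ndarray,
    toe: np.ndarray,
    sacrum: np.ndarray,
    rate: float = 100.0,
    side: str = "left",
    min_progression: float = 0.5,
) -> EventSet:
    """Coordinate-based events for one foot from anterior-posterior positions.

    Foot strikes are local maxima of (heel - sacrum) along the progression
    axis, foot offs local minima of (toe - sacrum); the sign of the smoothed
    sacrum velocity normalizes walking direction per sample so back-and-forth
    passes both contribute.
    """
    heel = np.asarray(heel, dtype=float)
    toe = np.asarray(toe, dtype=float)
    sacrum_f = _lowpass(np.asarray(sacrum, dtype=float), rate, 2.0)
    path = float(np.sum(np.abs(np.diff(sacrum_f))))
    if path < min_progression:
        raise NoProgressionError(
            f"no progression: sacrum path length {path:.3f} m below {min_progression} m"
        )
    v = np.gradient(sacrum_f) * rate
    direction = np.sign(v)
    direction[direction == 0] = 1.0

    rel_heel = _lowpass(heel - np.asarray(sacrum, dtype=float), rate, MARKER_FILTER_HZ) * direction
    rel_toe = _lowpass(toe - np.asarray(sacrum, dtype=float), rate, MARKER_FILTER_HZ) * direction

    min_dist = max(1, int(0.4 * rate))

    def _peaks(x: np.ndarray) -> np.ndarray:
        prom = 0.2 * (x.max() - x.min())
        idx, _ = sps.find_peaks(x, distance=min_dist, prominence=prom)
        return _refine_peaks(x, idx)

    strikes = _peaks(rel_heel) / rate
    offs = _peaks(-rel_toe) / rate
    return EventSet(strikes={side: strikes}, offs={side: offs}, source="marker")


def _refine_peaks(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Sub-sample peak refinement by 3-point parabolic interpolation."""
    refined = idx.astype(float)
    for j, i in enumerate(idx):
        if 0 < i < x.size - 1:
            denom = x[i - 1] - 2.0 * x[i] + x[i + 1]
            if denom != 0:
                delta = 0.5 * (x[i - 1] - x[i + 1]) / denom
                refined[j] = i + float(np.clip(delta, -0.5, 0.5))
    return refined


def detect_events_imu(
    foot_gyro_sagittal: np.ndarray,
    rate: float = 256.0,
    side: str = "left",
) -> EventSet:
    """Gyro-based events for one foot from the sagittal angular velocity (°/s).

    Mid-swings are the dominant positive peaks; foot strike is the first
    post-peak local minimum below an adaptive negative threshold, foot off
    the last pre-peak local minimum below it.  All thresholds scale with the
    signal so the detector is amplitude-invariant.
    """
    w = _lowpass(np.asarray(foot_gyro_sagittal, dtype=float), rate, GYRO_FILTER_HZ)
    if w.size < int(rate) or w.max() <= 0:
        raise InsufficientStridesError("insufficient strides: no positive swing peaks")

    min_dist = max(1, int(0.4 * rate))
    cand, props = sps.find_peaks(w, height=0.3 * w.max(), distance=min_dist)
    if cand.size < 2:
        raise InsufficientStridesError("insufficient strides: fewer than 2 mid-swing peaks")
    med_height = float(np.median(props["peak_heights"]))
    keep = props["peak_heights"] >= 0.4 * med_height
    mids = cand[keep]
    if mids.size < 2:
        raise InsufficientStridesError("insufficient strides: fewer than 2 mid-swing peaks")

    minima, min_props = sps.find_peaks(-w, prominence=0.05 * med_height)
    neg_thresh = -0.15 * med_height
    deep = minima[w[minima] < neg_thresh]

    strikes: List[float] = []
    offs: List[float] = []
    for i, p in enumerate(mids):
        nxt = mids[i + 1] if i + 1 < mids.size else w.size
        prv = mids[i - 1] if i > 0 else 0
        after = deep[(deep > p) & (deep < nxt)]
        if after.size:
            strikes.append(after[0] / rate)
        before = deep[(deep < p) & (deep > prv)]
        if before.size:
            offs.append(before[-1] / rate)
    return EventSet(
        strikes={side: np.asarray(strikes)},
        offs={side: np.asarray(offs)},
        source="imu",
    )


# ---------------------------------------------------------------------------
# Cycle segmentation
# ---------------------------------------------------------------------------

def segment_cycles(
    times: np.ndarray,
    values: np.ndarray,
    events: EventSet,
    side: str,
    outcome: str = "knee_flexion",
    system: str = "OPTO",
    max_duration_dev: float = 0.4,
) -> List[AngleCycle]:
    """Cut an angle stream into 101-point time-normalized gait cycles.

    One cycle per consecutive same-side foot-strike pair, linearly resampled
    to 0-100%.  Cycles whose duration deviates more than ``max_duration_dev``
    (fraction) from the median duration are discarded and logged.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    strikes = np.asarray(events.strikes.get(side, []), dtype=float)
    strikes = strikes[(strikes >= times[0]) & (strikes <= times[-1])]
    if strikes.size < 2:
        raise NoCompleteCycleError("no complete cycle: fewer than 2 foot strikes")

    durations = np.diff(strikes)
    median_dur = float(np.median(durations))
    cycles: List[AngleCycle] = []
    index = 0
    for t0, t1, dur in zip(strikes[:-1], strikes[1:], durations):
        if median_dur > 0 and abs(dur - median_dur) / median_dur > max_duration_dev:
            logger.info(
                "discarding cycle %.3f-%.3f s: duration %.3f s deviates >%.0f%% "
                "from median %.3f s",
                t0, t1, dur, 100 * max_duration_dev, median_dur,
            )
            continue
        grid = np.linspace(t0, t1, N_SAMPLES)
        samples = np.interp(grid, times, values)
        cycles.append(AngleCycle(outcome, side, index, system, samples))
        index += 1
    if not cycles:
        raise NoCompleteCycleError("no complete cycle: all cycles rejected")
    return cycles
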