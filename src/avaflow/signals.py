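"""Signal processing for pulsatile flow-loop recordings.

Raw recordings carry five DAQ channels at 20 kHz (pump position, pump-derived
flow, retrograde flow, LV pressure, aortic pressure) and a valve-opening-area
(AVA) series at the 2 kHz camera rate.  This module aligns the channels with
known or estimated inter-channel delays (circular cross-correlation), smooths
and decimates the flow onto the camera time base, splits the record into
cardiac cycles, and extracts one (Qpeak, AVApeak) point per recording: the
mean flow and mean AVA over the samples exceeding 97% of the peak flow — the
least pulsatile phase of ejection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SignalRecording",
    "SyncedBeat",
    "PeakPoint",
    "CalibrationRef",
    "estimate_delay",
    "smooth_and_resample",
    "compute_q_inst",
    "synchronize",
    "detect_ejection_window",
    "select_peak_points",
    "calibrate_pixel_area",
    "area_from_mask",
]

DAQ_CHANNELS = ("pump_position", "q_pump", "q_retro", "p_lv", "p_ao")

#: default smoothing windows: 0.04 s of flow at 20 kHz, 0.02 s of AVA at 2 kHz
FLOW_MA_SAMPLES = 800
AVA_MA_FRAMES = 40


@dataclass
class SignalRecording:
    """Raw multi-channel recording for one (valve, grade, cardiac output) cell."""

    valve_id: str
    grade: str
    co_lpm: float
    daq_rate: float
    camera_rate: float
    channels: Mapping[str, np.ndarray]  # pump_position cm, q_* ml/s, p_* mmHg
    ava_series: np.ndarray              # fraction of LVOT, at camera_rate
    lvot_area_mm2: float
    piston_area_cm2: float
    hr_bpm: float = 60.0

    def __post_init__(self) -> None:
        if self.lvot_area_mm2 <= 0:
            raise ValueError("lvot_area_mm2 must be positive")
        ratio = self.daq_rate / self.camera_rate
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("daq_rate must be an integer multiple of camera_rate")
        for name in DAQ_CHANNELS:
            if name not in self.channels or len(self.channels[name]) == 0:
                raise ValueError(f"channel {name!r} missing or empty")
        if len(self.ava_series) == 0:
            raise ValueError("empty ava_series")

    @property
    def decimation(self) -> int:
        return int(round(self.daq_rate / self.camera_rate))


@dataclass
class SyncedBeat:
    """One cardiac cycle on the common 2 kHz time base after synchronization."""

    time: np.ndarray            # s
    q_inst_mlps: np.ndarray     # transvalvular flow, ml/s
    q_inst_idx_mps: np.ndarray  # same, indexed to LVOT area, m/s
    q_pump_mlps: np.ndarray     # piston flow (retrograde not subtracted), ml/s
    ava_inst: np.ndarray        # fraction of LVOT
    p_lv: np.ndarray            # mmHg
    p_ao: np.ndarray            # mmHg
    ejection_window: tuple[int, int]  # half-open [start, end)
    rate: float = 2000.0

    def __post_init__(self) -> None:
        n = len(self.time)
        for arr in (self.q_inst_mlps, self.q_inst_idx_mps, self.q_pump_mlps,
                    self.ava_inst, self.p_lv, self.p_ao):
            if len(arr) != n:
                raise ValueError("all beat series must share one length")
        a, b = self.ejection_window
        if not (0 <= a <= b <= n):
            raise ValueError("ejection_window out of bounds")


@dataclass(frozen=True)
class PeakPoint:
    """Mean flow and AVA over the top-3%-of-peak samples of one cell."""

    valve_id: str
    grade: str
    co_lpm: float
    q_peak_idx_mps: float
    q_peak_mlps: float
    ava_peak_frac: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.ava_peak_frac <= 1.0:
            raise ValueError("ava_peak_frac must lie in [0, 1]")
        if self.q_peak_idx_mps <= 0:
            raise ValueError("q_peak_idx_mps must be positive")


@dataclass(frozen=True)
class CalibrationRef:
    """Known-area reference object for pixel-size calibration."""

    known_area_mm2: float
    pixel_count: int

    def __post_init__(self) -> None:
        if self.known_area_mm2 <= 0 or self.pixel_count <= 0:
            raise ValueError("known_area_mm2 and pixel_count must be positive")


def estimate_delay(x: Sequence[float], y: Sequence[float]) -> int:
    """Signed lag (in samples) by which ``x`` leads ``y``.

    Maximises the circular cross-correlation
    ``r(l) = (1/N) sum_n x(n) y(n+l)`` over all N lags (computed via FFT),
    and maps the argmax into the signed range ``(-N/2, N/2]``.  Ties are
    broken toward the smallest ``|l|``.  If either input is constant the
    correlation is flat; 0 is returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    xc = x - x.mean()
    yc = y - y.mean()
    if np.allclose(xc, 0) or np.allclose(yc, 0):
        warnings.warn("constant input: delay undefined, returning 0", stacklevel=2)
        return 0
    # r[l] = sum_n x(n) y(n+l), circularly
    r = np.fft.ifft(np.conj(np.fft.fft(xc)) * np.fft.fft(yc)).real
    signed = np.where(np.arange(n) > n // 2, np.arange(n) - n, np.arange(n))
    # exclude -N/2 for even N: the signed range is (-N/2, N/2]
    valid = signed > -(n // 2) if n % 2 == 0 else np.ones(n, bool)
    best = r[valid].max()
    cand = signed[valid & np.isclose(r, best, rtol=0, atol=1e-9 * max(1.0, abs(best)))]
    return int(cand[np.argmin(np.abs(cand))])


def smooth_and_resample(series: Sequence[float], window_samples: int,
                        decimate: int = 1) -> np.ndarray:
    """Centered moving average with shrinking edge windows, then decimation.

    The window around index ``i`` spans ``[i - (w-1)//2, i + w//2]`` clipped
    to the series bounds (the divisor shrinks accordingly, so no padding is
    invented).  Decimation keeps every ``decimate``-th smoothed sample
    starting at index 0; output length is ``ceil(N / decimate)``.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if window_samples < 1:
        raise ValueError("window_samples must be >= 1")
    if decimate < 1:
        raise ValueError("decimate must be >= 1")
    if window_samples > n:
        raise ValueError(f"window ({window_samples}) exceeds series length ({n})")
    left = (window_samples - 1) // 2
    right = window_samples // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(n)
    lo = np.clip(idx - left, 0, n)
    hi = np.clip(idx + right + 1, 0, n)
    smoothed = (csum[hi] - csum[lo]) / (hi - lo)
    return smoothed[::decimate]


def compute_q_inst(pump_position: Sequence[float], piston_area_cm2: float,
                   q_retro: Sequence[float], rate: float) -> np.ndarray:
    """Instantaneous transvalvular flow from piston motion, in ml/s.

    ``Q_inst(t) = d(position)/dt * piston_area - Q_retro(t)`` with the
    derivative taken by central differences (one-sided at the ends).
    Position in cm and piston area in cm^2 give ml/s directly.
    """
    pos = np.asarray(pump_position, dtype=float)
    qr = np.asarray(q_retro, dtype=float)
    if pos.shape != qr.shape:
        raise ValueError("pump_position and q_retro must have equal length")
    vel = np.gradient(pos, 1.0 / rate)
    return vel * piston_area_cm2 - qr


def detect_ejection_window(q_inst: Sequence[float],
                           threshold_frac: float = 0.02,
                           hysteresis_samples: int = 5) -> tuple[int, int]:
    """Longest contiguous interval with flow above 2% of the beat maximum.

    Sub-threshold gaps no longer than ``hysteresis_samples`` do not break a
    run.  Returns a half-open index interval ``[start, end)``.
    """
    q = np.asarray(q_inst, dtype=float)
    qmax = q.max() if q.size else -np.inf
    if not np.isfinite(qmax) or qmax <= 0:
        raise ValueError("ejection detection requires some positive flow")
    above = q > threshold_frac * qmax
    # close short gaps (hysteresis)
    idx = np.flatnonzero(above)
    runs: list[tuple[int, int]] = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev - 1 <= hysteresis_samples:
            prev = i
        else:
            runs.append((start, prev + 1))
            start = prev = i
    runs.append((start, prev + 1))
    return max(runs, key=lambda r: r[1] - r[0])


def synchronize(recording: SignalRecording,
                delays_ms: Mapping[str, float] | None = None,
                flow_ma_samples: int = FLOW_MA_SAMPLES,
                ava_ma_frames: int = AVA_MA_FRAMES) -> list[SyncedBeat]:
    """Align channels, smooth, decimate to the camera rate, and split beats.

    ``delays_ms`` maps channel name (``"ava"``, ``"q_retro"``, ...) to the
    lead of that channel relative to the pump-position reference, in ms
    (positive = the channel runs ahead).  Channels are circularly shifted
    back by their lead, the transvalvular flow is computed at the DAQ rate,
    smoothed over ``flow_ma_samples`` and decimated onto the camera rate;
    the AVA series is smoothed over ``ava_ma_frames``.  One
    :class:`SyncedBeat` is returned per cardiac cycle.
    """
    delays_ms = dict(delays_ms or {})
    dec = recording.decimation
    daq = {name: np.asarray(recording.channels[name], float)
           for name in DAQ_CHANNELS}
    ava = np.asarray(recording.ava_series, float)

    def unshift(arr: np.ndarray, lead_ms: float, rate: float) -> np.ndarray:
        # a channel leading by d has features d early; roll forward to undo
        return np.roll(arr, int(round(lead_ms * rate / 1000.0)))

    for name in DAQ_CHANNELS:
        if name in delays_ms:
            daq[name] = unshift(daq[name], delays_ms[name], recording.daq_rate)
    if "ava" in delays_ms:
        ava = unshift(ava, delays_ms["ava"], recording.camera_rate)

    q_inst_raw = compute_q_inst(daq["pump_position"], recording.piston_area_cm2,
                                daq["q_retro"], recording.daq_rate)
    q_inst = smooth_and_resample(q_inst_raw, flow_ma_samples, dec)
    q_pump = smooth_and_resample(
        q_inst_raw + daq["q_retro"], flow_ma_samples, dec)
    p_lv = daq["p_lv"][::dec]
    p_ao = daq["p_ao"][::dec]
    ava_s = smooth_and_resample(ava, ava_ma_frames, 1)

    n = min(len(q_inst), len(ava_s), len(p_lv), len(p_ao))
    time = np.arange(n) / recording.camera_rate
    beat_len = int(round(recording.camera_rate * 60.0 / recording.hr_bpm))
    n_beats = max(1, n // beat_len)

    beats = []
    for b in range(n_beats):
        sl = slice(b * beat_len, min((b + 1) * beat_len, n))
        qb = q_inst[sl]
        win = detect_ejection_window(qb)
        beats.append(SyncedBeat(
            time=time[sl] - time[sl][0],
            q_inst_mlps=qb,
            q_inst_idx_mps=qb / recording.lvot_area_mm2,
            q_pump_mlps=q_pump[sl],
            ava_inst=ava_s[sl],
            p_lv=p_lv[sl],
            p_ao=p_ao[sl],
            ejection_window=win,
            rate=recording.camera_rate,
        ))
    return beats


def select_peak_points(beats: Sequence[SyncedBeat], valve_id: str, grade: str,
                       co_lpm: float, lvot_area_mm2: float,
                       frac: float = 0.97, per_beat: bool = False) -> PeakPoint:
    """Extract the (Qpeak, AVApeak) point from the beats of one cell.

    All samples with ``q_inst > frac * max(q_inst)`` — by default the max
    pooled over every beat of the cell — are selected, and the means of the
    flow (both unit systems) and the AVA over that pool form the point.
    With ``per_beat=True`` the 97% threshold is applied within each beat
    before pooling.
    """
    if len(beats) == 0:
        raise ValueError("need at least one beat")
    q_all = np.concatenate([b.q_inst_mlps for b in beats])
    a_all = np.concatenate([b.ava_inst for b in beats])
    if per_beat:
        mask = np.concatenate([
            b.q_inst_mlps > frac * b.q_inst_mlps.max() for b in beats])
    else:
        mask = q_all > frac * q_all.max()
    q_sel = q_all[mask]
    a_sel = a_all[mask]
    if q_sel.size == 0:  # cannot happen for finite input: the argmax qualifies
        raise ValueError("empty peak pool")
    q_mlps = float(q_sel.mean())
    return PeakPoint(
        valve_id=valve_id, grade=grade, co_lpm=co_lpm,
        q_peak_idx_mps=q_mlps / lvot_area_mm2,
        q_peak_mlps=q_mlps,
        ava_peak_frac=float(np.clip(a_sel.mean(), 0.0, 1.0)),
    )


def calibrate_pixel_area(ref: CalibrationRef) -> float:
    """Pixel area (mm^2 per pixel) from a reference object of known area."""
    return ref.known_area_mm2 / ref.pixel_count


def area_from_mask(binary_image: np.ndarray, pixel_area_mm2: float) -> float:
    """Area of a binarized opening: foreground pixel count times pixel area."""
    mask = np.asarray(binary_image).astype(bool)
    return float(mask.sum()) * pixel_area_mm2
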