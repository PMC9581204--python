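"""Synthetic flow-loop data with the statistical structure the analysis assumes.

Two levels of fidelity share one seeded set of per-cell targets:

* :func:`generate_peak_dataset` draws the analytic (Qpeak, AVApeak) points
  directly: indexed peak flow from a linear cardiac-output map (calibrated to
  the rig's observed flow range) plus valve-specific jitter, and AVA from the
  ground-truth sigmoid with additive Gaussian noise.
* :func:`generate_recordings` builds full multi-beat waveforms for the same
  cells: a flat-topped piston pulse with raised-cosine shoulders (so the peak
  plateau is what the 97%-of-peak rule measures), a retrograde-flow notch at
  ejection onset, Windkessel-flavoured aortic pressure meeting the 110/70 mmHg
  afterload targets, LV pressure carrying a stiffness-dependent gradient, and
  an AVA channel that tracks the sigmoid of instantaneous flow through a
  first-order opening/closing lag.  Channels are offset by configurable known
  delays for the synchronization stage to undo.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .models import ModelParams, ValveDataset, sigmoid_ava
from .signals import SignalRecording

__all__ = [
    "GroundTruth",
    "SyntheticConfig",
    "co_flow_map",
    "generate_peak_dataset",
    "generate_recordings",
    "inject_missing",
]

#: cardiac-output / indexed-flow anchors the CO->Q map is calibrated to
_CO_FLOW_ANCHORS = ((0.5, 0.24), (2.5, 0.57), (5.0, 0.96))


def co_flow_map() -> tuple[float, float]:
    """Least-squares (slope, intercept) of the CO (L/min) -> indexed peak
    flow (m/s) calibration line."""
    co, q = np.array(_CO_FLOW_ANCHORS).T
    slope, intercept = np.polyfit(co, q, 1)
    return float(slope), float(intercept)


_DEFAULT_SLOPE, _DEFAULT_INTERCEPT = co_flow_map()


@dataclass(frozen=True)
class GroundTruth:
    """Ground-truth generative parameters.

    ``theta_star`` are the sigmoid hyperparameters (theta3, theta4
    dimensionless, theta5 in s/m); ``s_star_per_grade`` the relative
    stiffness per grade with the native grade pinned at exactly 1;
    ``noise_sd_ava`` the additive noise SD on the AVA fraction.
    """

    theta_star: tuple[float, float, float] = (0.72, 3.14, 2.80)
    s_star_per_grade: Mapping[str, float] = field(
        default_factory=lambda: {"a": 1.0, "b": 1.16, "c": 1.34})
    noise_sd_ava: float = 0.02
    co_to_qidx_slope: float = _DEFAULT_SLOPE
    co_to_qidx_intercept: float = _DEFAULT_INTERCEPT

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.theta_star):
            raise ValueError("theta_star entries must be positive")
        if self.noise_sd_ava < 0:
            raise ValueError("noise_sd_ava must be nonnegative")
        grades = list(self.s_star_per_grade)
        if not grades or self.s_star_per_grade[grades[0]] != 1.0:
            raise ValueError("the native (first) grade must have s = 1 exactly")
        if any(s <= 0 for s in self.s_star_per_grade.values()):
            raise ValueError("stiffness values must be positive")

    @property
    def params(self) -> ModelParams:
        return ModelParams(kind="sigmoid", theta=self.theta_star)

    def ava_of(self, q_idx, grade: str):
        return sigmoid_ava(q_idx, self.s_star_per_grade[grade], self.params)

    def q_of_co(self, co_lpm):
        return self.co_to_qidx_slope * np.asarray(co_lpm, float) \
            + self.co_to_qidx_intercept


@dataclass(frozen=True)
class SyntheticConfig:
    """Shape, rates and rig settings of the synthetic experiment.

    The defaults encode the reference experiment: 11 valves x 3 stiffness
    grades x 10 cardiac outputs (0.5-5.0 L/min), DAQ at 20 kHz, camera at
    2 kHz, afterload 110/70 mmHg, camera leading the DAQ reference by 14 ms
    and the mitral flow probe by 11 ms (so the probe leads the DAQ by 3 ms).
    """

    n_valves: int = 11
    grades: tuple[str, ...] = ("a", "b", "c")
    cardiac_outputs: tuple[float, ...] = (
        0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0)
    seed: int = 0
    sampling_rate_daq: float = 20000.0
    sampling_rate_camera: float = 2000.0
    delays_ms: Mapping[str, float] = field(
        default_factory=lambda: {"ava": 14.0, "q_retro": 3.0})
    systolic_mmhg: float = 110.0
    diastolic_mmhg: float = 70.0
    lvot_area_mm2: float = 530.0
    lvot_area_sd_mm2: float = 40.0
    hr_bpm: float = 60.0
    stroke_partition: str = "fixed_rate"   # or "fixed_stroke"
    stroke_volume_ml: float = 70.0         # used by "fixed_stroke"
    n_beats: int = 3
    piston_area_cm2: float = 12.0
    tau_open_s: float = 0.005
    retro_frac: float = 0.15               # notch amplitude as fraction of peak
    valve_jitter_sd_mps: float = 0.03
    cell_jitter_sd_mps: float = 0.01
    lv_baseline_mmhg: float = 8.0
    gradient_gain_mmhg: float = 32.0       # Delta-P at 1 m/s for s = 1
    gradient_stiffness_exp: float = 3.4

    def __post_init__(self) -> None:
        if self.n_valves < 2:
            raise ValueError("need at least 2 valves for cross-validation")
        if len(self.grades) == 0 or len(self.cardiac_outputs) == 0:
            raise ValueError("grades and cardiac_outputs must be nonempty")
        co = np.asarray(self.cardiac_outputs, float)
        if np.any(np.diff(co) <= 0):
            raise ValueError("cardiac_outputs must be strictly increasing")
        ratio = self.sampling_rate_daq / self.sampling_rate_camera
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                "camera rate must divide the DAQ rate for exact decimation")
        if self.stroke_partition not in ("fixed_rate", "fixed_stroke"):
            raise ValueError("stroke_partition must be fixed_rate or fixed_stroke")

    @property
    def valve_ids(self) -> tuple[str, ...]:
        return tuple(f"V{i + 1:02d}" for i in range(self.n_valves))

    def beat_seconds(self, co_lpm: float) -> float:
        """Cardiac-cycle duration at one cardiac-output setpoint."""
        return 60.0 / self.heart_rate(co_lpm)

    def heart_rate(self, co_lpm: float) -> float:
        if self.stroke_partition == "fixed_stroke":
            return co_lpm * 1000.0 / self.stroke_volume_ml
        return self.hr_bpm


def _cell_frame(config: SyntheticConfig, truth: GroundTruth) -> pd.DataFrame:
    """Seeded per-cell targets shared by both generator levels.

    One row per (valve, grade, CO): the target indexed peak flow (CO map
    plus valve offset plus cell jitter), the valve's LVOT area, and the
    ground-truth stiffness of the grade.
    """
    missing = [g for g in config.grades if g not in truth.s_star_per_grade]
    if missing:
        raise ValueError(f"grades without ground-truth stiffness: {missing}")
    rng = np.random.default_rng(config.seed)
    lvot = np.clip(
        rng.normal(config.lvot_area_mm2, config.lvot_area_sd_mm2,
                   config.n_valves),
        0.7 * config.lvot_area_mm2, 1.3 * config.lvot_area_mm2)
    valve_offset = rng.normal(0.0, config.valve_jitter_sd_mps, config.n_valves)
    rows = []
    for v, valve in enumerate(config.valve_ids):
        for grade in config.grades:
            for co in config.cardiac_outputs:
                q = (truth.q_of_co(co) + valve_offset[v]
                     + rng.normal(0.0, config.cell_jitter_sd_mps))
                rows.append({
                    "valve_id": valve, "grade": grade, "co_lpm": float(co),
                    "q_peak_idx_mps": max(float(q), 0.02),
                    "lvot_area_mm2": float(lvot[v]),
                    "s": float(truth.s_star_per_grade[grade]),
                })
    return pd.DataFrame(rows)


def generate_peak_dataset(config: SyntheticConfig,
                          truth: GroundTruth) -> ValveDataset:
    """Analytic factorial dataset of (Qpeak, AVApeak) points.

    One point per (valve, grade, cardiac output): AVA is the ground-truth
    sigmoid of the target flow plus Gaussian noise, clipped to [0, 1].
    Byte-identical output for identical (config, truth).
    """
    cells = _cell_frame(config, truth)
    noise_rng = np.random.default_rng([config.seed, 1])
    ava = np.array([
        truth.ava_of(row.q_peak_idx_mps, row.grade)
        for row in cells.itertuples()
    ])
    ava = ava + noise_rng.normal(0.0, truth.noise_sd_ava, len(cells)) \
        if truth.noise_sd_ava > 0 else ava
    cells = cells.assign(
        ava_peak_frac=np.clip(ava, 0.0, 1.0),
        q_peak_mlps=cells["q_peak_idx_mps"] * cells["lvot_area_mm2"],
    )
    lvot_areas = dict(cells.groupby("valve_id")["lvot_area_mm2"].first())
    points = cells[["valve_id", "grade", "co_lpm", "q_peak_idx_mps",
                    "q_peak_mlps", "ava_peak_frac", "s"]]
    return ValveDataset(points=points.copy(), lvot_areas=lvot_areas)


def _raised_cosine_pulse(t: np.ndarray, t0: float, t_ramp: float,
                         t_plateau: float, amplitude: float) -> np.ndarray:
    """Flat-topped pulse: cosine up-ramp, plateau, cosine down-ramp."""
    out = np.zeros_like(t)
    tau = t - t0
    up = (tau >= 0) & (tau < t_ramp)
    out[up] = 0.5 * amplitude * (1 - np.cos(np.pi * tau[up] / t_ramp))
    flat = (tau >= t_ramp) & (tau < t_ramp + t_plateau)
    out[flat] = amplitude
    down = (tau >= t_ramp + t_plateau) & (tau < 2 * t_ramp + t_plateau)
    out[down] = 0.5 * amplitude * (
        1 + np.cos(np.pi * (tau[down] - t_ramp - t_plateau) / t_ramp))
    return out


def _one_cycle(config: SyntheticConfig, truth: GroundTruth, q_target_mlps: float,
               lvot_mm2: float, s_star: float, co_lpm: float,
               retro_amplitude: float | None = None) -> dict[str, np.ndarray]:
    """Build one noiseless cardiac cycle of every channel (no delays yet)."""
    fs = config.sampling_rate_daq
    t_cyc = config.beat_seconds(co_lpm)
    hr = config.heart_rate(co_lpm)
    n = int(round(fs * t_cyc))
    t = np.arange(n) / fs

    sv_net = co_lpm * 1000.0 / hr  # forward ml per beat
    amp = q_target_mlps
    if retro_amplitude is None:
        retro_amplitude = config.retro_frac * amp
    t0 = 0.08

    # piston pulse sized so the net forward volume matches the CO setpoint;
    # the retrograde bump volume depends on the ramp length, so size twice
    v_bump = 0.0
    for _ in range(2):
        t_total = (sv_net + v_bump) / amp  # = t_plateau + t_ramp
        t_ramp = float(np.clip(t_total - 0.048, 0.006, 0.045))
        bump_sigma = t_ramp / 16
        v_bump = retro_amplitude * bump_sigma * np.sqrt(2 * np.pi)
    t_plateau = t_total - t_ramp

    # retrograde (mitral leak) bump late in the up-ramp, narrow enough that
    # its rise outpaces the flattening cosine ramp: carves the notch into
    # the transvalvular flow without touching the peak plateau
    bump_center = t0 + 0.85 * t_ramp
    t_ej = t_plateau + 2 * t_ramp
    if t0 + t_ej > 0.55 * t_cyc:
        raise ValueError(
            f"ejection ({t_ej:.3f}s) does not fit the cycle at {co_lpm} L/min")

    piston_sys = _raised_cosine_pulse(t, t0, t_ramp, t_plateau, amp)
    retro_bump = retro_amplitude * np.exp(-0.5 * ((t - bump_center) / bump_sigma) ** 2)

    # diastolic filling through the mitral valve (piston withdraws)
    fill_start = t0 + t_ej + 0.06
    fill_len = t_cyc - fill_start - 0.03
    fill_amp = (sv_net + v_bump) * np.pi / (2 * fill_len)
    fill = np.zeros_like(t)
    in_fill = (t >= fill_start) & (t < fill_start + fill_len)
    fill[in_fill] = -fill_amp * np.sin(np.pi * (t[in_fill] - fill_start) / fill_len)

    q_pump = piston_sys + fill            # piston flow, ml/s
    q_retro = retro_bump + fill           # mitral-probe flow, ml/s
    q_tv = q_pump - q_retro               # transvalvular flow (notched)

    # aortic pressure: skewed systolic hump peaking at the systolic target,
    # then a Windkessel-like exponential decay to the diastolic target
    p_dia, p_sys = config.diastolic_mmhg, config.systolic_mmhg
    beta = 0.3
    p_ao = np.full_like(t, p_dia)
    in_ej = (t >= t0) & (t < t0 + t_ej)
    tau_ej = (t[in_ej] - t0) / t_ej
    p_ao[in_ej] = p_dia + (p_sys - p_dia) * np.sin(np.pi * tau_ej / (1 + beta))
    p_end = p_dia + (p_sys - p_dia) * np.sin(np.pi / (1 + beta))
    after = t >= t0 + t_ej
    t_dia = t_cyc - t_ej - t0 + t0        # decay runs to end of cycle and wraps
    tau_wk = max(t_dia, 1e-3) / np.log((p_end - p_dia) / 0.5)
    p_ao[after] = p_dia + (p_end - p_dia) * np.exp(-(t[after] - t0 - t_ej) / tau_wk)
    pre = t < t0
    p_ao[pre] = p_dia + (p_end - p_dia) * np.exp(
        -(t[pre] + t_cyc - t0 - t_ej) / tau_wk)

    # LV pressure: aortic plus a stiffness-dependent gradient during ejection
    gain = config.gradient_gain_mmhg * s_star ** config.gradient_stiffness_exp
    dp = gain * (np.clip(q_tv, 0, None) / lvot_mm2) ** 2
    p_lv = np.full_like(t, config.lv_baseline_mmhg)
    p_lv[in_ej] = p_ao[in_ej] + dp[in_ej]
    # isovolumetric ramps so the LV trace is continuous
    ramp_n = int(round(0.04 * fs))
    i0 = int(round(t0 * fs))
    i1 = min(i0 + int(round(t_ej * fs)), n - 1)
    lo = max(i0 - ramp_n, 0)
    p_lv[lo:i0] = np.linspace(config.lv_baseline_mmhg, p_lv[i0], i0 - lo,
                              endpoint=False)
    hi = min(i1 + ramp_n, n)
    p_lv[i1:hi] = np.linspace(p_lv[i1 - 1], config.lv_baseline_mmhg, hi - i1)

    # valve opening area: first-order lag on the static sigmoid response
    dec = int(round(fs / config.sampling_rate_camera))
    q_idx_cam = np.clip(q_tv[::dec], 0, None) / lvot_mm2
    t3, t4, t5 = truth.theta_star
    target = t3 / s_star ** t4 * (expit(q_idx_cam * t5) - 0.5)
    dt_cam = dec / fs
    decay = np.exp(-dt_cam / config.tau_open_s)
    ava = np.empty_like(target)
    a = 0.0
    for i, tgt in enumerate(target):
        a = tgt + (a - tgt) * decay
        ava[i] = a

    # pump position from the piston flow (cm); periodic by construction
    pos = np.concatenate(([0.0], np.cumsum(
        0.5 * (q_pump[1:] + q_pump[:-1]) / fs))) / config.piston_area_cm2

    return {"pump_position": pos[:n], "q_pump": q_pump, "q_retro": q_retro,
            "p_lv": p_lv, "p_ao": p_ao, "ava": ava, "q_tv": q_tv}


def _apply_lead(arr: np.ndarray, lead_ms: float, rate: float) -> np.ndarray:
    """Record a channel that runs ahead of the reference by ``lead_ms``."""
    return np.roll(arr, -int(round(lead_ms * rate / 1000.0)))


def generate_recordings(
    config: SyntheticConfig, truth: GroundTruth,
    cells: Iterable[tuple[str, str, float]] | None = None,
) -> list[SignalRecording]:
    """Waveform-level recordings for every (valve, grade, CO) cell.

    ``cells`` optionally restricts generation to a subset of
    ``(valve_id, grade, co_lpm)`` triples.  Channels are tiled over
    ``config.n_beats`` cycles and circularly offset by the configured
    per-channel leads; the synchronization stage is expected to undo them.
    """
    frame = _cell_frame(config, truth)
    if cells is not None:
        wanted = {(v, g, float(c)) for v, g, c in cells}
        mask = frame.apply(lambda r: (r["valve_id"], r["grade"],
                                      float(r["co_lpm"])) in wanted, axis=1)
        frame = frame[mask]
    recs = []
    for row in frame.itertuples():
        cyc = _one_cycle(config, truth,
                         q_target_mlps=row.q_peak_idx_mps * row.lvot_area_mm2,
                         lvot_mm2=row.lvot_area_mm2, s_star=row.s,
                         co_lpm=row.co_lpm)
        channels = {name: np.tile(cyc[name], config.n_beats)
                    for name in ("pump_position", "q_pump", "q_retro",
                                 "p_lv", "p_ao")}
        ava = np.tile(cyc["ava"], config.n_beats)
        for name, lead in config.delays_ms.items():
            if name == "ava":
                ava = _apply_lead(ava, lead, config.sampling_rate_camera)
            elif name in channels:
                channels[name] = _apply_lead(channels[name], lead,
                                             config.sampling_rate_daq)
        recs.append(SignalRecording(
            valve_id=row.valve_id, grade=row.grade, co_lpm=row.co_lpm,
            daq_rate=config.sampling_rate_daq,
            camera_rate=config.sampling_rate_camera,
            channels=channels, ava_series=ava,
            lvot_area_mm2=row.lvot_area_mm2,
            piston_area_cm2=config.piston_area_cm2,
            hr_bpm=config.heart_rate(row.co_lpm),
        ))
    return recs


def inject_missing(dataset: ValveDataset, n_missing: int,
                   seed: int) -> ValveDataset:
    """Remove ``n_missing`` cells uniformly at random (seeded).

    Mirrors occasional lost recordings; refuses to empty the dataset or to
    strip a valve of all its points (which would break the fold structure).
    """
    total = dataset.n_points
    if n_missing < 0:
        raise ValueError("n_missing must be nonnegative")
    if n_missing >= total:
        raise ValueError(f"cannot remove {n_missing} of {total} points")
    if n_missing == 0:
        return ValveDataset(points=dataset.points.copy(),
                            lvot_areas=dict(dataset.lvot_areas))
    rng = np.random.default_rng(seed)
    drop = rng.choice(total, size=n_missing, replace=False)
    kept = dataset.points.drop(index=dataset.points.index[drop])
    lost = set(dataset.points["valve_id"].unique()) - set(kept["valve_id"])
    if lost:
        raise ValueError(f"removal would strip all points of valves {sorted(lost)}")
    return ValveDataset(points=kept.reset_index(drop=True),
                        lvot_areas=dict(dataset.lvot_areas))
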