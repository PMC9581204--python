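"""Beat-level hemodynamic summaries for the flow-loop experiment.

Covers the cumulative left-ventricular work integral W(T) = int_0^T P_LV dV/dt dt
(trapezoidal, mmHg·ml converted to J), the mean systolic flow over the
ejection window (raw ml/s and indexed to the LVOT area in m/s), the mean
positive transvalvular gradient during valve patency, and the relative
stiffness metric: the per-cardiac-output ratio of maximal LV work between a
stiffened grade and the native grade, averaged over the four highest outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence
import warnings

import numpy as np

from .signals import SyncedBeat, detect_ejection_window

__all__ = [
    "BeatHemodynamics",
    "StiffnessAssignment",
    "MMHG_TO_PA",
    "cumulative_lv_work",
    "max_lv_work",
    "relative_stiffness",
    "mean_systolic_flow",
    "mean_transvalvular_gradient",
    "beat_hemodynamics",
]

MMHG_TO_PA = 133.322
ML_TO_M3 = 1e-6

#: cardiac outputs (L/min) over which work ratios define relative stiffness
DEFAULT_RATIO_COS = (3.5, 4.0, 4.5, 5.0)


@dataclass(frozen=True)
class BeatHemodynamics:
    """Summary of one synchronized beat."""

    w_cum_J: np.ndarray
    w_max_J: float
    q_syst_mlps: float
    q_syst_idx_mps: float
    mean_gradient_mmhg: float

    def __post_init__(self) -> None:
        if self.mean_gradient_mmhg < 0:
            raise ValueError("mean gradient cannot be negative")


@dataclass(frozen=True)
class StiffnessAssignment:
    """Relative stiffness of one (valve, grade), with the per-CO work ratios."""

    valve_id: str
    grade: str
    s: float
    k_per_co: Mapping[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.s <= 0 or any(k <= 0 for k in self.k_per_co.values()):
            raise ValueError("stiffness and work ratios must be positive")


def cumulative_lv_work(p_lv_mmhg: Sequence[float], dvdt_mlps: Sequence[float],
                       time_s: Sequence[float],
                       dt_rtol: float = 1e-6) -> np.ndarray:
    """Cumulative LV work series in joules.

    Trapezoidal integration of ``P_LV * dV/dt`` with mmHg→Pa and ml→m^3
    conversion.  ``dvdt_mlps`` follows the ejection-positive convention
    (outflow from the ventricle counts as positive work).
    """
    p = np.asarray(p_lv_mmhg, dtype=float)
    dv = np.asarray(dvdt_mlps, dtype=float)
    t = np.asarray(time_s, dtype=float)
    if not (p.shape == dv.shape == t.shape):
        raise ValueError("p_lv, dvdt and time must have equal length")
    dt = np.diff(t)
    if dt.size and (dt.max() - dt.min()) > dt_rtol * max(dt.mean(), 1e-30):
        raise ValueError("nonuniform time step beyond tolerance")
    power_w = p * MMHG_TO_PA * dv * ML_TO_M3  # watts
    w = np.empty_like(p)
    w[0] = 0.0
    if dt.size:
        w[1:] = np.cumsum(0.5 * (power_w[1:] + power_w[:-1]) * dt)
    return w


def max_lv_work(w_cum_J: Sequence[float]) -> float:
    """W_max: the maximum of the cumulative work series over the cycle."""
    w = np.asarray(w_cum_J, dtype=float)
    if w.size == 0:
        raise ValueError("empty work series")
    return float(w.max())


def relative_stiffness(w_max_a: Mapping[float, float],
                       w_max_bc: Mapping[float, float],
                       valve_id: str = "", grade: str = "",
                       co_list: Sequence[float] = DEFAULT_RATIO_COS,
                       method: str = "mean") -> StiffnessAssignment:
    """Relative stiffness from maximal-LV-work ratios at the highest outputs.

    ``k_CO = Wmax_bc(CO) / Wmax_a(CO)`` at each cardiac output in
    ``co_list`` (default the four highest, 3.5-5.0 L/min); ``s`` is their
    arithmetic mean.  ``method="lsq"`` instead fits a single ratio k by
    least squares across the four outputs (``k = sum w_a*w_bc / sum w_a^2``).
    The native grade compared against itself yields s = 1.
    """
    ks: dict[float, float] = {}
    for co in co_list:
        if co not in w_max_a or co not in w_max_bc:
            raise ValueError(f"missing W_max at cardiac output {co} L/min")
        if w_max_a[co] <= 0:
            raise ValueError(f"nonpositive reference work at {co} L/min")
        ks[co] = w_max_bc[co] / w_max_a[co]
    if method == "lsq":
        wa = np.array([w_max_a[co] for co in co_list])
        wbc = np.array([w_max_bc[co] for co in co_list])
        s = float(wa @ wbc / (wa @ wa))
    elif method == "mean":
        s = float(np.mean(list(ks.values())))
    else:
        raise ValueError(f"unknown method {method!r}")
    return StiffnessAssignment(valve_id=valve_id, grade=grade, s=s, k_per_co=ks)


def mean_systolic_flow(q_inst_mlps: Sequence[float],
                       ejection_window: tuple[int, int],
                       lvot_area_mm2: float) -> tuple[float, float]:
    """Mean flow over the ejection window, raw and LVOT-indexed.

    Returns ``(Qsyst in ml/s, Qsyst indexed in m/s)``; the indexed value is
    the raw mean divided by the LVOT area (ml/s over mm^2 is m/s exactly).
    """
    a, b = ejection_window
    q = np.asarray(q_inst_mlps, dtype=float)[a:b]
    if q.size == 0:
        raise ValueError("empty ejection window")
    mean_mlps = float(q.mean())
    return mean_mlps, mean_mlps / lvot_area_mm2


def mean_transvalvular_gradient(p_lv_mmhg: Sequence[float],
                                p_ao_mmhg: Sequence[float],
                                patency_window: tuple[int, int]) -> float:
    """Mean of the strictly positive LV-aortic pressure differences (mmHg)
    within the valve-patency window; 0 (with a warning) if none are positive."""
    p_lv = np.asarray(p_lv_mmhg, dtype=float)
    p_ao = np.asarray(p_ao_mmhg, dtype=float)
    if p_lv.shape != p_ao.shape:
        raise ValueError("pressure series must have equal length")
    a, b = patency_window
    dp = (p_lv - p_ao)[a:b]
    pos = dp[dp > 0]
    if pos.size == 0:
        warnings.warn("no positive gradient samples in patency window",
                      stacklevel=2)
        return 0.0
    return float(pos.mean())


def beat_hemodynamics(beat: SyncedBeat, lvot_area_mm2: float) -> BeatHemodynamics:
    """All beat-level summaries for one synchronized beat.

    Work uses the piston flow (retrograde component included, as the piston
    displaces it too); systolic flow and gradient use the ejection window.
    """
    t = np.arange(len(beat.p_lv)) / beat.rate
    w = cumulative_lv_work(beat.p_lv, beat.q_pump_mlps, t)
    q_mlps, q_idx = mean_systolic_flow(beat.q_inst_mlps, beat.ejection_window,
                                       lvot_area_mm2)
    grad = mean_transvalvular_gradient(beat.p_lv, beat.p_ao,
                                       beat.ejection_window)
    return BeatHemodynamics(
        w_cum_J=w, w_max_J=max_lv_work(w),
        q_syst_mlps=q_mlps, q_syst_idx_mps=q_idx,
        mean_gradient_mmhg=grad,
    )
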