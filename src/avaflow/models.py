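"""Linear and sigmoid models of aortic valve opening area versus flow.

The aortic valve opening area (AVA), expressed as a fraction of the left
ventricular outflow tract (LVOT) area, is modelled as a function of the
LVOT-indexed peak transvalvular flow Q (m/s) and a dimensionless relative
valve stiffness s:

* linear:   ``F1(Q, s) = theta1 * Q * theta2 / s``  (unbounded in Q)
* sigmoid:  ``F2(Q, s) = theta3 / s**theta4 * (expit(Q * theta5) - 0.5)``
            (zero at Q = 0, saturating at ``theta3 / (2 * s**theta4)``)

Both are strictly increasing in Q and strictly decreasing in s; the
structural difference under test is the saturation of the sigmoid at high
flow.  Fitting is split in two nested least-squares problems: the
hyperparameters ``theta`` are fitted on training valves with their measured
stiffness held fixed, and the stiffness ``s`` of a held-out valve is then
fitted with ``theta`` frozen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit

__all__ = [
    "ModelParams",
    "ValveDataset",
    "linear_ava",
    "sigmoid_ava",
    "predict_ava",
    "fit_theta",
    "fit_stiffness",
    "LINEAR_INIT",
    "SIGMOID_INIT",
]

ModelKind = Literal["linear", "sigmoid"]
LinearForm = Literal["ratio", "power"]

#: fixed optimizer initialisations, so repeated fits are reproducible
LINEAR_INIT: tuple[float, ...] = (1.0, 0.1)
SIGMOID_INIT: tuple[float, ...] = (0.5, 1.0, 1.0)

#: lower bound on stiffness during the 1-D fit; physical ratios sit near 1
S_MIN = 1e-3

_FIT_TOL = 1e-12


@dataclass(frozen=True)
class ModelParams:
    """Fitted hyperparameter vector for one model family.

    Parameters
    ----------
    kind : {"linear", "sigmoid"}
        Model family.
    theta : array-like
        ``(theta1, theta2)`` for the linear model or
        ``(theta3, theta4, theta5)`` for the sigmoid model.
    linear_form : {"ratio", "power"}
        How stiffness enters the linear model: ``theta1*Q*theta2/s``
        (default) or ``theta1*Q*theta2**s``.
    """

    kind: ModelKind
    theta: tuple[float, ...]
    linear_form: LinearForm = "ratio"

    def __post_init__(self) -> None:
        theta = tuple(float(t) for t in self.theta)
        object.__setattr__(self, "theta", theta)
        expected = 2 if self.kind == "linear" else 3
        if self.kind not in ("linear", "sigmoid"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if len(theta) != expected:
            raise ValueError(
                f"{self.kind} model takes {expected} hyperparameters, got {len(theta)}"
            )
        if not np.all(np.isfinite(theta)):
            raise ValueError("non-finite hyperparameters")
        if self.kind == "sigmoid" and any(t <= 0 for t in theta):
            raise ValueError("sigmoid hyperparameters must be positive")

    @property
    def n_hyper(self) -> int:
        """Number of fitted hyperparameters (2 linear, 3 sigmoid)."""
        return len(self.theta)

    def predict(self, q_idx, s):
        """Evaluate the model at indexed flow ``q_idx`` (m/s) and stiffness ``s``."""
        return predict_ava(q_idx, s, self)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "theta": list(self.theta),
            "n_hyper": self.n_hyper,
            "linear_form": self.linear_form,
        }


def _check_s(s) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0):
        raise ValueError("relative stiffness s must be positive")
    return s


def linear_ava(q_idx, s, params: ModelParams):
    """Linear (in Q, through the origin) AVA fraction.

    Default form ``theta1 * Q * theta2 / s``; the ``power`` form uses
    ``theta1 * Q * theta2 ** s``.  Note the two thetas of the ratio form are
    identified only through their product.
    """
    if params.kind != "linear":
        raise ValueError("linear_ava requires linear params")
    s = _check_s(s)
    q = np.asarray(q_idx, dtype=float)
    t1, t2 = params.theta
    if params.linear_form == "power":
        return t1 * q * t2**s
    return t1 * q * t2 / s


def sigmoid_ava(q_idx, s, params: ModelParams):
    """Saturating sigmoid AVA fraction.

    ``F2 = theta3 / s**theta4 * (expit(Q*theta5) - 0.5)``: exactly zero at
    Q = 0 and approaching ``theta3 / (2 s**theta4)`` as Q grows.
    """
    if params.kind != "sigmoid":
        raise ValueError("sigmoid_ava requires sigmoid params")
    s = _check_s(s)
    q = np.asarray(q_idx, dtype=float)
    t3, t4, t5 = params.theta
    return t3 / s**t4 * (expit(q * t5) - 0.5)


def predict_ava(q_idx, s, params: ModelParams):
    """Dispatch to :func:`linear_ava` or :func:`sigmoid_ava` by ``params.kind``."""
    if params.kind == "linear":
        return linear_ava(q_idx, s, params)
    return sigmoid_ava(q_idx, s, params)


def fit_theta(
    q_idx,
    s,
    ava,
    kind: ModelKind,
    linear_form: LinearForm = "ratio",
    x0: tuple[float, ...] | None = None,
) -> ModelParams:
    """Fit the model hyperparameters on training points with known stiffness.

    Minimises ``sum_i (AVA_i - F(Q_i, s_i, theta))**2`` over theta with the
    Levenberg-Marquardt algorithm, from a fixed initial point so that the fit
    is deterministic.

    Parameters
    ----------
    q_idx, s, ava : array-like, same length
        Indexed peak flow (m/s), measured relative stiffness, and measured
        AVA fraction per training point.
    kind : {"linear", "sigmoid"}

    Returns
    -------
    ModelParams

    Raises
    ------
    ValueError
        If there are not strictly more points than hyperparameters.
    RuntimeError
        If the optimizer fails to converge.
    """
    q = np.asarray(q_idx, dtype=float)
    s_arr = _check_s(s)
    y = np.asarray(ava, dtype=float)
    if not (q.shape == s_arr.shape == y.shape):
        raise ValueError("q_idx, s and ava must have matching shapes")
    n_hyper = 2 if kind == "linear" else 3
    if q.size <= n_hyper:
        raise ValueError(
            f"underdetermined fit: {q.size} points for {n_hyper} hyperparameters"
        )
    if x0 is None:
        x0 = LINEAR_INIT if kind == "linear" else SIGMOID_INIT

    def resid(theta):
        p = _raw_params(kind, theta, linear_form)
        return _predict_raw(q, s_arr, p) - y

    sol = least_squares(
        resid, x0=np.asarray(x0, float), method="lm",
        ftol=_FIT_TOL, xtol=_FIT_TOL, gtol=_FIT_TOL, max_nfev=20000,
    )
    if not sol.success:
        raise RuntimeError(f"theta fit did not converge: {sol.message}")
    return ModelParams(kind=kind, theta=tuple(sol.x), linear_form=linear_form)


def _raw_params(kind, theta, linear_form):
    # evaluation without ModelParams validation: intermediate optimizer
    # iterates may transiently leave the positive orthant
    return {"kind": kind, "theta": tuple(float(t) for t in theta), "linear_form": linear_form}


def _predict_raw(q, s, p):
    if p["kind"] == "linear":
        t1, t2 = p["theta"]
        if p["linear_form"] == "power":
            return t1 * q * np.sign(t2) * np.abs(t2) ** s
        return t1 * q * t2 / s
    t3, t4, t5 = p["theta"]
    with np.errstate(over="ignore", invalid="ignore"):
        scale = t3 / np.abs(s) ** t4
    return scale * (expit(q * t5) - 0.5)


def fit_stiffness(q_idx, ava, params: ModelParams, s0: float = 1.0) -> float:
    """Fit the relative stiffness of one valve+grade with theta frozen.

    One-dimensional least squares over ``s > 0`` (trust-region reflective,
    lower bound ``1e-3`` to keep ``1/s`` terms finite), initialised at
    ``s = 1``.

    Returns
    -------
    float
        The fitted stiffness ``s_hat``.
    """
    q = np.asarray(q_idx, dtype=float)
    y = np.asarray(ava, dtype=float)
    if q.size == 0:
        raise ValueError("fit_stiffness requires at least one point")
    if q.shape != y.shape:
        raise ValueError("q_idx and ava must have matching shapes")

    def resid(svec):
        return predict_ava(q, svec[0], params) - y

    sol = least_squares(
        resid, x0=np.array([s0]), bounds=([S_MIN], [np.inf]), method="trf",
        ftol=_FIT_TOL, xtol=_FIT_TOL, gtol=_FIT_TOL, max_nfev=20000,
    )
    if not sol.success:
        raise RuntimeError(f"stiffness fit did not converge: {sol.message}")
    return float(sol.x[0])


_POINT_COLUMNS = [
    "valve_id", "grade", "co_lpm",
    "q_peak_idx_mps", "q_peak_mlps", "ava_peak_frac", "s",
]


@dataclass
class ValveDataset:
    """Factorial collection of peak points with stiffness assignments.

    ``points`` is a tidy DataFrame with one row per (valve, grade, cardiac
    output) cell and columns ``valve_id, grade, co_lpm, q_peak_idx_mps,
    q_peak_mlps, ava_peak_frac, s``.  ``lvot_areas`` maps valve id to LVOT
    area in mm^2.
    """

    points: pd.DataFrame
    lvot_areas: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in _POINT_COLUMNS if c not in self.points.columns]
        if missing:
            raise ValueError(f"points table missing columns: {missing}")
        if self.points["s"].le(0).any():
            raise ValueError("all stiffness assignments must be positive")
        self.points = self.points.reset_index(drop=True)

    @property
    def valves(self) -> list[str]:
        return sorted(self.points["valve_id"].unique())

    @property
    def grades(self) -> list[str]:
        return sorted(self.points["grade"].unique())

    @property
    def n_points(self) -> int:
        return len(self.points)

    def subset_valves(self, valve_ids: Iterable[str]) -> pd.DataFrame:
        ids = set(valve_ids)
        return self.points[self.points["valve_id"].isin(ids)]

    def valve_grade(self, valve_id: str, grade: str) -> pd.DataFrame:
        p = self.points
        return p[(p["valve_id"] == valve_id) & (p["grade"] == grade)]

    def stiffness_of(self, valve_id: str, grade: str) -> float:
        sub = self.valve_grade(valve_id, grade)
        if sub.empty:
            raise KeyError(f"no points for valve {valve_id} grade {grade}")
        return float(sub["s"].iloc[0])
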