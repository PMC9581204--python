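"""Modified leave-one-valve-out cross-validation.

Each fold trains the hyperparameters theta on every valve but one (with the
measured stiffness of each training point held fixed), then — with theta
frozen — fits the relative stiffness of the held-out valve once per grade.
The low-flow projection experiment refits s per (test valve, grade) on only
the lowest cardiac-output points and predicts AVA at the held-out highest
flows, emulating the clinical task of projecting valve area from a low-flow
state to normal flow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .models import (LinearForm, ModelKind, ModelParams, ValveDataset,
                     fit_stiffness, fit_theta, predict_ava)

__all__ = ["FoldSplit", "FoldResult", "make_folds", "run_crossval",
           "project_high_flow_ava"]


@dataclass(frozen=True)
class FoldSplit:
    """One leave-one-valve-out split."""

    fold_index: int
    train_valves: tuple[str, ...]
    test_valve: str
    m1: int                       # training point count
    m2: Mapping[str, int]         # test point count per grade

    def __post_init__(self) -> None:
        if self.test_valve in self.train_valves:
            raise ValueError("test valve cannot appear in the training set")


@dataclass
class FoldResult:
    """Fitted theta, per-grade stiffness, and projections for one fold."""

    fold_index: int
    test_valve: str
    params: ModelParams
    s_hat: Mapping[str, float]
    s_true: Mapping[str, float]
    projections: pd.DataFrame = field(default_factory=pd.DataFrame)


def make_folds(dataset: ValveDataset) -> list[FoldSplit]:
    """K folds for K valves; every valve is the held-out valve exactly once.

    ``m1``/``m2`` reflect the actual (possibly missing-data-reduced) point
    counts of each split.
    """
    valves = dataset.valves
    if len(valves) < 2:
        raise ValueError("cross-validation requires at least 2 valves")
    folds = []
    for j, test in enumerate(valves):
        train = tuple(v for v in valves if v != test)
        m1 = len(dataset.subset_valves(train))
        test_pts = dataset.subset_valves([test])
        m2 = dict(test_pts.groupby("grade").size())
        folds.append(FoldSplit(fold_index=j, train_valves=train,
                               test_valve=test, m1=m1, m2=m2))
    return folds


def run_crossval(dataset: ValveDataset, kind: ModelKind,
                 linear_form: LinearForm = "ratio",
                 holdouts: Sequence[int] = (3, 5)) -> list[FoldResult]:
    """Run the full modified K-fold procedure for one model family.

    Per fold: theta fitted on the training valves, then per grade of the
    test valve a frozen-theta stiffness fit (using all that grade's points)
    plus, for each holdout size, the low-flow projection of
    :func:`project_high_flow_ava`.
    """
    results = []
    for fold in make_folds(dataset):
        train = dataset.subset_valves(fold.train_valves)
        try:
            params = fit_theta(train["q_peak_idx_mps"], train["s"],
                               train["ava_peak_frac"], kind=kind,
                               linear_form=linear_form)
        except (ValueError, RuntimeError) as err:
            raise RuntimeError(
                f"theta fit failed on fold {fold.fold_index} "
                f"(test valve {fold.test_valve}): {err}") from err
        s_hat, s_true = {}, {}
        test_pts = dataset.subset_valves([fold.test_valve])
        for grade, sub in test_pts.groupby("grade"):
            try:
                s_hat[grade] = fit_stiffness(sub["q_peak_idx_mps"],
                                             sub["ava_peak_frac"], params)
            except (ValueError, RuntimeError) as err:
                raise RuntimeError(
                    f"stiffness fit failed on fold {fold.fold_index}, "
                    f"grade {grade}: {err}") from err
            s_true[grade] = float(sub["s"].iloc[0])
        proj = pd.concat(
            [project_high_flow_ava(fold, dataset, params, n) for n in holdouts],
            ignore_index=True) if holdouts else pd.DataFrame()
        results.append(FoldResult(fold_index=fold.fold_index,
                                  test_valve=fold.test_valve, params=params,
                                  s_hat=s_hat, s_true=s_true,
                                  projections=proj))
    return results


def project_high_flow_ava(fold: FoldSplit, dataset: ValveDataset,
                          params: ModelParams,
                          n_holdout: int) -> pd.DataFrame:
    """Predict AVA at the highest flows from the low-flow points only.

    Per grade of the fold's test valve: the ``n_holdout`` highest
    cardiac-output points (ranked by setpoint) are held out, s is refitted
    on the remaining low-flow points with the fold's frozen theta, and the
    model is evaluated at the held-out Qpeak values.

    Returns a tidy frame with one row per held-out point:
    ``fold, valve_id, grade, co_lpm, q_peak_idx_mps, ava_true, ava_pred,
    s_hat_lowflow, n_holdout``.
    """
    if n_holdout < 1:
        raise ValueError("n_holdout must be >= 1")
    rows = []
    test_pts = dataset.subset_valves([fold.test_valve])
    for grade, sub in test_pts.groupby("grade"):
        sub = sub.sort_values("co_lpm")
        if len(sub) < n_holdout + 1:
            raise ValueError(
                f"grade {grade} of valve {fold.test_valve} has {len(sub)} "
                f"points; need at least {n_holdout + 1}")
        low = sub.iloc[:-n_holdout]
        high = sub.iloc[-n_holdout:]
        s_low = fit_stiffness(low["q_peak_idx_mps"], low["ava_peak_frac"],
                              params)
        pred = predict_ava(high["q_peak_idx_mps"].to_numpy(), s_low, params)
        for (_, r), p in zip(high.iterrows(), pred):
            rows.append({
                "fold": fold.fold_index, "valve_id": fold.test_valve,
                "grade": grade, "co_lpm": r["co_lpm"],
                "q_peak_idx_mps": r["q_peak_idx_mps"],
                "ava_true": r["ava_peak_frac"], "ava_pred": float(p),
                "s_hat_lowflow": s_low, "n_holdout": n_holdout,
            })
    return pd.DataFrame(rows)
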