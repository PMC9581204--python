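"""Accuracy and agreement metrics for measured-versus-predicted comparisons.

The model-selection endpoint is the Akaike information criterion in its
least-squares form, ``AIC = n ln(MSE) + 2k`` with ``k`` counting the model
hyperparameters plus one (the residual-variance estimate).  Agreement
between measured and predicted quantities is summarised the way method-
comparison studies do: ordinary least-squares regression of predicted on
measured, Pearson correlation, Bland-Altman bias with a t-based confidence
interval, 1.96-SD limits of agreement, and a coefficient of variation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = ["EvalReport", "mse", "aic", "agreement_stats", "compare_models"]


@dataclass(frozen=True)
class EvalReport:
    """Agreement summary for one (model, task) comparison."""

    n: int
    mse: float
    pearson_r: float
    slope: float
    intercept: float
    bias: float
    bias_ci: tuple[float, float]
    limits_of_agreement: tuple[float, float]
    cv_percent: float
    aic: float | None = None
    n_hyper: int | None = None


def mse(true: Sequence[float], pred: Sequence[float]) -> float:
    """Mean squared difference between two equal-length vectors."""
    t = np.asarray(true, dtype=float)
    p = np.asarray(pred, dtype=float)
    if t.shape != p.shape or t.size == 0:
        raise ValueError("true and pred must be nonempty and of equal length")
    return float(np.mean((p - t) ** 2))


def aic(mse_value: float, n: int, n_hyper: int) -> float:
    """Least-squares AIC: ``n ln(MSE) + 2 (n_hyper + 1)``, natural log.

    A zero MSE (perfect fit) makes the log degenerate; ``-inf`` is returned
    with a warning rather than raising, so rankings still resolve.
    """
    if mse_value < 0:
        raise ValueError("mse_value cannot be negative")
    if mse_value == 0:
        warnings.warn("perfect fit: AIC is -inf", stacklevel=2)
        return -math.inf
    return n * math.log(mse_value) + 2 * (n_hyper + 1)


def agreement_stats(measured: Sequence[float], predicted: Sequence[float],
                    confidence: float = 0.95,
                    n_hyper: int | None = None) -> EvalReport:
    """Full agreement report between measured and predicted values.

    Regression (slope/intercept) and Pearson r regress *predicted on
    measured*; bias is ``mean(predicted - measured)`` with a t-based CI of
    the mean; limits of agreement are ``bias +/- 1.96 sd``; the coefficient
    of variation is ``100 * sd(differences) / mean(measured)``.  If
    ``n_hyper`` is given the report also carries the AIC of the comparison.
    """
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if m.shape != p.shape:
        raise ValueError("measured and predicted must have equal length")
    n = m.size
    if n < 3:
        raise ValueError("agreement statistics require n >= 3")
    if not (np.all(np.isfinite(m)) and np.all(np.isfinite(p))):
        raise ValueError("non-finite values")
    if np.allclose(m, m[0]):
        raise ValueError("measured values have zero variance")

    reg = stats.linregress(m, p)
    diffs = p - m
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    tcrit = stats.t.ppf(0.5 + confidence / 2, df=n - 1)
    half = tcrit * sd / math.sqrt(n)
    err = mse(m, p)
    return EvalReport(
        n=n,
        mse=err,
        pearson_r=float(reg.rvalue),
        slope=float(reg.slope),
        intercept=float(reg.intercept),
        bias=bias,
        bias_ci=(bias - half, bias + half),
        limits_of_agreement=(bias - 1.96 * sd, bias + 1.96 * sd),
        cv_percent=100.0 * sd / float(m.mean()),
        aic=aic(err, n, n_hyper) if n_hyper is not None else None,
        n_hyper=n_hyper,
    )


def compare_models(reports: Mapping[str, EvalReport]) -> list[dict]:
    """Rank models by ascending AIC (lower is better).

    All reports must describe the same prediction task (equal n) and carry
    an AIC.  Returns a list of ``{"model", "aic", "delta_aic"}`` dicts in
    rank order; exact ties keep the input order and are flagged.
    """
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    ns = {r.n for r in reports.values()}
    if len(ns) > 1:
        raise ValueError(f"reports describe different task sizes: {sorted(ns)}")
    if any(r.aic is None for r in reports.values()):
        raise ValueError("every report needs an AIC (pass n_hyper)")
    items = list(reports.items())
    order = sorted(range(len(items)), key=lambda i: (items[i][1].aic, i))
    best = items[order[0]][1].aic
    ranking = []
    for rank, i in enumerate(order):
        name, rep = items[i]
        ranking.append({
            "model": name, "rank": rank, "aic": rep.aic,
            "delta_aic": rep.aic - best,
            "tied": sum(r.aic == rep.aic for _, r in items) > 1,
        })
    return ranking
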