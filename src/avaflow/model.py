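"""High-level Model/Results interface.

:class:`AvaFlowModel` wraps a peak-point dataset and one model family;
``fit()`` runs the modified leave-one-valve-out cross-validation and returns
an :class:`AvaFlowResults` carrying the per-fold hyperparameters (reported
as mean +/- SD across folds), the measured-versus-
predicted stiffness table, the low-flow projection predictions, agreement
reports, a ``summary()`` table, and the nomogram construction.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import crossval, evaluation, nomogram
from .models import LinearForm, ModelKind, ModelParams, ValveDataset

__all__ = ["AvaFlowModel", "AvaFlowResults"]


class AvaFlowModel:
    """AVA-versus-flow model over a factorial valve dataset.

    Parameters
    ----------
    dataset : ValveDataset or DataFrame
        Peak points with stiffness assignments (tidy columns
        ``valve_id, grade, co_lpm, q_peak_idx_mps, q_peak_mlps,
        ava_peak_frac, s``).
    kind : {"sigmoid", "linear"}
    linear_form : {"ratio", "power"}
        Stiffness parameterization of the linear model.
    holdouts : sequence of int
        High-flow holdout sizes for the projection experiment.
    """

    def __init__(self, dataset: ValveDataset | pd.DataFrame,
                 kind: ModelKind = "sigmoid",
                 linear_form: LinearForm = "ratio",
                 holdouts: Sequence[int] = (3, 5)):
        if isinstance(dataset, pd.DataFrame):
            dataset = ValveDataset(points=dataset)
        self.dataset = dataset
        self.kind = kind
        self.linear_form = linear_form
        self.holdouts = tuple(holdouts)

    @classmethod
    def from_dataframe(cls, points: pd.DataFrame, **kwargs) -> "AvaFlowModel":
        return cls(ValveDataset(points=points), **kwargs)

    def fit(self) -> "AvaFlowResults":
        """Run the modified K-fold cross-validation and collect results."""
        folds = crossval.run_crossval(self.dataset, self.kind,
                                      linear_form=self.linear_form,
                                      holdouts=self.holdouts)
        return AvaFlowResults(self, folds)


class AvaFlowResults:
    """Fitted cross-validation results for one model family."""

    def __init__(self, model: AvaFlowModel,
                 fold_results: list[crossval.FoldResult]):
        self.model = model
        self.fold_results = fold_results
        thetas = np.array([fr.params.theta for fr in fold_results])
        #: across-fold mean of the hyperparameters
        self.params = thetas.mean(axis=0)
        #: across-fold SD of the hyperparameters
        self.params_sd = thetas.std(axis=0, ddof=1) if len(thetas) > 1 \
            else np.zeros_like(self.params)
        self.stiffness_frame = pd.DataFrame([
            {"fold": fr.fold_index, "valve_id": fr.test_valve, "grade": g,
             "s_true": fr.s_true[g], "s_hat": fr.s_hat[g]}
            for fr in fold_results for g in sorted(fr.s_hat)
        ])
        self.projections = pd.concat(
            [fr.projections for fr in fold_results], ignore_index=True) \
            if fold_results else pd.DataFrame()

    @property
    def kind(self) -> ModelKind:
        return self.model.kind

    @property
    def n_hyper(self) -> int:
        return self.fold_results[0].params.n_hyper

    def mean_params(self) -> ModelParams:
        """ModelParams built from the across-fold mean theta."""
        return ModelParams(kind=self.kind, theta=tuple(self.params),
                           linear_form=self.model.linear_form)

    def stiffness_report(self, confidence: float = 0.95) -> evaluation.EvalReport:
        """Agreement of predicted with measured relative stiffness."""
        sf = self.stiffness_frame
        return evaluation.agreement_stats(sf["s_true"], sf["s_hat"],
                                          confidence=confidence,
                                          n_hyper=self.n_hyper)

    def projection_report(self, n_holdout: int,
                          confidence: float = 0.95) -> evaluation.EvalReport:
        """Agreement of projected with true AVA at the held-out high flows."""
        sub = self.projections[self.projections["n_holdout"] == n_holdout]
        if sub.empty:
            raise ValueError(f"no projections with n_holdout={n_holdout}")
        return evaluation.agreement_stats(sub["ava_true"], sub["ava_pred"],
                                          confidence=confidence,
                                          n_hyper=self.n_hyper)

    def isostiffness_lines(self, q_grid=None, per_fold: bool = True,
                           ) -> list[nomogram.IsostiffnessLine]:
        """One line per (fold, grade) from the fold's theta and fitted s
        (``per_fold=False``: one line per grade from the mean theta and the
        mean fitted s)."""
        lines = []
        if per_fold:
            for fr in self.fold_results:
                for g in sorted(fr.s_hat):
                    lines += nomogram.isostiffness_lines(
                        fr.params, [fr.s_hat[g]], q_grid,
                        provenance=f"valve={fr.test_valve},fold={fr.fold_index}",
                        grades=[g])
        else:
            mp = self.mean_params()
            for g, sub in self.stiffness_frame.groupby("grade"):
                lines += nomogram.isostiffness_lines(
                    mp, [float(sub["s_hat"].mean())], q_grid,
                    provenance="group-mean", grades=[g])
        return lines

    def nomogram_table(self, q_grid=None) -> pd.DataFrame:
        """Per-grade mean isostiffness lines with SE bands, as a tidy table."""
        return nomogram.lines_to_frame(
            nomogram.grade_mean_lines(self.isostiffness_lines(q_grid)))

    def plot_nomogram(self, ax=None, q_grid=None):
        """Plot per-valve lines and per-grade mean bands (needs matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        lines = self.isostiffness_lines(q_grid)
        colors = {}
        for ln in lines:
            c = colors.setdefault(ln.grade, f"C{len(colors)}")
            ax.plot(ln.q_grid, ln.ava_values, color=c, alpha=0.25, lw=0.8)
        for ml in nomogram.grade_mean_lines(lines):
            c = colors.get(ml.grade, "k")
            ax.plot(ml.q_grid, ml.ava_values, color=c, lw=2,
                    label=f"grade {ml.grade} (s={ml.s:.2f})")
            if ml.band_lo is not None:
                ax.fill_between(ml.q_grid, ml.band_lo, ml.band_hi,
                                color=c, alpha=0.2)
        ax.set_xlabel("indexed peak flow [m/s]")
        ax.set_ylabel("AVA [fraction of LVOT]")
        ax.legend()
        return ax

    def summary(self, confidence: float = 0.95) -> str:
        """Human-readable fit summary."""
        names = ("theta1", "theta2") if self.kind == "linear" \
            else ("theta3", "theta4", "theta5")
        lines = [
            f"{'AVA-flow cross-validated fit':^64}",
            "=" * 64,
            f"Model family:       {self.kind} ({self.model.linear_form})"
            if self.kind == "linear" else f"Model family:       {self.kind}",
            f"Valves (folds):     {len(self.fold_results)}",
            f"Points:             {self.model.dataset.n_points}",
            "-" * 64,
            "Hyperparameters (mean +/- SD across folds):",
        ]
        for name, m, sd in zip(names, self.params, self.params_sd):
            lines.append(f"    {name:<8s} {m:10.4f} +/- {sd:.4f}")
        rep = self.stiffness_report(confidence)
        lines += [
            "-" * 64,
            "Stiffness prediction (measured vs. predicted s):",
            f"    n = {rep.n}, r = {rep.pearson_r:.3f}, "
            f"slope = {rep.slope:.3f}, intercept = {rep.intercept:.3f}",
            f"    bias = {rep.bias:.3f}  CI[{rep.bias_ci[0]:.3f}; "
            f"{rep.bias_ci[1]:.3f}]  CV = {rep.cv_percent:.0f}%",
            f"    MSE = {rep.mse:.3e}  AIC = {rep.aic:.1f}",
        ]
        for n_h in self.model.holdouts:
            pr = self.projection_report(n_h, confidence)
            lines += [
                "-" * 64,
                f"AVA projection from low flow ({n_h} highest COs held out):",
                f"    n = {pr.n}, slope = {pr.slope:.3f}, r = {pr.pearson_r:.3f}",
                f"    MSE = {pr.mse:.3e}  AIC = {pr.aic:.1f}",
            ]
        lines.append("=" * 64)
        return "\n".join(lines)
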