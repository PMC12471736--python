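"""Model/Results interface over the full pipeline.

``NAMClassifier`` is built from a cohort table (or DataFrame); ``fit()``
performs the stratified split, optional bootstrap augmentation, train-only
z-scoring and network optimization, and returns a ``NAMResults`` carrying
the fitted parameters, training trace, held-out predictions, metric and
calibration reports, attributions and a printable ``summary()``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import evaluation, explain
from .data import (FeatureTable, SplitAssignment, StandardizationParams,
                   apply_standardizer, derive_ratios, fit_standardizer,
                   stratified_split)
from .evaluation import BootstrapConfig, CalibrationReport, MetricReport
from .nam import NAMConfig, NAMParams, init_nam, predict_batch, \
    shape_function_grid
from .synthetic import bootstrap_augment
from .training import TrainConfig, TrainTrace, train_nam


class NAMClassifier:
    """A neural additive binary classifier for a tabular cohort.

    Parameters
    ----------
    table : FeatureTable
        The full cohort (features + 0/1 labels), unstandardized.
    nam_config, train_config : optional
        Architecture and optimization settings; defaults are the
        [64, 32]/dropout-0.2, Adam lr 1e-3 protocol.
    add_ratios : bool
        Derive any absent panel ratio columns before modelling.
    """

    def __init__(self, table: FeatureTable,
                 nam_config: NAMConfig | None = None,
                 train_config: TrainConfig | None = None,
                 add_ratios: bool = False) -> None:
        self.table = derive_ratios(table) if add_ratios else table
        self.nam_config = nam_config or NAMConfig()
        self.train_config = train_config or TrainConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_column: str = "label",
                       **kwargs) -> "NAMClassifier":
        return cls(FeatureTable.from_dataframe(df, label_column), **kwargs)

    def fit(self, test_fraction: float = 0.2, split_seed: int = 0,
            augment: str | None = "train-only",
            monitor_fraction: float = 0.1, seed: int = 0) -> "NAMResults":
        """Split, standardize, optionally augment, and train.

        ``augment``: ``'train-only'`` (default; the training split is
        doubled by a bootstrap resample of itself, leakage-safe),
        ``'pre-split'`` (the whole cohort is doubled before splitting —
        reproduces the literal published flow but lets original/resample
        twins straddle the split; a leakage warning is emitted), or ``None``.

        A ``monitor_fraction`` slice of the training split is held out
        (stratified) to drive the scheduler and early stopping when the
        monitor is validation-based; with ``monitor='accuracy'`` the test
        split itself is monitored, replicating the published (leaky)
        stopping rule.
        """
        if augment not in (None, "none", "train-only", "pre-split"):
            raise ValueError(f"unknown augment mode {augment!r}")
        table = self.table
        if augment == "pre-split":
            warnings.warn(
                "pre-split augmentation lets bootstrap copies of one "
                "subject appear in both train and test (information "
                "leakage); 'train-only' is the leakage-safe default",
                UserWarning, stacklevel=2)
            table = bootstrap_augment(table, seed=seed)
        split = stratified_split(table, test_fraction, split_seed)
        train_tab = table.subset(split.train_indices)
        test_tab = table.subset(split.test_indices)
        if augment == "train-only":
            train_tab = bootstrap_augment(train_tab, seed=seed)

        scaler = fit_standardizer(train_tab)
        train_z = apply_standardizer(scaler, train_tab)
        test_z = apply_standardizer(scaler, test_tab)

        if self.train_config.monitor == "accuracy":
            fit_tab, monitor_tab = train_z, test_z
        else:
            vsplit = stratified_split(train_z, monitor_fraction,
                                      seed=split_seed + 1)
            fit_tab = train_z.subset(vsplit.train_indices)
            monitor_tab = train_z.subset(vsplit.test_indices)

        params0 = init_nam(self.nam_config, table.p, seed=seed,
                           feature_names=table.feature_names)
        params, trace = train_nam(params0, fit_tab, monitor_tab,
                                  self.train_config)
        return NAMResults(self, params, scaler, split, trace,
                          train_tab, test_tab, train_z, test_z)


class NAMResults:
    """Fitted model state plus evaluation and explanation accessors."""

    def __init__(self, model: NAMClassifier, params: NAMParams,
                 scaler: StandardizationParams, split: SplitAssignment,
                 trace: TrainTrace, train_table: FeatureTable,
                 test_table: FeatureTable, train_z: FeatureTable,
                 test_z: FeatureTable) -> None:
        self.model = model
        self.params = params
        self.scaler = scaler
        self.split = split
        self.trace = trace
        self.train_table = train_table
        self.test_table = test_table
        self.train_z = train_z
        self.test_z = test_z
        self.test_predictions = predict_batch(params, test_z)

    # -- prediction -------------------------------------------------------
    def predict(self, table: FeatureTable | pd.DataFrame | None = None):
        """Evaluation-mode predictions (default: the held-out test split)."""
        if table is None:
            return self.test_predictions
        if isinstance(table, pd.DataFrame):
            df = table.copy()
            if "label" not in df.columns:
                df["label"] = 0
            table = FeatureTable.from_dataframe(df)
        return predict_batch(self.params, apply_standardizer(self.scaler,
                                                             table))

    # -- evaluation -------------------------------------------------------
    def metrics(self, threshold: float = 0.5,
                bootstrap: BootstrapConfig | None = None) -> MetricReport:
        """Test-split metric suite, optionally with percentile-bootstrap CIs."""
        return evaluation.metric_report(self.test_predictions.probabilities,
                                        self.test_table.labels, threshold,
                                        bootstrap)

    def calibration(self, n_bins: int = 10,
                    weighted: bool = False) -> CalibrationReport:
        return evaluation.calibration_report(
            self.test_predictions.probabilities, self.test_table.labels,
            n_bins, weighted)

    # -- explanation ------------------------------------------------------
    def attributions(self, table_z: FeatureTable | None = None,
                     raw_table: FeatureTable | None = None
                     ) -> explain.AttributionSet:
        """Centered per-feature contributions; reference = training split."""
        if table_z is None:
            table_z, raw_table = self.test_z, self.test_table
        return explain.additive_attributions(self.params, table_z,
                                             self.train_z, raw_table)

    def importance(self, bootstrap: BootstrapConfig | None = None
                   ) -> explain.ImportanceReport:
        return explain.global_importance(self.attributions(), bootstrap)

    def intrinsic_importance(self) -> np.ndarray:
        return explain.nam_intrinsic_importance(self.params, self.test_z)

    def classwise(self) -> explain.ClasswiseReport:
        return explain.classwise_summary(self.attributions(),
                                         self.test_table.labels,
                                         self.test_table,
                                         self.intrinsic_importance())

    def shape_function(self, feature: str | int,
                       grid: np.ndarray | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
        """(grid, f_i(grid)) for one learned shape, on the standardized scale."""
        i = feature if isinstance(feature, int) \
            else self.params.feature_names.index(feature)
        if grid is None:
            col = self.train_z.values[:, i]
            grid = np.linspace(np.quantile(col, 0.01),
                               np.quantile(col, 0.99), 101)
        return np.asarray(grid), shape_function_grid(self.params, i, grid)

    # -- presentation -----------------------------------------------------
    def summary(self, bootstrap: BootstrapConfig | None = None,
                top_features: int = 10) -> str:
        """Plain-text report: fit info, test metrics, top feature importances."""
        rep = self.metrics(bootstrap=bootstrap)
        imp = self.importance()
        lines = [
            "Neural Additive Model — binary classification",
            "=" * 54,
            f"train rows: {self.train_table.n:>6d}    "
            f"test rows: {self.test_table.n}",
            f"features:   {self.params.p:>6d}    "
            f"hidden: {list(self.params.config.hidden_sizes)}  "
            f"dropout: {self.params.config.dropout_rate}",
            f"stopped at epoch {self.trace.stop_epoch}, restored weights "
            f"from epoch {self.trace.best_epoch} "
            f"(monitor: {self.trace.monitor})",
            "-" * 54,
            f"{'metric':<20}{'value':>9}{'95% CI':>22}",
        ]
        for k in ("accuracy", "balanced_accuracy", "f1", "mcc",
                  "sensitivity", "specificity", "ppv", "npv", "roc_auc",
                  "brier"):
            v = rep.values[k]
            ci = rep.intervals.get(k)
            ci_txt = f"[{ci[0]:.3f}, {ci[1]:.3f}]" if ci else ""
            lines.append(f"{k:<20}{v:>9.3f}{ci_txt:>22}")
        lines.append("-" * 54)
        lines.append(f"top {top_features} features by mean |phi| "
                     "(logit scale):")
        order = np.argsort(imp.rank)[:top_features]
        for i in order:
            lines.append(f"  {imp.rank[i]:>2d}. {imp.feature_names[i]:<10}"
                         f"{imp.mean_abs_phi[i]:.4f}")
        return "\n".join(lines)
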