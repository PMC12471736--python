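"""Diagnostic metric suite, percentile-bootstrap CIs, and calibration.

Threshold metrics are computed from a confusion matrix with the documented
tie rule (probability equal to the threshold counts as positive).  Quotients
whose denominator is zero (e.g. LR+ when specificity = 1) are reported as
NaN — the package's "undefined" marker — never as 0 or infinity; bootstrap
iterations where a metric is undefined are dropped and counted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

THRESHOLD_METRICS = ("accuracy", "balanced_accuracy", "f1", "mcc",
                     "sensitivity", "specificity", "ppv", "npv",
                     "lr_plus", "lr_minus")
ALL_METRICS = THRESHOLD_METRICS + ("roc_auc", "brier")


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class BootstrapConfig:
    n_iterations: int = 1000
    level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")


@dataclass
class MetricReport:
    """Point estimates (NaN = undefined) with optional percentile CIs."""

    values: dict[str, float]
    intervals: dict[str, tuple[float, float]] = field(default_factory=dict)
    n: int = 0
    threshold: float = 0.5
    dropped_iterations: dict[str, int] = field(default_factory=dict)

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "threshold": self.threshold,
            "metrics": {
                k: {"value": None if math.isnan(v) else v,
                    **({"ci_lower": self.intervals[k][0],
                        "ci_upper": self.intervals[k][1]}
                       if k in self.intervals else {})}
                for k, v in self.values.items()},
            "dropped_bootstrap_iterations": self.dropped_iterations,
        }


def confusion_at_threshold(probabilities: np.ndarray, labels: np.ndarray,
                           threshold: float = 0.5) -> ConfusionMatrix:
    """Tally the confusion matrix; p >= threshold predicts positive."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.shape != y.shape:
        raise ValueError("probabilities and labels must have equal length")
    if p.size == 0:
        raise ValueError("empty input")
    pred = (p >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    return ConfusionMatrix(tp, fp, fn, tn)


def _div(num: float, den: float) -> float:
    return num / den if den != 0 else float("nan")


def compute_metrics(cm: ConfusionMatrix) -> MetricReport:
    """The threshold metric suite from a confusion matrix.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    accuracy = (TP+TN)/n, balanced accuracy = (sens+spec)/2,
    PPV = TP/(TP+FP), NPV = TN/(TN+FN), F1 = 2*PPV*sens/(PPV+sens),
    MCC = (TP*TN - FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
    LR+ = sens/(1-spec), LR- = (1-sens)/spec.
    """
    if cm.n < 1:
        raise ValueError("empty confusion matrix")
    tp, fp, fn, tn = (float(cm.tp), float(cm.fp), float(cm.fn),
                      float(cm.tn))
    sens = _div(tp, tp + fn)
    spec = _div(tn, tn + fp)
    acc = (tp + tn) / cm.n
    bal = (sens + spec) / 2.0
    ppv = _div(tp, tp + fp)
    npv = _div(tn, tn + fn)
    f1 = _div(2.0 * ppv * sens, ppv + sens)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = _div(tp * tn - fp * fn, math.sqrt(denom)) if denom > 0 \
        else float("nan")
    lr_plus = _div(sens, 1.0 - spec)
    lr_minus = _div(1.0 - sens, spec)
    return MetricReport(
        {"accuracy": acc, "balanced_accuracy": bal, "f1": f1, "mcc": mcc,
         "sensitivity": sens, "specificity": spec, "ppv": ppv, "npv": npv,
         "lr_plus": lr_plus, "lr_minus": lr_minus},
        n=cm.n)


def roc_auc(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Rank-statistic (Mann-Whitney) AUC; tied scores contribute 1/2."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present for ROC AUC")
    return float(roc_auc_score(y, np.asarray(probabilities, dtype=float)))


def _metric_value(name: str, probabilities: np.ndarray, labels: np.ndarray,
                  threshold: float) -> float:
    if name in THRESHOLD_METRICS:
        cm = confusion_at_threshold(probabilities, labels, threshold)
        return compute_metrics(cm)[name]
    if name == "roc_auc":
        if len(np.unique(labels)) < 2:
            return float("nan")
        return roc_auc(probabilities, labels)
    if name == "brier":
        return float(np.mean((probabilities - labels) ** 2))
    raise ValueError(f"unknown metric {name!r}")


def bootstrap_ci(probabilities: np.ndarray, labels: np.ndarray,
                 metric: str, threshold: float = 0.5,
                 config: BootstrapConfig | None = None
                 ) -> tuple[float, float, float, int]:
    """Percentile-bootstrap CI for one metric on (probability, label) pairs.

    Returns (point, lower, upper, n_dropped): pairs are resampled with
    replacement ``n_iterations`` times; the interval is the (1±level)/2
    percentile of the resampled statistics; undefined iterations are
    dropped and counted.
    """
    config = config or BootstrapConfig()
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.size < 2:
        raise ValueError("need at least 2 samples to bootstrap")
    point = _metric_value(metric, p, y, threshold)
    rng = np.random.default_rng(config.seed)
    stats = np.empty(config.n_iterations)
    for b in range(config.n_iterations):
        idx = rng.integers(0, p.size, size=p.size)
        stats[b] = _metric_value(metric, p[idx], y[idx], threshold)
    defined = stats[~np.isnan(stats)]
    dropped = int(config.n_iterations - defined.size)
    if defined.size == 0:
        raise ValueError(f"metric {metric!r} undefined in every "
                         "bootstrap iteration")
    alpha = (1.0 - config.level) / 2.0
    lower = float(np.quantile(defined, alpha))
    upper = float(np.quantile(defined, 1.0 - alpha))
    return point, lower, upper, dropped


def metric_report(probabilities: np.ndarray, labels: np.ndarray,
                  threshold: float = 0.5,
                  bootstrap: BootstrapConfig | None = None) -> MetricReport:
    """Full metric suite (threshold metrics + AUC + Brier), optionally with CIs.

    With a bootstrap config, one shared resampling stream yields the CI for
    every metric (the resamples are identical across metrics, matching the
    practice of bootstrapping the test-set results once).
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    cm = confusion_at_threshold(p, y, threshold)
    report = compute_metrics(cm)
    report.threshold = threshold
    report.values["roc_auc"] = _metric_value("roc_auc", p, y, threshold)
    report.values["brier"] = _metric_value("brier", p, y, threshold)
    if bootstrap is not None:
        rng = np.random.default_rng(bootstrap.seed)
        stats = {k: [] for k in report.values}
        for _ in range(bootstrap.n_iterations):
            idx = rng.integers(0, p.size, size=p.size)
            pb, yb = p[idx], y[idx]
            cmb = compute_metrics(confusion_at_threshold(pb, yb, threshold))
            for k in THRESHOLD_METRICS:
                stats[k].append(cmb[k])
            stats["roc_auc"].append(_metric_value("roc_auc", pb, yb,
                                                  threshold))
            stats["brier"].append(_metric_value("brier", pb, yb, threshold))
        alpha = (1.0 - bootstrap.level) / 2.0
        for k, vals in stats.items():
            arr = np.asarray(vals)
            defined = arr[~np.isnan(arr)]
            report.dropped_iterations[k] = int(arr.size - defined.size)
            if defined.size:
                report.intervals[k] = (float(np.quantile(defined, alpha)),
                                       float(np.quantile(defined,
                                                         1.0 - alpha)))
    return report


@dataclass
class CalibrationReport:
    """Reliability binning over [0, 1] plus Brier score."""

    bin_edges: np.ndarray
    bin_mean_predicted: np.ndarray   # NaN for empty bins
    bin_observed_frequency: np.ndarray
    bin_counts: np.ndarray
    calibration_deviation: float
    brier: float
    weighted: bool = False

    def to_dict(self) -> dict:
        def clean(a):
            return [None if math.isnan(v) else float(v) for v in a]
        return {
            "bin_edges": self.bin_edges.tolist(),
            "bin_mean_predicted": clean(self.bin_mean_predicted),
            "bin_observed_frequency": clean(self.bin_observed_frequency),
            "bin_counts": self.bin_counts.tolist(),
            "calibration_deviation": self.calibration_deviation,
            "brier": self.brier,
            "weighted": self.weighted,
        }


def calibration_report(probabilities: np.ndarray, labels: np.ndarray,
                       n_bins: int = 10,
                       weighted: bool = False) -> CalibrationReport:
    """Equal-width reliability bins, calibration deviation, Brier score.

    ``calibration_deviation`` is the unweighted mean over non-empty bins of
    |mean predicted - observed frequency|; with ``weighted=True`` bins are
    count-weighted (the expected calibration error, ECE).  Brier is the mean
    squared gap between probability and outcome.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    # right-closed last bin so p = 1.0 lands in the top bin
    which = np.minimum(np.digitize(p, edges[1:], right=False), n_bins - 1)
    mean_pred = np.full(n_bins, np.nan)
    obs_freq = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        mask = which == b
        counts[b] = int(mask.sum())
        if counts[b]:
            mean_pred[b] = p[mask].mean()
            obs_freq[b] = y[mask].mean()
    nonempty = counts > 0
    gaps = np.abs(mean_pred[nonempty] - obs_freq[nonempty])
    if weighted:
        deviation = float(np.sum(gaps * counts[nonempty]) / counts.sum())
    else:
        deviation = float(gaps.mean()) if gaps.size else 0.0
    brier = float(np.mean((p - y) ** 2)) if p.size else 0.0
    return CalibrationReport(edges, mean_pred, obs_freq, counts,
                             deviation, brier, weighted)
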