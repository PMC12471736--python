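"""Exact additive attributions, a brute-force Shapley oracle, and reports.

For an additive model the Shapley value of feature i under interventional
imputation is exactly the centered shape function
``phi_i(x) = f_i(x_i) - E_ref[f_i]``; no sampling approximation is needed.
The enumeration oracle here computes Shapley values for *any* black-box
predictor by summing over all 2^p coalitions and exists to verify that
theorem numerically (and to attribute non-additive baselines on tiny p).

All attributions live on the logit scale: a positive phi pushes the sample
toward label 1 (AMI), a negative one toward the control class.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .data import FeatureTable
from .evaluation import BootstrapConfig
from .nam import NAMParams, predict_batch


@dataclass
class AttributionSet:
    """Per-sample centered contributions with their common base value.

    ``base_value + phi.sum(axis=1)`` reconstructs each sample's logit.
    """

    phi: np.ndarray          # (n, p)
    base_value: float
    logits: np.ndarray       # (n,)
    probabilities: np.ndarray
    feature_names: list[str]
    feature_values: np.ndarray | None = None  # raw (unstandardized) values

    @property
    def n(self) -> int:
        return self.phi.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.phi, columns=self.feature_names)
        df["base_value"] = self.base_value
        df["logit"] = self.logits
        df["probability"] = self.probabilities
        return df


def additive_attributions(params: NAMParams, table: FeatureTable,
                          reference: FeatureTable,
                          raw_table: FeatureTable | None = None
                          ) -> AttributionSet:
    """phi_i(x) = f_i(x_i) - mean_ref f_i; base = bias + sum of ref means.

    ``table`` and ``reference`` must be standardized with the training
    scaler; the reference (conventionally the training set) defines the
    expectation the contributions are centered on.  ``raw_table`` optionally
    carries the unstandardized values for report annotation.
    """
    if reference.n == 0:
        raise ValueError("reference table must be non-empty")
    preds = predict_batch(params, table)
    ref_preds = predict_batch(params, reference)
    ref_means = ref_preds.contributions.mean(axis=0)
    phi = preds.contributions - ref_means
    base = params.bias + ref_means.sum()
    raw = raw_table.values if raw_table is not None else None
    return AttributionSet(phi, float(base), preds.logits,
                          preds.probabilities, list(table.feature_names),
                          raw)


def shapley_enumeration_oracle(predict_fn: Callable[[np.ndarray], np.ndarray],
                               row: np.ndarray, background: np.ndarray,
                               p_max: int = 10) -> np.ndarray:
    """Exact interventional Shapley values by full coalition enumeration.

    ``predict_fn`` maps an (m, p) matrix to m logits.  For each coalition S,
    features outside S are replaced by every background row in turn and the
    predictions averaged; phi is the Shapley-weighted sum of marginal gains.
    Guarded to p <= p_max because cost grows as 2^p.

    Satisfies efficiency: phi.sum() = f(row) - mean_b f(background).
    """
    row = np.asarray(row, dtype=float)
    bg = np.asarray(background, dtype=float)
    if bg.ndim != 2 or row.shape != (bg.shape[1],):
        raise ValueError("row and background shapes are inconsistent")
    p = row.shape[0]
    if p > p_max:
        raise ValueError(f"p={p} exceeds p_max={p_max}; enumeration over "
                         f"2^{p} coalitions refused")
    m = bg.shape[0]
    values: dict[frozenset, float] = {}
    for r in range(p + 1):
        for S in itertools.combinations(range(p), r):
            x = bg.copy()
            x[:, list(S)] = row[list(S)]
            values[frozenset(S)] = float(np.mean(predict_fn(x)))
    phi = np.zeros(p)
    fact = math.factorial
    for i in range(p):
        others = [j for j in range(p) if j != i]
        for r in range(p):
            w = fact(r) * fact(p - r - 1) / fact(p)
            for S in itertools.combinations(others, r):
                s = frozenset(S)
                phi[i] += w * (values[s | {i}] - values[s])
    return phi


@dataclass
class ImportanceReport:
    """Global importance: mean |phi| per feature with bootstrap CIs and ranks."""

    feature_names: list[str]
    mean_abs_phi: np.ndarray
    rank: np.ndarray                       # 1 = most important
    ci_lower: np.ndarray | None = None
    ci_upper: np.ndarray | None = None

    def ordered_features(self) -> list[str]:
        order = np.argsort(self.rank)
        return [self.feature_names[i] for i in order]

    def to_dict(self) -> dict:
        out = {}
        for i, name in enumerate(self.feature_names):
            entry = {"mean_abs_phi": float(self.mean_abs_phi[i]),
                     "rank": int(self.rank[i])}
            if self.ci_lower is not None:
                entry["ci_lower"] = float(self.ci_lower[i])
                entry["ci_upper"] = float(self.ci_upper[i])
            out[name] = entry
        return out


def global_importance(attrs: AttributionSet,
                      boot: BootstrapConfig | None = None
                      ) -> ImportanceReport:
    """Mean |phi| per feature; CIs bootstrap over samples; descending ranks."""
    if attrs.n < 2:
        raise ValueError("need at least 2 samples for importance")
    point = np.abs(attrs.phi).mean(axis=0)
    order = np.argsort(-point, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(1, len(order) + 1)
    lo = hi = None
    if boot is not None:
        rng = np.random.default_rng(boot.seed)
        stats = np.empty((boot.n_iterations, attrs.phi.shape[1]))
        for b in range(boot.n_iterations):
            idx = rng.integers(0, attrs.n, size=attrs.n)
            stats[b] = np.abs(attrs.phi[idx]).mean(axis=0)
        alpha = (1.0 - boot.level) / 2.0
        lo = np.quantile(stats, alpha, axis=0)
        hi = np.quantile(stats, 1.0 - alpha, axis=0)
    return ImportanceReport(list(attrs.feature_names), point, rank, lo, hi)


def nam_intrinsic_importance(params: NAMParams,
                             table: FeatureTable) -> np.ndarray:
    """Per-feature mean |f_i(x_i) - mean f_i|, normalized to sum to 1.

    The model's own importance measure: how much each shape function moves
    the logit across the table, as a share of the total movement.
    """
    if table.n == 0:
        raise ValueError("table must be non-empty")
    contrib = predict_batch(params, table).contributions
    centered = np.abs(contrib - contrib.mean(axis=0)).mean(axis=0)
    total = centered.sum()
    if total == 0:
        warnings.warn("all shape functions are constant; returning a "
                      "uniform importance vector", stacklevel=2)
        return np.full(params.p, 1.0 / params.p)
    return centered / total


@dataclass
class ClasswiseReport:
    """Per-class attribution and raw-value summaries, plus rank concordance."""

    feature_names: list[str]
    classes: list[int]
    mean_phi: dict[int, np.ndarray]
    sd_phi: dict[int, np.ndarray]
    mean_value: dict[int, np.ndarray] | None
    sd_value: dict[int, np.ndarray] | None
    rank_concordance: float | None = None

    def to_dict(self) -> dict:
        out: dict = {"classes": self.classes, "features": {}}
        for i, name in enumerate(self.feature_names):
            entry: dict = {}
            for c in self.classes:
                entry[str(c)] = {
                    "mean_phi": float(self.mean_phi[c][i]),
                    "sd_phi": float(self.sd_phi[c][i]),
                }
                if self.mean_value is not None:
                    entry[str(c)]["mean_value"] = float(self.mean_value[c][i])
                    entry[str(c)]["sd_value"] = float(self.sd_value[c][i])
            out["features"][name] = entry
        if self.rank_concordance is not None:
            out["rank_concordance"] = self.rank_concordance
        return out


def classwise_summary(attrs: AttributionSet, labels: np.ndarray,
                      table: FeatureTable | None = None,
                      intrinsic_importance: np.ndarray | None = None
                      ) -> ClasswiseReport:
    """Mean/SD of phi (and of raw values) per class.

    With an intrinsic importance vector, also reports the Spearman rank
    concordance between the model's intrinsic importance and the
    attribution-based mean-|phi| importance.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (attrs.n,):
        raise ValueError("labels must align with the attribution set")
    classes = [0, 1]
    for c in classes:
        if not (labels == c).any():
            raise ValueError(f"class {c} absent; class-wise summary needs "
                             "both classes")
    mean_phi, sd_phi = {}, {}
    mean_val: dict[int, np.ndarray] | None = {} if table is not None else None
    sd_val: dict[int, np.ndarray] | None = {} if table is not None else None
    for c in classes:
        mask = labels == c
        mean_phi[c] = attrs.phi[mask].mean(axis=0)
        sd_phi[c] = attrs.phi[mask].std(axis=0)
        if table is not None:
            mean_val[c] = table.values[mask].mean(axis=0)
            sd_val[c] = table.values[mask].std(axis=0)
    concordance = None
    if intrinsic_importance is not None:
        mean_abs = np.abs(attrs.phi).mean(axis=0)
        concordance = float(spearmanr(intrinsic_importance,
                                      mean_abs).statistic)
    return ClasswiseReport(list(attrs.feature_names), classes, mean_phi,
                           sd_phi, mean_val, sd_val, concordance)


def per_sample_report(attrs: AttributionSet, sample: int,
                      top_k: int | None = None,
                      order: str = "abs") -> dict:
    """Ordered contribution listing for one sample (waterfall-plot ready).

    Contributions sorted by descending |phi| (``order='abs'``, default) or
    by signed value descending (``order='signed'``); each entry carries the
    raw feature value when available and the direction it pushes.  The full
    listing plus the base value sums to the sample's logit.
    """
    if not 0 <= sample < attrs.n:
        raise IndexError(f"sample index {sample} out of range")
    phi = attrs.phi[sample]
    if order == "abs":
        idx = np.argsort(-np.abs(phi), kind="stable")
    elif order == "signed":
        idx = np.argsort(-phi, kind="stable")
    else:
        raise ValueError("order must be 'abs' or 'signed'")
    k = len(phi) if top_k is None else min(top_k, len(phi))
    entries = []
    for i in idx[:k]:
        entry = {
            "feature": attrs.feature_names[i],
            "phi": float(phi[i]),
            "direction": "toward AMI" if phi[i] > 0 else
                         ("toward control" if phi[i] < 0 else "neutral"),
        }
        if attrs.feature_values is not None:
            entry["value"] = float(attrs.feature_values[sample, i])
        entries.append(entry)
    return {
        "sample": int(sample),
        "base_value": attrs.base_value,
        "logit": float(attrs.logits[sample]),
        "probability": float(attrs.probabilities[sample]),
        "contributions": entries,
        "omitted_phi_sum": float(phi[idx[k:]].sum()),
    }
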