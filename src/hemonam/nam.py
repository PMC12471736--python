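"""The neural additive model: one small MLP per feature, summed with a bias.

Each feature x_i passes through a dedicated subnetwork f_i (scalar in, two
hidden ReLU layers, scalar out); the prediction logit is the exact sum
``sum_i f_i(x_i) + b0`` squashed by a sigmoid.  Because the logit is a plain
sum, per-feature contributions are read off the forward pass — no post-hoc
approximation is involved.

Weights for all p subnetworks are stored as stacked arrays so a batch forward
pass is a handful of einsums; a per-feature view is available through
:meth:`NAMParams.subnetwork` for scalar-level inspection and testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit

from .data import FeatureTable, StandardizationParams


@dataclass
class NAMConfig:
    """Architecture of every feature subnetwork."""

    hidden_sizes: tuple[int, int] = (64, 32)
    dropout_rate: float = 0.2
    activation: str = "relu"

    def __post_init__(self) -> None:
        h1, h2 = self.hidden_sizes
        if h1 < 1 or h2 < 1:
            raise ValueError("hidden sizes must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        if self.activation != "relu":
            raise ValueError("only ReLU activation is supported")


@dataclass
class SubnetworkParams:
    """One feature's weights: scalar -> h1 -> h2 -> scalar."""

    w1: np.ndarray  # (h1,)
    b1: np.ndarray  # (h1,)
    w2: np.ndarray  # (h2, h1)
    b2: np.ndarray  # (h2,)
    w3: np.ndarray  # (h2,)
    b3: float


@dataclass
class NAMParams:
    """All subnetwork weights (stacked over features) plus the global bias."""

    config: NAMConfig
    feature_names: list[str]
    W1: np.ndarray  # (p, h1)
    B1: np.ndarray  # (p, h1)
    W2: np.ndarray  # (p, h1, h2)
    B2: np.ndarray  # (p, h2)
    W3: np.ndarray  # (p, h2)
    B3: np.ndarray  # (p,)
    bias: float = 0.0

    @property
    def p(self) -> int:
        return self.W1.shape[0]

    def subnetwork(self, i: int) -> SubnetworkParams:
        return SubnetworkParams(self.W1[i], self.B1[i], self.W2[i].T,
                                self.B2[i], self.W3[i], float(self.B3[i]))

    def set_subnetwork(self, i: int, sub: SubnetworkParams) -> None:
        self.W1[i] = sub.w1
        self.B1[i] = sub.b1
        self.W2[i] = np.asarray(sub.w2).T
        self.B2[i] = sub.b2
        self.W3[i] = sub.w3
        self.B3[i] = sub.b3

    def copy(self) -> "NAMParams":
        return NAMParams(self.config, list(self.feature_names),
                         self.W1.copy(), self.B1.copy(), self.W2.copy(),
                         self.B2.copy(), self.W3.copy(), self.B3.copy(),
                         self.bias)

    def weight_arrays(self) -> list[np.ndarray]:
        """Multiplicative weights (L2-decayed during training)."""
        return [self.W1, self.W2, self.W3]

    def offset_arrays(self) -> list[np.ndarray]:
        return [self.B1, self.B2, self.B3]

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path,
             standardizer: StandardizationParams | None = None) -> None:
        doc = {
            "config": {"hidden_sizes": list(self.config.hidden_sizes),
                       "dropout_rate": self.config.dropout_rate,
                       "activation": self.config.activation},
            "feature_names": self.feature_names,
            "weights": {k: getattr(self, k).tolist()
                        for k in ("W1", "B1", "W2", "B2", "W3", "B3")},
            "bias": self.bias,
        }
        if standardizer is not None:
            doc["standardizer"] = {"mean": standardizer.mean.tolist(),
                                   "std": standardizer.std.tolist(),
                                   "feature_names": standardizer.feature_names}
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def load(cls, path: str | Path
             ) -> tuple["NAMParams", StandardizationParams | None]:
        d = json.loads(Path(path).read_text())
        cfg = NAMConfig(tuple(d["config"]["hidden_sizes"]),
                        d["config"]["dropout_rate"],
                        d["config"]["activation"])
        w = {k: np.asarray(v) for k, v in d["weights"].items()}
        params = cls(cfg, d["feature_names"], w["W1"], w["B1"], w["W2"],
                     w["B2"], w["W3"], w["B3"], d["bias"])
        scaler = None
        if "standardizer" in d:
            s = d["standardizer"]
            scaler = StandardizationParams(np.asarray(s["mean"]),
                                           np.asarray(s["std"]),
                                           s["feature_names"])
        return params, scaler


@dataclass
class AdditivePrediction:
    """One row's contributions f_i(x_i), their sum + bias, and the probability."""

    contributions: np.ndarray
    logit: float
    probability: float


@dataclass
class PredictionSet:
    """Batch predictions: per-sample logit, probability, contribution matrix."""

    contributions: np.ndarray  # (n, p)
    logits: np.ndarray         # (n,)
    probabilities: np.ndarray  # (n,)
    feature_names: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return self.logits.shape[0]


def init_nam(config: NAMConfig, p: int, seed: int = 0,
             feature_names: list[str] | None = None) -> NAMParams:
    """He-scaled random weights (variance 2/fan-in), zero offsets, bias 0."""
    if p < 1:
        raise ValueError("p must be >= 1")
    h1, h2 = config.hidden_sizes
    rng = np.random.default_rng(seed)
    W1 = rng.normal(0.0, np.sqrt(2.0 / 1), size=(p, h1))
    W2 = rng.normal(0.0, np.sqrt(2.0 / h1), size=(p, h1, h2))
    W3 = rng.normal(0.0, np.sqrt(2.0 / h2), size=(p, h2))
    names = feature_names if feature_names is not None \
        else [f"x{i}" for i in range(p)]
    if len(names) != p:
        raise ValueError("feature_names length must equal p")
    return NAMParams(config, list(names), W1, np.zeros((p, h1)), W2,
                     np.zeros((p, h2)), W3, np.zeros(p), bias=0.0)


def parameter_count(config: NAMConfig) -> int:
    """Trainable parameters per subnetwork (global bias excluded)."""
    h1, h2 = config.hidden_sizes
    return (h1 * 1 + h1) + (h2 * h1 + h2) + (1 * h2 + 1)


def _forward_stack(params: NAMParams, X: np.ndarray,
                   dropout_masks: tuple[np.ndarray, np.ndarray] | None = None,
                   keep_hidden: bool = False):
    """Vectorized forward pass over a standardized batch X (n, p).

    Returns (contributions, hidden) where contributions is (n, p); hidden
    activations are kept only when requested (for backprop).
    """
    rate = params.config.dropout_rate
    Z1 = X[:, :, None] * params.W1[None] + params.B1[None]      # (n,p,h1)
    A1 = np.maximum(Z1, 0.0)
    if dropout_masks is not None and rate > 0:
        A1 = A1 * dropout_masks[0] / (1.0 - rate)
    Z2 = np.einsum("nph,phk->npk", A1, params.W2) + params.B2[None]
    A2 = np.maximum(Z2, 0.0)
    if dropout_masks is not None and rate > 0:
        A2 = A2 * dropout_masks[1] / (1.0 - rate)
    contrib = np.einsum("npk,pk->np", A2, params.W3) + params.B3[None]
    if keep_hidden:
        return contrib, (Z1, A1, Z2, A2)
    return contrib, None


def subnet_forward(subnet: SubnetworkParams, x: float | np.ndarray,
                   training: bool = False,
                   dropout_mask: tuple[np.ndarray, np.ndarray] | None = None,
                   dropout_rate: float = 0.0) -> float | np.ndarray:
    """Evaluate one subnetwork on a scalar (or vector of scalars).

    Evaluation mode is deterministic and dropout-free; training mode applies
    inverted dropout (kept units scaled by 1/(1-rate)) via the given masks.
    """
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    a1 = np.maximum(x_arr[:, None] * subnet.w1[None] + subnet.b1[None], 0.0)
    if training and dropout_rate > 0:
        if dropout_mask is None:
            raise ValueError("training with dropout requires a mask")
        m1, m2 = dropout_mask
        if m1.shape[-1] != subnet.w1.shape[0] or \
                m2.shape[-1] != subnet.w3.shape[0]:
            raise ValueError("dropout mask shape mismatch")
        a1 = a1 * m1 / (1.0 - dropout_rate)
    a2 = np.maximum(a1 @ np.asarray(subnet.w2).T + subnet.b2[None], 0.0)
    if training and dropout_rate > 0:
        a2 = a2 * m2 / (1.0 - dropout_rate)
    out = a2 @ subnet.w3 + subnet.b3
    return float(out[0]) if np.isscalar(x) or np.asarray(x).ndim == 0 else out


def nam_forward(params: NAMParams, row: np.ndarray,
                training: bool = False,
                dropout_masks=None) -> AdditivePrediction:
    """Forward pass on one row; logit = contributions.sum() + bias exactly."""
    row = np.asarray(row, dtype=float)
    if row.shape != (params.p,):
        raise ValueError(f"row length {row.shape} != p={params.p}")
    masks = dropout_masks if training else None
    contrib, _ = _forward_stack(params, row[None, :], masks)
    contributions = contrib[0]
    logit = contributions.sum() + params.bias
    return AdditivePrediction(contributions, float(logit),
                              float(expit(logit)))


def predict_batch(params: NAMParams, table: FeatureTable) -> PredictionSet:
    """Evaluation-mode predictions for every row of a standardized table."""
    if table.feature_names != params.feature_names:
        raise ValueError("feature names do not match the trained schema")
    contrib, _ = _forward_stack(params, table.values)
    logits = contrib.sum(axis=1) + params.bias
    return PredictionSet(contrib, logits, expit(logits),
                         list(params.feature_names))


def predict_matrix(params: NAMParams, X: np.ndarray) -> PredictionSet:
    """Like :func:`predict_batch` but on a bare standardized matrix."""
    contrib, _ = _forward_stack(params, np.asarray(X, dtype=float))
    logits = contrib.sum(axis=1) + params.bias
    return PredictionSet(contrib, logits, expit(logits),
                         list(params.feature_names))


def shape_function_grid(params: NAMParams, feature_index: int,
                        grid: np.ndarray) -> np.ndarray:
    """Evaluate the learned f_i over a grid of standardized values."""
    sub = params.subnetwork(feature_index)
    return np.asarray(subnet_forward(sub, np.asarray(grid, dtype=float)))
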