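"""Weight-score neural network and four-level risk stratification.

A fully connected rectifier network (56 inputs, three hidden layers of 22
units, one output) produces a per-sample weight score.  Because nested
rectifier layers are unbounded, the single output node applies a logistic
squash so the score lies on [0,1], where the year-specific thresholds are
defined (for 1992: non-risk [0,0.2), low [0.2,0.5), medium [0.5,0.71), high
[0.71,1], scores above 0.93 clamped into high risk).

The training target for the weight score is configurable: binary
cross-entropy against the lung-cancer outcome (``target="event"``), or
soft targets at the stratum-interval midpoints against an ordinal risk
label (``target="ordinal"``, used when a ground-truth latent state exists,
i.e. on synthetic cohorts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .states import RISK_STATES

__all__ = [
    "DNNParams",
    "DNNTrainConfig",
    "YearThresholds",
    "DEFAULT_THRESHOLDS",
    "StratifierOutput",
    "CalibrationReport",
    "init_params",
    "rectifier",
    "forward",
    "train_dnn",
    "stratify",
    "stratify_scores",
    "calibrate",
    "confusion",
    "ORDINAL_TARGETS",
]


def rectifier(x: np.ndarray) -> np.ndarray:
    """Linear rectification: f(x) = x for x > 0, else 0."""
    return np.maximum(x, 0.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class DNNParams:
    """Layer weights/biases of the weight-score network plus input scaling."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    x_mean: np.ndarray | None = None
    x_std: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.biases):
            raise ValueError("weights and biases must pair up")
        for k, (W, b) in enumerate(zip(self.weights, self.biases)):
            if W.shape[0] != b.shape[0]:
                raise ValueError(f"layer {k}: bias length {b.shape[0]} != rows {W.shape[0]}")
            if k > 0 and W.shape[1] != self.weights[k - 1].shape[0]:
                raise ValueError(f"layer {k}: input width does not chain")
            if not (np.isfinite(W).all() and np.isfinite(b).all()):
                raise ValueError(f"layer {k}: non-finite parameters")

    @property
    def architecture(self) -> tuple[int, ...]:
        return (self.weights[0].shape[1],) + tuple(W.shape[0] for W in self.weights)


def init_params(
    sizes: tuple[int, ...] = (56, 22, 22, 22, 1), seed: int = 42
) -> DNNParams:
    """He-normal initialization of the layer stack."""
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes, sizes[1:]):
        weights.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_out, fan_in)))
        biases.append(np.zeros(fan_out))
    return DNNParams(weights=weights, biases=biases)


def _forward_pass(params: DNNParams, X: np.ndarray):
    """Hidden activations (rectified) and the squashed output score."""
    if params.x_mean is not None:
        X = (X - params.x_mean) / params.x_std
    acts = [X]
    h = X
    for W, b in zip(params.weights[:-1], params.biases[:-1]):
        h = rectifier(h @ W.T + b)
        acts.append(h)
    z = h @ params.weights[-1].T + params.biases[-1]
    return acts, _sigmoid(z[:, 0])


def forward(params: DNNParams, features: np.ndarray) -> np.ndarray | float:
    """Weight score in [0,1] for one feature vector or a matrix of rows."""
    X = np.asarray(features, dtype=float)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    if X.shape[1] != params.architecture[0]:
        raise ValueError(
            f"expected {params.architecture[0]} features, got {X.shape[1]}"
        )
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    _, score = _forward_pass(params, X)
    return float(score[0]) if single else score


#: Soft weight-score targets for ordinal training: the midpoint of each
#: stratum's 1992 threshold interval, ordered high→medium→low→non.
ORDINAL_TARGETS = {0: 0.82, 1: 0.605, 2: 0.35, 3: 0.10}


@dataclass
class DNNTrainConfig:
    learning_rate: float = 0.01
    batch_size: int = 32
    episodes: int = 30  # training epochs
    seed: int = 42
    hidden: tuple[int, ...] = (22, 22, 22)
    target: str = "event"  # "event" (binary outcome) or "ordinal" (risk level)


def train_dnn(
    X: np.ndarray, y: np.ndarray, config: DNNTrainConfig | None = None
) -> tuple[DNNParams, pd.DataFrame]:
    """Mini-batch SGD on cross-entropy between score and target.

    ``target="event"`` treats y as a binary outcome (requires both classes);
    ``target="ordinal"`` maps y ∈ {0..3} (high→non) to soft targets at the
    stratum midpoints.  Inputs are standardized with training moments stored
    in the returned parameters.  Returns the parameters and a per-epoch loss
    log; with ``episodes=0`` the initial parameters are returned untrained.
    """
    config = config or DNNTrainConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if config.target == "event":
        if np.unique(y).size < 2:
            raise ValueError("training outcome has a single class")
        t = y
    elif config.target == "ordinal":
        t = np.vectorize(ORDINAL_TARGETS.__getitem__)(y.astype(int)).astype(float)
    else:
        raise ValueError(f"unknown target {config.target!r}")

    sizes = (X.shape[1],) + tuple(config.hidden) + (1,)
    params = init_params(sizes, seed=config.seed)
    params.x_mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    params.x_std = sd

    rng = np.random.default_rng(config.seed)
    n = X.shape[0]
    log: list[dict] = []
    eps = 1e-12
    for epoch in range(config.episodes):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            acts, p = _forward_pass(params, X[idx])
            tb = t[idx]
            losses.append(
                float(-np.mean(tb * np.log(p + eps) + (1 - tb) * np.log(1 - p + eps)))
            )
            # output delta of cross-entropy through the logistic squash
            delta = (p - tb)[:, None] / len(idx)
            for k in range(len(params.weights) - 1, -1, -1):
                a = acts[k]
                gW = delta.T @ a
                gb = delta.sum(axis=0)
                if k > 0:
                    delta = (delta @ params.weights[k]) * (acts[k] > 0)
                params.weights[k] -= config.learning_rate * gW
                params.biases[k] -= config.learning_rate * gb
        log.append({"epoch": epoch, "loss": float(np.mean(losses))})
    return params, pd.DataFrame(log, columns=["epoch", "loss"])


@dataclass(frozen=True)
class YearThresholds:
    """Weight cut-offs (t_low, t_med, t_high, t_max) for one follow-up year."""

    year: int
    cuts: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        t_low, t_med, t_high, t_max = self.cuts
        if not (0.0 < t_low < t_med < t_high <= t_max <= 1.0):
            raise ValueError("cuts must satisfy 0 < t_low < t_med < t_high <= t_max <= 1")


#: 1992 cuts; later years default to these unless a threshold table overrides.
DEFAULT_THRESHOLDS = YearThresholds(year=1992, cuts=(0.2, 0.5, 0.71, 0.93))


@dataclass
class StratifierOutput:
    weight_score: np.ndarray
    stratum: np.ndarray


def stratify(score: float, thresholds: YearThresholds = DEFAULT_THRESHOLDS) -> str:
    """Map a weight score to its risk stratum.

    Half-open intervals closed at the top: [0, t_low) → non, [t_low, t_med)
    → low, [t_med, t_high) → medium, [t_high, 1] → high.  Scores in
    (t_max, 1] clamp into high risk.
    """
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score {score} outside [0, 1]")
    t_low, t_med, t_high, _ = thresholds.cuts
    if score < t_low:
        return "non"
    if score < t_med:
        return "low"
    if score < t_high:
        return "medium"
    return "high"


def stratify_scores(
    scores: np.ndarray, thresholds: YearThresholds = DEFAULT_THRESHOLDS
) -> np.ndarray:
    """Vectorized :func:`stratify`."""
    s = np.asarray(scores, dtype=float)
    if ((s < 0) | (s > 1)).any():
        raise ValueError("scores outside [0, 1]")
    t_low, t_med, t_high, _ = thresholds.cuts
    out = np.full(s.shape, "non", dtype=object)
    out[s >= t_low] = "low"
    out[s >= t_med] = "medium"
    out[s >= t_high] = "high"
    return out


@dataclass
class CalibrationReport:
    brier: float
    log_loss: float
    bins: pd.DataFrame


def calibrate(scores: np.ndarray, outcomes: np.ndarray, n_bins: int = 10) -> CalibrationReport:
    """Brier score, log loss (probabilities clipped at 1e-15) and reliability bins."""
    s = np.asarray(scores, dtype=float)
    o = np.asarray(outcomes, dtype=float)
    if s.shape != o.shape:
        raise ValueError("scores and outcomes must have equal length")
    if not np.isin(o, (0.0, 1.0)).all():
        raise ValueError("outcomes must be binary")
    brier = float(np.mean((s - o) ** 2))
    p = np.clip(s, 1e-15, 1 - 1e-15)
    ll = float(-np.mean(o * np.log(p) + (1 - o) * np.log(1 - p)))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(s, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        m = which == b
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "n": int(m.sum()),
                "mean_score": float(s[m].mean()) if m.any() else np.nan,
                "event_rate": float(o[m].mean()) if m.any() else np.nan,
            }
        )
    return CalibrationReport(brier=brier, log_loss=ll, bins=pd.DataFrame(rows))


def confusion(
    predicted: np.ndarray, true: np.ndarray, labels: tuple[str, ...] = RISK_STATES
) -> tuple[np.ndarray, float, dict[str, float]]:
    """4×4 count matrix (rows = true, cols = predicted), overall and per-class accuracy."""
    pred = np.asarray(predicted, dtype=object)
    tru = np.asarray(true, dtype=object)
    if pred.shape != tru.shape:
        raise ValueError("predicted and true must have equal length")
    known = set(labels)
    bad = (set(pred) | set(tru)) - known
    if bad:
        raise ValueError(f"unknown labels {sorted(map(str, bad))}")
    mat = _sk_confusion(tru, pred, labels=list(labels))
    acc = float(np.trace(mat)) / max(len(pred), 1)
    per_class = {}
    for i, lbl in enumerate(labels):
        row = mat[i].sum()
        per_class[lbl] = float(mat[i, i] / row) if row else np.nan
    return mat, acc, per_class
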