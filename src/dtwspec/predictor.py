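"""One-step EEG prediction with a single-hidden-layer perceptron.

A small MLP (tanh hidden layer the same size as the input layer, linear
output, no regularization) predicts the next sample of one EEG channel from
the 41 preceding samples (the immediately preceding point plus 40 further
lags).  Training examples are drawn only from the 1 s window preceding each
trial marker, and the network is trained with plain gradient descent in
batches of 50 examples.

Per trial, predictability is summarized as the sum of squared one-step
errors (SSE) over that trial's pre-trial window.  Separate models are fit
per subject and per condition (task/rest): the first task block trains the
task model and the second rest block the rest model, with the remaining
blocks held out — roughly an 80/20 train/test split.  The channel is z-scored
with statistics from the training windows only, so held-out data never leaks
into scaling or training.

If the final training SSE exceeds a threshold (a fraction of the SSE of the
constant-mean predictor, i.e. 1 - R^2 target), the net is considered stuck in
a poor optimum and is re-initialized with the next seed, up to a retry limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import EEGRecording, TrialTable

__all__ = [
    "MLPConfig",
    "MLPModel",
    "ConvergenceError",
    "build_training_set",
    "train_mlp",
    "predict_sse",
    "trial_sse",
]


class ConvergenceError(RuntimeError):
    """All re-initializations finished above the training-error threshold."""


@dataclass
class MLPConfig:
    n_lags: int = 40  # lags beyond the immediately preceding point -> 41 inputs
    hidden: int | None = None  # default: same as input size
    batch_size: int = 50
    learning_rate: float = 0.05
    epochs: int = 200
    train_sse_threshold: float = 0.5  # fraction of constant-mean predictor SSE
    max_retrains: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lags < 0:
            raise ValueError("n_lags must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.hidden is not None and self.hidden < 1:
            raise ValueError("hidden must be >= 1")

    @property
    def n_inputs(self) -> int:
        return self.n_lags + 1

    @property
    def n_hidden(self) -> int:
        return self.hidden if self.hidden is not None else self.n_inputs


@dataclass
class MLPModel:
    W1: np.ndarray  # hidden x inputs
    b1: np.ndarray
    w2: np.ndarray  # hidden
    b2: float
    train_sse: float
    norm: tuple[float, float] = (0.0, 1.0)  # (mean, sd) used to z-score the signal

    def forward(self, X: np.ndarray) -> np.ndarray:
        H = np.tanh(X @ self.W1.T + self.b1)
        return H @ self.w2 + self.b2


def window_examples(signal: np.ndarray, t: int, window: int, n_inputs: int):
    """(X, y) sliding one-step examples wholly inside [t - window, t)."""
    seg = signal[t - window : t]
    n_ex = window - n_inputs
    if n_ex <= 0:
        raise ValueError("window shorter than input size + 1")
    X = np.lib.stride_tricks.sliding_window_view(seg[:-1], n_inputs)[:n_ex]
    y = seg[n_inputs:]
    return X.copy(), y.copy()


def build_training_set(
    signal: np.ndarray,
    trials: TrialTable,
    rate: float,
    cfg: MLPConfig,
    norm: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Stack one-step examples from every trial's 1 s pre-trial window.

    The signal is z-scored; when ``norm`` is not given the statistics are
    computed from the supplied trials' windows themselves (training usage).
    Returns (X, y, (mean, sd)).
    """
    signal = np.asarray(signal, dtype=float).ravel()
    window = int(round(rate))
    if window <= cfg.n_inputs:
        raise ValueError("pre-trial window must exceed the MLP input size")
    for t in trials.trial_sample:
        if t - window < 0:
            raise ValueError(f"trial at sample {t} is closer to start than the 1 s window")
    if norm is None:
        pooled = np.concatenate([signal[t - window : t] for t in trials.trial_sample])
        norm = (float(pooled.mean()), float(pooled.std() or 1.0))
    z = (signal - norm[0]) / norm[1]
    Xs, ys = [], []
    for t in trials.trial_sample:
        X, y = window_examples(z, int(t), window, cfg.n_inputs)
        Xs.append(X)
        ys.append(y)
    return np.concatenate(Xs), np.concatenate(ys), norm


def _init(cfg: MLPConfig, seed: int) -> MLPModel:
    rng = np.random.default_rng(seed)
    n_in, n_h = cfg.n_inputs, cfg.n_hidden
    s1 = 1.0 / np.sqrt(n_in)
    s2 = 1.0 / np.sqrt(n_h)
    return MLPModel(
        W1=rng.uniform(-s1, s1, size=(n_h, n_in)),
        b1=rng.uniform(-s1, s1, size=n_h),
        w2=rng.uniform(-s2, s2, size=n_h),
        b2=float(rng.uniform(-s2, s2)),
        train_sse=np.inf,
    )


def _sse(model: MLPModel, X: np.ndarray, y: np.ndarray) -> float:
    return float(np.sum((model.forward(X) - y) ** 2))


def _train_once(model: MLPModel, X: np.ndarray, y: np.ndarray, cfg: MLPConfig) -> MLPModel:
    lr = cfg.learning_rate
    n = len(y)
    bounds = list(range(0, n, cfg.batch_size))
    for _ in range(cfg.epochs):
        for start in bounds:
            Xb = X[start : start + cfg.batch_size]
            yb = y[start : start + cfg.batch_size]
            H = np.tanh(Xb @ model.W1.T + model.b1)
            pred = H @ model.w2 + model.b2
            err = pred - yb  # d(MSE/2)/dpred up to 1/nb
            nb = len(yb)
            g_out = err / nb
            gw2 = H.T @ g_out
            gb2 = g_out.sum()
            g_h = np.outer(g_out, model.w2) * (1.0 - H**2)
            gW1 = g_h.T @ Xb
            gb1 = g_h.sum(axis=0)
            model.w2 -= lr * gw2
            model.b2 -= lr * gb2
            model.W1 -= lr * gW1
            model.b1 -= lr * gb1
    model.train_sse = _sse(model, X, y)
    return model


def train_mlp(X: np.ndarray, y: np.ndarray, cfg: MLPConfig) -> MLPModel:
    """Batch gradient descent with retrain-on-poor-fit.

    The first initialization whose final training SSE falls below
    ``train_sse_threshold * SSE(constant-mean predictor)`` is returned;
    :class:`ConvergenceError` is raised when ``max_retrains`` seeds all fail.
    With ``epochs == 0`` the (seeded) initialization itself is returned.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if len(y) == 0:
        raise ValueError("empty training set")
    if X.shape[1] != cfg.n_inputs:
        raise ValueError(f"expected {cfg.n_inputs} inputs, got {X.shape[1]}")
    sse_baseline = float(np.sum((y - y.mean()) ** 2))
    threshold = cfg.train_sse_threshold * sse_baseline
    for attempt in range(cfg.max_retrains):
        model = _init(cfg, cfg.seed + attempt)
        if cfg.epochs == 0:
            model.train_sse = _sse(model, X, y)
            return model
        model = _train_once(model, X, y, cfg)
        if model.train_sse <= threshold:
            return model
    raise ConvergenceError(
        f"training SSE stayed above {cfg.train_sse_threshold:.2f} x baseline "
        f"after {cfg.max_retrains} initializations"
    )


def predict_sse(
    model: MLPModel,
    signal: np.ndarray,
    trials: TrialTable,
    rate: float,
    cfg: MLPConfig,
) -> np.ndarray:
    """Per-trial SSE of one-step predictions over each pre-trial window."""
    if model.W1.shape[1] != cfg.n_inputs:
        raise ValueError("model input size does not match config")
    signal = np.asarray(signal, dtype=float).ravel()
    z = (signal - model.norm[0]) / model.norm[1]
    window = int(round(rate))
    out = np.zeros(len(trials))
    for idx, t in enumerate(trials.trial_sample):
        X, y = window_examples(z, int(t), window, cfg.n_inputs)
        out[idx] = float(np.sum((model.forward(X) - y) ** 2))
    return out


def _subset(trials: TrialTable, mask: np.ndarray) -> TrialTable:
    return TrialTable(
        trial_sample=trials.trial_sample[mask],
        block_id=trials.block_id[mask],
        block_type=[t for t, m in zip(trials.block_type, mask) if m],
    )


def trial_sse(
    eeg: EEGRecording,
    trials: TrialTable,
    channel: str | int,
    cfg: MLPConfig,
) -> np.ndarray:
    """SSE for every trial: per-condition models with held-out test blocks.

    The task model trains on the first task block, the rest model on the
    second rest block (or the only one).  SSE is reported for all trials of
    the condition, training blocks included (in-sample there).
    """
    signal = eeg.channel(channel)
    sse = np.full(len(trials), np.nan)
    for cond in ("task", "rest"):
        mask = trials.condition_mask(cond)
        if not mask.any():
            continue
        blocks = list(dict.fromkeys(trials.block_id[mask]))  # ordered unique
        train_block = blocks[min(1 if cond == "rest" else 0, len(blocks) - 1)]
        train_mask = mask & (trials.block_id == train_block)
        X, y, norm = build_training_set(signal, _subset(trials, train_mask), eeg.rate, cfg)
        model = train_mlp(X, y, cfg)
        model.norm = norm
        sse[mask] = predict_sse(model, signal, _subset(trials, mask), eeg.rate, cfg)
    return sse
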