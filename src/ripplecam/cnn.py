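"""Five-category 1D CNN episode classifier.

Architecture (fixed input length 2205 samples = 88.2 ms at 25 kHz):

    input 1x2205
      -> Conv1D, 128 filters, kernel 500, stride 10, valid  -> 171 x 128, ReLU
      -> MaxPool1D, size 10, stride 5                       -> 33 x 128
      -> Flatten                                            -> 4224
      -> FC 500, ReLU
      -> FC 5, softmax

The conv stride (10) and pool stride (5) are the unique integers consistent
with the layer sizes 2205 -> 171 and 171 -> 33 under valid windows.

Training is classical momentum SGD on the softmax cross-entropy loss with
coupled L2 weight decay, mini-batches reshuffled every epoch.  The network
is small enough that forward and backward passes are written directly as
NumPy matrix products; every gradient is verified against central finite
differences in the test suite.

The classifier consumes standardized (not log-transformed) zero-padded
waveforms: the log compression exists only to make the similarity selection
robust, while the network should see the true spike amplitudes.

Exposed in the statsmodels idiom: :class:`RippleEpisodeCNN` is constructed
from data, ``fit`` returns a :class:`CNNResults` carrying the trained
parameters, the training history and evaluation utilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix
from sklearn.metrics import roc_auc_score

from .waveforms import CATEGORIES, PAD_LENGTH, RippleError, RippleWaveform

logger = logging.getLogger(__name__)

_EPS_LOG = 1e-12  # clamp for log of vanishing probabilities


# ---------------------------------------------------------------------------
# Architecture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CnnArchitecture:
    """Layer-size arithmetic for the one-conv-layer network."""

    input_len: int = PAD_LENGTH
    conv_filters: int = 128
    conv_kernel: int = 500
    conv_stride: int = 10
    pool_size: int = 10
    pool_stride: int = 5
    fc_hidden: int = 500
    n_classes: int = 5

    @property
    def conv_out_len(self) -> int:
        return (self.input_len - self.conv_kernel) // self.conv_stride + 1

    @property
    def pool_out_len(self) -> int:
        return (self.conv_out_len - self.pool_size) // self.pool_stride + 1

    @property
    def flatten_size(self) -> int:
        return self.pool_out_len * self.conv_filters

    def __post_init__(self) -> None:
        if self.input_len < self.conv_kernel or self.conv_out_len < self.pool_size:
            raise RippleError("architecture: layer sizes collapse to nothing")
        for f in ("conv_filters", "conv_stride", "pool_stride", "fc_hidden", "n_classes"):
            if getattr(self, f) < 1:
                raise RippleError(f"architecture: {f} must be >= 1")


@dataclass
class TrainingConfig:
    """Momentum-SGD hyperparameters (defaults follow the study conditions)."""

    batch_size: int = 64
    epochs: int = 400
    learning_rate: float = 0.001
    momentum: float = 0.5
    weight_decay: float = 0.005
    shuffle_each_epoch: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1:
            raise RippleError("batch_size and epochs must be positive")
        if self.learning_rate <= 0:
            raise RippleError("learning_rate must be positive")
        if not (0 <= self.momentum < 1) or self.weight_decay < 0:
            raise RippleError("invalid momentum or weight_decay")


# ---------------------------------------------------------------------------
# Parameters and the numerical core
# ---------------------------------------------------------------------------

_PARAM_NAMES = ("Wc", "bc", "W1", "b1", "W2", "b2")


def init_params(
    arch: CnnArchitecture, seed: int = 0, dtype=np.float32
) -> Dict[str, np.ndarray]:
    """He-uniform weights for the ReLU layers, zero biases, seeded."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))

    def he(shape, fan_in):
        lim = np.sqrt(6.0 / fan_in)
        return rng.uniform(-lim, lim, size=shape).astype(dtype)

    return {
        "Wc": he((arch.conv_filters, arch.conv_kernel), arch.conv_kernel),
        "bc": np.zeros(arch.conv_filters, dtype=dtype),
        "W1": he((arch.fc_hidden, arch.flatten_size), arch.flatten_size),
        "b1": np.zeros(arch.fc_hidden, dtype=dtype),
        "W2": he((arch.n_classes, arch.fc_hidden), arch.fc_hidden),
        "b2": np.zeros(arch.n_classes, dtype=dtype),
    }


def _conv_windows(X: np.ndarray, arch: CnnArchitecture) -> np.ndarray:
    """im2col view: (batch, conv_out_len, conv_kernel)."""
    return sliding_window_view(X, arch.conv_kernel, axis=1)[:, :: arch.conv_stride, :]


def _forward_cache(params, X: np.ndarray, arch: CnnArchitecture) -> Dict[str, np.ndarray]:
    """Full forward pass keeping intermediates for backprop / Grad-CAM."""
    if X.ndim != 2 or X.shape[1] != arch.input_len:
        raise RippleError(
            f"input must be (batch, {arch.input_len}); got {X.shape}"
        )
    win = _conv_windows(X, arch)                       # (B, S, K)
    conv_pre = win @ params["Wc"].T + params["bc"]     # (B, S, F)
    A = np.maximum(conv_pre, 0.0)                      # feature maps
    pw = sliding_window_view(A, arch.pool_size, axis=1)[:, :: arch.pool_stride]
    # pw: (B, P, F, pool_size)
    pool_arg = pw.argmax(axis=-1)                      # (B, P, F)
    pooled = np.take_along_axis(pw, pool_arg[..., None], axis=-1)[..., 0]
    flat = pooled.reshape(X.shape[0], arch.flatten_size)
    h_pre = flat @ params["W1"].T + params["b1"]
    h = np.maximum(h_pre, 0.0)
    logits = h @ params["W2"].T + params["b2"]
    return {
        "win": win, "conv_pre": conv_pre, "A": A, "pool_arg": pool_arg,
        "flat": flat, "h_pre": h_pre, "h": h, "logits": logits,
    }


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, computed in float64 for tight normalization."""
    z = np.asarray(logits, dtype=np.float64)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def forward(params, X: np.ndarray, arch: CnnArchitecture) -> np.ndarray:
    """Class probabilities, shape (batch, n_classes); rows sum to 1."""
    return softmax(_forward_cache(params, X, arch)["logits"])


def _backprop_from_logits(
    params, cache, dlogits: np.ndarray, arch: CnnArchitecture,
    stop_at_feature_maps: bool = False,
):
    """Shared backward pass.

    With ``stop_at_feature_maps`` returns the gradient with respect to the
    (post-ReLU) conv feature maps A — what Grad-CAM needs; otherwise returns
    parameter gradients.
    """
    h, h_pre, flat = cache["h"], cache["h_pre"], cache["flat"]
    dh = dlogits @ params["W2"]
    dh_pre = dh * (h_pre > 0)
    dflat = dh_pre @ params["W1"]
    B = dlogits.shape[0]
    dpooled = dflat.reshape(B, arch.pool_out_len, arch.conv_filters)

    # max-pool backward: route each pooled gradient to its argmax position
    pool_arg = cache["pool_arg"]                       # (B, P, F)
    S = arch.conv_out_len
    b_idx = np.arange(B)[:, None, None]
    f_idx = np.arange(arch.conv_filters)[None, None, :]
    s_idx = np.arange(arch.pool_out_len)[None, :, None] * arch.pool_stride + pool_arg
    lin = (b_idx * S + s_idx) * arch.conv_filters + f_idx
    dA = np.bincount(
        lin.ravel(), weights=dpooled.ravel().astype(np.float64),
        minlength=B * S * arch.conv_filters,
    ).reshape(B, S, arch.conv_filters).astype(dlogits.dtype)

    if stop_at_feature_maps:
        return dA

    dconv_pre = dA * (cache["conv_pre"] > 0)
    win = cache["win"]
    K = arch.conv_kernel
    dWc = (
        dconv_pre.reshape(-1, arch.conv_filters).T @ win.reshape(-1, K)
    )
    return {
        "Wc": dWc,
        "bc": dconv_pre.sum(axis=(0, 1)),
        "W1": dh_pre.T @ flat,
        "b1": dh_pre.sum(axis=0),
        "W2": dlogits.T @ h,
        "b2": dlogits.sum(axis=0),
    }


def cross_entropy(probs: np.ndarray, targets_onehot: np.ndarray) -> float:
    """Mean softmax cross-entropy, natural log: E = -sum_i T_i ln z_i."""
    p = np.asarray(probs, dtype=np.float64)
    T = np.asarray(targets_onehot, dtype=np.float64)
    if p.ndim == 1:
        p, T = p[None, :], T[None, :]
    picked = (p * T).sum(axis=1)
    if np.any(picked < _EPS_LOG):
        logger.warning("cross_entropy: clamping %d vanishing probabilities",
                       int((picked < _EPS_LOG).sum()))
        picked = np.maximum(picked, _EPS_LOG)
    return float(-np.log(picked).mean())


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(labels), n_classes))
    out[np.arange(len(labels)), labels] = 1.0
    return out


def loss_and_grads(params, X, labels, arch: CnnArchitecture):
    """Mean cross-entropy loss and parameter gradients for one mini-batch."""
    cache = _forward_cache(params, X, arch)
    probs = softmax(cache["logits"])
    T = one_hot(labels, arch.n_classes)
    loss = cross_entropy(probs, T)
    dlogits = ((probs - T) / X.shape[0]).astype(X.dtype)
    grads = _backprop_from_logits(params, cache, dlogits, arch)
    return loss, grads


# ---------------------------------------------------------------------------
# Dataset split
# ---------------------------------------------------------------------------

def split_dataset(
    events: Sequence[RippleWaveform],
    test_per_category: int = 10,
    seed: int = 0,
) -> Tuple[List[RippleWaveform], List[RippleWaveform]]:
    """Stratified random split with a fixed number of test events per category."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    by_cat: Dict[str, List[RippleWaveform]] = {}
    for ev in events:
        by_cat.setdefault(ev.category, []).append(ev)
    train: List[RippleWaveform] = []
    test: List[RippleWaveform] = []
    for cat in CATEGORIES:
        if cat not in by_cat:
            continue
        group = by_cat[cat]
        if len(group) <= test_per_category:
            raise RippleError(
                f"category {cat!r} has {len(group)} events; need more than "
                f"test_per_category={test_per_category} to keep a training class"
            )
        perm = rng.permutation(len(group))
        test.extend(group[i] for i in perm[:test_per_category])
        train.extend(group[i] for i in perm[test_per_category:])
    return train, test


# ---------------------------------------------------------------------------
# Evaluation report
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Confusion matrix (rows = true category) and derived metrics."""

    confusion: np.ndarray
    accuracy: float
    micro_precision: float
    micro_recall: float
    balanced_accuracy: float
    micro_f1: float
    auc: Optional[float] = None

    def to_dict(self) -> dict:
        d = {
            "confusion_matrix": self.confusion.astype(int).tolist(),
            "accuracy": self.accuracy,
            "micro_precision": self.micro_precision,
            "micro_recall": self.micro_recall,
            "balanced_accuracy": self.balanced_accuracy,
            "micro_f1": self.micro_f1,
        }
        if self.auc is not None:
            d["auc"] = self.auc
        return d


def metrics_from_confusion(cm: np.ndarray) -> EvaluationReport:
    """Metrics derived purely from an integer confusion matrix.

    For single-label multiclass data micro precision, micro recall and micro
    F1 all reduce to the accuracy (trace over total); balanced accuracy is
    the macro average of per-class recalls.
    """
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise RippleError("confusion matrix must be square")
    if np.any(cm < 0):
        raise RippleError("confusion matrix entries must be non-negative")
    total = cm.sum()
    if total == 0:
        raise RippleError("empty confusion matrix")
    tp = np.diag(cm).astype(float)
    acc = float(tp.sum() / total)
    row = cm.sum(axis=1).astype(float)
    recalls = tp[row > 0] / row[row > 0]
    return EvaluationReport(
        confusion=cm,
        accuracy=acc,
        micro_precision=acc,
        micro_recall=acc,
        balanced_accuracy=float(recalls.mean()),
        micro_f1=acc,
    )


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class RippleEpisodeCNN:
    """Episode classifier built from padded, standardized waveforms.

    Parameters
    ----------
    X : ndarray (n_events, input_len)
        Standardized, zero-padded waveforms.
    y : ndarray (n_events,)
        Integer category labels in annotation order.
    architecture : CnnArchitecture, optional
    init_seed : int
        Seeds the He-uniform weight initialization.
    dtype : numpy dtype
        float32 by default; use float64 for gradient verification.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        architecture: Optional[CnnArchitecture] = None,
        init_seed: int = 0,
        dtype=np.float32,
    ):
        self.arch = architecture or CnnArchitecture()
        self.X = np.ascontiguousarray(np.asarray(X), dtype=dtype)
        self.y = np.asarray(y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[1] != self.arch.input_len:
            raise RippleError(
                f"X must be (n, {self.arch.input_len}); got {self.X.shape}"
            )
        if len(self.y) != len(self.X):
            raise RippleError("X and y lengths differ")
        if self.y.min() < 0 or self.y.max() >= self.arch.n_classes:
            raise RippleError("labels out of range")
        self.init_seed = init_seed
        self.dtype = dtype

    @classmethod
    def from_events(cls, events: Sequence[RippleWaveform], **kw) -> "RippleEpisodeCNN":
        """Build from padded :class:`RippleWaveform` events."""
        from .waveforms import as_matrix, labels_of
        for ev in events:
            if ev.stage != "padded":
                raise RippleError(f"event {ev.id!r} is stage {ev.stage!r}; pad first")
        return cls(as_matrix(events), labels_of(events), **kw)

    def fit(self, config: Optional[TrainingConfig] = None) -> "CNNResults":
        """Train with mini-batch momentum SGD; returns a results object."""
        config = config or TrainingConfig()
        if config.batch_size > len(self.X):
            raise RippleError("batch_size exceeds training-set size")
        params = init_params(self.arch, self.init_seed, self.dtype)
        velocity = {k: np.zeros_like(v) for k, v in params.items()}
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 31]))
        n = len(self.X)
        history = []
        decay_on = ("Wc", "W1", "W2")  # L2 decay on weights, not biases
        for epoch in range(config.epochs):
            order = rng.permutation(n) if config.shuffle_each_epoch else np.arange(n)
            for start in range(0, n, config.batch_size):
                idx = order[start : start + config.batch_size]
                loss, grads = loss_and_grads(params, self.X[idx], self.y[idx], self.arch)
                if not np.isfinite(loss):
                    raise RippleError(
                        f"non-finite loss at epoch {epoch}; diverged "
                        f"(learning_rate={config.learning_rate})"
                    )
                for k in _PARAM_NAMES:
                    g = grads[k].astype(self.dtype)
                    if k in decay_on:
                        g = g + config.weight_decay * params[k]
                    velocity[k] = config.momentum * velocity[k] - config.learning_rate * g
                    params[k] = params[k] + velocity[k]
            ep_probs = self._predict_proba_params(params, self.X)
            ep_loss = cross_entropy(ep_probs, one_hot(self.y, self.arch.n_classes))
            ep_acc = float((ep_probs.argmax(axis=1) == self.y).mean())
            history.append({"epoch": epoch + 1, "accuracy": ep_acc, "loss": ep_loss})
            if (epoch + 1) % 10 == 0 or epoch == 0:
                logger.info("epoch %d: accuracy %.4f loss %.4f", epoch + 1, ep_acc, ep_loss)
        return CNNResults(self, params, pd.DataFrame(history), config)

    def _predict_proba_params(self, params, X, batch: int = 256) -> np.ndarray:
        X = np.ascontiguousarray(np.asarray(X), dtype=self.dtype)
        out = [forward(params, X[i : i + batch], self.arch) for i in range(0, len(X), batch)]
        return np.vstack(out)


class CNNResults:
    """Trained classifier: parameters, history, prediction and evaluation."""

    def __init__(self, model: RippleEpisodeCNN, params, history: pd.DataFrame,
                 config: TrainingConfig):
        self.model = model
        self.params = params
        self.history = history
        self.config = config

    @property
    def arch(self) -> CnnArchitecture:
        return self.model.arch

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.model._predict_proba_params(self.params, X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Argmax class per event; ties resolve to the lowest class index."""
        return self.predict_proba(X).argmax(axis=1)

    def evaluate(self, X: np.ndarray, y: np.ndarray) -> EvaluationReport:
        """Confusion matrix (rows = true), matrix-based metrics, and micro
        one-vs-rest AUC from the softmax scores."""
        if len(X) == 0:
            raise RippleError("empty test set")
        y = np.asarray(y, dtype=int)
        probs = self.predict_proba(X)
        pred = probs.argmax(axis=1)
        cm = _sk_confusion_matrix(y, pred, labels=np.arange(self.arch.n_classes))
        report = metrics_from_confusion(cm)
        try:
            report.auc = float(
                roc_auc_score(one_hot(y, self.arch.n_classes), probs, average="micro")
            )
        except ValueError:  # e.g. a class absent from the test set
            logger.warning("AUC undefined for this test set; leaving it out")
        return report

    def feature_maps_and_grad(self, x: np.ndarray, k: int):
        """Conv feature maps A (S x F) and d logit_k / dA for one input.

        This is the pair of quantities Grad-CAM consumes: the post-ReLU
        feature maps of the conv layer and the gradient of the pre-softmax
        class score with respect to them.
        """
        arch = self.arch
        if not (0 <= k < arch.n_classes):
            raise RippleError(f"class index {k} out of range")
        X = np.ascontiguousarray(np.asarray(x), dtype=self.model.dtype).reshape(1, -1)
        cache = _forward_cache(self.params, X, arch)
        dlogits = np.zeros((1, arch.n_classes), dtype=self.model.dtype)
        dlogits[0, k] = 1.0
        dA = _backprop_from_logits(self.params, cache, dlogits, arch,
                                   stop_at_feature_maps=True)
        return cache["A"][0], dA[0]

    def summary(self) -> str:
        a = self.arch
        last = self.history.iloc[-1]
        lines = [
            "Ripple-firing episode CNN",
            "=" * 42,
            f"input length        {a.input_len}",
            f"conv                {a.conv_filters} filters, kernel {a.conv_kernel}, "
            f"stride {a.conv_stride} -> {a.conv_out_len}",
            f"max-pool            size {a.pool_size}, stride {a.pool_stride} "
            f"-> {a.pool_out_len}",
            f"flatten             {a.flatten_size}",
            f"fully connected     {a.fc_hidden} -> {a.n_classes} (softmax)",
            "-" * 42,
            f"epochs              {int(last['epoch'])}",
            f"batch size          {self.config.batch_size}",
            f"learning rate       {self.config.learning_rate}",
            f"momentum            {self.config.momentum}",
            f"weight decay        {self.config.weight_decay}",
            f"final train accuracy {last['accuracy']:.4f}",
            f"final train loss     {last['loss']:.4f}",
        ]
        return "\n".join(lines)
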