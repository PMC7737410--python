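"""Eight-direction movement classification of the four EMG input types.

A small convolutional network (one 3x3 x 32-filter layer over the
signals x 25-time-point trial image, 2x2 max-pooling, a 64-unit hidden
layer and an 8-way softmax, trained with Adam and early stopping) is
evaluated with stratified fivefold cross-validation on each input type
(EMG-input, IC-input, EMG-synergy, ICA-synergy) in both coordinate
frames. The network is implemented directly in numpy so training is
fully deterministic given a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from synergyemg.preprocess import TrialSet, epoch, relabel_frame

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierConfig",
    "ClassifierReport",
    "SmallCNN",
    "INPUT_TYPES",
    "assemble_inputs",
    "stratified_folds",
    "crossval_cnn",
    "run_comparison",
]

INPUT_TYPES = ("EMG-input", "IC-input", "EMG-synergy", "ICA-synergy")

N_CLASSES = 8


@dataclass(frozen=True)
class ClassifierConfig:
    kernel: int = 3
    n_filters: int = 32
    hidden: int = 64
    folds: int = 5
    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-3
    val_frac: float = 0.1
    patience: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("need at least 2 folds")


@dataclass
class ClassifierReport:
    input_type: str
    frame: str
    fold_accuracies: np.ndarray
    mean_accuracy: float
    confusion: np.ndarray  # 8 x 8 counts, rows = true direction
    n_inputs: int
    extras: dict = field(default_factory=dict)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SmallCNN:
    """Conv(3x3, 32) -> ReLU -> maxpool(2x2) -> dense(64) -> softmax(8).

    Pure-numpy implementation with Adam and early stopping on a held-out
    validation split of the training data; gradients never need to reach
    the input, so the convolution backward pass only computes filter
    gradients.
    """

    def __init__(self, config: ClassifierConfig, seed: int):
        self.cfg = config
        self.rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        self._adam: dict[str, list] = {}

    # -- architecture ---------------------------------------------------
    def _init_params(self, n_ch: int, n_t: int) -> None:
        cfg = self.cfg
        kh, kw = min(cfg.kernel, n_ch), min(cfg.kernel, n_t)
        self.kh, self.kw = kh, kw
        h, w = n_ch - kh + 1, n_t - kw + 1
        self.ph, self.pw = max(h // 2, 1), max(w // 2, 1)
        self.pool_h = 2 if h >= 2 else 1
        self.pool_w = 2 if w >= 2 else 1
        d_flat = self.ph * self.pw * cfg.n_filters
        rng = self.rng
        p = self.params
        p["Wf"] = rng.normal(0, np.sqrt(2.0 / (kh * kw)), (kh, kw, cfg.n_filters))
        p["bf"] = np.zeros(cfg.n_filters)
        p["W1"] = rng.normal(0, np.sqrt(2.0 / d_flat), (d_flat, cfg.hidden))
        p["b1"] = np.zeros(cfg.hidden)
        p["W2"] = rng.normal(0, np.sqrt(2.0 / cfg.hidden), (cfg.hidden, N_CLASSES))
        p["b2"] = np.zeros(N_CLASSES)
        self._adam = {k: [np.zeros_like(v), np.zeros_like(v), 0]
                      for k, v in p.items()}

    def _forward(self, X: np.ndarray, cache: bool = False):
        p = self.params
        win = sliding_window_view(X, (self.kh, self.kw), axis=(1, 2))
        conv = np.tensordot(win, p["Wf"], axes=([3, 4], [0, 1])) + p["bf"]
        relu1 = np.maximum(conv, 0.0)
        n, h, w, f = relu1.shape
        h2, w2 = self.ph * self.pool_h, self.pw * self.pool_w
        blocks = relu1[:, :h2, :w2].reshape(
            n, self.ph, self.pool_h, self.pw, self.pool_w, f)
        pooled = blocks.max(axis=(2, 4))
        flat = pooled.reshape(n, -1)
        z1 = flat @ p["W1"] + p["b1"]
        a1 = np.maximum(z1, 0.0)
        logits = a1 @ p["W2"] + p["b2"]
        if not cache:
            return logits
        return logits, (win, conv, relu1, blocks, pooled, flat, z1, a1)

    def _backward(self, X, y_onehot, logits, cache):
        p = self.params
        win, conv, relu1, blocks, pooled, flat, z1, a1 = cache
        n = X.shape[0]
        probs = _softmax(logits)
        dlogits = (probs - y_onehot) / n
        g = {}
        g["W2"] = a1.T @ dlogits
        g["b2"] = dlogits.sum(axis=0)
        da1 = dlogits @ p["W2"].T
        dz1 = da1 * (z1 > 0)
        g["W1"] = flat.T @ dz1
        g["b1"] = dz1.sum(axis=0)
        dflat = dz1 @ p["W1"].T
        dpooled = dflat.reshape(pooled.shape)
        # route gradient to the max element of each pooling block
        mask = blocks == pooled[:, :, None, :, None, :]
        mask = mask / np.maximum(mask.sum(axis=(2, 4), keepdims=True), 1)
        dblocks = mask * dpooled[:, :, None, :, None, :]
        drelu1 = np.zeros_like(relu1)
        h2, w2 = self.ph * self.pool_h, self.pw * self.pool_w
        drelu1[:, :h2, :w2] = dblocks.reshape(n, h2, w2, -1)
        dconv = drelu1 * (conv > 0)
        g["Wf"] = np.tensordot(win, dconv, axes=([0, 1, 2], [0, 1, 2]))
        g["bf"] = dconv.sum(axis=(0, 1, 2))
        return g

    def _adam_step(self, grads: dict) -> None:
        lr = self.cfg.learning_rate
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, gk in grads.items():
            m, v, t = self._adam[k]
            t += 1
            m[...] = b1 * m + (1 - b1) * gk
            v[...] = b2 * v + (1 - b2) * gk**2
            self._adam[k][2] = t
            mhat = m / (1 - b1**t)
            vhat = v / (1 - b2**t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    def _loss(self, X, y) -> float:
        logits = self._forward(X)
        logp = logits - logits.max(axis=1, keepdims=True)
        logp = logp - np.log(np.exp(logp).sum(axis=1, keepdims=True))
        return float(-logp[np.arange(len(y)), y].mean())

    # -- training -------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "SmallCNN":
        cfg = self.cfg
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        self._init_params(X.shape[1], X.shape[2])
        n = len(y)
        n_val = max(1, int(round(cfg.val_frac * n)))
        perm = self.rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        Xtr, ytr = X[tr_idx], y[tr_idx]
        Xval, yval = X[val_idx], y[val_idx]
        eye = np.eye(N_CLASSES)
        best_loss, best_params, wait = np.inf, None, 0
        for _ in range(cfg.epochs):
            order = self.rng.permutation(len(ytr))
            for b0 in range(0, len(ytr), cfg.batch_size):
                idx = order[b0:b0 + cfg.batch_size]
                logits, cache = self._forward(Xtr[idx], cache=True)
                grads = self._backward(Xtr[idx], eye[ytr[idx]], logits, cache)
                self._adam_step(grads)
            vloss = self._loss(Xval, yval)
            if vloss < best_loss - 1e-5:
                best_loss, wait = vloss, 0
                best_params = {k: v.copy() for k, v in self.params.items()}
            else:
                wait += 1
                if wait > cfg.patience:
                    break
        if best_params is not None:
            self.params = best_params
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self._forward(np.asarray(X, dtype=float)), axis=1)


def assemble_inputs(
    stage_signals: dict,
    input_type: str,
    onsets_s: np.ndarray,
    direction: np.ndarray,
    posture: np.ndarray,
    fs: float = 50.0,
    frame: str = "extrinsic",
    rotation_sign: int = -1,
) -> TrialSet:
    """Epoch one of the four derived signal types into classifier trials.

    ``stage_signals`` maps input type to its signals x samples matrix at
    50 Hz (EMG-input: 95 filtered channels; IC-input: retained ICs;
    EMG-synergy / ICA-synergy: synergy activations T from the
    full-dataset factorization). Raises a KeyError naming the missing
    upstream stage. All trial sets produced from the same onset list
    share identical labels and trial order.
    """
    if input_type not in INPUT_TYPES:
        raise ValueError(f"unknown input type {input_type!r}")
    if input_type not in stage_signals or stage_signals[input_type] is None:
        raise KeyError(
            f"input type {input_type!r} requires an upstream stage that "
            "has not been run")
    ts = epoch(stage_signals[input_type], fs, onsets_s, direction, posture,
               input_type=input_type)
    if frame != "extrinsic":
        ts = relabel_frame(ts, frame, rotation_sign=rotation_sign)
    return ts


def stratified_folds(direction: np.ndarray, posture: np.ndarray,
                     n_folds: int, seed: int) -> list:
    """Fold indices stratified jointly by direction x posture so that
    every input type and both coordinate frames share identical splits."""
    key = np.asarray(direction) * 10 + (np.asarray(posture) != 0)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(key)), key))


def _standardize(train: np.ndarray, test: np.ndarray):
    mu = train.mean(axis=0, keepdims=True)
    sd = train.std(axis=0, keepdims=True)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


def crossval_cnn(
    trialset: TrialSet,
    config: ClassifierConfig | None = None,
    folds: list | None = None,
) -> ClassifierReport:
    """Stratified k-fold evaluation of the CNN on one trial set.

    Features are z-scored using training-fold statistics only. Returns
    per-fold accuracies and the confusion matrix aggregated over the
    held-out folds (every trial is tested exactly once).
    """
    config = ClassifierConfig() if config is None else config
    X = np.asarray(trialset.data, dtype=float)
    y = trialset.direction - 1
    counts = np.bincount(y, minlength=N_CLASSES)
    if counts.min() < config.folds:
        raise ValueError(
            f"class with {counts.min()} trials cannot support "
            f"{config.folds}-fold stratified splits")
    epochs = config.epochs
    if counts.min() < 20 and epochs > 40:
        logger.warning("small-data regime (%d trials in the smallest "
                       "class); capping epochs at 40", counts.min())
        config = ClassifierConfig(**{**config.__dict__, "epochs": 40})
    if folds is None:
        folds = stratified_folds(trialset.direction, trialset.posture,
                                 config.folds, config.seed)
    accs = []
    confusion = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    for k, (tr, te) in enumerate(folds):
        Xtr, Xte = _standardize(X[tr], X[te])
        net = SmallCNN(config, seed=config.seed + 1000 * k)
        net.fit(Xtr, y[tr])
        pred = net.predict(Xte)
        accs.append(float(np.mean(pred == y[te])))
        np.add.at(confusion, (y[te], pred), 1)
    accs = np.asarray(accs)
    return ClassifierReport(
        input_type=trialset.input_type or "unknown",
        frame=trialset.frame,
        fold_accuracies=accs,
        mean_accuracy=float(accs.mean()),
        confusion=confusion,
        n_inputs=X.shape[1],
    )


CONTRASTS = [
    ("EMG-input", "EMG-synergy"),
    ("IC-input", "ICA-synergy"),
    ("EMG-input", "IC-input"),
    ("EMG-synergy", "ICA-synergy"),
]


def run_comparison(
    trialsets: dict,
    config: ClassifierConfig | None = None,
) -> tuple[dict, pd.DataFrame, pd.DataFrame]:
    """Evaluate all (input type, frame) combinations on shared folds.

    ``trialsets`` maps (input_type, frame) -> TrialSet; all trial sets
    must contain the same trials in the same order. Returns the report
    per combination, a summary table, and the standard pairwise
    contrasts (Welch t-tests over intrinsic-frame fold accuracies).
    """
    config = ClassifierConfig() if config is None else config
    first = next(iter(trialsets.values()))
    folds = stratified_folds(first.direction, first.posture, config.folds,
                             config.seed)
    reports = {}
    rows = []
    for (input_type, frame), ts in trialsets.items():
        rep = crossval_cnn(ts, config, folds=folds)
        rep.input_type, rep.frame = input_type, frame
        reports[(input_type, frame)] = rep
        rows.append({
            "input_type": input_type, "frame": frame,
            "n_inputs": rep.n_inputs,
            "mean_accuracy": rep.mean_accuracy,
            "sd_accuracy": float(rep.fold_accuracies.std(ddof=1)),
        })
    summary = pd.DataFrame(rows)
    tests = []
    for a, b in CONTRASTS:
        ka, kb = (a, "intrinsic"), (b, "intrinsic")
        if ka in reports and kb in reports:
            t, p = stats.ttest_ind(reports[ka].fold_accuracies,
                                   reports[kb].fold_accuracies,
                                   equal_var=False)
            tests.append({"contrast": f"{a} vs {b}", "t": float(t),
                          "p": float(p)})
    return reports, summary, pd.DataFrame(tests)
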