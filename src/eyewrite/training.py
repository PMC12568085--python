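"""Training loop and leave-one-subject-out evaluation harness.

The classifier is trained by minimising multi-class cross-entropy with
Adam (AMSGrad variant, L2 weight decay 0.1) under a cosine-annealing
warm-restart learning-rate schedule (max 1e-3, restart period 16 epochs).
Evaluation is leave-one-subject-out: each fold augments the training
subjects' raw trajectories, preprocesses everything, trains from scratch,
and scores the held-out subject with the final-epoch weights.  No inner
validation split is used — the held-out subject leaves no principled way
to build one.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict
from typing import Callable, Literal, Optional, Sequence

import numpy as np

from .augmentation import (DEFAULT_WARP, DISTORTION_I, DISTORTION_II,
                           DistortionConfig, WarpConfig, augment_training_set)
from .core import DatasetBundle, Sample, SubjectSplit, loso_splits
from .filtering import FilterConfig
from .metrics import compute_metrics, wilcoxon_signed_rank
from .nn import CnnTcnNet, ModelConfig, Param
from .normalization import NormalizationConfig, preprocess

__all__ = [
    "TrainConfig",
    "AugmentationConfig",
    "FoldResult",
    "LosoReport",
    "cross_entropy",
    "softmax",
    "cosine_lr",
    "AdamAMSGrad",
    "train_fold",
    "run_loso",
    "wilcoxon_signed_rank",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters (defaults: the reference recipe)."""

    epochs: int = 400
    batch_size: int = 512
    weight_decay: float = 0.1
    amsgrad: bool = True
    lr_max: float = 1e-3
    lr_min: float = 0.0
    cosine_period: int = 16
    schedule_unit: Literal["epoch", "step"] = "epoch"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.cosine_period < 1:
            raise ValueError("epochs, batch_size and cosine_period must be >= 1")
        if not (self.lr_min == 0 or 0 < self.lr_min <= self.lr_max):
            raise ValueError("need 0 < lr_min <= lr_max, or lr_min = 0")


@dataclass(frozen=True)
class AugmentationConfig:
    """The three training-set augmentations; ``enabled=False`` skips all."""

    enabled: bool = True
    distortion1: DistortionConfig = field(default_factory=lambda: DISTORTION_I)
    distortion2: DistortionConfig = field(default_factory=lambda: DISTORTION_II)
    warp: WarpConfig = field(default_factory=lambda: DEFAULT_WARP)
    seed: int = 0


@dataclass
class FoldResult:
    """Per-subject scores of one leave-one-subject-out fold."""

    test_subject: str
    loss: float
    accuracy: float
    precision: float
    recall: float
    f1: float

    def __post_init__(self) -> None:
        for name in ("accuracy", "precision", "recall", "f1"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be a percentage, got {v}")
        if self.loss < 0:
            raise ValueError("loss must be >= 0")


@dataclass
class LosoReport:
    """All fold results plus their mean/std aggregate."""

    folds: list[FoldResult]
    config_fingerprint: str = ""

    _METRICS = ("loss", "accuracy", "precision", "recall", "f1")

    def mean(self, metric: str) -> float:
        return float(np.mean([getattr(f, metric) for f in self.folds]))

    def std(self, metric: str) -> float:
        # population std, matching per-subject result tables
        return float(np.std([getattr(f, metric) for f in self.folds]))

    def to_dict(self) -> dict:
        return {
            "folds": [asdict(f) for f in self.folds],
            "mean": {m: self.mean(m) for m in self._METRICS},
            "std": {m: self.std(m) for m in self._METRICS},
            "config_fingerprint": self.config_fingerprint,
        }

    def summary(self) -> str:
        """A per-subject results table with mean/std rows."""
        header = (f"{'Subject':<14}{'Loss':>8}{'Acc (%)':>10}"
                  f"{'Prec (%)':>10}{'Rec (%)':>10}{'F1 (%)':>10}")
        lines = [header, "-" * len(header)]
        for f in self.folds:
            lines.append(f"{f.test_subject:<14}{f.loss:>8.4f}{f.accuracy:>10.2f}"
                         f"{f.precision:>10.2f}{f.recall:>10.2f}{f.f1:>10.2f}")
        lines.append("-" * len(header))
        lines.append(f"{'Average':<14}{self.mean('loss'):>8.4f}"
                     f"{self.mean('accuracy'):>10.2f}{self.mean('precision'):>10.2f}"
                     f"{self.mean('recall'):>10.2f}{self.mean('f1'):>10.2f}")
        lines.append(f"{'Std. Dev.':<14}{self.std('loss'):>8.4f}"
                     f"{self.std('accuracy'):>10.2f}{self.std('precision'):>10.2f}"
                     f"{self.std('recall'):>10.2f}{self.std('f1'):>10.2f}")
        return "\n".join(lines)


# -- loss and schedule ------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probabilities: np.ndarray, labels_onehot: np.ndarray) -> float:
    """Mean multi-class cross-entropy of predicted probabilities.

    ``probabilities`` rows must sum to 1 (within 1e-6); values are clipped
    below at 1e-12 before the log.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels_onehot, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {y.shape}")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    return float(-(y * np.log(np.clip(p, 1e-12, None))).sum() / p.shape[0])


def cosine_lr(iteration: int, cfg: TrainConfig) -> float:
    """Cosine-annealing warm-restart schedule.

    lr(t) = lr_min + (lr_max - lr_min)/2 * (1 + cos(pi * (t mod P) / P))
    restarts to lr_max every P iterations.
    """
    if iteration < 0:
        raise ValueError("iteration must be >= 0")
    P = cfg.cosine_period
    phase = (iteration % P) / P
    return cfg.lr_min + 0.5 * (cfg.lr_max - cfg.lr_min) * (1 + np.cos(np.pi * phase))


class AdamAMSGrad:
    """Adam with optional AMSGrad max-of-second-moment and L2 weight decay.

    Weight decay is added to the gradient before the moment updates (the
    classical L2 formulation, not decoupled decay).
    """

    def __init__(self, params: Sequence[Param], weight_decay: float = 0.0,
                 amsgrad: bool = True, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.weight_decay = weight_decay
        self.amsgrad = amsgrad
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.vmax = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1 - b1 ** self.t
        c2 = 1 - b2 ** self.t
        for i, p in enumerate(self.params):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            vhat = self.v[i] / c2
            if self.amsgrad:
                np.maximum(self.vmax[i], vhat, out=self.vmax[i])
                vhat = self.vmax[i]
            p.data -= lr * (self.m[i] / c1) / (np.sqrt(vhat) + self.eps)


# -- fold training ----------------------------------------------------------

def _encode(samples: Sequence[Sample], class_set: Sequence[str]
            ) -> tuple[np.ndarray, np.ndarray]:
    index = {c: i for i, c in enumerate(class_set)}
    X = np.stack([s.trajectory.points for s in samples])  # (B, L, 2)
    y = np.array([index[s.label] for s in samples], dtype=int)
    return X, y


def train_fold(split: SubjectSplit, class_set: Sequence[str],
               model_cfg: ModelConfig, train_cfg: TrainConfig,
               filter_cfg: Optional[FilterConfig] = None,
               norm_cfg: Optional[NormalizationConfig] = None,
               aug_cfg: Optional[AugmentationConfig] = None,
               log: Optional[Callable[[dict], None]] = None) -> FoldResult:
    """Train on all subjects but one, score the held-out subject.

    Pipeline per fold: augment the raw training samples (when enabled),
    preprocess augmented + original training data and the raw test data,
    train the model from scratch, evaluate the final-epoch weights.
    """
    if not split.train or not split.test:
        raise ValueError("both folds must be non-empty")
    filter_cfg = filter_cfg or FilterConfig.disabled()
    norm_cfg = norm_cfg or NormalizationConfig()
    aug_cfg = aug_cfg or AugmentationConfig()

    train_samples = list(split.train)
    if aug_cfg.enabled:
        train_samples = augment_training_set(
            train_samples, aug_cfg.distortion1, aug_cfg.distortion2,
            aug_cfg.warp, seed=aug_cfg.seed)
    train_samples = [preprocess(s, filter_cfg, norm_cfg) for s in train_samples]
    test_samples = [preprocess(s, filter_cfg, norm_cfg) for s in split.test]

    X_train, y_train = _encode(train_samples, class_set)
    X_test, y_test = _encode(test_samples, class_set)
    n_classes = len(class_set)

    # single precision halves step time with no effect on results
    model = CnnTcnNet(model_cfg).astype(np.float32)
    X_train = X_train.astype(np.float32)
    X_test = X_test.astype(np.float32)
    opt = AdamAMSGrad(model.parameters(), weight_decay=train_cfg.weight_decay,
                      amsgrad=train_cfg.amsgrad)
    rng = np.random.default_rng(train_cfg.seed)
    n = X_train.shape[0]
    eye = np.eye(n_classes)

    step = 0
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, train_cfg.batch_size):
            idx = order[start:start + train_cfg.batch_size]
            t = epoch if train_cfg.schedule_unit == "epoch" else step
            lr = cosine_lr(t, train_cfg)
            logits = model.forward(X_train[idx], training=True)
            probs = softmax(logits)
            onehot = eye[y_train[idx]]
            loss = cross_entropy(probs, onehot)
            model.zero_grad()
            model.backward((probs - onehot) / idx.size)
            opt.step(lr)
            epoch_loss += loss * idx.size
            step += 1
        if log is not None:
            log({"subject": split.test_subject, "epoch": epoch,
                 "lr": lr, "train_loss": epoch_loss / n})

    logits = model.forward(X_test, training=False)
    probs = softmax(logits)
    loss = cross_entropy(probs, np.eye(n_classes)[y_test])
    preds = [class_set[i] for i in probs.argmax(axis=1)]
    truths = [class_set[i] for i in y_test]
    acc, prec, rec, f1 = compute_metrics(preds, truths, class_set)
    return FoldResult(test_subject=split.test_subject, loss=loss,
                      accuracy=acc, precision=prec, recall=rec, f1=f1)


def run_loso(bundle: DatasetBundle, model_cfg: ModelConfig,
             train_cfg: TrainConfig,
             filter_cfg: Optional[FilterConfig] = None,
             norm_cfg: Optional[NormalizationConfig] = None,
             aug_cfg: Optional[AugmentationConfig] = None,
             log: Optional[Callable[[dict], None]] = None,
             verbose: bool = False) -> LosoReport:
    """Full leave-one-subject-out evaluation of a bundle."""
    folds = []
    for split in loso_splits(bundle):
        t0 = time.time()
        fold = train_fold(split, bundle.class_set, model_cfg, train_cfg,
                          filter_cfg, norm_cfg, aug_cfg, log=log)
        folds.append(fold)
        if verbose:
            print(f"[{bundle.name}] subject {split.test_subject}: "
                  f"acc {fold.accuracy:.2f}%  loss {fold.loss:.4f}  "
                  f"({time.time() - t0:.1f} s)")
    fingerprint = (f"model={model_cfg.fusion},L={model_cfg.input_length};"
                   f"epochs={train_cfg.epochs},batch={train_cfg.batch_size},"
                   f"seed={train_cfg.seed}")
    return LosoReport(folds=folds, config_fingerprint=fingerprint)
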