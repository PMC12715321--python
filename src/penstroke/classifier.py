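"""Patient-disjoint cross-validated classification of handwriting rows.

Row instances are scored by a small convolutional network (one convolutional
layer, average pooling, and a dense softmax head) trained from scratch with
minibatch SGD — deliberately desk-scale so the full 5-fold protocol runs on a
single CPU in minutes.  An optional ``pretrained_plugin`` backbone accepts any
user-supplied feature-extraction callable and trains only a logistic head on
top of the frozen features.

Cross-validation is *patient-disjoint*: folds partition subjects (stratified
by class), every instance of a subject lives in its subject's fold, and each
instance is scored exactly once, by the model whose validation fold holds its
subject.  The per-patient likelihood-ratio score (LR, in [0, 1]) is the mean
of the subject's out-of-fold instance probabilities; values near 1 indicate
handwriting the model reads as impaired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DatasetError
from .preprocess import InstanceDataset, RowInstance


@dataclass(frozen=True)
class ClassifierConfig:
    """Hyperparameters of the row-instance scorer and the CV protocol."""

    backbone: str = "small_conv"  # small_conv | pretrained_plugin
    input_size: tuple[int, int] = (32, 96)
    n_filters: int = 8
    kernel: int = 5
    pool: int = 4
    head_width: int = 16
    learning_rate: float = 0.1
    epochs: int = 8
    batch_size: int = 32
    folds: int = 5
    seed: int = 0
    class_weighting: bool = True
    feature_fn: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self):
        if self.folds < 2:
            raise ConfigurationError("folds must be >= 2")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.backbone not in ("small_conv", "pretrained_plugin"):
            raise ConfigurationError(f"unknown backbone {self.backbone!r}")
        if self.backbone == "pretrained_plugin" and self.feature_fn is None:
            raise ConfigurationError("pretrained_plugin requires feature_fn")


@dataclass(frozen=True)
class PatientScore:
    """Per-patient likelihood-ratio score from out-of-fold probabilities."""

    subject_id: str
    lr: float
    n_instances: int


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, H, W) -> (B, H', W', k*k) patch matrix for a valid convolution."""
    b, h, w = x.shape
    s0, s1, s2 = x.strides
    shape = (b, h - k + 1, w - k + 1, k, k)
    strides = (s0, s1, s2, s1, s2)
    cols = np.lib.stride_tricks.as_strided(x, shape, strides)
    return cols.reshape(b, shape[1], shape[2], k * k)


class SmallConvNet:
    """Two-class scorer: conv → ReLU → average pool → dense → ReLU → softmax.

    Pure-numpy implementation trained end-to-end with minibatch SGD and
    cross-entropy loss; weight init, batch order, and therefore predictions
    are fully determined by the seed.
    """

    def __init__(self, config: ClassifierConfig):
        self.cfg = config
        h, w = config.input_size
        k, f, p = config.kernel, config.n_filters, config.pool
        self.ph = (h - k + 1) // p
        self.pw = (w - k + 1) // p
        if self.ph < 1 or self.pw < 1:
            raise ConfigurationError("input_size too small for kernel/pool")
        rng = np.random.default_rng(config.seed)
        self.K = rng.normal(0, 1.0 / k, size=(f, k * k))
        self.bK = np.zeros(f)
        d = self.ph * self.pw * f
        self.W1 = rng.normal(0, np.sqrt(2.0 / d), size=(d, config.head_width))
        self.b1 = np.zeros(config.head_width)
        self.W2 = rng.normal(0, np.sqrt(2.0 / config.head_width),
                             size=(config.head_width, 2))
        self.b2 = np.zeros(2)
        self._rng = rng
        self.history: list[dict[str, float]] = []

    # -- forward -----------------------------------------------------------
    def _forward(self, x: np.ndarray, keep: bool = False):
        p = self.cfg.pool
        cols = _im2col(x, self.cfg.kernel)  # (B, H', W', kk)
        z1 = cols @ self.K.T + self.bK  # (B, H', W', F)
        a1 = np.maximum(z1, 0.0)
        b, hh, ww, f = a1.shape
        hc, wc = self.ph * p, self.pw * p
        pooled = a1[:, :hc, :wc].reshape(b, self.ph, p, self.pw, p, f).mean(axis=(2, 4))
        flat = pooled.reshape(b, -1)
        z2 = flat @ self.W1 + self.b1
        a2 = np.maximum(z2, 0.0)
        logits = a2 @ self.W2 + self.b2
        if keep:
            return logits, (cols, z1, flat, z2, a2)
        return logits

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities, rows summing to 1; batch-order invariant."""
        x = self._check_input(x)
        return _softmax(self._forward(x))

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1:] != self.cfg.input_size:
            raise ValueError(
                f"instances of shape {x.shape[1:]} do not match "
                f"input_size {self.cfg.input_size}"
            )
        # ink-dark [0,1] rasters become ink-high signal on zero background
        return 1.0 - x

    # -- training ----------------------------------------------------------
    def fit(self, x: np.ndarray, y: np.ndarray,
            sample_weight: np.ndarray | None = None) -> "SmallConvNet":
        x = self._check_input(x)
        y = np.asarray(y, dtype=int)
        n = len(y)
        w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)
        w = w / w.mean()
        lr, p = self.cfg.learning_rate, self.cfg.pool
        for epoch in range(self.cfg.epochs):
            order = self._rng.permutation(n)
            losses = []
            for start in range(0, n, self.cfg.batch_size):
                idx = order[start : start + self.cfg.batch_size]
                xb, yb, wb = x[idx], y[idx], w[idx]
                logits, (cols, z1, flat, z2, a2) = self._forward(xb, keep=True)
                prob = _softmax(logits)
                losses.append(
                    float(np.average(-np.log(prob[np.arange(len(yb)), yb] + 1e-12),
                                     weights=wb))
                )
                # backprop
                dlogits = prob.copy()
                dlogits[np.arange(len(yb)), yb] -= 1.0
                dlogits *= (wb / wb.sum())[:, None]
                dW2 = a2.T @ dlogits
                db2 = dlogits.sum(axis=0)
                da2 = dlogits @ self.W2.T
                dz2 = da2 * (z2 > 0)
                dW1 = flat.T @ dz2
                db1 = dz2.sum(axis=0)
                dflat = dz2 @ self.W1.T
                b = len(yb)
                dpool = dflat.reshape(b, self.ph, self.pw, self.cfg.n_filters)
                da1 = np.zeros_like(z1)
                hc, wc = self.ph * p, self.pw * p
                da1[:, :hc, :wc] = np.repeat(
                    np.repeat(dpool, p, axis=1), p, axis=2
                ) / (p * p)
                dz1 = da1 * (z1 > 0)
                dK = np.einsum("bxyk,bxyf->fk", cols, dz1)
                dbK = dz1.sum(axis=(0, 1, 2))
                self.W2 -= lr * dW2
                self.b2 -= lr * db2
                self.W1 -= lr * dW1
                self.b1 -= lr * db1
                self.K -= lr * dK
                self.bK -= lr * dbK
            logits = self._forward(x)
            acc = float((logits.argmax(axis=1) == y).mean())
            self.history.append(
                {"epoch": epoch, "train_loss": float(np.mean(losses)), "train_acc": acc}
            )
        return self


class _FrozenBackboneModel:
    """Logistic head over a frozen user-supplied feature extractor."""

    def __init__(self, config: ClassifierConfig):
        self.cfg = config
        self._rng = np.random.default_rng(config.seed)
        self.w: np.ndarray | None = None
        self.b = 0.0
        self._mu: np.ndarray | None = None
        self._sd: np.ndarray | None = None
        self.history: list[dict[str, float]] = []

    def _features(self, x: np.ndarray) -> np.ndarray:
        feats = np.asarray(self.cfg.feature_fn(np.asarray(x, dtype=float)), float)
        if feats.ndim != 2:
            raise ValueError("feature_fn must return a (n, d) array")
        return feats

    def fit(self, x, y, sample_weight=None):
        f = self._features(x)
        y = np.asarray(y, int)
        w = np.ones(len(y)) if sample_weight is None else np.asarray(sample_weight, float)
        w = w / w.mean()
        self._mu = f.mean(axis=0)
        self._sd = f.std(axis=0) + 1e-12
        f = (f - self._mu) / self._sd
        self.w = np.zeros(f.shape[1])
        n = len(y)
        for epoch in range(self.cfg.epochs):
            order = self._rng.permutation(n)
            losses = []
            for start in range(0, n, self.cfg.batch_size):
                idx = order[start : start + self.cfg.batch_size]
                z = f[idx] @ self.w + self.b
                prob = 1.0 / (1.0 + np.exp(-z))
                err = (prob - y[idx]) * w[idx]
                losses.append(float(np.average(
                    -(y[idx] * np.log(prob + 1e-12)
                      + (1 - y[idx]) * np.log(1 - prob + 1e-12)),
                    weights=w[idx])))
                self.w -= self.cfg.learning_rate * f[idx].T @ err / len(idx)
                self.b -= self.cfg.learning_rate * err.mean()
            self.history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                                 "train_acc": float("nan")})
        return self

    def predict_proba(self, x) -> np.ndarray:
        f = (self._features(x) - self._mu) / self._sd
        p1 = 1.0 / (1.0 + np.exp(-(f @ self.w + self.b)))
        return np.column_stack([1 - p1, p1])


def _stack(instances: Sequence[RowInstance]) -> np.ndarray:
    return np.stack([inst.raster for inst in instances])


def assign_folds(
    dataset: InstanceDataset | Mapping[str, int],
    folds: int,
    seed: int,
) -> dict[str, int]:
    """Stratified, patient-disjoint fold assignment: subject → fold index.

    Subjects of each class are shuffled (seeded) and dealt round-robin, so per
    class the fold sizes differ by at most one subject.  Raises when a class
    has fewer subjects than folds.
    """
    mapping = dataset.subject_to_class if isinstance(dataset, InstanceDataset) else dict(dataset)
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    for cls in sorted(set(mapping.values())):
        subjects = sorted(s for s, c in mapping.items() if c == cls)
        if len(subjects) < folds:
            raise DatasetError(
                f"class {cls} has {len(subjects)} subjects, fewer than {folds} folds"
            )
        order = rng.permutation(len(subjects))
        start = int(rng.integers(folds))  # rotate so remainders spread across folds
        for i, j in enumerate(order):
            assignment[subjects[j]] = (start + i) % folds
    return assignment


def train_fold(
    instances: Sequence[RowInstance],
    labels: Sequence[int],
    config: ClassifierConfig,
    seed: int | None = None,
):
    """Train one scorer on the training instances of one fold."""
    y = np.asarray(labels, int)
    if len(np.unique(y)) < 2:
        raise DatasetError("training set must contain both classes")
    cfg = config if seed is None else _with_seed(config, seed)
    model = (SmallConvNet(cfg) if cfg.backbone == "small_conv"
             else _FrozenBackboneModel(cfg))
    weight = None
    if cfg.class_weighting:
        freq = np.bincount(y, minlength=2) / len(y)
        weight = 1.0 / freq[y]
    model.fit(_stack(instances), y, sample_weight=weight)
    return model


def _with_seed(config: ClassifierConfig, seed: int) -> ClassifierConfig:
    from dataclasses import replace

    return replace(config, seed=seed)


def predict(model, instances: Sequence[RowInstance]) -> np.ndarray:
    """Per-instance probability of class 1."""
    return model.predict_proba(_stack(instances))[:, 1]


@dataclass
class CVResult:
    """Outputs of one patient-disjoint cross-validation run."""

    oof_probabilities: np.ndarray  # aligned with dataset.instances
    patient_scores: list[PatientScore]
    fold_assignment: dict[str, int]
    fold_metrics: pd.DataFrame  # fold, epoch, train_loss, train_acc, val_acc

    def scores_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"subject_id": s.subject_id, "lr": s.lr, "n_instances": s.n_instances}
             for s in self.patient_scores]
        )


def cross_validate(dataset: InstanceDataset, config: ClassifierConfig) -> CVResult:
    """Patient-disjoint k-fold CV with per-patient LR aggregation.

    Each instance is scored once, by the model whose validation fold contains
    its subject; a patient's LR is the mean of those out-of-fold instance
    probabilities (never probabilities from models trained on the patient's
    own rows).
    """
    assignment = assign_folds(dataset, config.folds, config.seed)
    subj = np.array([inst.subject_id for inst in dataset.instances])
    inst_fold = np.array([assignment[s] for s in subj])
    oof = np.full(len(dataset.instances), np.nan)
    fold_rows = []
    for fold in range(config.folds):
        train_idx = np.nonzero(inst_fold != fold)[0]
        val_idx = np.nonzero(inst_fold == fold)[0]
        if len(val_idx) == 0:
            continue
        model = train_fold(
            [dataset.instances[i] for i in train_idx],
            dataset.labels[train_idx],
            config,
            seed=config.seed + fold,
        )
        probs = predict(model, [dataset.instances[i] for i in val_idx])
        oof[val_idx] = probs
        val_acc = float(((probs >= 0.5).astype(int) == dataset.labels[val_idx]).mean())
        for rec in getattr(model, "history", []):
            fold_rows.append({"fold": fold, **rec, "val_acc": val_acc})
    assert not np.isnan(oof).any(), "every instance must be scored exactly once"

    patient_scores = []
    for subject in sorted(assignment):
        idx = np.nonzero(subj == subject)[0]
        if len(idx) == 0:
            continue
        patient_scores.append(
            PatientScore(subject, float(oof[idx].mean()), int(len(idx)))
        )
    return CVResult(
        oof_probabilities=oof,
        patient_scores=patient_scores,
        fold_assignment=assignment,
        fold_metrics=pd.DataFrame(fold_rows),
    )
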