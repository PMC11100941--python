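"""Clinical labels and latent-space prediction heads.

Label schema follows standard knee-osteoarthritis scoring: Kellgren-Lawrence
(KL, ordinal 0-4; diagnosis = KL >= 2) and region-wise MOAKS features
(osteophytes 0-3 binned to 0-2, cartilage thinning binarized at the >10%
level, cartilage holes binarized at any-hole).  Predictors operate on shape
latents: a grid-searched MLP (binary cross-entropy for binary tasks, a
consistent-rank-logits ordinal head for graded tasks) and logistic
regression; interpretability comes from linear latent interpolation and
traversal along a logistic classifier's coefficient vector.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    cohen_kappa_score,
    f1_score,
    roc_auc_score,
)

from . import nn
from .nn import Tensor

MOAKS_REGIONS = (
    "medial-anterior",
    "lateral-anterior",
    "medial-central",
    "lateral-central",
    "medial-posterior",
    "lateral-posterior",
)


@dataclass
class ClinicalLabelRecord:
    shape_id: str
    kl: int  # 0..4
    osteophyte_raw: dict = field(default_factory=dict)  # region -> 0..3
    thinning_raw: dict = field(default_factory=dict)  # region -> 0..3
    hole_raw: dict = field(default_factory=dict)  # region -> 0..3
    future_oa: int | None = None
    future_kr: int | None = None
    # derived
    oa: int = 0
    osteophyte_binned: dict = field(default_factory=dict)  # region -> 0..2
    thinning_binary: dict = field(default_factory=dict)
    hole_binary: dict = field(default_factory=dict)


def bin_labels(record: ClinicalLabelRecord) -> ClinicalLabelRecord:
    """Derive the analysis labels from raw grades.

    OA = 1 iff KL >= 2; osteophyte grades 2/3 collapse to binned level 2;
    thinning is binary with grades {2, 3} (> 10% of the region) positive;
    hole is binary with any grade >= 1 positive.
    """
    if record.kl not in range(5):
        raise ValueError(f"KL grade {record.kl} outside 0..4")
    for name, d in (
        ("osteophyte", record.osteophyte_raw),
        ("thinning", record.thinning_raw),
        ("hole", record.hole_raw),
    ):
        for region, g in d.items():
            if g not in range(4):
                raise ValueError(f"{name} grade {g} in region {region} outside 0..3")
    record.oa = int(record.kl >= 2)
    record.osteophyte_binned = {r: min(g, 2) for r, g in record.osteophyte_raw.items()}
    record.thinning_binary = {r: int(g >= 2) for r, g in record.thinning_raw.items()}
    record.hole_binary = {r: int(g >= 1) for r, g in record.hole_raw.items()}
    return record


# -- CORAL ordinal head ------------------------------------------------------
def coral_loss(logits: np.ndarray | Tensor, grade: int, n_classes: int):
    """Consistent-rank-logits loss for one sample.

    `logits` are the K-1 ordered-threshold scores (shared weights, ordered
    biases); the loss is the sum of binary cross-entropies of
    sigmoid(logit_k) against the cumulative targets 1[grade > k].
    """
    if grade not in range(n_classes):
        raise ValueError(f"grade {grade} outside 0..{n_classes - 1}")
    targets = (grade > np.arange(n_classes - 1)).astype(np.float64)
    if isinstance(logits, Tensor):
        p = nn.sigmoid(logits)
        t = Tensor(targets)
        eps = 1e-7
        return -(t * _log(p, eps) + (1.0 - t) * _log(1.0 - p, eps)).sum()
    p = 1.0 / (1.0 + np.exp(-np.asarray(logits, dtype=np.float64)))
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-(targets * np.log(p) + (1 - targets) * np.log(1 - p)).sum())


def _log(x: Tensor, eps: float) -> Tensor:
    out = Tensor(np.log(np.maximum(x.data, eps)), x.requires_grad, (x,))

    def _bw(g):
        if x.requires_grad:
            x._accum(g / np.maximum(x.data, eps))

    out._backward = _bw
    return out


def coral_predict(logits: np.ndarray) -> np.ndarray:
    """Predicted grade = number of thresholds whose sigmoid exceeds 0.5."""
    logits = np.atleast_2d(np.asarray(logits, dtype=np.float64))
    return (1.0 / (1.0 + np.exp(-logits)) > 0.5).sum(axis=1)


# -- MLP head with optional CORAL output -------------------------------------
@dataclass
class MLPHeadConfig:
    depth: int = 2
    width: int = 64
    dropout: float = 0.2
    lr: float = 1e-3
    batch: int = 64
    epochs: int = 200
    task: str = "binary"  # "binary" | "ordinal"
    n_classes: int = 2
    seed: int = 0


class MLPHead:
    """Small MLP on latent codes; BCE for binary, CORAL for ordinal tasks."""

    def __init__(self, cfg: MLPHeadConfig, n_features: int):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        dims = [n_features] + [cfg.width] * cfg.depth
        self.params: dict[str, Tensor] = {}
        for j, (a, b) in enumerate(zip(dims[:-1], dims[1:])):
            self.params[f"w{j}"] = Tensor(nn.he_init(rng, a, (a, b)), True)
            self.params[f"b{j}"] = Tensor(np.zeros(b), True)
        n_out = 1 if cfg.task == "binary" else 1  # shared weight vector for CORAL
        self.params["head_w"] = Tensor(nn.glorot_init(rng, cfg.width, n_out, (cfg.width, n_out)), True)
        self.params["head_b"] = Tensor(
            np.zeros(1 if cfg.task == "binary" else cfg.n_classes - 1), True
        )
        self._rng = rng

    def _scores(self, x: np.ndarray, train: bool = False) -> Tensor:
        h = Tensor(np.asarray(x, dtype=np.float32))
        for j in range(self.cfg.depth):
            h = nn.relu(h @ self.params[f"w{j}"] + self.params[f"b{j}"])
            if train and self.cfg.dropout > 0:
                h = nn.dropout(h, self.cfg.dropout, self._rng)
        base = h @ self.params["head_w"]  # (N, 1)
        if self.cfg.task == "binary":
            return base + self.params["head_b"]
        ones = Tensor(np.ones((1, self.cfg.n_classes - 1), dtype=np.float32))
        return base @ ones + self.params["head_b"]  # (N, K-1) shared-weight logits

    def fit(self, x: np.ndarray, y: np.ndarray) -> "MLPHead":
        cfg = self.cfg
        opt = nn.AdamW([{"params": list(self.params.values()), "lr": cfg.lr, "weight_decay": 0.0}])
        n = len(x)
        for _ in range(cfg.epochs):
            order = self._rng.permutation(n)
            for lo in range(0, n, cfg.batch):
                idx = order[lo : lo + cfg.batch]
                scores = self._scores(x[idx], train=True)
                if cfg.task == "binary":
                    t = Tensor(y[idx].astype(np.float32).reshape(-1, 1))
                    p = nn.sigmoid(scores)
                    loss = -(t * _log(p, 1e-7) + (1.0 - t) * _log(1.0 - p, 1e-7)).mean()
                else:
                    cum = (y[idx][:, None] > np.arange(cfg.n_classes - 1)[None, :]).astype(np.float32)
                    t = Tensor(cum)
                    p = nn.sigmoid(scores)
                    loss = -(t * _log(p, 1e-7) + (1.0 - t) * _log(1.0 - p, 1e-7)).mean()
                opt.zero_grad()
                loss.backward()
                opt.step()
        return self

    def predict_scores(self, x: np.ndarray) -> np.ndarray:
        return self._scores(x, train=False).data

    def predict(self, x: np.ndarray) -> np.ndarray:
        s = self.predict_scores(x)
        if self.cfg.task == "binary":
            return (s[:, 0] > 0).astype(int)
        return coral_predict(s)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        s = self.predict_scores(x)
        return 1.0 / (1.0 + np.exp(-s[:, 0] if self.cfg.task == "binary" else -s))


# -- grid search ---------------------------------------------------------------
@dataclass
class ClassifierSpec:
    head: str = "mlp"  # "mlp" | "logistic"
    task: str = "binary"  # "binary" | "ordinal"
    n_classes: int = 2
    selection_metric: str = "auto"  # kappa (ordinal) | auroc | auprc
    depths: tuple = (2, 3)
    widths: tuple = (64, 128, 256)
    dropouts: tuple = (0.2, 0.4)
    lrs: tuple = (1e-3, 1e-4, 1e-5)
    batches: tuple = (64, 128, 256, 512)
    epochs: int = 200

    def metric_name(self) -> str:
        if self.selection_metric != "auto":
            return self.selection_metric
        return "kappa" if self.task == "ordinal" else "auroc"


@dataclass
class FittedClassifier:
    model: object
    config: dict
    validation_score: float
    report: dict


def _score(metric: str, y_true, y_pred, y_prob) -> float:
    if metric == "kappa":
        return cohen_kappa_score(y_true, y_pred, weights="quadratic")
    if metric == "auroc":
        return roc_auc_score(y_true, y_prob)
    if metric == "auprc":
        return average_precision_score(y_true, y_prob)
    raise ValueError(f"unknown metric {metric!r}")


def train_classifier(
    latents: np.ndarray,
    labels: np.ndarray,
    spec: ClassifierSpec,
    split: tuple[np.ndarray, np.ndarray],
    seed: int = 0,
) -> FittedClassifier:
    """Fit a latent-space head; grid-search MLPs on the validation split."""
    tr, va = split
    y_tr = labels[tr]
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training split contains a single class")
    metric = spec.metric_name()
    if spec.head == "logistic":
        model = LogisticRegression(max_iter=2000, random_state=seed).fit(latents[tr], y_tr)
        y_pred = model.predict(latents[va])
        y_prob = model.predict_proba(latents[va])[:, 1] if spec.task == "binary" else None
        score = _score(metric, labels[va], y_pred, y_prob)
        return FittedClassifier(model, {"head": "logistic"}, float(score), {metric: float(score)})

    best = None
    for depth, width, dropout, lr, batch in itertools.product(
        spec.depths, spec.widths, spec.dropouts, spec.lrs, spec.batches
    ):
        cfg = MLPHeadConfig(
            depth=depth,
            width=width,
            dropout=dropout,
            lr=lr,
            batch=batch,
            epochs=spec.epochs,
            task=spec.task,
            n_classes=spec.n_classes,
            seed=seed,
        )
        head = MLPHead(cfg, latents.shape[1]).fit(latents[tr], y_tr)
        y_pred = head.predict(latents[va])
        y_prob = head.predict_proba(latents[va]) if spec.task == "binary" else None
        score = _score(metric, labels[va], y_pred, y_prob)
        key = (score, -depth, -width)
        if best is None or key > best[0]:
            best = (key, head, cfg, score)
    _, head, cfg, score = best
    return FittedClassifier(
        head,
        {k: getattr(cfg, k) for k in ("depth", "width", "dropout", "lr", "batch")},
        float(score),
        {metric: float(score)},
    )


# -- metrics -------------------------------------------------------------------
def metrics(predictions: np.ndarray, labels: np.ndarray, task: str, probabilities: np.ndarray | None = None, threshold: float = 0.5) -> dict:
    """Task-appropriate evaluation report.

    Ordinal tasks: quadratic-weighted kappa + accuracy.  Binary tasks:
    AUROC/AUPRC from probabilities plus accuracy and F1 at `threshold`
    (choose the threshold on a validation split, not the test set).
    """
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if len(predictions) == 0 or len(predictions) != len(labels):
        raise ValueError("predictions and labels must be non-empty and aligned")
    report: dict[str, float] = {"accuracy": float(accuracy_score(labels, predictions))}
    if task == "ordinal":
        report["kappa"] = float(cohen_kappa_score(labels, predictions, weights="quadratic"))
    elif task == "binary":
        report["f1"] = float(f1_score(labels, predictions, zero_division=0))
        if probabilities is not None:
            if len(np.unique(labels)) < 2:
                report["auroc"] = float("nan")
                report["auprc"] = float("nan")
            else:
                report["auroc"] = float(roc_auc_score(labels, probabilities))
                report["auprc"] = float(average_precision_score(labels, probabilities))
    else:
        raise ValueError(f"unknown task {task!r}")
    return report


# -- interpretability ----------------------------------------------------------
def interpolate_latents(z_a: np.ndarray, z_b: np.ndarray, n_steps: int) -> np.ndarray:
    """Evenly spaced linear interpolation including both endpoints."""
    z_a, z_b = np.asarray(z_a, dtype=float), np.asarray(z_b, dtype=float)
    if z_a.shape != z_b.shape:
        raise ValueError("latent lengths differ")
    alphas = np.linspace(0.0, 1.0, n_steps)
    return (1.0 - alphas)[:, None] * z_a[None, :] + alphas[:, None] * z_b[None, :]


def traverse_classifier(z: np.ndarray, direction: np.ndarray, steps: np.ndarray) -> np.ndarray:
    """z + c * unit(direction) for each step c (direction = LR coefficients)."""
    direction = np.asarray(direction, dtype=float).ravel()
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValueError("zero direction vector")
    d = direction / norm
    steps = np.asarray(steps, dtype=float)
    return np.asarray(z, dtype=float)[None, :] + steps[:, None] * d[None, :]


def mean_latent_by_stratum(latents: np.ndarray, strata: np.ndarray, value) -> np.ndarray:
    mask = np.asarray(strata) == value
    if not mask.any():
        raise ValueError(f"no latents in stratum {value!r}")
    return latents[mask].mean(axis=0)
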