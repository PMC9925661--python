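"""Objectives, optimizer, training loop and the multi-seed reporting protocol.

The symptom head trains with a multi-target Smooth L1 objective: the mean
over the eight symptoms of ``0.5 r^2`` when the absolute residual ``r`` is
below one score point and ``|r| - 0.5`` otherwise.  The classification
baselines (binary, five-class) use softmax cross-entropy and the
total-score baseline a single-target Smooth L1, all under the same loop.
Optimization is AdamW with a linear warm-up then linear decay schedule; a
checkpoint is kept after every epoch and the one with the best dev-set
selection metric (binary-diagnosis micro-F1 by default, ties resolved to
the earliest epoch) is returned.  The reporting protocol repeats training
under several seeds and reports mean +/- sample standard deviation.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import evaluation
from .model import HierModel, ModelConfig, make_backend
from .transcripts import (
    BINARY_CUTOFF,
    SEVERITY_ORDER,
    Corpus,
    DiagnosticLabels,
    SymptomProfile,
    ValidationError,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Objectives
# ---------------------------------------------------------------------------

def smooth_l1_elementwise(residuals: np.ndarray) -> np.ndarray:
    r = np.abs(residuals)
    return np.where(r < 1.0, 0.5 * r * r, r - 0.5)


def smooth_l1(pred, gold) -> float:
    """Multi-target Smooth L1: mean over symptoms of the piecewise term."""
    p = pred.as_array() if isinstance(pred, SymptomProfile) else np.asarray(pred, float)
    g = gold.as_array() if isinstance(gold, SymptomProfile) else np.asarray(gold, float)
    if p.shape != g.shape:
        raise ValidationError(f"length mismatch: {p.shape} vs {g.shape}")
    return float(smooth_l1_elementwise(p - g).mean())


def smooth_l1_grad(pred: np.ndarray, gold: np.ndarray) -> np.ndarray:
    """d smooth_l1 / d pred (mean reduction)."""
    r = np.asarray(pred, float) - np.asarray(gold, float)
    return np.where(np.abs(r) < 1.0, r, np.sign(r)) / r.size


def _softmax(logits: np.ndarray) -> np.ndarray:
    e = np.exp(logits - logits.max())
    return e / e.sum()


def cross_entropy(logits: np.ndarray, label: int) -> tuple[float, np.ndarray]:
    """Softmax cross-entropy loss and its gradient w.r.t. the logits."""
    probs = _softmax(np.asarray(logits, float))
    loss = -float(np.log(max(probs[label], 1e-300)))
    grad = probs.copy()
    grad[label] -= 1.0
    return loss, grad


def head_target(head_type: str, profile: SymptomProfile):
    labels = DiagnosticLabels.from_profile(profile)
    if head_type == "symptoms8":
        return profile.as_array()
    if head_type == "binary":
        return int(labels.total >= BINARY_CUTOFF)
    if head_type == "severity5":
        return SEVERITY_ORDER.index(labels.severity)
    if head_type == "total_regression":
        return float(labels.total)
    raise ValidationError(f"unknown head type {head_type!r}")


def head_loss(head_type: str, out: np.ndarray, target) -> tuple[float, np.ndarray]:
    """Training loss and head-output gradient for one interview."""
    if head_type == "symptoms8":
        loss = float(smooth_l1_elementwise(out - target).mean())
        return loss, smooth_l1_grad(out, target)
    if head_type in ("binary", "severity5"):
        return cross_entropy(out, int(target))
    # total_regression: single-target Smooth L1
    r = out - np.array([target])
    loss = float(smooth_l1_elementwise(r)[0])
    return loss, smooth_l1_grad(out, np.array([target]))


recast_binary = evaluation.recast_binary


# ---------------------------------------------------------------------------
# Optimizer and schedule
# ---------------------------------------------------------------------------

class AdamW:
    """Adam with decoupled weight decay (applied to matrices only)."""

    def __init__(self, params: dict[str, np.ndarray], weight_decay: float = 0.01,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: Mapping[str, np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for key, p in self.params.items():
            g = grads[key]
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            update = (self.m[key] / bc1) / (np.sqrt(self.v[key] / bc2) + self.eps)
            if p.ndim >= 2:
                p -= lr * self.weight_decay * p
            p -= lr * update


def lr_schedule(step: int, total_steps: int, base_lr: float, warmup_fraction: float) -> float:
    """Linear warm-up to base_lr, then linear decay to zero."""
    warmup = max(1, int(round(warmup_fraction * total_steps)))
    if step < warmup:
        return base_lr * (step + 1) / warmup
    remaining = max(1, total_steps - warmup)
    return base_lr * max(0.0, (total_steps - step) / remaining)


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TrainConfig:
    epochs: int = 200
    learning_rate: float = 3e-5
    weight_decay: float = 0.01
    warmup_fraction: float = 0.1
    batch_size: int = 4
    grad_accum: int = 1
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    selection_metric: str = "binary_micro_f1"

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if self.batch_size < 1 or self.grad_accum < 1:
            raise ValidationError("batch_size and grad_accum must be >= 1")


@dataclasses.dataclass
class TrainedModel:
    model: HierModel
    backend: object
    best_epoch: int
    log: pd.DataFrame
    seed: int

    def predict_interview(self, interview):
        X = self.model.interview_embeddings(interview, self.backend)
        return self.model.predict(X)

    def predict_profiles(self, corpus: Corpus, split: str) -> dict[str, SymptomProfile]:
        if self.model.config.head_type != "symptoms8":
            raise ValidationError("predict_profiles requires the symptoms8 head")
        out: dict[str, SymptomProfile] = {}
        for iv in corpus.split(split):
            scores = self.predict_interview(iv)
            out[iv.id] = SymptomProfile.from_array(np.clip(scores, 0, 3), kind="predicted")
        return out

    def save(self, path) -> None:
        self.model.save(path)


def _dev_selection_metric(
    model: HierModel, backend, corpus: Corpus, metric: str, split: str = "dev"
) -> float:
    head = model.config.head_type
    # heads without a severity recasting always select on the binary rule
    if metric == "severity5_micro_f1" and head != "binary":
        recast, target_head, classes = (
            evaluation.recast_severity, "severity5", tuple(range(5)),
        )
    elif metric in ("binary_micro_f1", "severity5_micro_f1"):
        recast, target_head, classes = recast_binary, "binary", (0, 1)
    else:
        raise ValidationError(f"unknown selection metric {metric!r}")
    pred, gold = [], []
    for iv in corpus.split(split):
        X = model.interview_embeddings(iv, backend)
        pred.append(recast(head, model.predict(X)))
        gold.append(head_target(target_head, corpus.labels[iv.id]))
    mi_f1, _ = evaluation.f1_scores(pred, gold, classes=classes)
    return mi_f1


def train(
    corpus: Corpus,
    model_config: ModelConfig,
    train_config: TrainConfig,
    seed: int,
) -> TrainedModel:
    """Train one model; return the best dev checkpoint and the epoch log."""
    train_ivs = corpus.split("train")
    dev_ivs = corpus.split("dev")
    if not train_ivs or not dev_ivs:
        raise ValidationError("corpus needs nonempty train and dev splits")
    missing = [iv.id for iv in train_ivs + dev_ivs if iv.id not in corpus.labels]
    if missing:
        raise ValidationError(f"interviews without labels: {missing[:5]}")

    config = dataclasses.replace(model_config, seed=seed)
    backend = make_backend(config)
    model = HierModel(config)
    rng = np.random.default_rng(seed)

    # turn embeddings are deterministic per backend; precompute once
    emb = {iv.id: model.interview_embeddings(iv, backend) for iv in train_ivs}
    targets = {iv.id: head_target(config.head_type, corpus.labels[iv.id]) for iv in train_ivs}

    optimizer = AdamW(model.params, weight_decay=train_config.weight_decay)
    n = len(train_ivs)
    batches_per_epoch = int(np.ceil(n / train_config.batch_size))
    steps_per_epoch = int(np.ceil(batches_per_epoch / train_config.grad_accum))
    total_steps = train_config.epochs * steps_per_epoch

    ids = [iv.id for iv in train_ivs]
    best_metric = -np.inf
    best_epoch = -1
    best_params = model.copy_params()
    rows = []
    step = 0
    for epoch in range(1, train_config.epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        accum: dict[str, np.ndarray] | None = None
        accum_count = 0
        for b in range(batches_per_epoch):
            batch = [ids[j] for j in order[b * train_config.batch_size : (b + 1) * train_config.batch_size]]
            grads_sum: dict[str, np.ndarray] = {}
            for iid in batch:
                out, cache = model.forward(emb[iid])
                loss, dout = head_loss(config.head_type, out, targets[iid])
                epoch_loss += loss
                grads, _ = model.backward(cache, dout)
                for k, g in grads.items():
                    grads_sum[k] = grads_sum.get(k, 0.0) + g
            for k in grads_sum:
                grads_sum[k] /= len(batch)
            if accum is None:
                accum = grads_sum
            else:
                for k in accum:
                    accum[k] += grads_sum[k]
            accum_count += 1
            if accum_count == train_config.grad_accum or b == batches_per_epoch - 1:
                for k in accum:
                    accum[k] /= accum_count
                lr = lr_schedule(step, total_steps, train_config.learning_rate,
                                 train_config.warmup_fraction)
                optimizer.step(accum, lr)
                step += 1
                accum, accum_count = None, 0
        epoch_loss /= n
        dev_metric = _dev_selection_metric(
            model, backend, corpus, train_config.selection_metric
        )
        rows.append({"epoch": epoch, "train_loss": epoch_loss, "dev_miF1": dev_metric})
        if dev_metric > best_metric:  # strict: ties keep the earliest epoch
            best_metric = dev_metric
            best_epoch = epoch
            best_params = model.copy_params()
        logger.debug("epoch %d loss %.4f dev miF1 %.3f", epoch, epoch_loss, dev_metric)

    model.params = best_params
    log = pd.DataFrame(rows)
    return TrainedModel(model=model, backend=backend, best_epoch=best_epoch, log=log, seed=seed)


def select_checkpoint(dev_metrics: Sequence[float]) -> int:
    """1-based epoch of the best dev metric (earliest on ties)."""
    arr = np.asarray(dev_metrics, dtype=float)
    if arr.size == 0:
        raise ValidationError("empty metric log")
    return int(np.argmax(arr)) + 1


# ---------------------------------------------------------------------------
# Multi-seed reporting
# ---------------------------------------------------------------------------

def mean_sd(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


def format_mean_sd(values: Sequence[float]) -> str:
    m, s = mean_sd(values)
    return f"{m:.3f} ± {s:.3f}"


def multi_seed_report(
    corpus: Corpus,
    model_configs: Mapping[str, ModelConfig],
    train_config: TrainConfig,
    split: str = "test",
) -> pd.DataFrame:
    """Train each configured model under every seed; tabulate mean +/- sd.

    Rows are model names (e.g. the symptom head and the three baseline
    heads); columns hold the per-metric mean and sample standard deviation
    across seeds.
    """
    if len(train_config.seeds) < 2:
        raise ValidationError("the reporting protocol needs >= 2 seeds")
    rows = {}
    for name, mc in model_configs.items():
        per_seed: dict[str, list[float]] = {}
        for seed in train_config.seeds:
            trained = train(corpus, mc, train_config, seed)
            metrics = evaluation.head_metrics(trained, corpus, split)
            for key, value in metrics.items():
                per_seed.setdefault(key, []).append(value)
        row = {}
        for key, values in per_seed.items():
            m, s = mean_sd(values)
            row[f"{key}_mean"] = m
            row[f"{key}_sd"] = s
        rows[name] = row
    return pd.DataFrame.from_dict(rows, orient="index")
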