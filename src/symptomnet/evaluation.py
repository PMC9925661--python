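"""Evaluation metrics and report assembly.

Regression tasks use the mean absolute error and a macro-averaged MAE that
first computes the MAE inside each severity class and then averages the
occupied classes with equal weight, which keeps the scarce high-severity
interviews from being drowned out.  Classification tasks use micro- and
macro-averaged F1 (counts pooled over classes vs unweighted mean of
per-class F1).  Per-symptom quality is additionally summarised with the
relative RMSE, the RMSE normalised by that of a predictor that always
outputs the training-set mean: values below 1 beat the mean predictor,
1 matches it, above 1 is worse.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .transcripts import (
    BINARY_CUTOFF,
    SEVERITY_ORDER,
    SYMPTOM_KEYS,
    SYMPTOM_PRESENT_CUTOFF,
    Corpus,
    SymptomProfile,
    ValidationError,
    severity_class,
)

logger = logging.getLogger(__name__)


class UndefinedDenominatorError(ValidationError):
    """The RRMSE denominator (gold variance around the training mean) is zero."""


# ---------------------------------------------------------------------------
# Metric primitives
# ---------------------------------------------------------------------------

def mae(pred: Sequence[float], gold: Sequence[float]) -> float:
    """Mean absolute error."""
    p = np.asarray(pred, dtype=float)
    g = np.asarray(gold, dtype=float)
    if p.shape != g.shape or p.size == 0:
        raise ValidationError(f"mae needs equal nonzero lengths, got {p.shape} vs {g.shape}")
    return float(np.mean(np.abs(p - g)))


def ma_mae(
    pred: Sequence[float],
    gold: Sequence[float],
    class_of: Callable[[float], object] | Sequence[object],
) -> float:
    """Macro-averaged MAE over classes of the gold values.

    ``class_of`` is either a callable mapping a gold value to its class or a
    per-item class-label sequence.  Only occupied classes contribute.
    """
    p = np.asarray(pred, dtype=float)
    g = np.asarray(gold, dtype=float)
    if p.shape != g.shape or p.size == 0:
        raise ValidationError("ma_mae needs equal nonzero lengths")
    if callable(class_of):
        labels = [class_of(v) for v in g]
    else:
        labels = list(class_of)
        if len(labels) != p.size:
            raise ValidationError("class label sequence length mismatch")
    by_class: dict[object, list[int]] = {}
    for i, c in enumerate(labels):
        by_class.setdefault(c, []).append(i)
    if not by_class:
        raise ValidationError("ma_mae: all classes empty")
    per_class = [mae(p[idx], g[idx]) for idx in map(list, by_class.values())]
    return float(np.mean(per_class))


def f1_scores(
    pred_labels: Sequence, gold_labels: Sequence, classes: Sequence
) -> tuple[float, float]:
    """(micro-F1, macro-F1) for single-label classification.

    Micro-F1 pools true-positive / false-positive / false-negative counts
    over all classes; macro-F1 is the unweighted mean of per-class F1,
    where a per-class F1 with a zero denominator is defined as 0.
    """
    pred = list(pred_labels)
    gold = list(gold_labels)
    if len(pred) != len(gold) or not pred:
        raise ValidationError("f1_scores needs equal nonzero lengths")
    class_set = list(classes)
    for label in pred + gold:
        if label not in class_set:
            raise ValidationError(f"label {label!r} outside the class set")
    tp_sum = fp_sum = fn_sum = 0
    per_class_f1 = []
    for c in class_set:
        tp = sum(1 for p, g in zip(pred, gold) if p == c and g == c)
        fp = sum(1 for p, g in zip(pred, gold) if p == c and g != c)
        fn = sum(1 for p, g in zip(pred, gold) if p != c and g == c)
        tp_sum += tp
        fp_sum += fp
        fn_sum += fn
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        per_class_f1.append(
            2 * precision * recall / (precision + recall) if precision + recall else 0.0
        )
    micro_p = tp_sum / (tp_sum + fp_sum) if tp_sum + fp_sum else 0.0
    micro_r = tp_sum / (tp_sum + fn_sum) if tp_sum + fn_sum else 0.0
    mi_f1 = 2 * micro_p * micro_r / (micro_p + micro_r) if micro_p + micro_r else 0.0
    return float(mi_f1), float(np.mean(per_class_f1))


def rrmse(pred: Sequence[float], gold: Sequence[float], train_mean: float) -> float:
    """Relative RMSE: sqrt( sum (pred-gold)^2 / sum (gold-train_mean)^2 )."""
    p = np.asarray(pred, dtype=float)
    g = np.asarray(gold, dtype=float)
    if p.shape != g.shape or p.size == 0:
        raise ValidationError("rrmse needs equal nonzero lengths")
    denom = float(np.sum((g - train_mean) ** 2))
    if denom <= 0.0:
        raise UndefinedDenominatorError(
            "gold values are constant and equal to the training mean"
        )
    return float(np.sqrt(np.sum((p - g) ** 2) / denom))


# ---------------------------------------------------------------------------
# Recasting a head's decoded output onto the three evaluation tasks
# ---------------------------------------------------------------------------

def severity_index(total: float) -> int:
    return SEVERITY_ORDER.index(severity_class(total))


def recast_binary(head_type: str, decoded) -> int:
    """Any head's decoded output -> binary diagnosis (1 = depressed)."""
    if head_type == "symptoms8":
        return int(np.sum(decoded) >= BINARY_CUTOFF)
    if head_type == "binary":
        return int(decoded[0])
    if head_type == "severity5":
        return int(decoded[0] >= 2)  # moderate or above
    return int(decoded >= BINARY_CUTOFF)


def recast_severity(head_type: str, decoded) -> int:
    if head_type == "symptoms8":
        return severity_index(min(float(np.sum(decoded)), 24.0))
    if head_type == "severity5":
        return int(decoded[0])
    if head_type == "total_regression":
        return severity_index(float(np.clip(decoded, 0, 24)))
    raise ValidationError("binary head has no severity recasting")


def recast_total(head_type: str, decoded) -> float:
    if head_type == "symptoms8":
        return float(np.sum(decoded))
    if head_type == "total_regression":
        return float(np.clip(decoded, 0, 24))
    raise ValidationError(f"{head_type} head has no total-score recasting")


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TrainStats:
    """Training-split statistics used as the naive-predictor reference."""

    symptom_means: np.ndarray  # (8,)
    total_mean: float

    @classmethod
    def from_corpus(cls, corpus: Corpus, split: str = "train") -> "TrainStats":
        table = corpus.score_table(split)
        if table.empty:
            raise ValidationError(f"no labeled interviews in split {split!r}")
        means = table.mean(axis=0).to_numpy()
        return cls(symptom_means=means, total_mean=float(table.sum(axis=1).mean()))


@dataclasses.dataclass
class EvalReport:
    n: int
    binary_miF1: float
    binary_maF1: float
    mae: float
    ma_mae: float
    miF1_5c: float
    maF1_5c: float
    per_symptom: pd.DataFrame  # index symptom, columns MAE, RRMSE, miF1, maF1
    severity_profiles: pd.DataFrame  # mean gold/pred profile per severity group

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "binary": {"miF1": self.binary_miF1, "maF1": self.binary_maF1},
            "regression": {"MAE": self.mae, "maMAE": self.ma_mae},
            "severity5": {"miF1": self.miF1_5c, "maF1": self.maF1_5c},
            "per_symptom": self.per_symptom.round(6).to_dict(orient="index"),
            "severity_profiles": self.severity_profiles.round(6).to_dict(orient="index"),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    def to_table(self) -> str:
        lines = [
            f"n = {self.n}",
            f"binary diagnosis   miF1 {self.binary_miF1:.3f}  maF1 {self.binary_maF1:.3f}",
            f"total score        MAE {self.mae:.3f}  maMAE {self.ma_mae:.3f}",
            f"5-class severity   miF1 {self.miF1_5c:.3f}  maF1 {self.maF1_5c:.3f}",
            "",
            self.per_symptom.round(3).to_string(),
        ]
        return "\n".join(lines)

    def radar_csv(self, path: str | Path) -> None:
        self.severity_profiles.to_csv(Path(path))


def evaluate(
    predictions: Mapping[str, SymptomProfile],
    corpus: Corpus,
    split: str = "test",
    train_stats: TrainStats | None = None,
) -> EvalReport:
    """Score symptom-profile predictions against gold on one corpus split.

    The eight predicted scores are recast onto the three coarser tasks
    (binary diagnosis, total-score regression, five-class severity) through
    the standard conversion rules; per-symptom F1 uses the 1.5-point
    presence cutoff and per-symptom RRMSE the training-split means.
    """
    ivs = corpus.split(split)
    ids = [iv.id for iv in ivs if iv.id in corpus.labels]
    if not ids:
        raise ValidationError(f"no labeled interviews in split {split!r}")
    missing = [i for i in ids if i not in predictions]
    if missing:
        raise ValidationError(f"missing predictions for {missing[:5]} (and maybe more)")
    if train_stats is None:
        train_stats = TrainStats.from_corpus(corpus)

    P = np.stack([predictions[i].as_array() for i in ids])
    G = np.stack([corpus.labels[i].as_array() for i in ids])
    pred_totals = P.sum(axis=1)
    gold_totals = G.sum(axis=1)

    pred_bin = (pred_totals >= BINARY_CUTOFF).astype(int)
    gold_bin = (gold_totals >= BINARY_CUTOFF).astype(int)
    binary_mi, binary_ma = f1_scores(pred_bin.tolist(), gold_bin.tolist(), classes=(0, 1))

    pred_sev = [severity_index(min(t, 24.0)) for t in pred_totals]
    gold_sev = [severity_index(t) for t in gold_totals]
    mi5, ma5 = f1_scores(pred_sev, gold_sev, classes=tuple(range(5)))

    total_mae = mae(pred_totals, gold_totals)
    occupied = sorted(set(gold_sev))
    if len(occupied) < 5:
        logger.warning(
            "maMAE: only %d of 5 severity classes occupied in split %r; "
            "empty classes are skipped", len(occupied), split,
        )
    total_ma_mae = ma_mae(pred_totals, gold_totals, gold_sev)

    rows = {}
    for k, key in enumerate(SYMPTOM_KEYS):
        pk, gk = P[:, k], G[:, k]
        pred_presence = (pk >= SYMPTOM_PRESENT_CUTOFF).astype(int)
        gold_presence = (gk >= SYMPTOM_PRESENT_CUTOFF).astype(int)
        mi, ma = f1_scores(pred_presence.tolist(), gold_presence.tolist(), classes=(0, 1))
        rows[key] = {
            "MAE": mae(pk, gk),
            "RRMSE": rrmse(pk, gk, train_stats.symptom_means[k]),
            "miF1": mi,
            "maF1": ma,
        }
    per_symptom = pd.DataFrame.from_dict(rows, orient="index")

    profile_rows = {}
    groups = [(SEVERITY_ORDER[s].value, [i for i, g in enumerate(gold_sev) if g == s])
              for s in range(5)]
    groups += [
        ("non_depressed", list(np.flatnonzero(gold_bin == 0))),
        ("depressed", list(np.flatnonzero(gold_bin == 1))),
    ]
    for name, idx in groups:
        if not idx:
            continue
        profile_rows[f"{name}/gold"] = dict(zip(SYMPTOM_KEYS, G[idx].mean(axis=0)))
        profile_rows[f"{name}/pred"] = dict(zip(SYMPTOM_KEYS, P[idx].mean(axis=0)))
    severity_profiles = pd.DataFrame.from_dict(profile_rows, orient="index")

    return EvalReport(
        n=len(ids),
        binary_miF1=binary_mi,
        binary_maF1=binary_ma,
        mae=total_mae,
        ma_mae=total_ma_mae,
        miF1_5c=mi5,
        maF1_5c=ma5,
        per_symptom=per_symptom,
        severity_profiles=severity_profiles,
    )


def head_metrics(trained, corpus: Corpus, split: str = "test") -> dict[str, float]:
    """Task metrics for any head type, recast where applicable."""
    head = trained.model.config.head_type
    ivs = corpus.split(split)
    decoded = [trained.predict_interview(iv) for iv in ivs]
    gold_totals = [float(sum(corpus.labels[iv.id].scores.values())) for iv in ivs]
    gold_bin = [int(t >= BINARY_CUTOFF) for t in gold_totals]
    gold_sev = [severity_index(t) for t in gold_totals]

    pred_bin = [recast_binary(head, d) for d in decoded]
    mi, ma = f1_scores(pred_bin, gold_bin, classes=(0, 1))
    metrics = {"binary_miF1": mi, "binary_maF1": ma}
    if head in ("symptoms8", "total_regression"):
        pred_totals = [recast_total(head, d) for d in decoded]
        metrics["MAE"] = mae(pred_totals, gold_totals)
        metrics["maMAE"] = ma_mae(pred_totals, gold_totals, gold_sev)
    if head in ("symptoms8", "severity5", "total_regression"):
        pred_sev = [recast_severity(head, d) for d in decoded]
        mi5, ma5 = f1_scores(pred_sev, gold_sev, classes=tuple(range(5)))
        metrics["miF1_5c"] = mi5
        metrics["maF1_5c"] = ma5
    return metrics


# ---------------------------------------------------------------------------
# Prediction file I/O
# ---------------------------------------------------------------------------

def write_predictions(path: str | Path, predictions: Mapping[str, SymptomProfile]) -> None:
    rows = {iid: prof.scores for iid, prof in predictions.items()}
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(SYMPTOM_KEYS))
    frame.index.name = "interview_id"
    frame.to_csv(Path(path))


def read_predictions(path: str | Path) -> dict[str, SymptomProfile]:
    frame = pd.read_csv(Path(path), index_col="interview_id")
    missing = [c for c in SYMPTOM_KEYS if c not in frame.columns]
    if missing:
        raise ValidationError(f"predictions file missing columns {missing}")
    return {
        str(iid): SymptomProfile(
            {k: float(np.clip(row[k], 0, 3)) for k in SYMPTOM_KEYS}, kind="predicted"
        )
        for iid, row in frame.iterrows()
    }
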