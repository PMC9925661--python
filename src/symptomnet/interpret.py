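"""Interpretability analyses: saliency, the diagnosis-question shortcut check.

Turn saliency is a first-order gradient attribution: for one interview and
one symptom, the importance of turn i is the Euclidean norm of the gradient
of that symptom's (unclamped) predicted score with respect to the turn's
embedding.  The shortcut analysis targets the "have you been diagnosed with
depression" prompt: answers are classified into yes / no / other with an
editable cue lexicon, group differences are tested with Fisher's exact
test, and a perturbed corpus (yes and no answers swapped, other answers
resampled) measures how much the model leans on that single answer.
"""

from __future__ import annotations

import copy
import dataclasses
import importlib.resources
import logging
import re
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import fisher_exact

from .synthetic import load_templates
from .transcripts import Corpus, Interview, Speaker, ValidationError
from .training import TrainedModel

logger = logging.getLogger(__name__)


class DegenerateTableError(ValidationError):
    """The 2x2 association table has an empty row or column."""


# ---------------------------------------------------------------------------
# Gradient saliency
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SaliencyMap:
    interview_id: str
    symptom_index: int
    importance: np.ndarray  # one non-negative value per turn

    def __post_init__(self) -> None:
        self.importance = np.asarray(self.importance, dtype=float)
        if not np.all(np.isfinite(self.importance)):
            raise ValidationError("saliency values must be finite")

    def top_turn(self) -> int:
        return int(np.argmax(self.importance))


def turn_saliency(
    trained: TrainedModel,
    interview: Interview,
    symptom_index: int,
    agg: str = "l2",
) -> SaliencyMap:
    """Per-turn importance of one symptom prediction.

    The gradient is taken with respect to the turn embeddings (the model's
    input features at the interview level), aggregated to a scalar per turn
    with the L2 norm (``agg="abs_sum"`` for the absolute sum).
    """
    model = trained.model
    if model.config.head_type != "symptoms8":
        raise ValidationError("saliency requires a symptoms8 model")
    if not 0 <= symptom_index < 8:
        raise ValidationError(f"symptom_index must be in 0..7, got {symptom_index}")
    X = model.interview_embeddings(interview, trained.backend)
    out, cache = model.forward(X)
    dout = np.zeros_like(out)
    dout[symptom_index] = 1.0
    _, d_embeddings = model.backward(cache, dout)
    if agg == "l2":
        importance = np.linalg.norm(d_embeddings, axis=1)
    elif agg == "abs_sum":
        importance = np.abs(d_embeddings).sum(axis=1)
    else:
        raise ValidationError(f"unknown aggregation {agg!r}")
    return SaliencyMap(interview.id, symptom_index, importance)


def saliency_table(
    trained: TrainedModel, corpus: Corpus, split: str = "test",
    symptoms: Sequence[int] = tuple(range(8)),
) -> pd.DataFrame:
    """Long-format saliency export: interview id, turn index, symptom, importance."""
    from .transcripts import SYMPTOM_KEYS

    rows = []
    for iv in corpus.split(split):
        for k in symptoms:
            smap = turn_saliency(trained, iv, k)
            for t, value in zip(iv.turns, smap.importance):
                rows.append(
                    {
                        "interview_id": iv.id,
                        "turn_index": t.index,
                        "symptom": SYMPTOM_KEYS[k],
                        "importance": value,
                    }
                )
    return pd.DataFrame(rows)


def saliency_html(table: pd.DataFrame, corpus: Corpus, path: str | Path) -> None:
    """Minimal heat-map view: turns shaded by normalised importance."""
    by_iv = {iv.id: iv for iv in corpus.interviews}
    parts = ["<html><body>"]
    for (iid, symptom), group in table.groupby(["interview_id", "symptom"]):
        iv = by_iv[iid]
        vmax = group["importance"].max() or 1.0
        parts.append(f"<h3>{iid} — {symptom}</h3>")
        for _, row in group.sort_values("turn_index").iterrows():
            turn = iv.turns[int(row["turn_index"])]
            alpha = row["importance"] / vmax
            parts.append(
                f'<div style="background: rgba(255,0,0,{alpha:.3f})">'
                f"<b>{turn.speaker.value}:</b> {turn.text}</div>"
            )
    parts.append("</body></html>")
    Path(path).write_text("\n".join(parts), encoding="utf-8")


# ---------------------------------------------------------------------------
# Diagnosis-question answer classification
# ---------------------------------------------------------------------------

def load_answer_lexicon() -> dict:
    text = (
        importlib.resources.files("symptomnet") / "data" / "answer_lexicon.yaml"
    ).read_text(encoding="utf-8")
    return yaml.safe_load(text)


_TOKEN_RE = re.compile(r"[a-z']+")


def classify_answer(answer_text: str, lexicon: Mapping | None = None) -> str:
    """Classify a diagnosis-question answer into "yes" / "no" / "other".

    Left-to-right cue scan: a no-cue decides "no"; a yes-cue decides "yes"
    unless a negation token occurs in the three preceding tokens; no cue at
    all gives "other".
    """
    lex = lexicon if lexicon is not None else load_answer_lexicon()
    yes_cues = set(lex["yes_cues"])
    no_cues = set(lex["no_cues"])
    negations = set(lex["negations"])
    tokens = _TOKEN_RE.findall(answer_text.lower())
    for i, token in enumerate(tokens):
        if token in no_cues:
            return "no"
        if token in yes_cues:
            window = tokens[max(0, i - 3) : i]
            return "no" if any(w in negations for w in window) else "yes"
    return "other"


def find_diagnosis_answer(interview: Interview, prompt: str | None = None) -> int | None:
    """Turn index of the participant answer following the diagnosis prompt."""
    if prompt is None:
        prompt = load_templates()["diagnosis_prompt"]
    prompt_norm = prompt.lower().strip()
    for pos, turn in enumerate(interview.turns):
        if turn.speaker is Speaker.INTERVIEWER and prompt_norm in turn.text.lower():
            for nxt in interview.turns[pos + 1 :]:
                if nxt.speaker is Speaker.PARTICIPANT:
                    return nxt.index
            return None
    return None


def fisher_association(
    group_labels: Sequence[int], answer_categories: Sequence[str]
) -> float:
    """Two-sided Fisher exact p-value on the 2x2 groups-by-(yes,no) table.

    "other" answers are excluded before tabulation; a table with an empty
    row or column raises :class:`DegenerateTableError`.
    """
    groups = list(group_labels)
    answers = list(answer_categories)
    if len(groups) != len(answers):
        raise ValidationError("group and answer sequences must align")
    kept = [(g, a) for g, a in zip(groups, answers) if a in ("yes", "no")]
    table = np.zeros((2, 2), dtype=int)
    for g, a in kept:
        table[int(bool(g)), 0 if a == "yes" else 1] += 1
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise DegenerateTableError(f"degenerate 2x2 table {table.tolist()}")
    return float(fisher_exact(table, alternative="two-sided")[1])


def answer_association_report(corpus: Corpus, split: str = "test") -> dict:
    """Fisher tests of diagnosis-question answers vs the binary groups."""
    groups, answers = [], []
    for iv in corpus.split(split):
        idx = find_diagnosis_answer(iv)
        if idx is None or iv.id not in corpus.labels:
            continue
        total = sum(corpus.labels[iv.id].scores.values())
        groups.append(int(total >= 10))
        answers.append(classify_answer(iv.turns[idx].text))
    counts = pd.crosstab(pd.Series(groups, name="depressed"),
                         pd.Series(answers, name="answer"))
    return {"p_value": fisher_association(groups, answers),
            "counts": counts.to_dict()}


# ---------------------------------------------------------------------------
# Answer perturbation robustness check
# ---------------------------------------------------------------------------

def perturb_answers(
    corpus: Corpus, seed: int, pools: Mapping[str, Sequence[str]] | None = None
) -> Corpus:
    """Swap yes and no diagnosis answers; resample the evasive ones.

    Each "yes" answer is replaced by a random variation from the "no"
    answer pool and vice versa; each "other" answer by another random
    "other" variation.  All remaining turns are byte-identical.  Interviews
    without the prompt are left unchanged (and logged).
    """
    if pools is None:
        pools = load_templates()["answers"]
    rng = np.random.default_rng(seed)
    out = copy.deepcopy(corpus)
    n_missing = 0
    for iv in out.interviews:
        idx = find_diagnosis_answer(iv)
        if idx is None:
            n_missing += 1
            continue
        pos = next(i for i, t in enumerate(iv.turns) if t.index == idx)
        category = classify_answer(iv.turns[pos].text)
        target_pool = {"yes": "no", "no": "yes", "other": "other"}[category]
        choices = list(pools[target_pool])
        if category == "other" and iv.turns[pos].text in choices and len(choices) > 1:
            choices.remove(iv.turns[pos].text)
        iv.turns[pos].text = choices[int(rng.integers(len(choices)))]
    if n_missing:
        logger.warning("%d interviews had no diagnosis prompt; left unchanged", n_missing)
    return out


def perturbation_delta_report(report_before, report_after) -> dict:
    """Signed metric differences (after minus before) for the robustness check."""
    delta = {
        "miF1": report_after.binary_miF1 - report_before.binary_miF1,
        "maF1": report_after.binary_maF1 - report_before.binary_maF1,
        "MAE": report_after.mae - report_before.mae,
        "maMAE": report_after.ma_mae - report_before.ma_mae,
    }
    formatted = {
        "miF1": f"{delta['miF1'] * 100:+.2f}%",
        "maF1": f"{delta['maF1'] * 100:+.2f}%",
        "MAE": f"{delta['MAE']:+.2f}",
        "maMAE": f"{delta['maMAE']:+.2f}",
    }
    return {"delta": delta, "formatted": formatted}
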