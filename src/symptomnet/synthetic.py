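"""Synthetic interview-corpus generator.

The real clinical-interview corpus this package targets is access-restricted,
so training, evaluation, network analysis and shortcut analysis are exercised
on generated corpora that reproduce the statistical structure the method
assumes:

* eight correlated ordinal symptom scores (0--3) with class imbalance that is
  strongest at the high end of the scale, drawn from a Gaussian copula with
  per-symptom thresholds;
* turn-structured dialogues whose middle section carries symptom-indicative
  utterances, with marker intensity proportional to the gold score;
* a "have you been diagnosed with depression" prompt whose answer is
  stochastically linked to the true binary status via a leakage probability.

The generator makes no attempt at linguistic realism; it exists to give the
model a learnable, controllable signal.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import logging
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .transcripts import (
    SYMPTOM_KEYS,
    Corpus,
    Interview,
    Speaker,
    SymptomProfile,
    Turn,
    ValidationError,
    total_score,
)

logger = logging.getLogger(__name__)

#: Single-factor loadings behind the default latent correlation matrix.
#: Core affective items (low mood, anhedonia, worthlessness) load highest;
#: the psychomotor item loads lowest, mirroring how weakly it co-occurs.
_DEFAULT_LOADINGS = np.array([0.80, 0.85, 0.65, 0.70, 0.60, 0.75, 0.65, 0.50])

#: Default standard-normal cutpoints mapping the latent to scores 0..3.
#: Chosen so P(score=0) is about one half and P(score=3) about 0.05, with
#: the psychomotor item shifted toward lower scores.
_CORE_THRESHOLDS = (-0.10, 0.75, 1.60)
_MOVING_THRESHOLDS = (0.50, 1.25, 2.00)


def default_correlation() -> np.ndarray:
    corr = np.outer(_DEFAULT_LOADINGS, _DEFAULT_LOADINGS)
    np.fill_diagonal(corr, 1.0)
    return corr


def default_thresholds() -> np.ndarray:
    thr = np.tile(np.array(_CORE_THRESHOLDS), (len(SYMPTOM_KEYS), 1))
    thr[SYMPTOM_KEYS.index("moving")] = _MOVING_THRESHOLDS
    return thr


def load_templates() -> dict:
    """Load the bundled utterance template bank."""
    text = (
        importlib.resources.files("symptomnet") / "data" / "templates.yaml"
    ).read_text(encoding="utf-8")
    bank = yaml.safe_load(text)
    # YAML may parse unquoted answer keys as booleans; normalise to strings.
    bank["answers"] = {
        {True: "yes", False: "no"}.get(k, k): v for k, v in bank["answers"].items()
    }
    return bank


@dataclasses.dataclass
class GeneratorConfig:
    """Parameters of the synthetic corpus generator.

    leakage is the probability that the diagnosis-question answer is
    congruent with the true binary status; with the remaining probability
    the answer is incongruent or evasive ("other") with equal odds.
    """

    n_interviews: int = 200
    correlation: np.ndarray = dataclasses.field(default_factory=default_correlation)
    thresholds: np.ndarray = dataclasses.field(default_factory=default_thresholds)
    leakage: float = 0.8
    target_depressed_rate: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        self.correlation = np.asarray(self.correlation, dtype=float)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        k = len(SYMPTOM_KEYS)
        if self.correlation.shape != (k, k):
            raise ValidationError(f"correlation matrix must be {k}x{k}")
        if not np.allclose(self.correlation, self.correlation.T):
            raise ValidationError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.correlation), 1.0):
            raise ValidationError("correlation matrix must have unit diagonal")
        if self.thresholds.shape != (k, 3):
            raise ValidationError(f"thresholds must be {k}x3")
        if np.any(np.diff(self.thresholds, axis=1) <= 0):
            raise ValidationError("per-symptom thresholds must be strictly increasing")
        if not 0.0 <= self.leakage <= 1.0:
            raise ValidationError("leakage must be in [0,1]")
        if self.n_interviews < 1:
            raise ValidationError("n_interviews must be positive")


def _cholesky(corr: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValidationError("correlation matrix is not positive definite") from exc


def gen_scores(config: GeneratorConfig) -> pd.DataFrame:
    """Draw gold symptom-score profiles from the Gaussian copula.

    A latent multivariate normal with the configured correlation matrix is
    sampled and each coordinate discretised through its three thresholds;
    the result is an ``n_interviews`` x 8 integer DataFrame.
    """
    chol = _cholesky(config.correlation)
    rng = np.random.default_rng(config.seed)
    latent = rng.standard_normal((config.n_interviews, len(SYMPTOM_KEYS))) @ chol.T
    scores = (latent[:, :, None] >= config.thresholds[None, :, :]).sum(axis=2)
    return pd.DataFrame(scores.astype(int), columns=list(SYMPTOM_KEYS))


def render_interview(
    profile: SymptomProfile,
    config: GeneratorConfig,
    seed: int,
    interview_id: str = "synthetic",
    templates: dict | None = None,
) -> Interview:
    """Render one gold profile into a turn-structured interview.

    Layout: >=3 opening small-talk turns; a middle block with one
    question/answer pair per symptom, the answer containing as many
    marker utterances as the gold score (score 0: a neutral line half the
    time); the diagnosis prompt with a leakage-linked answer; >=2 closing
    turns.  Byte-identical for a fixed (profile, config, seed).
    """
    bank = templates if templates is not None else load_templates()
    rng = np.random.default_rng(seed)
    turns: list[Turn] = []

    def add(speaker: Speaker, text: str) -> None:
        turns.append(Turn(speaker=speaker, text=text, index=len(turns)))

    def pick(pool: Sequence[str]) -> str:
        return pool[int(rng.integers(len(pool)))]

    # opening small talk
    n_open_pairs = int(rng.integers(2, 4))  # 4 or 6 opening turns
    for _ in range(n_open_pairs):
        add(Speaker.INTERVIEWER, pick(bank["opener_questions"]))
        add(Speaker.PARTICIPANT, pick(bank["opener_answers"]))

    middle_start = len(turns)

    # symptom block: one question/answer pair per symptom in fixed order
    for key in SYMPTOM_KEYS:
        score = int(profile.scores[key])
        add(Speaker.INTERVIEWER, bank["questions"][key])
        tiers = bank["symptom_templates"][key]
        if score == 0:
            text = pick(tiers[0]) if rng.random() < 0.5 else "nothing much to say about that"
        else:
            text = " ".join(pick(tiers[score]) for _ in range(score))
        add(Speaker.PARTICIPANT, text)

    # diagnosis prompt with leakage-linked answer
    depressed = total_score(profile) >= 10
    congruent = "yes" if depressed else "no"
    incongruent = "no" if depressed else "yes"
    u = rng.random()
    if u < config.leakage:
        pool_name = congruent
    elif u < config.leakage + (1.0 - config.leakage) / 2.0:
        pool_name = incongruent
    else:
        pool_name = "other"
    add(Speaker.INTERVIEWER, bank["diagnosis_prompt"])
    add(Speaker.PARTICIPANT, pick(bank["answers"][pool_name]))

    middle_stop = len(turns)

    # closing
    add(Speaker.INTERVIEWER, pick(bank["closer_questions"]))
    add(Speaker.PARTICIPANT, pick(bank["closer_answers"]))
    add(Speaker.INTERVIEWER, "okay that's everything thanks again for coming in")

    iv = Interview(id=interview_id, turns=turns)
    # stash block boundaries for the saliency analyses (not serialised)
    iv.middle_block = (middle_start, middle_stop)  # type: ignore[attr-defined]
    return iv


def middle_block_range(interview: Interview) -> tuple[int, int]:
    """Turn-index range [start, stop) of the symptom-marker middle block.

    Uses the stashed boundaries when present; otherwise locates the block
    from the first symptom question to the diagnosis answer.
    """
    if hasattr(interview, "middle_block"):
        return interview.middle_block  # type: ignore[attr-defined]
    bank = load_templates()
    questions = set(bank["questions"].values())
    starts = [t.index for t in interview.turns if t.text in questions]
    prompt = [t.index for t in interview.turns if t.text == bank["diagnosis_prompt"]]
    if not starts or not prompt:
        raise ValidationError(f"interview {interview.id!r} has no recognisable middle block")
    return min(starts), prompt[0] + 2


def gen_corpus(
    config: GeneratorConfig,
    split_fractions: Sequence[float] = (0.6, 0.15, 0.25),
) -> Corpus:
    """Generate a labeled corpus with disjoint train/dev/test splits."""
    fracs = np.asarray(split_fractions, dtype=float)
    if fracs.shape != (3,) or np.any(fracs < 0) or abs(fracs.sum() - 1.0) > 1e-9:
        raise ValidationError("split_fractions must be 3 non-negative values summing to 1")
    n = config.n_interviews
    n_train = int(round(n * fracs[0]))
    n_dev = int(round(n * fracs[1]))
    n_test = n - n_train - n_dev
    if min(n_train, n_dev, n_test) < 1:
        raise ValidationError(
            f"n={n} too small for nonempty splits {n_train}/{n_dev}/{n_test}"
        )

    scores = gen_scores(config)
    bank = load_templates()
    master = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    render_seeds = master.integers(0, 2**31 - 1, size=n)

    interviews: list[Interview] = []
    labels: dict[str, SymptomProfile] = {}
    split_names = ["train"] * n_train + ["dev"] * n_dev + ["test"] * n_test
    for i in range(n):
        profile = SymptomProfile.from_array(scores.iloc[i].to_numpy(), kind="gold")
        iid = f"synth_{i:05d}"
        iv = render_interview(
            profile, config, int(render_seeds[i]), interview_id=iid, templates=bank
        )
        iv.split = split_names[i]
        interviews.append(iv)
        labels[iid] = profile

    corpus = Corpus(interviews, labels)
    for name in ("train", "dev", "test"):
        table = corpus.score_table(name)
        totals = table.sum(axis=1)
        logger.info(
            "split %s: n=%d depressed=%.1f%% mean total=%.2f",
            name, len(table), 100.0 * (totals >= 10).mean(), totals.mean(),
        )
    return corpus
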