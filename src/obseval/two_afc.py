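"""Two-alternative forced-choice reader-study data model and analysis.

A study presents an expert reader with side-by-side pairs of one real and
one synthetic image; the reader picks the image perceived as real and
states a confidence level from 1 to 5.  Because the proportion of correct
choices in a 2-AFC experiment equals the reader's AUC, per-reader percent
accuracy is the study's figure of merit; accuracy near 50% means the
reader cannot tell synthetic from real.

This module is a local (non-web) counterpart of such a study platform:
session construction with seeded shuffling and side randomization,
response-log scoring with exact binomial inference versus chance, pooling
across readers, confidence-level tallies, and System Usability Scale
(SUS) questionnaire scoring.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .exceptions import DomainError, ParameterError, StudyError

__all__ = [
    "StudyConfig",
    "TrialPair",
    "ResponseRecord",
    "ReaderSummary",
    "build_session",
    "save_session",
    "load_session",
    "score_responses",
    "pooled_summary",
    "confidence_fraction",
    "sus_score",
    "read_response_log",
    "write_response_log",
    "read_sus_responses",
    "SUS_LEVELS",
]


@dataclass
class StudyConfig:
    """Investigator-side description of a 2-AFC study.

    ``pairs`` lists (synthetic_image_path, real_image_path) in upload
    order.  ``display_features`` records UI capabilities (contrast
    adjustment, intensity inversion, result email) as metadata only; no
    computation depends on them.
    """

    project_title: str
    passcode: str
    instructions: str
    pairs: list
    shuffle: bool = False
    shuffle_seed: int = 0
    investigator_contact: str = ""
    display_features: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not re.fullmatch(r"\d{4}", str(self.passcode)):
            raise ParameterError("passcode must be exactly 4 digits")
        if not self.pairs:
            raise ParameterError("pair list must be non-empty")
        self.pairs = [(str(s), str(r)) for s, r in self.pairs]


@dataclass
class TrialPair:
    """One presented pair; ``left_is_real`` records the side randomization."""

    trial_id: int
    left_is_real: bool
    synthetic_ref: str
    real_ref: str


@dataclass
class ResponseRecord:
    """One reader decision.  ``chose_real`` is True when the reader picked
    the real image, i.e. when the decision was correct."""

    reader_id: str
    trial_id: int
    chose_real: bool
    confidence: int
    comment: Optional[str] = None

    def __post_init__(self) -> None:
        if self.confidence not in (1, 2, 3, 4, 5):
            raise ParameterError(
                f"confidence must be in 1..5, got {self.confidence}"
            )


@dataclass
class ReaderSummary:
    """Per-reader (or pooled) 2-AFC outcome.

    ``confidence_tally`` is a 2x5 count table: row 0 = correct decisions,
    row 1 = incorrect decisions, columns = confidence levels 1..5.
    ``percent_accuracy`` keeps full precision; the rounded integer value
    is what study reports print.  ``below_chance_flag`` is set when the
    95% Clopper-Pearson upper bound falls below 0.5, which usually
    signals an untrained observer rather than informative data.
    """

    reader_id: str
    n_trials: int
    n_correct: int
    percent_accuracy: float
    percent_accuracy_rounded: int
    median_confidence: float
    confidence_tally: np.ndarray
    binomial_p_vs_chance: float
    ci95: tuple
    below_chance_flag: bool
    missing_trials: list = field(default_factory=list)


def build_session(config: StudyConfig) -> list[TrialPair]:
    """Materialize the trial sequence from a study config.

    If ``shuffle`` is set, pair order is a seeded permutation; the
    left/right placement of the real image is a seeded fair coin per
    trial.  The same config always yields the identical session.
    """
    for s, r in config.pairs:
        for p in (s, r):
            if not Path(p).exists():
                raise StudyError(f"image file not found: {p}")
    rng = np.random.default_rng(config.shuffle_seed)
    order = np.arange(len(config.pairs))
    if config.shuffle:
        order = rng.permutation(order)
    coins = rng.integers(0, 2, size=len(order)).astype(bool)
    return [
        TrialPair(
            trial_id=i + 1,
            left_is_real=bool(coins[i]),
            synthetic_ref=config.pairs[j][0],
            real_ref=config.pairs[j][1],
        )
        for i, j in enumerate(order)
    ]


def save_session(config: StudyConfig, session: Sequence[TrialPair], path) -> None:
    payload = {
        "config": asdict(config),
        "trials": [asdict(t) for t in session],
    }
    payload["config"]["pairs"] = [list(p) for p in config.pairs]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)


def load_session(path) -> tuple[StudyConfig, list[TrialPair]]:
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    cfg = StudyConfig(**payload["config"])
    trials = [TrialPair(**t) for t in payload["trials"]]
    ids = [t.trial_id for t in trials]
    if ids != list(range(1, len(trials) + 1)):
        raise StudyError("trial_ids must be unique and contiguous from 1")
    return cfg, trials


def _lower_median(values: Sequence[int]) -> float:
    """Median with the lower-median convention for even counts."""
    v = sorted(values)
    return float(v[(len(v) - 1) // 2])


def score_responses(
    session: Sequence[TrialPair],
    log: Sequence[ResponseRecord],
    reader_id: str,
) -> ReaderSummary:
    """Score one reader's responses against a session.

    Accuracy is the fraction of trials where the real image was chosen;
    inference versus chance (probability 1/2) uses the exact two-sided
    binomial test and the Clopper-Pearson 95% interval.  Unanswered
    trials are reported in ``missing_trials`` rather than silently
    dropped.
    """
    valid_ids = {t.trial_id for t in session}
    records = [r for r in log if r.reader_id == reader_id]
    if not records:
        raise StudyError(f"no responses for reader {reader_id!r}")
    seen: set[int] = set()
    for r in records:
        if r.trial_id not in valid_ids:
            raise StudyError(
                f"reader {reader_id!r} responded to unknown trial {r.trial_id}"
            )
        if r.trial_id in seen:
            raise StudyError(
                f"duplicate response for (reader {reader_id!r}, trial {r.trial_id})"
            )
        seen.add(r.trial_id)
    missing = sorted(valid_ids - seen)

    n = len(records)
    n_correct = sum(r.chose_real for r in records)
    tally = np.zeros((2, 5), dtype=int)
    for r in records:
        tally[0 if r.chose_real else 1, r.confidence - 1] += 1
    pct = 100.0 * n_correct / n
    test = binomtest(n_correct, n, 0.5)
    ci = test.proportion_ci(confidence_level=0.95, method="exact")
    return ReaderSummary(
        reader_id=reader_id,
        n_trials=n,
        n_correct=n_correct,
        percent_accuracy=pct,
        percent_accuracy_rounded=int(round(pct)),
        median_confidence=_lower_median([r.confidence for r in records]),
        confidence_tally=tally,
        binomial_p_vs_chance=float(test.pvalue),
        ci95=(float(ci.low), float(ci.high)),
        below_chance_flag=bool(ci.high < 0.5),
        missing_trials=missing,
    )


def pooled_summary(summaries: Sequence[ReaderSummary]) -> ReaderSummary:
    """Pool reader summaries by summing counts and re-running inference."""
    if not summaries:
        raise ParameterError("summaries must be non-empty")
    if len(summaries) == 1:
        s = summaries[0]
        return ReaderSummary(**{**asdict_np(s), "reader_id": "pooled"})
    n = sum(s.n_trials for s in summaries)
    n_correct = sum(s.n_correct for s in summaries)
    tally = np.sum([s.confidence_tally for s in summaries], axis=0)
    confs: list[int] = []
    for s in summaries:
        for level in range(5):
            confs.extend([level + 1] * int(s.confidence_tally[:, level].sum()))
    pct = 100.0 * n_correct / n
    test = binomtest(n_correct, n, 0.5)
    ci = test.proportion_ci(confidence_level=0.95, method="exact")
    return ReaderSummary(
        reader_id="pooled",
        n_trials=n,
        n_correct=n_correct,
        percent_accuracy=pct,
        percent_accuracy_rounded=int(round(pct)),
        median_confidence=_lower_median(confs),
        confidence_tally=tally,
        binomial_p_vs_chance=float(test.pvalue),
        ci95=(float(ci.low), float(ci.high)),
        below_chance_flag=bool(ci.high < 0.5),
        missing_trials=[],
    )


def asdict_np(s: ReaderSummary) -> dict:
    d = asdict(s)
    d["confidence_tally"] = np.asarray(s.confidence_tally)
    return d


def confidence_fraction(
    summary: ReaderSummary, correct: bool, min_confidence: int
) -> tuple[int, int]:
    """(count, percent) of decisions with given correctness at confidence
    >= ``min_confidence``; percent is of all decisions of that correctness,
    rounded to the nearest integer."""
    if min_confidence not in (1, 2, 3, 4, 5):
        raise ParameterError("min_confidence must be in 1..5")
    row = summary.confidence_tally[0 if correct else 1]
    total = int(row.sum())
    if total == 0:
        raise DomainError(
            "no decisions with the requested correctness; percentage undefined"
        )
    count = int(row[min_confidence - 1:].sum())
    return count, int(round(100.0 * count / total))


# ---------------------------------------------------------------------------
# System Usability Scale
# ---------------------------------------------------------------------------

SUS_LEVELS = (
    "strongly disagree",
    "disagree",
    "neutral",
    "agree",
    "strongly agree",
)


def sus_score(responses: Sequence[str]) -> float:
    """Score a ten-item SUS questionnaire on a 0-100 scale.

    Odd-numbered items (1-based) map strongly disagree..strongly agree to
    0..4; even-numbered items map to 4..0; the summed item scores are
    multiplied by 2.5.
    """
    if len(responses) != 10:
        raise ParameterError(f"expected exactly 10 item responses, got {len(responses)}")
    total = 0
    for i, resp in enumerate(responses):
        label = str(resp).strip().lower()
        if label not in SUS_LEVELS:
            raise ParameterError(f"invalid response label for item {i + 1}: {resp!r}")
        v = SUS_LEVELS.index(label)
        total += v if i % 2 == 0 else 4 - v
    return 2.5 * total


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def read_response_log(path, session: Sequence[TrialPair]) -> list[ResponseRecord]:
    """Read a response-log CSV (reader_id,trial_id,chosen_side,confidence,comment).

    ``chosen_side`` is 'left' or 'right'; correctness is derived from the
    session's per-trial side randomization.
    """
    df = pd.read_csv(path, dtype={"reader_id": str, "comment": str})
    required = {"reader_id", "trial_id", "chosen_side", "confidence"}
    if not required.issubset(df.columns):
        raise StudyError(f"response log missing columns: {sorted(required - set(df.columns))}")
    by_id = {t.trial_id: t for t in session}
    records = []
    for row in df.itertuples(index=False):
        tid = int(row.trial_id)
        if tid not in by_id:
            raise StudyError(f"response references unknown trial {tid}")
        side = str(row.chosen_side).strip().lower()
        if side not in ("left", "right"):
            raise StudyError(f"chosen_side must be 'left' or 'right', got {row.chosen_side!r}")
        chose_real = (side == "left") == by_id[tid].left_is_real
        comment = getattr(row, "comment", None)
        if comment is not None and (pd.isna(comment) or comment == ""):
            comment = None
        records.append(
            ResponseRecord(
                reader_id=str(row.reader_id),
                trial_id=tid,
                chose_real=bool(chose_real),
                confidence=int(row.confidence),
                comment=comment,
            )
        )
    return records


def write_response_log(
    records: Sequence[ResponseRecord], session: Sequence[TrialPair], path
) -> None:
    by_id = {t.trial_id: t for t in session}
    rows = []
    for r in records:
        t = by_id[r.trial_id]
        real_side = "left" if t.left_is_real else "right"
        other = "right" if t.left_is_real else "left"
        rows.append(
            {
                "reader_id": r.reader_id,
                "trial_id": r.trial_id,
                "chosen_side": real_side if r.chose_real else other,
                "confidence": r.confidence,
                "comment": r.comment if r.comment is not None else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_sus_responses(path) -> list[float]:
    """Read a SUS CSV (columns item1..item10, one row per respondent);
    return a score per respondent."""
    df = pd.read_csv(path, dtype=str)
    cols = [f"item{i}" for i in range(1, 11)]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise StudyError(f"SUS file missing columns: {missing}")
    return [sus_score([row[c] for c in cols]) for _, row in df.iterrows()]
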