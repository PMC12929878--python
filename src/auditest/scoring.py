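"""Trial- and task-level scoring.

Sentence material is scored by keywords (three canonical keywords per
sentence, 0–3 per trial, percent correct over a list); digits-in-noise
trials are all-or-nothing on the ordered digit triple; adaptive tracks
delegate to the staircase estimators.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .staircase import combine_runs

__all__ = [
    "KeywordKey",
    "ScoreSummary",
    "normalize_tokens",
    "score_keywords",
    "aggregate_keyword_list",
    "score_din_trial",
    "assemble_results",
]

_PUNCT = re.compile(r"[^\w\s']", flags=re.UNICODE)


def normalize_tokens(text_or_tokens) -> list[str]:
    """Lower-case and strip punctuation; accepts a string or token list."""
    if isinstance(text_or_tokens, str):
        tokens = text_or_tokens.split()
    else:
        tokens = list(text_or_tokens)
    out = []
    for tok in tokens:
        tok = _PUNCT.sub("", str(tok).lower()).strip()
        if tok:
            out.append(tok)
    return out


@dataclass(frozen=True)
class KeywordKey:
    """The three canonical keywords of one sentence."""

    keywords: tuple[str, str, str]

    def __post_init__(self) -> None:
        normalized = tuple(normalize_tokens(self.keywords))
        if len(normalized) != 3:
            raise ValueError(f"a sentence key has exactly 3 keywords, got {self.keywords!r}")
        object.__setattr__(self, "keywords", normalized)


def _crude_stem(token: str) -> str:
    """Strip common English inflection suffixes (a deliberately simple
    stemmer for the optional lenient-scoring mode)."""
    for suffix in ("ing", "ed", "es", "s"):
        if token.endswith(suffix) and len(token) - len(suffix) >= 3:
            return token[: -len(suffix)]
    return token


def score_keywords(response_tokens, key: KeywordKey, *, lenient: bool = False) -> int:
    """Count key keywords present in the response (0–3).

    Matching is exact token equality after lower-casing and punctuation
    stripping; each keyword is credited at most once. Order in the
    response is irrelevant and an empty response scores 0. With
    ``lenient``, simple plural/tense variants also match (crude suffix
    stemming) — off by default because human scorers' leniency rules
    vary and are not standardized.
    """
    response = set(normalize_tokens(response_tokens))
    if lenient:
        stems = {_crude_stem(tok) for tok in response}
        return sum(
            1 for kw in key.keywords if kw in response or _crude_stem(kw) in stems
        )
    return sum(1 for kw in key.keywords if kw in response)


def aggregate_keyword_list(scores: Sequence[int], keywords_per_trial: int = 3) -> float:
    """Percent correct for a list of keyword scores: 100·Σ/(3·n)."""
    scores = list(scores)
    if not scores:
        raise ValueError("cannot aggregate an empty score list")
    for i, s in enumerate(scores):
        if not (0 <= s <= keywords_per_trial):
            raise ValueError(f"score {s} at position {i} outside 0–{keywords_per_trial}")
    return 100.0 * sum(scores) / (keywords_per_trial * len(scores))


def score_din_trial(response_digits, presented_digits) -> bool:
    """All-or-nothing digit-triple scoring: correct iff all three digits
    match in order (shorter or reordered responses are incorrect)."""
    response = [int(d) for d in response_digits]
    presented = [int(d) for d in presented_digits]
    if len(presented) != 3:
        raise ValueError(f"a trial presents exactly 3 digits, got {len(presented)}")
    return response == presented


@dataclass(frozen=True)
class ScoreSummary:
    """Per-condition, per-run score block."""

    condition: str
    run: int
    n_trials: int
    per_trial: tuple = ()
    percent_correct: float | None = None
    threshold: float | None = None


def assemble_results(trials, task=None, *, keywords_per_trial: int = 3) -> list[ScoreSummary]:
    """Group trial records into per-condition, per-run summaries.

    Practice-flagged trials are excluded. Keyword tasks aggregate to
    percent correct; trials that carry a presented level but keyword-less
    scoring (adaptive tasks) are summarized by trial count only — their
    thresholds come from the staircase estimators via
    :func:`summarize_adaptive_runs`.
    """
    groups: dict[tuple[str, int], list] = {}
    for rec in trials:
        if getattr(rec, "practice", False):
            continue
        key = (getattr(rec, "condition", "") or "", int(getattr(rec, "run", 0)))
        groups.setdefault(key, []).append(rec)

    summaries = []
    for (condition, run), recs in sorted(groups.items()):
        kw_scores = [rec.keyword_score for rec in recs if getattr(rec, "keyword_score", None) is not None]
        if kw_scores:
            if len(kw_scores) != len(recs):
                raise ValueError(
                    f"condition {condition!r} run {run} mixes keyword-scored and "
                    "unscored trials; score sets must be homogeneous"
                )
            summaries.append(
                ScoreSummary(
                    condition=condition,
                    run=run,
                    n_trials=len(recs),
                    per_trial=tuple(kw_scores),
                    percent_correct=aggregate_keyword_list(kw_scores, keywords_per_trial),
                )
            )
        else:
            summaries.append(ScoreSummary(condition=condition, run=run, n_trials=len(recs)))
    return summaries


def summarize_adaptive_runs(run_thresholds: Iterable[float], condition: str = "") -> ScoreSummary:
    """Final adaptive-task score: the mean threshold across runs."""
    thresholds = list(run_thresholds)
    return ScoreSummary(
        condition=condition,
        run=-1,
        n_trials=len(thresholds),
        per_trial=tuple(thresholds),
        threshold=combine_runs(thresholds),
    )
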