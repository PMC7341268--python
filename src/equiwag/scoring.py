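"""Per-individual welfare scoring.

Each indicator response maps to a welfare level (good / medium / bad); a
level maps to points (default 25 / 12.5 / 1); a category score is the sum
over the category's four questions; a score maps to a letter grade on a
ten-bin scale from J (worst, scores up to 10) to A (best, 90 to 100).

Multi-select questions are scored *worst-of*: the welfare level of the
individual is the worst level among its selected responses.  This is the
conservative choice — adding a finding can never make the individual look
better — and a :class:`ScoreConfig` switch (``multiselect_rule``) allows
best-of or modal scoring for sensitivity analyses.

When a main question is unanswered and the schema defines an answered
alternate, the alternate's response is used and the substitution recorded.
If neither is answered the category score is incomplete and the individual
is excluded from that category's population aggregation downstream.
"""

from __future__ import annotations

import bisect
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .errors import EquiwagError
from .schema import CategorySpec, EARSRecord, QuestionSpec, RecordSet, CATEGORIES

_LEVEL_ORDER = {"bad": 0, "medium": 1, "good": 2}  # worst -> best


@dataclass(frozen=True)
class ScoreConfig:
    """Points per welfare level and the multi-select scoring rule."""

    score_good: float = 25.0
    score_medium: float = 12.5
    score_bad: float = 1.0
    multiselect_rule: str = "worst"  # "worst" | "best" | "modal"

    def __post_init__(self):
        if not (self.score_good > self.score_medium > self.score_bad > 0):
            raise EquiwagError("scores must satisfy good > medium > bad > 0")
        if self.multiselect_rule not in ("worst", "best", "modal"):
            raise EquiwagError(f"unknown multiselect rule {self.multiselect_rule!r}")

    def points(self, level: str) -> float:
        return {"good": self.score_good, "medium": self.score_medium, "bad": self.score_bad}[level]


@dataclass(frozen=True)
class GradeScale:
    """Letter bins worst-to-best; letter i covers (edges[i-1], edges[i]]."""

    letters: tuple = ("J", "I", "H", "G", "F", "E", "D", "C", "B", "A")
    upper_edges: tuple = (10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0, 100.0)

    def __post_init__(self):
        if len(self.letters) != len(self.upper_edges):
            raise EquiwagError("one upper edge per letter required")
        if list(self.upper_edges) != sorted(self.upper_edges):
            raise EquiwagError("upper edges must increase")

    def grade_of(self, score: float) -> str:
        if not (0 < score <= self.upper_edges[-1]):
            raise EquiwagError(f"score {score} outside (0, {self.upper_edges[-1]}]")
        return self.letters[bisect.bisect_left(self.upper_edges, score)]


DEFAULT_SCALE = GradeScale()


@dataclass(frozen=True)
class CategoryScore:
    """An individual's summed score for one welfare category."""

    equid_id: str
    category: str
    score: Optional[float]
    levels: dict = field(default_factory=dict)  # question_id actually used -> level
    alternates_used: tuple = ()  # (main_id, alternate_id) pairs
    complete: bool = True


def welfare_level(question: QuestionSpec, responses, rule: str = "worst") -> Optional[str]:
    """Welfare level of a response set; None when the set is empty.

    Single-select questions map their single response; multi-select
    questions combine levels with ``rule`` (worst-of by default; modal
    breaks ties toward the worse level).
    """
    responses = frozenset(responses or ())
    if not responses:
        return None
    unknown = [r for r in responses if r not in question.level_map]
    if unknown:
        raise EquiwagError(f"{question.question_id}: response(s) {unknown} outside vocabulary")
    levels = [question.level_of(r) for r in responses]
    if len(levels) == 1:
        return levels[0]
    if rule == "worst":
        return min(levels, key=_LEVEL_ORDER.get)
    if rule == "best":
        return max(levels, key=_LEVEL_ORDER.get)
    counts = Counter(levels)
    best_count = max(counts.values())
    return min((lv for lv, c in counts.items() if c == best_count), key=_LEVEL_ORDER.get)


def level_score(level: str, cfg: ScoreConfig = ScoreConfig()) -> float:
    if level not in _LEVEL_ORDER:
        raise EquiwagError(f"unknown welfare level {level!r}")
    return cfg.points(level)


def resolve_question(record: EARSRecord, spec: CategorySpec, main: QuestionSpec):
    """The (question, responses) pair actually usable for a main slot.

    Prefers the main question's own responses; falls back to an answered
    alternate; returns (main, None) when neither is answered.
    """
    responses = record.responses.get(main.question_id)
    if responses:
        return main, responses
    alt = spec.alternates.get(main.question_id)
    if alt is not None:
        alt_responses = record.responses.get(alt.question_id)
        if alt_responses:
            return alt, alt_responses
    return main, None


def category_score(record: EARSRecord, spec: CategorySpec, cfg: ScoreConfig = ScoreConfig()) -> CategoryScore:
    """Sum the four question scores of one category for one individual."""
    if spec.category not in CATEGORIES:
        raise EquiwagError(f"unknown category {spec.category!r}")
    levels = {}
    alternates_used = []
    total = 0.0
    complete = True
    for main in spec.mains:
        question, responses = resolve_question(record, spec, main)
        if responses is None:
            complete = False
            continue
        if question is not main:
            alternates_used.append((main.question_id, question.question_id))
        level = welfare_level(question, responses, rule=cfg.multiselect_rule)
        levels[question.question_id] = level
        total += cfg.points(level)
    return CategoryScore(
        equid_id=record.equid_id,
        category=spec.category,
        score=total if complete else None,
        levels=levels,
        alternates_used=tuple(alternates_used),
        complete=complete,
    )


def grade_of_score(score: float, scale: GradeScale = DEFAULT_SCALE) -> str:
    """Letter grade of a category score in (0, 100]."""
    return scale.grade_of(score)


def score_records(rs: RecordSet, cfg: ScoreConfig = ScoreConfig(), categories: Iterable[str] = CATEGORIES) -> dict:
    """All category scores for a record set.

    Returns {category: [CategoryScore, ...]} with one entry per record,
    including incomplete scores (callers decide how to treat them).
    """
    out = {}
    for cat in categories:
        spec = rs.schema.category_spec(cat)
        out[cat] = [category_score(r, spec, cfg) for r in rs]
    return out
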