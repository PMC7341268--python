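"""Population-level aggregation of individual welfare scores.

The population grade for a category is the *worst-case cumulative* grade:
bin the individual category scores into the letter scale, accumulate bin
percentages from the worst grade upward, and assign the first letter at
which the cumulative share of animals reaches the threshold (default 15%).
A population in which 15% of animals sit in grade J is graded J regardless
of how well the remaining 85% score — the rule is deliberately protective
of the worst-off animals.

The threshold comparison uses exact rational arithmetic on counts
(``100 * cumulative_count >= threshold * n``) so a population with exactly
15% in the worst bin grades worst, with no float-edge artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import EquiwagError
from .schema import (
    AGE_CATEGORIES,
    CATEGORIES,
    DISTRICTS,
    RecordSet,
    SEXES,
    SPECIES,
    WORK_TYPES,
)
from .scoring import (
    CategoryScore,
    DEFAULT_SCALE,
    GradeScale,
    ScoreConfig,
    category_score,
    resolve_question,
    welfare_level,
)

DEFAULT_THRESHOLD_PCT = 15.0
DEFAULT_MIN_STRATUM_N = 5

STRATUM_INDICATORS = {
    "district": ("district", DISTRICTS),
    "sex": ("sex", SEXES),
    "species": ("species", SPECIES),
    "age_category": ("age_category", AGE_CATEGORIES),
    "work_type": ("work_type", WORK_TYPES),
}


@dataclass(frozen=True)
class PopulationGrade:
    """Letter grade for a set of individuals plus the bin distribution."""

    category: Optional[str]
    n_individuals: int
    n_excluded: int
    threshold_pct: float
    bin_percentages: dict  # letter (worst->best) -> %
    cumulative_percentages: dict
    grade: str


def _score_values(scores: Iterable) -> tuple:
    """Split scores into complete float values and an excluded count."""
    values, excluded = [], 0
    for s in scores:
        if isinstance(s, CategoryScore):
            if s.complete and s.score is not None:
                values.append(s.score)
            else:
                excluded += 1
        elif s is None:
            excluded += 1
        else:
            values.append(float(s))
    return values, excluded


def population_grade(
    scores: Iterable,
    threshold_pct: float = DEFAULT_THRESHOLD_PCT,
    scale: GradeScale = DEFAULT_SCALE,
    category: Optional[str] = None,
) -> PopulationGrade:
    """Aggregate individual category scores into one population grade.

    ``scores`` may be :class:`CategoryScore` objects (incomplete ones are
    excluded and counted) or plain numbers.
    """
    values, excluded = _score_values(scores)
    n = len(values)
    if n == 0:
        raise EquiwagError("population_grade needs at least one complete score")
    counts = {letter: 0 for letter in scale.letters}
    for v in values:
        counts[scale.grade_of(v)] += 1
    threshold = Fraction(str(threshold_pct))
    bin_pct, cum_pct = {}, {}
    cum_count = 0
    grade = None
    for letter in scale.letters:  # worst -> best
        cum_count += counts[letter]
        bin_pct[letter] = 100.0 * counts[letter] / n
        cum_pct[letter] = 100.0 * cum_count / n
        if grade is None and Fraction(100 * cum_count, n) >= threshold:
            grade = letter
    return PopulationGrade(
        category=category,
        n_individuals=n,
        n_excluded=excluded,
        threshold_pct=float(threshold_pct),
        bin_percentages=bin_pct,
        cumulative_percentages=cum_pct,
        grade=grade,
    )


@dataclass
class GradeMatrix:
    """Stratified grade table: one row per stratum, one column per category."""

    frame: pd.DataFrame  # index (indicator, level), columns CATEGORIES
    stratum_sizes: dict = field(default_factory=dict)  # (indicator, level) -> n records
    min_stratum_n: int = DEFAULT_MIN_STRATUM_N
    details: dict = field(default_factory=dict)  # (indicator, level, category) -> PopulationGrade


def grade_matrix(
    rs: RecordSet,
    cfg: ScoreConfig = ScoreConfig(),
    scale: GradeScale = DEFAULT_SCALE,
    threshold_pct: float = DEFAULT_THRESHOLD_PCT,
    min_stratum_n: int = DEFAULT_MIN_STRATUM_N,
    indicators: Iterable[str] = tuple(STRATUM_INDICATORS),
) -> GradeMatrix:
    """Population grades for every demographic stratum and welfare category.

    Strata smaller than ``min_stratum_n`` records are reported as excluded
    rather than graded (small groups lack the data for a stable grade).
    """
    for ind in indicators:
        if ind not in STRATUM_INDICATORS:
            raise EquiwagError(f"unknown indicator {ind!r}")
    specs = {cat: rs.schema.category_spec(cat) for cat in CATEGORIES}
    per_record = {
        cat: [category_score(r, spec, cfg) for r in rs] for cat, spec in specs.items()
    }

    strata = [("overall", "Overall", np.ones(len(rs), dtype=bool))]
    for ind in indicators:
        attr, vocab = STRATUM_INDICATORS[ind]
        values = np.array([getattr(r, attr) for r in rs], dtype=object)
        for level in vocab:
            mask = values == level
            if mask.any():
                strata.append((ind, level, mask))

    rows, sizes, details = {}, {}, {}
    for ind, level, mask in strata:
        n_records = int(mask.sum())
        sizes[(ind, level)] = n_records
        row = {}
        for cat in CATEGORIES:
            if n_records < min_stratum_n:
                row[cat] = f"excluded (n<{min_stratum_n})"
                continue
            scores = [s for s, keep in zip(per_record[cat], mask) if keep]
            complete = [s for s in scores if s.complete]
            if not complete:
                row[cat] = "no data"
                continue
            pg = population_grade(scores, threshold_pct, scale, category=cat)
            details[(ind, level, cat)] = pg
            row[cat] = pg.grade
        rows[(ind, level)] = row

    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(CATEGORIES))
    frame.index = pd.MultiIndex.from_tuples(frame.index, names=["indicator", "stratum"])
    return GradeMatrix(frame=frame, stratum_sizes=sizes, min_stratum_n=min_stratum_n, details=details)


def response_table(
    rs: RecordSet,
    question_id: str,
    by: str = "species",
    decimals: Optional[int] = 1,
) -> pd.DataFrame:
    """Percentage of answered individuals giving each response, by group.

    Mirrors the survey report layout: one row per response (with its welfare
    level), one column per group plus an overall column.  Percentages are
    over individuals that answered the question; for multi-select questions
    an individual counts once per selected response, so columns may sum to
    more than 100.
    """
    q = rs.schema.question(question_id)
    if by not in STRATUM_INDICATORS:
        raise EquiwagError(f"unknown indicator {by!r}")
    attr, vocab = STRATUM_INDICATORS[by]
    answered = [r for r in rs if r.responses.get(question_id)]
    groups = [g for g in vocab if any(getattr(r, attr) == g for r in answered)]

    def pct_column(records):
        n = len(records)
        col = {}
        for resp in q.vocabulary:
            count = sum(1 for r in records if resp in r.responses[question_id])
            col[resp] = 100.0 * count / n if n else float("nan")
        return col

    data = {g: pct_column([r for r in answered if getattr(r, attr) == g]) for g in groups}
    data["Overall (%)"] = pct_column(answered)
    frame = pd.DataFrame(data, index=list(q.vocabulary))
    frame.insert(0, "welfare_level", [q.level_of(r) for r in q.vocabulary])
    frame.index.name = "response"
    if decimals is not None:
        num = frame.columns.drop("welfare_level")
        frame[num] = frame[num].round(decimals)  # round-half-even
    return frame


@dataclass
class DriverReport:
    """Poor-welfare drivers of one category: per-question level proportions."""

    category: str
    frame: pd.DataFrame  # index question_id, columns n_answered / pct_bad / pct_medium / pct_good
    ranking: tuple  # question ids, worst driver first


def driver_report(rs: RecordSet, category: str, cfg: ScoreConfig = ScoreConfig()) -> DriverReport:
    """Rank a category's questions by the share of individuals at poor welfare.

    The primary sort key is the percentage of individuals at the *bad* level,
    the secondary key the percentage at *medium*; ties keep schema order.
    Alternate questions stand in for unanswered mains, as in scoring.
    """
    spec = rs.schema.category_spec(category)
    tallies = {}  # question_id actually used -> Counter of levels
    order = []
    for main in spec.mains:
        for r in rs:
            question, responses = resolve_question(r, spec, main)
            if responses is None:
                continue
            level = welfare_level(question, responses, rule=cfg.multiselect_rule)
            qid = question.question_id
            if qid not in tallies:
                tallies[qid] = {"bad": 0, "medium": 0, "good": 0, "n": 0}
                order.append(qid)
            tallies[qid][level] += 1
            tallies[qid]["n"] += 1
    rows = {}
    for qid in order:
        t = tallies[qid]
        n = t["n"]
        rows[qid] = {
            "n_answered": n,
            "pct_bad": 100.0 * t["bad"] / n,
            "pct_medium": 100.0 * t["medium"] / n,
            "pct_good": 100.0 * t["good"] / n,
        }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "question_id"
    ranking = tuple(
        sorted(order, key=lambda qid: (-rows[qid]["pct_bad"], -rows[qid]["pct_medium"], order.index(qid)))
    )
    frame = frame.loc[list(ranking)]
    return DriverReport(category=category, frame=frame, ranking=ranking)
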