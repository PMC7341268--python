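"""Data model, controlled vocabularies, validation and CSV I/O for
equid welfare assessment records.

An assessment record describes one working equid: where it was assessed
(district, brick kiln), its demography (species, sex, age category, work
type), who handles it, and its responses to the welfare indicator
questionnaire.  The questionnaire is described by a machine-readable schema
(:class:`Schema`) of :class:`QuestionSpec` entries: five welfare categories
(nutrition, health, behaviour, housing, working), each with four main
questions and, for some, an alternate question used when the main one cannot
be answered in the field.

Vocabulary matching is deliberately forgiving on the way in — survey exports
are noisy — and canonical on the way out: values are matched after trimming,
case-folding and dash normalisation, and stored exactly as the shipped
schema spells them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
import yaml

from .errors import SchemaError, ValidationError

WELFARE_LEVELS = ("bad", "medium", "good")  # worst -> best
CATEGORIES = ("nutrition", "health", "behaviour", "housing", "working")

DISTRICTS = ("Dhading", "Lalitpur")
SPECIES = ("donkey", "horse", "mule")
SEXES = ("female", "gelding", "jack/stallion/entire")
AGE_CATEGORIES = ("foal", "juvenile", "young adult", "adult", "geriatric")
WORK_TYPES = ("pack", "vehicle")
HANDLER_ATTITUDES = (
    "Relaxed and confident",
    "Cautious/fearful",
    "Assertive/indifferent",
    "Aggressive",
)

DEMOGRAPHY_COLUMNS = (
    "equid_id",
    "kiln_id",
    "district",
    "species",
    "sex",
    "age_category",
    "work_type",
    "handler_id",
    "handler_attitude",
)

MULTISELECT_DELIMITER = ";"

_WS = re.compile(r"\s+")


def normalize_token(value: str) -> str:
    """Normalisation key used for case-insensitive vocabulary matching."""
    value = value.replace("–", "-").replace("—", "-")
    return _WS.sub(" ", value).strip().casefold()


@dataclass(frozen=True)
class QuestionSpec:
    """One welfare indicator question and its response vocabulary."""

    question_id: str
    prompt: str
    category: str
    role: str = "main"  # "main" | "alternate"
    alternate_for: Optional[str] = None
    multiselect: bool = False
    level_map: Mapping[str, str] = field(default_factory=dict)
    # Responses that must not co-occur with any other response (the
    # "no findings" options of multi-select questions).
    exclusive: frozenset = frozenset()

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise SchemaError(f"{self.question_id}: unknown category {self.category!r}")
        if self.role not in ("main", "alternate"):
            raise SchemaError(f"{self.question_id}: unknown role {self.role!r}")
        if self.role == "alternate" and not self.alternate_for:
            raise SchemaError(f"{self.question_id}: alternate without alternate_for")
        bad_levels = set(self.level_map.values()) - set(WELFARE_LEVELS)
        if bad_levels:
            raise SchemaError(f"{self.question_id}: unknown welfare level(s) {sorted(bad_levels)}")
        keys = [normalize_token(r) for r in self.level_map]
        if len(keys) != len(set(keys)):
            raise SchemaError(f"{self.question_id}: duplicate response strings in level_map")
        unknown_excl = set(self.exclusive) - set(self.level_map)
        if unknown_excl:
            raise SchemaError(f"{self.question_id}: exclusive responses not in vocabulary: {sorted(unknown_excl)}")
        # Frozen canonical lookup, built once.
        object.__setattr__(self, "_lookup", {normalize_token(r): r for r in self.level_map})

    @property
    def vocabulary(self) -> tuple:
        """Canonical response strings, in schema order."""
        return tuple(self.level_map)

    def canonical(self, raw: str) -> Optional[str]:
        """Return the canonical spelling of ``raw``, or None if unknown."""
        return self._lookup.get(normalize_token(raw))

    def level_of(self, response: str) -> str:
        return self.level_map[response]


@dataclass(frozen=True)
class CategorySpec:
    """A welfare category: its four main questions plus their alternates."""

    category: str
    mains: tuple  # four QuestionSpec, schema order
    alternates: Mapping[str, QuestionSpec]  # main question_id -> alternate


class Schema:
    """Ordered collection of :class:`QuestionSpec` with structural checks."""

    def __init__(self, questions: Iterable[QuestionSpec], multiselect_delimiter: str = MULTISELECT_DELIMITER):
        self.questions = tuple(questions)
        self.multiselect_delimiter = multiselect_delimiter
        self._by_id = {}
        for q in self.questions:
            if q.question_id in self._by_id:
                raise SchemaError(f"duplicate question_id {q.question_id!r}")
            self._by_id[q.question_id] = q
        for q in self.questions:
            if q.role == "alternate":
                main = self._by_id.get(q.alternate_for)
                if main is None or main.role != "main":
                    raise SchemaError(
                        f"{q.question_id}: alternate_for {q.alternate_for!r} is not a main question"
                    )
                if main.category != q.category:
                    raise SchemaError(
                        f"{q.question_id}: alternate crosses categories "
                        f"({q.category} vs {main.category})"
                    )
        for cat in CATEGORIES:
            n_main = sum(1 for q in self.questions if q.category == cat and q.role == "main")
            if n_main != 4:
                raise SchemaError(f"category {cat!r} has {n_main} main questions, expected 4")

    def __iter__(self):
        return iter(self.questions)

    def __contains__(self, question_id: str) -> bool:
        return question_id in self._by_id

    def question(self, question_id: str) -> QuestionSpec:
        try:
            return self._by_id[question_id]
        except KeyError:
            raise SchemaError(f"unknown question_id {question_id!r}") from None

    def question_ids(self) -> tuple:
        return tuple(q.question_id for q in self.questions)

    def category_spec(self, category: str) -> CategorySpec:
        if category not in CATEGORIES:
            raise SchemaError(f"unknown category {category!r}")
        mains = tuple(q for q in self.questions if q.category == category and q.role == "main")
        alternates = {
            q.alternate_for: q
            for q in self.questions
            if q.category == category and q.role == "alternate"
        }
        return CategorySpec(category=category, mains=mains, alternates=alternates)


@dataclass(frozen=True)
class EARSRecord:
    """One assessed equid: demography, handler fields and responses.

    ``responses`` maps question_id to a frozenset of canonical response
    strings; a question the assessor could not answer is simply absent from
    the mapping (never present with an empty set).
    """

    equid_id: str
    kiln_id: str
    district: str
    species: str
    sex: str
    age_category: str
    work_type: str
    handler_id: str
    handler_attitude: Optional[str]
    responses: Mapping[str, frozenset]


@dataclass(frozen=True)
class Issue:
    """One validation problem: the field it concerns and why."""

    field: str
    message: str

    def __str__(self) -> str:
        return f"{self.field}: {self.message}"


def _check_vocab(value, vocab, field_name, issues, allow_missing=False):
    if value is None or value == "":
        if not allow_missing:
            issues.append(Issue(field_name, "missing value"))
        return
    if value not in vocab:
        issues.append(Issue(field_name, f"unknown value {value!r}"))


def validate_record(record: EARSRecord, schema: Schema) -> list:
    """Return every invariant violation in ``record`` (empty list if valid)."""
    issues: list = []
    if not record.equid_id:
        issues.append(Issue("equid_id", "missing value"))
    _check_vocab(record.district, DISTRICTS, "district", issues)
    _check_vocab(record.species, SPECIES, "species", issues)
    _check_vocab(record.sex, SEXES, "sex", issues)
    _check_vocab(record.age_category, AGE_CATEGORIES, "age_category", issues)
    _check_vocab(record.work_type, WORK_TYPES, "work_type", issues)
    _check_vocab(record.handler_attitude, HANDLER_ATTITUDES, "handler_attitude", issues, allow_missing=True)
    for qid, resp in record.responses.items():
        if qid not in schema:
            issues.append(Issue(qid, "unknown question"))
            continue
        q = schema.question(qid)
        if len(resp) == 0:
            issues.append(Issue(qid, "empty response set (omit the question instead)"))
            continue
        unknown = [r for r in resp if r not in q.level_map]
        for r in unknown:
            issues.append(Issue(qid, f"unknown response {r!r}"))
        if not q.multiselect and len(resp) > 1:
            issues.append(Issue(qid, f"{len(resp)} responses to a single-select question"))
        if q.multiselect and len(resp) > 1:
            clash = resp & q.exclusive
            if clash:
                issues.append(
                    Issue(qid, f"exclusive response {sorted(clash)[0]!r} combined with other responses")
                )
    return issues


class RecordSet:
    """An ordered, schema-bound collection of assessment records."""

    def __init__(self, records: Iterable[EARSRecord], schema: Schema):
        self.records = tuple(records)
        self.schema = schema
        seen = set()
        for r in self.records:
            if r.equid_id in seen:
                raise ValidationError([Issue("equid_id", f"duplicate {r.equid_id!r}")])
            seen.add(r.equid_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, RecordSet)
            and self.records == other.records
            and self.schema.question_ids() == other.schema.question_ids()
        )

    def validate(self) -> list:
        """All issues across all records, as (equid_id, Issue) pairs."""
        out = []
        for r in self.records:
            for issue in validate_record(r, self.schema):
                out.append((r.equid_id, issue))
        return out


# ---------------------------------------------------------------------------
# schema file I/O


def _schema_from_mapping(payload: Mapping) -> Schema:
    try:
        raw_questions = payload["questions"]
    except (KeyError, TypeError):
        raise SchemaError("schema file must contain a 'questions' list") from None
    questions = []
    for entry in raw_questions:
        questions.append(
            QuestionSpec(
                question_id=str(entry["id"]),
                prompt=str(entry.get("prompt", entry["id"])),
                category=str(entry["category"]),
                role=str(entry.get("role", "main")),
                alternate_for=entry.get("alternate_for"),
                multiselect=bool(entry.get("multiselect", False)),
                level_map={str(k): str(v) for k, v in entry["levels"].items()},
                exclusive=frozenset(str(r) for r in entry.get("exclusive", ())),
            )
        )
    return Schema(questions, multiselect_delimiter=str(payload.get("multiselect_delimiter", MULTISELECT_DELIMITER)))


def load_schema(path) -> Schema:
    """Load a question schema from a YAML (or JSON) file."""
    with open(path, "r", encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    return _schema_from_mapping(payload)


def default_schema() -> Schema:
    """The shipped 22-question WAG schema (20 mains + 2 alternates)."""
    ref = resources.files("equiwag").joinpath("data/wag_schema.yaml")
    payload = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return _schema_from_mapping(payload)


# ---------------------------------------------------------------------------
# record CSV I/O


def _match_closed(raw: str, vocab: tuple) -> Optional[str]:
    key = normalize_token(raw)
    for v in vocab:
        if normalize_token(v) == key:
            return v
    return None


def load_records(path, schema: Optional[Schema] = None) -> RecordSet:
    """Read assessment records from CSV and validate them against ``schema``.

    Multi-select cells are split on the schema's delimiter; values are matched
    to the controlled vocabularies case-insensitively after whitespace
    trimming and stored canonically.  Raises :class:`ValidationError` listing
    every rejected row with its row number and reason; a missing mandatory
    column raises :class:`SchemaError`.
    """
    schema = schema or default_schema()
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in DEMOGRAPHY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    question_cols = [qid for qid in schema.question_ids() if qid in frame.columns]

    records = []
    issues = []
    seen_ids = set()
    for pos, row in enumerate(frame.to_dict("records"), start=2):  # 1-based incl. header
        rec_issues = []

        def closed(colname, vocab, allow_missing=False):
            raw = row.get(colname, "").strip()
            if raw == "":
                if not allow_missing:
                    rec_issues.append(Issue(colname, "missing value"))
                return None
            value = _match_closed(raw, vocab)
            if value is None:
                rec_issues.append(Issue(colname, f"unknown value {raw!r}"))
            return value

        equid_id = row["equid_id"].strip()
        if not equid_id:
            rec_issues.append(Issue("equid_id", "missing value"))
        elif equid_id in seen_ids:
            rec_issues.append(Issue("equid_id", f"duplicate {equid_id!r}"))

        district = closed("district", DISTRICTS)
        species = closed("species", SPECIES)
        sex = closed("sex", SEXES)
        age_category = closed("age_category", AGE_CATEGORIES)
        work_type = closed("work_type", WORK_TYPES)
        handler_attitude = closed("handler_attitude", HANDLER_ATTITUDES, allow_missing=True)

        responses = {}
        for qid in question_cols:
            cell = row[qid].strip()
            if cell == "":
                continue
            q = schema.question(qid)
            parts = [p for p in (s.strip() for s in cell.split(schema.multiselect_delimiter)) if p]
            canon = []
            for p in parts:
                c = q.canonical(p)
                if c is None:
                    rec_issues.append(Issue(qid, f"unknown response {p!r}"))
                else:
                    canon.append(c)
            if not q.multiselect and len(parts) > 1:
                rec_issues.append(Issue(qid, f"{len(parts)} responses to a single-select question"))
            if q.multiselect and len(canon) > 1 and set(canon) & q.exclusive:
                rec_issues.append(
                    Issue(qid, "exclusive response combined with other responses")
                )
            if canon:
                responses[qid] = frozenset(canon)

        if rec_issues:
            issues.extend((f"row {pos}", i) for i in rec_issues)
            continue
        seen_ids.add(equid_id)
        records.append(
            EARSRecord(
                equid_id=equid_id,
                kiln_id=row["kiln_id"].strip(),
                district=district,
                species=species,
                sex=sex,
                age_category=age_category,
                work_type=work_type,
                handler_id=row["handler_id"].strip(),
                handler_attitude=handler_attitude,
                responses=responses,
            )
        )
    if issues:
        raise ValidationError([Issue(f"{where} {i.field}", i.message) for where, i in issues])
    return RecordSet(records, schema)


def records_frame(rs: RecordSet) -> pd.DataFrame:
    """RecordSet as a DataFrame in the canonical column order."""
    schema = rs.schema
    rows = []
    for r in rs:
        row = {
            "equid_id": r.equid_id,
            "kiln_id": r.kiln_id,
            "district": r.district,
            "species": r.species,
            "sex": r.sex,
            "age_category": r.age_category,
            "work_type": r.work_type,
            "handler_id": r.handler_id,
            "handler_attitude": r.handler_attitude or "",
        }
        for q in schema:
            resp = r.responses.get(q.question_id)
            if not resp:
                row[q.question_id] = ""
            else:
                ordered = [v for v in q.vocabulary if v in resp]
                row[q.question_id] = schema.multiselect_delimiter.join(ordered)
        rows.append(row)
    columns = list(DEMOGRAPHY_COLUMNS) + list(schema.question_ids())
    return pd.DataFrame(rows, columns=columns)


def write_records(rs: RecordSet, path) -> None:
    """Write a RecordSet to CSV (UTF-8, deterministic column order).

    Multi-select responses are joined with the schema delimiter in
    vocabulary order, so ``load_records(write_records(rs)) == rs``.
    """
    frame = records_frame(rs)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, encoding="utf-8")
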