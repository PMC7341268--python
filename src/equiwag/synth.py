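"""Seeded generator of synthetic equid welfare survey populations.

The generator produces :class:`~equiwag.schema.RecordSet` populations with
exact, configured demography (strata counts are deterministic — only the
questionnaire responses are random) and per-stratum marginal response
distributions.  ``study_mimic_config`` (alias ``paper_mimic_config``)
encodes the Nepalese brick-kiln survey population: 2,448 equids (55
donkeys, 1,365 horses, 1,028 mules) across 41 kilns in two districts
worked by 126 handlers, with per-species response marginals matching the
published summary tables.

Sampling model
--------------
* Single-select questions: one categorical draw per record from the
  stratum's (renormalised) probability vector.
* Multi-select questions: the exclusive "no findings" response is drawn
  first with its configured probability; records without it include each
  remaining response as an independent Bernoulli with conditional
  probability p_r / (1 - p_exclusive); a record that ends up with no
  response at all is repaired by drawing exactly one response from the
  renormalised non-exclusive vector (a questionnaire cannot record an
  empty finding list).  ``implied_marginals`` gives the closed-form
  per-response marginal this model actually produces.
* Questions without a configured marginal are left unanswered (this is how
  the two unanswerable main questions trigger their alternates).
* Dependence hooks override a response's probability inside one class of a
  single-select "class" question (e.g. boost a fear sign among equids of
  aggressive handlers), giving the class-description analysis a non-null
  regime to detect.

Responses are drawn independently across questions: the generator
reproduces marginal distributions, not the survey's unknown joint
structure.

Seeding is counter-based: question draws for stratum *i*, question *j* use
``default_rng([seed, i, j])``, so streams are independent across strata —
changing one stratum's count leaves every other stratum's draws unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigError
from .schema import (
    AGE_CATEGORIES,
    DISTRICTS,
    EARSRecord,
    QuestionSpec,
    RecordSet,
    SEXES,
    SPECIES,
    Schema,
    WORK_TYPES,
    default_schema,
)

__all__ = [
    "StratumSpec",
    "DependenceHook",
    "SynthConfig",
    "generate_population",
    "study_mimic_config",
    "paper_mimic_config",
    "marginal_check",
    "implied_marginals",
]


@dataclass(frozen=True)
class StratumSpec:
    district: str
    species: str
    sex: str
    age_category: str
    work_type: str
    count: int


@dataclass(frozen=True)
class DependenceHook:
    """Boost one response's probability inside one class of records."""

    class_question: str
    class_value: str
    question: str
    response: str
    boost_pct: float  # added percentage points on the response probability


@dataclass(frozen=True)
class SynthConfig:
    strata: Tuple[StratumSpec, ...]
    kilns: Dict[str, int]  # district -> number of kilns
    handlers: Dict[str, int]  # district -> number of handlers
    # question_id -> {response: prob} or {species: {response: prob}}
    marginals: Dict[str, dict]
    hooks: Tuple[DependenceHook, ...] = ()
    seed: int = 0
    kiln_size_range: Tuple[int, int] = (8, 64)


# ---------------------------------------------------------------------------
# deterministic integer allocation


def largest_remainder(total: int, weights) -> list:
    """Partition ``total`` into integer parts proportional to ``weights``.

    Largest-remainder (Hamilton) apportionment; ties broken by index, so
    the split is deterministic.
    """
    weights = np.asarray(weights, dtype=float)
    if total < 0 or (weights < 0).any() or weights.sum() <= 0:
        raise ConfigError("largest_remainder", "total and weights must be nonnegative, weights nonzero")
    shares = total * weights / weights.sum()
    floors = np.floor(shares).astype(int)
    remainder = total - floors.sum()
    order = np.argsort(-(shares - floors), kind="stable")
    floors[order[:remainder]] += 1
    return floors.tolist()


def _kiln_sizes(total: int, n_kilns: int, lo: int, hi: int, where: str) -> list:
    if not (n_kilns * lo <= total <= n_kilns * hi):
        raise ConfigError(
            where,
            f"{total} equids cannot fill {n_kilns} kilns with sizes in [{lo}, {hi}]",
        )
    return largest_remainder(total, [1.0] * n_kilns)


# ---------------------------------------------------------------------------
# config validation


def _is_per_species(marginal: dict) -> bool:
    return bool(marginal) and set(marginal) <= set(SPECIES)


def validate_config(cfg: SynthConfig, schema: Schema) -> None:
    """Raise :class:`ConfigError` naming the offending field path."""
    if not cfg.strata:
        raise ConfigError("strata", "at least one stratum required")
    for i, s in enumerate(cfg.strata):
        path = f"strata[{i}]"
        if s.count <= 0:
            raise ConfigError(f"{path}.count", f"must be positive, got {s.count}")
        for name, value, vocab in (
            ("district", s.district, DISTRICTS),
            ("species", s.species, SPECIES),
            ("sex", s.sex, SEXES),
            ("age_category", s.age_category, AGE_CATEGORIES),
            ("work_type", s.work_type, WORK_TYPES),
        ):
            if value not in vocab:
                raise ConfigError(f"{path}.{name}", f"unknown value {value!r}")
    lo, hi = cfg.kiln_size_range
    for district in sorted({s.district for s in cfg.strata}):
        if cfg.kilns.get(district, 0) <= 0:
            raise ConfigError(f"kilns[{district}]", "district needs at least one kiln")
        if cfg.handlers.get(district, 0) <= 0:
            raise ConfigError(f"handlers[{district}]", "district needs at least one handler")
        total = sum(s.count for s in cfg.strata if s.district == district)
        _kiln_sizes(total, cfg.kilns[district], lo, hi, f"kilns[{district}]")

    for qid, marginal in cfg.marginals.items():
        if qid not in schema:
            raise ConfigError(f"marginals[{qid}]", "unknown question")
        q = schema.question(qid)
        variants = marginal.values() if _is_per_species(marginal) else [marginal]
        keys = marginal.keys() if _is_per_species(marginal) else [None]
        for key, vec in zip(keys, variants):
            path = f"marginals[{qid}]" + (f"[{key}]" if key else "")
            for resp, p in vec.items():
                if resp not in q.level_map:
                    raise ConfigError(path, f"response {resp!r} outside vocabulary")
                if not (0.0 <= p <= 1.0):
                    raise ConfigError(path, f"probability {p} for {resp!r} outside [0, 1]")
            if not q.multiselect and abs(sum(vec.values()) - 1.0) > 1e-9:
                raise ConfigError(path, f"probabilities sum to {sum(vec.values())}, expected 1")

    for i, h in enumerate(cfg.hooks):
        path = f"hooks[{i}]"
        if h.class_question not in schema or schema.question(h.class_question).multiselect:
            raise ConfigError(f"{path}.class_question", "must be a single-select schema question")
        if h.class_value not in schema.question(h.class_question).level_map:
            raise ConfigError(f"{path}.class_value", f"unknown response {h.class_value!r}")
        if h.question not in schema:
            raise ConfigError(f"{path}.question", f"unknown question {h.question!r}")
        if h.response not in schema.question(h.question).level_map:
            raise ConfigError(f"{path}.response", f"unknown response {h.response!r}")
        if not (0 < h.boost_pct <= 100):
            raise ConfigError(f"{path}.boost_pct", "must be in (0, 100]")


# ---------------------------------------------------------------------------
# response sampling


def _marginal_for(cfg: SynthConfig, qid: str, species: str) -> Optional[dict]:
    marginal = cfg.marginals.get(qid)
    if marginal is None:
        return None
    if _is_per_species(marginal):
        return marginal.get(species)
    return marginal


def _split_exclusive(q: QuestionSpec, marginal: dict):
    vocab = list(q.vocabulary)
    p = np.array([marginal.get(r, 0.0) for r in vocab])
    excl = np.array([r in q.exclusive for r in vocab])
    return vocab, p, excl


def implied_marginals(q: QuestionSpec, marginal: dict) -> dict:
    """Per-response marginal the sampler actually produces for ``q``.

    Identical to the configured vector for single-select questions (after
    renormalisation); for multi-select questions it accounts for the
    empty-set repair step.
    """
    vocab, p, excl = _split_exclusive(q, marginal)
    if not q.multiselect:
        return dict(zip(vocab, (p / p.sum()).tolist()))
    p_excl = min(1.0, p[excl].sum())
    out = {}
    not_excl = 1.0 - p_excl
    p_non = np.where(excl, 0.0, p)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_cond = np.clip(np.where(not_excl > 0, p_non / not_excl, 0.0), 0.0, 1.0)
    p_empty = float(np.prod(1.0 - p_cond[~excl])) if (~excl).any() else 1.0
    renorm = p_non / p_non.sum() if p_non.sum() > 0 else np.zeros_like(p_non)
    for i, r in enumerate(vocab):
        if excl[i]:
            out[r] = float(p[i])
        else:
            out[r] = float(not_excl * (p_cond[i] + p_empty * renorm[i]))
    return out


def _draw_single(rng: np.random.Generator, n: int, q: QuestionSpec, marginal: dict) -> list:
    vocab = list(q.vocabulary)
    p = np.array([marginal.get(r, 0.0) for r in vocab])
    p = p / p.sum()
    idx = rng.choice(len(vocab), size=n, p=p)
    return [frozenset((vocab[i],)) for i in idx]


def _draw_multi(rng: np.random.Generator, n: int, q: QuestionSpec, marginal: dict) -> list:
    vocab, p, excl = _split_exclusive(q, marginal)
    p_excl_total = min(1.0, float(p[excl].sum()))
    excl_idx = np.flatnonzero(excl & (p > 0))
    non_idx = np.flatnonzero(~excl)

    is_excl = rng.random(n) < p_excl_total
    # which exclusive response (usually there is exactly one)
    chosen_excl = np.zeros(n, dtype=int)
    if excl_idx.size:
        pe = p[excl_idx] / p[excl_idx].sum()
        chosen_excl = rng.choice(excl_idx, size=n, p=pe)

    not_excl = 1.0 - p_excl_total
    with np.errstate(divide="ignore", invalid="ignore"):
        p_cond = np.clip(np.where(not_excl > 0, p / not_excl, 0.0), 0.0, 1.0)
    member = np.zeros((n, len(vocab)), dtype=bool)
    for j in non_idx:
        member[:, j] = rng.random(n) < p_cond[j]

    sets = []
    p_non = np.where(excl, 0.0, p)
    renorm = p_non / p_non.sum() if p_non.sum() > 0 else None
    empty_rows = [i for i in range(n) if not is_excl[i] and not member[i, non_idx].any()]
    fallback = {}
    if empty_rows:
        if renorm is not None:
            picks = rng.choice(len(vocab), size=len(empty_rows), p=renorm)
            fallback = dict(zip(empty_rows, picks))
        elif excl_idx.size:
            fallback = {i: chosen_excl[i] for i in empty_rows}
        else:
            raise ConfigError(f"marginals[{q.question_id}]", "no positive response probability")
    for i in range(n):
        if is_excl[i] and excl_idx.size:
            sets.append(frozenset((vocab[chosen_excl[i]],)))
        else:
            chosen = [vocab[j] for j in non_idx if member[i, j]]
            if not chosen:
                chosen = [vocab[fallback[i]]]
            sets.append(frozenset(chosen))
    return sets


def _boosted(marginal: dict, q: QuestionSpec, response: str, boost_pct: float) -> dict:
    out = dict(marginal)
    delta = boost_pct / 100.0
    new_p = min(1.0, out.get(response, 0.0) + delta)
    if q.multiselect:
        out[response] = new_p
        return out
    # single-select: take the added mass proportionally from the other responses
    old_p = out.get(response, 0.0)
    others = {r: p for r, p in out.items() if r != response}
    total_others = sum(others.values())
    scale = (1.0 - new_p) / total_others if total_others > 0 else 0.0
    out = {r: p * scale for r, p in others.items()}
    out[response] = new_p
    return out


# ---------------------------------------------------------------------------
# population generation


def generate_population(cfg: SynthConfig, schema: Optional[Schema] = None) -> RecordSet:
    """Generate a validated RecordSet from ``cfg`` (deterministic per seed)."""
    schema = schema or default_schema()
    validate_config(cfg, schema)

    question_ids = list(schema.question_ids())
    q_index = {qid: j for j, qid in enumerate(question_ids)}
    hook_class_questions = [h.class_question for h in cfg.hooks]
    # class questions must be drawn before the questions they influence
    draw_order = [qid for qid in question_ids if qid in hook_class_questions]
    draw_order += [qid for qid in question_ids if qid not in draw_order]

    # responses per stratum
    stratum_responses = []  # list of dict qid -> list[frozenset|None]
    for s_idx, stratum in enumerate(cfg.strata):
        n = stratum.count
        responses: dict = {}
        for qid in draw_order:
            q = schema.question(qid)
            marginal = _marginal_for(cfg, qid, stratum.species)
            if marginal is None:
                continue
            rng = np.random.default_rng([cfg.seed, s_idx, q_index[qid]])
            draw = _draw_multi if q.multiselect else _draw_single
            sets = draw(rng, n, q, marginal)
            for hook in cfg.hooks:
                if hook.question != qid:
                    continue
                class_resp = responses.get(hook.class_question)
                if class_resp is None:
                    continue
                mask = [hook.class_value in cr for cr in class_resp]
                n_hooked = int(np.sum(mask))
                if n_hooked == 0:
                    continue
                boosted = _boosted(marginal, q, hook.response, hook.boost_pct)
                redraw = draw(rng, n_hooked, q, boosted)
                it = iter(redraw)
                sets = [next(it) if m else orig for orig, m in zip(sets, mask)]
            responses[qid] = sets
        stratum_responses.append(responses)

    # deterministic demography: kilns, handlers, identifiers
    district_order = [d for d in DISTRICTS if any(s.district == d for s in cfg.strata)]
    kiln_ids: Dict[str, list] = {}
    kiln_capacity: Dict[str, list] = {}
    kiln_handlers: Dict[str, dict] = {}
    lo, hi = cfg.kiln_size_range
    for district in district_order:
        total = sum(s.count for s in cfg.strata if s.district == district)
        n_kilns = cfg.kilns[district]
        sizes = _kiln_sizes(total, n_kilns, lo, hi, f"kilns[{district}]")
        tag = district[:3].upper()
        kiln_ids[district] = [f"{tag}-K{j + 1:02d}" for j in range(n_kilns)]
        kiln_capacity[district] = sizes
        handlers_per_kiln = largest_remainder(cfg.handlers[district] - n_kilns, sizes)
        h_counter = 0
        kiln_handlers[district] = {}
        for j, kid in enumerate(kiln_ids[district]):
            n_h = 1 + handlers_per_kiln[j]  # at least one handler per kiln
            kiln_handlers[district][kid] = [f"{tag}-H{h_counter + m + 1:03d}" for m in range(n_h)]
            h_counter += n_h

    kiln_cursor = {d: 0 for d in district_order}  # index of current kiln
    kiln_fill = {d: 0 for d in district_order}  # records already in current kiln
    kiln_rr = {}  # kiln_id -> round-robin handler position

    records = []
    eq_counter = 0
    for s_idx, stratum in enumerate(cfg.strata):
        responses = stratum_responses[s_idx]
        for i in range(stratum.count):
            district = stratum.district
            while kiln_fill[district] >= kiln_capacity[district][kiln_cursor[district]]:
                kiln_cursor[district] += 1
                kiln_fill[district] = 0
            kid = kiln_ids[district][kiln_cursor[district]]
            kiln_fill[district] += 1
            handlers = kiln_handlers[district][kid]
            pos = kiln_rr.get(kid, 0)
            handler_id = handlers[pos % len(handlers)]
            kiln_rr[kid] = pos + 1

            rec_responses = {
                qid: sets[i] for qid, sets in responses.items() if sets[i]
            }
            attitude_resp = rec_responses.get("handler_interaction")
            eq_counter += 1
            records.append(
                EARSRecord(
                    equid_id=f"EQ{eq_counter:05d}",
                    kiln_id=kid,
                    district=district,
                    species=stratum.species,
                    sex=stratum.sex,
                    age_category=stratum.age_category,
                    work_type=stratum.work_type,
                    handler_id=handler_id,
                    handler_attitude=next(iter(attitude_resp)) if attitude_resp else None,
                    responses=rec_responses,
                )
            )
    return RecordSet(records, schema)


# ---------------------------------------------------------------------------
# study-mimic configuration
#
# Per-species response marginals, in percent, transcribed from the published
# survey summary tables.  Printed columns that do not sum to 100 (rounding,
# and the multi-select feed question whose denominator convention differs)
# are renormalised for single-select questions and used as per-response
# Bernoulli probabilities for multi-select ones.

_T = {"donkey": 0, "horse": 1, "mule": 2}


def _per_species(table: dict) -> dict:
    """{response: (donkey, horse, mule) pct} -> per-species prob dicts."""
    return {
        sp: {resp: vals[_T[sp]] / 100.0 for resp, vals in table.items()}
        for sp in SPECIES
    }


STUDY_MARGINALS_PCT = {
    "body_condition": {
        "Very thin/poor": (1.9, 9.1, 2.1),
        "Thin/moderate": (58.5, 50.0, 42.3),
        "Ideal": (37.7, 38.8, 53.4),
        "Fat": (1.9, 2.2, 2.2),
        "Very fat": (0.0, 0.0, 0.0),
    },
    "diet": {
        "Pasture": (25.8, 27.4, 27.4),
        "Vitamins/minerals": (8.3, 10.9, 10.9),
        "Browse": (6.9, 3.5, 2.6),
        "Straw/stover": (0.5, 0.6, 0.9),
        "Chopped fibre/chaff": (0.0, 1.1, 0.7),
        "Hay": (0.0, 0.4, 0.6),
        "Haylage": (0.0, 0.1, 0.2),
        "Straights": (16.1, 15.1, 14.4),
        "Creep feed": (5.5, 2.8, 2.8),
        "Legumes/pulses": (3.2, 1.9, 1.2),
        "Cereal grains": (10.6, 9.9, 10.8),
        "Mix/muesli": (5.5, 9.8, 10.8),
        "Silage": (0.0, 0.2, 0.5),
    },
    "water_access_working": {
        "Free access": (0.0, 2.7, 4.5),
        "Limited access": (95.7, 96.5, 94.0),
        "No access": (4.3, 0.8, 1.5),
    },
    "water_point_housed": {
        "Free access": (0.0, 2.2, 1.6),
        "Limited access": (96.1, 97.3, 98.3),
        "No access": (3.9, 0.5, 0.1),
    },
    "lameness": {
        "No lameness": (90.7, 93.8, 93.6),
        "Lame but still moving": (5.6, 5.7, 6.0),
        "Severely lame": (3.7, 0.5, 0.4),
    },
    "coat_condition": {
        "Yes": (91.5, 88.8, 92.4),
        "No": (8.5, 11.2, 7.6),
    },
    "skin_alterations": {
        "No signs present": (40.3, 41.4, 36.1),
        "Scars": (19.4, 27.9, 33.7),
        "Alopecia": (18.1, 16.8, 21.2),
        "Swellings": (4.2, 1.3, 1.2),
        "Open wounds": (18.1, 12.0, 7.4),
        "Sarcoids": (0.0, 0.7, 0.4),
    },
    "illness_signs": {
        "No signs present": (61.1, 80.3, 88.4),
        "Eye discharge": (11.1, 11.4, 5.9),
        "Nasal discharge": (19.4, 6.9, 4.7),
        "Signs of diarrhoea": (8.3, 0.5, 0.3),
        "Discharge (penis or vulva)": (0.0, 0.2, 0.3),
        "Abdominal pain": (0.0, 0.7, 0.4),
    },
    "harmful_practices": {
        "No": (61.4, 60.0, 56.3),
        "Limb tethering or hobbling": (31.6, 37.6, 42.5),
        "Amputations or mutilations": (3.5, 0.1, 0.1),
        "Firing and hot branding": (3.5, 0.2, 0.2),
        "Rope noseband": (0.0, 0.0, 0.1),
    },
    "general_attitude": {
        "At ease": (83.6, 76.6, 70.1),
        "Alert and active": (14.5, 21.1, 26.5),
        "Agitated, aggressive": (0.0, 1.1, 1.1),
        "Apathetic, depressed, withdrawn": (1.8, 1.3, 2.3),
    },
    "fear_signs": {
        "No signs of fear and distress present": (75.0, 77.7, 72.9),
        "Head shyness": (10.0, 5.2, 3.8),
        "Unpredictable or sudden movements": (8.3, 8.2, 9.1),
        "Showing the whites of the eyes": (0.0, 5.1, 9.3),
        "Sudden startle responses": (3.3, 1.4, 1.2),
        "Aggressive behaviour": (1.7, 2.1, 3.2),
        "Trembling": (1.7, 0.4, 0.3),
    },
    "handler_interaction": {
        "Relaxed and confident": (91.4, 92.8, 90.4),
        "Cautious/fearful": (0.0, 6.9, 9.0),
        "Assertive/indifferent": (8.6, 0.0, 0.0),
        "Aggressive": (0.0, 0.4, 0.6),
    },
    "working_hours": {
        "Less than or equal to 3 h": (1.8, 0.1, 0.0),
        "More than 3, less than or equal to 6 h": (8.8, 5.2, 5.5),
        "More than 6, less than or equal to 9 h": (86.0, 94.2, 93.5),
        "More than 9 h": (1.8, 0.6, 0.9),
    },
    "working_days": {
        "5 days or less": (1.8, 1.2, 0.7),
        "6 days": (91.1, 84.6, 86.4),
        "7 days": (7.1, 14.2, 12.9),
    },
    "rest_breaks": {
        "Yes, equipment removed": (1.8, 13.3, 7.3),
        "Yes, equipment not removed": (76.4, 72.5, 84.8),
        "No": (21.8, 14.2, 7.9),
    },
    "shade_access": {
        "Access to shade": (37.2, 23.8, 23.4),
        "Limited access to shade": (58.1, 72.4, 73.6),
        "No access to shade": (4.7, 3.7, 2.9),
    },
    "housing_regime": {
        "Stabled equid - access to field": (30.5, 26.0, 24.6),
        "Kept outside - access to shelter": (0.0, 0.8, 0.1),
        "Indoor housing": (69.5, 73.1, 75.0),
        "Kept outside - no access to shelter": (0.0, 0.0, 0.0),
    },
    "environment_clean": {
        "Yes": (65.5, 74.9, 85.3),
        "No": (34.5, 25.1, 14.7),
    },
    "stable_dimensions": {
        "Satisfactory": (61.0, 69.8, 85.4),
        "Not-Satisfactory": (39.0, 30.2, 14.6),
    },
    "lying_area": {
        "Yes": (44.1, 70.7, 82.7),
        "No": (55.9, 29.3, 17.3),
    },
}

STUDY_TOTALS = {"donkey": 55, "horse": 1365, "mule": 1028}
STUDY_KILNS = {"Dhading": 24, "Lalitpur": 17}
STUDY_HANDLERS = {"Dhading": 58, "Lalitpur": 68}

# Mixes shown only graphically in the survey report (no printed counts);
# chosen to respect the reported orderings: geldings > stallions > females,
# young adults most frequent, pack animals the majority, foals rare.
SEX_MIX = {"female": 0.09, "gelding": 0.60, "jack/stallion/entire": 0.31}
AGE_MIX = {"foal": 0.002, "juvenile": 0.14, "young adult": 0.45, "adult": 0.308, "geriatric": 0.10}
WORK_MIX = {"pack": 0.72, "vehicle": 0.28}


def _normalised_marginals(schema: Schema) -> dict:
    marginals = {}
    for qid, table in STUDY_MARGINALS_PCT.items():
        q = schema.question(qid)
        per_sp = _per_species(table)
        if not q.multiselect:
            for sp, vec in per_sp.items():
                total = sum(vec.values())
                per_sp[sp] = {r: p / total for r, p in vec.items()}
        marginals[qid] = per_sp
    return marginals


def study_mimic_config(seed: int = 0, schema: Optional[Schema] = None) -> SynthConfig:
    """Configuration reproducing the surveyed brick-kiln population.

    Species totals, kiln and handler counts are exact; districts receive
    equids proportionally to their kiln counts; sex, age and work-type mixes
    follow the reported orderings.  All integer splits use largest-remainder
    apportionment, so the demography is deterministic.
    """
    schema = schema or default_schema()
    strata = []
    for species in SPECIES:
        district_counts = largest_remainder(
            STUDY_TOTALS[species], [STUDY_KILNS[d] for d in DISTRICTS]
        )
        for district, d_count in zip(DISTRICTS, district_counts):
            sex_counts = largest_remainder(d_count, list(SEX_MIX.values()))
            for sex, s_count in zip(SEX_MIX, sex_counts):
                age_counts = largest_remainder(s_count, list(AGE_MIX.values()))
                for age, a_count in zip(AGE_MIX, age_counts):
                    work_counts = largest_remainder(a_count, list(WORK_MIX.values()))
                    for work, w_count in zip(WORK_MIX, work_counts):
                        if w_count > 0:
                            strata.append(
                                StratumSpec(district, species, sex, age, work, w_count)
                            )
    return SynthConfig(
        strata=tuple(strata),
        kilns=dict(STUDY_KILNS),
        handlers=dict(STUDY_HANDLERS),
        marginals=_normalised_marginals(schema),
        hooks=(),
        seed=seed,
    )


paper_mimic_config = study_mimic_config


def with_seed(cfg: SynthConfig, seed: int) -> SynthConfig:
    return replace(cfg, seed=seed)


# ---------------------------------------------------------------------------
# marginal diagnostics


def marginal_check(rs: RecordSet, cfg: SynthConfig) -> pd.DataFrame:
    """Empirical-vs-configured marginal deviations per question.

    ``max_abs_dev_pct`` is the largest |empirical − configured| percentage
    over responses (and species groups, when the marginal is per-species).
    ``flagged`` marks questions whose empirical marginal strays more than
    three binomial standard errors from the marginal the sampler is
    *designed* to produce (``implied_marginals``), which for single-select
    questions equals the configured vector.
    """
    schema = rs.schema
    rows = {}
    for qid, marginal in cfg.marginals.items():
        q = schema.question(qid)
        groups = (
            [(sp, marginal[sp]) for sp in SPECIES if sp in marginal]
            if _is_per_species(marginal)
            else [(None, marginal)]
        )
        max_dev = 0.0
        flagged = False
        for sp, vec in groups:
            recs = [r for r in rs if (sp is None or r.species == sp) and r.responses.get(qid)]
            n = len(recs)
            if n == 0:
                continue
            implied = implied_marginals(q, vec)
            for resp in q.vocabulary:
                emp = sum(1 for r in recs if resp in r.responses[qid]) / n
                max_dev = max(max_dev, abs(emp - vec.get(resp, 0.0)) * 100.0)
                target = implied[resp]
                se = math.sqrt(max(target * (1.0 - target), 0.0) / n)
                if abs(emp - target) > 3.0 * se + 1e-12:
                    flagged = True
        rows[qid] = {"max_abs_dev_pct": max_dev, "flagged": flagged}
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "question_id"
    return frame
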