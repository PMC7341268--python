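import pytest

from equiwag import (
    EARSRecord,
    RecordSet,
    default_schema,
    generate_population,
    study_mimic_config,
)
from equiwag.synth import with_seed


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def mimic_rs(schema):
    """The study-mimic synthetic population at a fixed seed."""
    return generate_population(with_seed(study_mimic_config(schema=schema), 1), schema)


def make_record(schema, equid_id="EQ1", levels=None, **overrides):
    """A fully answered record whose responses realise the given welfare
    levels per question (default: everything good)."""
    level_target = levels or {}
    responses = {}
    for q in schema:
        if q.role == "alternate":
            continue
        if q.question_id in ("fibre_availability", "age_started_working"):
            # mimic the field situation: mains unanswered, alternates answered
            continue
        want = level_target.get(q.question_id, "good")
        choice = next(r for r in q.vocabulary if q.level_of(r) == want)
        responses[q.question_id] = frozenset((choice,))
    for q in schema:
        if q.role == "alternate":
            want = level_target.get(
                q.question_id, level_target.get(q.alternate_for, "good")
            )
            choice = next(r for r in q.vocabulary if q.level_of(r) == want)
            responses[q.question_id] = frozenset((choice,))
    responses.update(
        {k: frozenset(v) for k, v in overrides.pop("responses", {}).items()}
    )
    fields = dict(
        equid_id=equid_id,
        kiln_id="DHA-K01",
        district="Dhading",
        species="horse",
        sex="gelding",
        age_category="adult",
        work_type="pack",
        handler_id="DHA-H001",
        handler_attitude="Relaxed and confident",
        responses=responses,
    )
    fields.update(overrides)
    return EARSRecord(**fields)


def small_synth_cfg(schema, seed=0, n_per_stratum=40, hooks=()):
    """A compact generator config reusing the study-mimic marginals."""
    from dataclasses import replace

    from equiwag.synth import StratumSpec, study_mimic_config

    base = study_mimic_config(schema=schema)
    strata = (
        StratumSpec("Dhading", "horse", "gelding", "adult", "pack", n_per_stratum),
        StratumSpec("Dhading", "mule", "female", "young adult", "vehicle", n_per_stratum),
        StratumSpec("Lalitpur", "donkey", "jack/stallion/entire", "adult", "pack", n_per_stratum),
    )
    return replace(
        base,
        strata=strata,
        kilns={"Dhading": 2, "Lalitpur": 1},
        handlers={"Dhading": 4, "Lalitpur": 2},
        hooks=tuple(hooks),
        seed=seed,
    )


@pytest.fixture()
def small_rs(schema):
    """Six fully answered records spanning both districts and all species."""
    recs = [
        make_record(schema, "EQ1"),
        make_record(schema, "EQ2", species="mule"),
        make_record(schema, "EQ3", species="donkey", district="Lalitpur", kiln_id="LAL-K01"),
        make_record(schema, "EQ4", sex="female", levels={"body_condition": "medium"}),
        make_record(schema, "EQ5", work_type="vehicle", levels={"lameness": "bad"}),
        make_record(schema, "EQ6", age_category="geriatric", handler_attitude="Aggressive",
                    levels={"handler_interaction": "bad"}),
    ]
    return RecordSet(recs, schema)
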