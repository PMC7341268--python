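"""Synthetic population generator: determinism, exact demography, marginals."""

from collections import Counter
from dataclasses import replace

import numpy as np
import pytest

from equiwag import generate_population, marginal_check, study_mimic_config
from equiwag.errors import ConfigError
from equiwag.schema import records_frame
from equiwag.synth import (
    DependenceHook,
    StratumSpec,
    SynthConfig,
    implied_marginals,
    largest_remainder,
    validate_config,
    with_seed,
)

from conftest import small_synth_cfg


class TestLargestRemainder:
    def test_partitions_exactly(self):
        assert sum(largest_remainder(2448, [24, 17])) == 2448
        assert largest_remainder(10, [1, 1, 1]) == [4, 3, 3]

    def test_degenerate_weight(self):
        assert largest_remainder(7, [1.0, 0.0]) == [7, 0]


class TestStudyMimicDemography:
    def test_exact_printed_totals(self, mimic_rs):
        assert len(mimic_rs) == 2448
        species = Counter(r.species for r in mimic_rs)
        assert species == {"horse": 1365, "mule": 1028, "donkey": 55}
        assert len({r.kiln_id for r in mimic_rs}) == 41
        assert len({r.handler_id for r in mimic_rs}) == 126

    def test_kiln_sizes_within_observed_range(self, mimic_rs):
        sizes = Counter(r.kiln_id for r in mimic_rs)
        assert min(sizes.values()) >= 8 and max(sizes.values()) <= 64

    def test_district_kiln_split(self, mimic_rs):
        kilns = {}
        for r in mimic_rs:
            kilns.setdefault(r.district, set()).add(r.kiln_id)
        assert len(kilns["Dhading"]) == 24 and len(kilns["Lalitpur"]) == 17

    def test_unanswered_mains_trigger_alternates(self, mimic_rs):
        assert all("fibre_availability" not in r.responses for r in mimic_rs)
        assert all("water_point_housed" in r.responses for r in mimic_rs)

    def test_handler_attitude_mirrors_question(self, mimic_rs):
        for r in list(mimic_rs)[:200]:
            assert {r.handler_attitude} == set(r.responses["handler_interaction"])


class TestDeterminism:
    def test_same_seed_same_population(self, schema):
        cfg = small_synth_cfg(schema, seed=9)
        rs1 = generate_population(cfg, schema)
        rs2 = generate_population(cfg, schema)
        assert rs1 == rs2
        assert records_frame(rs1).equals(records_frame(rs2))

    def test_different_seed_differs(self, schema):
        rs1 = generate_population(small_synth_cfg(schema, seed=1), schema)
        rs2 = generate_population(small_synth_cfg(schema, seed=2), schema)
        assert rs1 != rs2

    def test_stream_independence_across_strata(self, schema):
        """Growing one stratum leaves the other strata's draws unchanged."""
        cfg = small_synth_cfg(schema, seed=4, n_per_stratum=30)
        bigger = replace(
            cfg, strata=(replace(cfg.strata[0], count=60),) + cfg.strata[1:]
        )
        rs_a = generate_population(cfg, schema)
        rs_b = generate_population(bigger, schema)
        resp_a = [r.responses for r in rs_a][30:]  # strata 2 and 3
        resp_b = [r.responses for r in rs_b][60:]
        assert resp_a == resp_b


class TestResponseSampling:
    def test_degenerate_marginal(self, schema):
        cfg = small_synth_cfg(schema, seed=0)
        cfg = replace(
            cfg,
            marginals={"working_days": {"7 days": 1.0}},
        )
        rs = generate_population(cfg, schema)
        assert all(r.responses["working_days"] == frozenset({"7 days"}) for r in rs)

    def test_single_select_frequencies_within_3se(self, schema):
        n = 10000
        cfg = SynthConfig(
            strata=(StratumSpec("Dhading", "horse", "gelding", "adult", "pack", n),),
            kilns={"Dhading": 200},
            handlers={"Dhading": 220},
            marginals={
                "lameness": {
                    "No lameness": 0.7,
                    "Lame but still moving": 0.2,
                    "Severely lame": 0.1,
                }
            },
            seed=123,
        )
        rs = generate_population(cfg, schema)
        counts = Counter(next(iter(r.responses["lameness"])) for r in rs)
        for resp, p in cfg.marginals["lameness"].items():
            se = np.sqrt(p * (1 - p) / n)
            assert abs(counts[resp] / n - p) <= 3 * se

    def test_exclusive_responses_never_co_occur(self, mimic_rs):
        for r in mimic_rs:
            for qid in ("skin_alterations", "illness_signs", "fear_signs", "harmful_practices"):
                resp = r.responses[qid]
                q = mimic_rs.schema.question(qid)
                if resp & q.exclusive:
                    assert len(resp) == 1

    def test_dependence_hook_boosts_class_marginal(self, schema):
        hook = DependenceHook(
            "handler_interaction", "Relaxed and confident", "fear_signs", "Head shyness", 30.0
        )
        cfg = small_synth_cfg(schema, seed=2, n_per_stratum=400, hooks=(hook,))
        cfg = replace(cfg, kilns={"Dhading": 15, "Lalitpur": 8}, handlers={"Dhading": 20, "Lalitpur": 10})
        rs = generate_population(cfg, schema)
        inside = [r for r in rs if r.handler_attitude == "Relaxed and confident"]
        outside = [r for r in rs if r.handler_attitude != "Relaxed and confident"]
        p_in = np.mean(["Head shyness" in r.responses["fear_signs"] for r in inside])
        p_out = np.mean(["Head shyness" in r.responses["fear_signs"] for r in outside])
        assert p_in - p_out > 0.15  # planted ~30-point boost


class TestMarginalCheck:
    def test_degenerate_marginal_zero_deviation(self, schema):
        cfg = replace(
            small_synth_cfg(schema, seed=0),
            marginals={"working_days": {"7 days": 1.0}},
        )
        rs = generate_population(cfg, schema)
        chk = marginal_check(rs, cfg)
        assert chk.loc["working_days", "max_abs_dev_pct"] == 0.0
        assert not chk.loc["working_days", "flagged"]

    def test_mismatched_config_is_flagged(self, schema):
        cfg = replace(
            small_synth_cfg(schema, seed=0, n_per_stratum=120),
            kilns={"Dhading": 4, "Lalitpur": 2},
            handlers={"Dhading": 6, "Lalitpur": 3},
            marginals={"working_days": {"6 days": 0.9, "7 days": 0.1}},
        )
        rs = generate_population(cfg, schema)
        wrong = replace(cfg, marginals={"working_days": {"6 days": 0.2, "7 days": 0.8}})
        chk = marginal_check(rs, wrong)
        assert chk.loc["working_days", "flagged"]

    def test_implied_equals_configured_for_single_select(self, schema):
        q = schema.question("working_days")
        marginal = {"5 days or less": 0.2, "6 days": 0.5, "7 days": 0.3}
        assert implied_marginals(q, marginal) == pytest.approx(marginal)

    def test_multiselect_implied_marginals_match_empirical(self, schema):
        """The closed-form sampler marginal agrees with a large sample."""
        n = 20000
        cfg = SynthConfig(
            strata=(StratumSpec("Dhading", "mule", "gelding", "adult", "pack", n),),
            kilns={"Dhading": 400},
            handlers={"Dhading": 410},
            marginals={
                "skin_alterations": {
                    "No signs present": 0.4,
                    "Scars": 0.3,
                    "Alopecia": 0.2,
                    "Open wounds": 0.05,
                }
            },
            seed=7,
        )
        rs = generate_population(cfg, schema)
        implied = implied_marginals(
            schema.question("skin_alterations"), cfg.marginals["skin_alterations"]
        )
        for resp, target in implied.items():
            emp = sum(1 for r in rs if resp in r.responses["skin_alterations"]) / n
            se = np.sqrt(max(target * (1 - target), 1e-9) / n)
            assert abs(emp - target) <= 4 * se, resp


class TestConfigValidation:
    def test_bad_probability_vector(self, schema):
        cfg = replace(
            small_synth_cfg(schema),
            marginals={"working_days": {"6 days": 0.5, "7 days": 0.2}},
        )
        with pytest.raises(ConfigError, match=r"marginals\[working_days\]"):
            validate_config(cfg, schema)

    def test_unknown_stratum_species(self, schema):
        cfg = small_synth_cfg(schema)
        cfg = replace(cfg, strata=(replace(cfg.strata[0], species="zebra"),) + cfg.strata[1:])
        with pytest.raises(ConfigError, match=r"strata\[0\]\.species"):
            validate_config(cfg, schema)

    def test_kiln_capacity_infeasible(self, schema):
        cfg = replace(small_synth_cfg(schema, n_per_stratum=4), kilns={"Dhading": 2, "Lalitpur": 1})
        with pytest.raises(ConfigError, match=r"kilns\[Dhading\].*cannot fill"):
            validate_config(cfg, schema)

    def test_hook_field_paths(self, schema):
        hook = DependenceHook("handler_interaction", "Serene", "fear_signs", "Head shyness", 20.0)
        cfg = small_synth_cfg(schema, hooks=(hook,))
        with pytest.raises(ConfigError, match=r"hooks\[0\]\.class_value"):
            validate_config(cfg, schema)
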