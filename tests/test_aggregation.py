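"""Population grading, stratified matrices, response tables, driver ranking."""

import numpy as np
import pytest

from equiwag import RecordSet, driver_report, grade_matrix, population_grade, response_table
from equiwag.aggregation import STRATUM_INDICATORS
from equiwag.errors import EquiwagError
from equiwag.schema import CATEGORIES
from equiwag.scoring import DEFAULT_SCALE

from conftest import make_record

ATTAINABLE = sorted({a + b + c + d for a in (1, 12.5, 25) for b in (1, 12.5, 25)
                     for c in (1, 12.5, 25) for d in (1, 12.5, 25)})


def oracle_population_grade(values, threshold_pct=15.0):
    """Independent brute force: bin by explicit interval scan, accumulate
    counts worst->best, first bin whose cumulative count reaches threshold."""
    letters = list("JIHGFEDCBA")
    edges = [10, 20, 30, 40, 50, 60, 70, 80, 90, 100]
    counts = [0] * 10
    for v in values:
        for i, hi in enumerate(edges):
            if v <= hi:
                counts[i] += 1
                break
    cum = 0
    for letter, c in zip(letters, counts):
        cum += c
        if cum * 100 >= threshold_pct * len(values):
            return letter
    raise AssertionError("unreachable")


class TestPopulationGrade:
    def test_single_bin_population(self):
        assert population_grade([100.0] * 100).grade == "A"

    def test_threshold_reached_exactly(self):
        assert population_grade([5.0] * 15 + [95.0] * 85).grade == "J"

    def test_threshold_just_missed(self):
        assert population_grade([5.0] * 14 + [95.0] * 86).grade == "A"

    def test_matches_brute_force_on_random_populations(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(1, 200))
            values = rng.choice(ATTAINABLE, size=n)
            assert population_grade(values).grade == oracle_population_grade(values)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        values = list(rng.choice(ATTAINABLE, size=80))
        ref = population_grade(values)
        for _ in range(5):
            rng.shuffle(values)
            pg = population_grade(values)
            assert pg.grade == ref.grade and pg.bin_percentages == ref.bin_percentages

    def test_monotone_in_individual_scores(self):
        rng = np.random.default_rng(6)
        order = DEFAULT_SCALE.letters
        for _ in range(200):
            values = list(rng.choice(ATTAINABLE, size=int(rng.integers(2, 60))))
            before = population_grade(values).grade
            i = int(rng.integers(len(values)))
            higher = [v for v in ATTAINABLE if v > values[i]]
            if not higher:
                continue
            values[i] = float(rng.choice(higher))
            after = population_grade(values).grade
            assert order.index(after) >= order.index(before)

    def test_bin_and_cumulative_invariants(self):
        pg = population_grade([5.0, 15.0, 15.0, 95.0])
        assert abs(sum(pg.bin_percentages.values()) - 100.0) < 1e-9
        cum = list(pg.cumulative_percentages.values())
        assert cum == sorted(cum) and abs(cum[-1] - 100.0) < 1e-9

    def test_fractional_threshold_edge(self):
        # 14.999% in the worst bin must not trigger a 15% threshold
        n = 100000
        k = 14999
        assert population_grade([5.0] * k + [95.0] * (n - k)).grade == "A"
        assert population_grade([5.0] * 15000 + [95.0] * (n - 15000)).grade == "J"

    def test_empty_input_errors(self):
        with pytest.raises(EquiwagError):
            population_grade([])


class TestGradeMatrix:
    def test_single_stratum_matches_population_grade(self, schema):
        recs = [make_record(schema, f"EQ{i}") for i in range(8)]
        rs = RecordSet(recs, schema)
        gm = grade_matrix(rs)
        from equiwag import score_records

        for cat in CATEGORIES:
            expected = population_grade(score_records(rs)[cat]).grade
            assert gm.frame.loc[("overall", "Overall"), cat] == expected

    def test_small_stratum_excluded(self, schema):
        recs = [make_record(schema, f"EQ{i}") for i in range(8)]
        recs += [make_record(schema, f"F{i}", age_category="foal") for i in range(3)]
        gm = grade_matrix(RecordSet(recs, schema), min_stratum_n=5)
        row = gm.frame.loc[("age_category", "foal")]
        assert all(cell == "excluded (n<5)" for cell in row)

    def test_mimic_matrix_shape(self, mimic_rs):
        gm = grade_matrix(mimic_rs)
        assert list(gm.frame.columns) == list(CATEGORIES)
        indicators = gm.frame.index.get_level_values("indicator")
        assert set(indicators) == {"overall"} | set(STRATUM_INDICATORS)
        # stratum sizes within each indicator partition the population
        for ind in STRATUM_INDICATORS:
            total = sum(n for (i, _), n in gm.stratum_sizes.items() if i == ind)
            assert total == len(mimic_rs)

    def test_unknown_indicator_errors(self, small_rs):
        with pytest.raises(EquiwagError):
            grade_matrix(small_rs, indicators=("altitude",))


class TestResponseTable:
    def test_uniform_response_is_100pct(self, schema):
        recs = [make_record(schema, f"EQ{i}") for i in range(4)]
        tbl = response_table(RecordSet(recs, schema), "water_access_working")
        assert tbl.loc["Free access", "Overall (%)"] == 100.0

    def test_even_split(self, schema):
        recs = [
            make_record(schema, f"EQ{i}", responses={
                "water_access_working": {"Limited access" if i < 2 else "No access"}
            })
            for i in range(4)
        ]
        tbl = response_table(RecordSet(recs, schema), "water_access_working")
        assert tbl.loc["Limited access", "Overall (%)"] == 50.0
        assert tbl.loc["No access", "Overall (%)"] == 50.0

    def test_multiselect_counts_individuals_per_response(self, schema):
        recs = [
            make_record(schema, "EQ1", responses={"skin_alterations": {"Scars", "Alopecia"}}),
            make_record(schema, "EQ2", responses={"skin_alterations": {"Scars"}}),
        ]
        tbl = response_table(RecordSet(recs, schema), "skin_alterations")
        assert tbl.loc["Scars", "Overall (%)"] == 100.0
        assert tbl.loc["Alopecia", "Overall (%)"] == 50.0
        # columns may exceed 100 in total for multi-select questions
        assert tbl["Overall (%)"].sum() > 100.0

    def test_mimic_tables_close_to_configured_marginals(self, mimic_rs, schema):
        """Single-select empirical percentages track the generator's inputs."""
        from equiwag.synth import study_mimic_config

        cfg = study_mimic_config(schema=schema)
        tbl = response_table(mimic_rs, "working_days", decimals=None)
        for sp in ("horse", "mule"):
            for resp, p in cfg.marginals["working_days"][sp].items():
                n_sp = sum(1 for r in mimic_rs if r.species == sp)
                se = 100.0 * np.sqrt(p * (1 - p) / n_sp)
                assert abs(tbl.loc[resp, sp] - 100.0 * p) <= max(3.0 * se, 0.75)


class TestDriverReport:
    def test_all_good_population_keeps_input_order(self, schema):
        recs = [make_record(schema, f"EQ{i}") for i in range(6)]
        dr = driver_report(RecordSet(recs, schema), "housing")
        assert (dr.frame["pct_bad"] == 0).all()
        spec_order = [q.question_id for q in schema.category_spec("housing").mains]
        assert list(dr.ranking) == spec_order

    def test_universally_bad_question_ranks_first(self, schema):
        recs = [
            make_record(schema, f"EQ{i}", levels={"environment_clean": "bad"})
            for i in range(6)
        ]
        dr = driver_report(RecordSet(recs, schema), "housing")
        assert dr.ranking[0] == "environment_clean"
        assert dr.frame.loc["environment_clean", "pct_bad"] == 100.0

    def test_matches_brute_force_recount(self, mimic_rs):
        from equiwag.scoring import resolve_question, welfare_level

        for cat in CATEGORIES:
            dr = driver_report(mimic_rs, cat)
            spec = mimic_rs.schema.category_spec(cat)
            for main in spec.mains:
                counts = {"bad": 0, "medium": 0, "good": 0}
                used_id = None
                for r in mimic_rs:
                    q, resp = resolve_question(r, spec, main)
                    if resp is None:
                        continue
                    used_id = q.question_id
                    counts[welfare_level(q, resp)] += 1
                if used_id is None:
                    continue
                n = sum(counts.values())
                assert dr.frame.loc[used_id, "pct_bad"] == pytest.approx(100.0 * counts["bad"] / n)
                assert dr.frame.loc[used_id, "pct_medium"] == pytest.approx(100.0 * counts["medium"] / n)
            # ranking is a permutation of the four used questions
            assert len(dr.ranking) == 4
            order = [dr.frame.loc[q, ["pct_bad", "pct_medium"]].tolist() for q in dr.ranking]
            assert order == sorted(order, reverse=True)
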