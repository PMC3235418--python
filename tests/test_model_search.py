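import json

import numpy as np
import pytest

from fuzzygrn import (
    DataValidationError,
    DomainError,
    NodeModel,
    SearchSpaceError,
    alternative_frequency,
    cod,
    count_models,
    exhaustive_search,
    load_models,
    model_edges,
    predict_node,
    predict_series,
    rule_sign,
    save_search_results,
)
from fuzzygrn.fuzzy_core import ACTIVATION, INHIBITION

from ._bruteforce import enumerate_ranked
from .conftest import dataset_from_normalized


class TestCod:
    def test_exact_match_scores_one(self):
        assert cod([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_constant_mean_predictor_scores_zero(self):
        obs = np.array([1.0, 2.0, 3.0, 6.0])
        assert cod(np.full(4, obs.mean()), obs) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        # SSE = 1, SST = 2 -> 1 - 1/2
        assert cod([1.0, 2.0, 4.0], [1.0, 2.0, 3.0]) == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(DataValidationError):
            cod([1.0, 2.0], [1.0, 1.0])


class TestPrediction:
    def test_identity_rule_reproduces_observed_series(self, rng):
        norm = rng.uniform(-0.8, 0.8, size=(2, 10))
        norm[1] = norm[0]  # gB is a perfect copy of gA
        ds = dataset_from_normalized(norm, ["gA", "gB"])
        m = NodeModel(output="gA", inputs=("gB",), rules=(ACTIVATION,))
        pred = predict_series(m, ds)
        np.testing.assert_allclose(pred, ds.log2_row("gA"), atol=1e-9)

    def test_inhibition_rule_is_negation_composition(self, small_dataset):
        m = NodeModel(output="gA", inputs=("gB",), rules=(INHIBITION,))
        pred = predict_series(m, small_dataset, scale="normalized")
        np.testing.assert_allclose(pred, -small_dataset.normalized_row("gB"),
                                   atol=1e-12)

    def test_two_input_worked_example(self):
        # inputs 0.684 (inhibition) and -0.125 (activation): combined triple
        # (0.809, 1.191, 0) -> centroid -0.4045..., then tangent back-transform
        ds = dataset_from_normalized([[0.684, 0.1], [-0.125, 0.2], [0.3, 0.4]],
                                     ["g1", "g3", "out"])
        m = NodeModel(output="out", inputs=("g1", "g3"),
                      rules=(INHIBITION, ACTIVATION))
        got = predict_node(m, ds, 0, scale="normalized")
        assert got == pytest.approx((0.0 - 0.809) / (0.809 + 1.191), abs=1e-9)

    def test_missing_input_rejected(self, small_dataset):
        m = NodeModel(output="gA", inputs=("nope",), rules=(ACTIVATION,))
        with pytest.raises(DataValidationError):
            predict_series(m, small_dataset)


class TestExhaustiveSearch:
    def test_model_count_formula(self, small_dataset):
        # 4 candidates, up to 2 inputs: 4*27 + 6*27^2 = 4482
        assert count_models(4, 2) == 4482
        res = exhaustive_search(small_dataset, "gA",
                                ["gB", "gC", "gD", "gA"], max_inputs=2,
                                lag=1, top_m=5)
        assert res.n_evaluated == 4482

    def test_planted_copy_recovered_with_identity_rule(self, rng):
        norm = rng.uniform(-0.8, 0.8, size=(3, 10))
        norm[1] = norm[0]  # "copy" mirrors the output exactly
        ds = dataset_from_normalized(norm, ["out", "copy", "decoy"])
        res = exhaustive_search(ds, "out", max_inputs=1, top_m=3)
        assert res.best.inputs == ("copy",)
        assert res.best.rules == (ACTIVATION,)
        assert res.best.fitness == pytest.approx(1.0, abs=1e-9)

    def test_matches_independent_bruteforce_ranking(self, rng):
        """The production search must agree model-for-model with a scalar
        enumerator written separately from the vectorized path."""
        norm = rng.uniform(-0.85, 0.85, size=(4, 9))
        ds = dataset_from_normalized(norm, ["out", "c1", "c2", "c3"])
        candidates = ["c1", "c2", "c3"]
        res = exhaustive_search(ds, "out", candidates, max_inputs=2,
                                top_m=3000)
        oracle = enumerate_ranked(
            {c: list(ds.normalized_row(c)) for c in candidates},
            list(ds.log2_row("out")), candidates, 2,
        )
        assert len(res.ranked_models) == len(oracle) == count_models(3, 2)
        for got, (fit, _, subset, rules) in zip(res.ranked_models, oracle):
            assert got.inputs == subset
            assert got.rules == rules
            assert got.fitness == pytest.approx(fit, abs=1e-9)

    def test_best_fitness_monotone_in_max_inputs(self, small_dataset):
        fits = [
            exhaustive_search(small_dataset, "gA", max_inputs=k, top_m=1,
                              lag=1).best.fitness
            for k in (1, 2, 3)
        ]
        assert fits[0] <= fits[1] <= fits[2]

    def test_deterministic_ranking(self, small_dataset):
        a = exhaustive_search(small_dataset, "gA", max_inputs=2, top_m=50)
        b = exhaustive_search(small_dataset, "gA", max_inputs=2, top_m=50)
        assert a.ranked_models == b.ranked_models
        assert a.input_frequency == b.input_frequency

    def test_lag0_excludes_self_lag1_permits_it(self, small_dataset):
        res0 = exhaustive_search(small_dataset, "gA", max_inputs=1, top_m=5)
        assert "gA" not in res0.candidates
        with pytest.raises(DomainError):
            exhaustive_search(small_dataset, "gA", ["gA", "gB"], max_inputs=1)
        res1 = exhaustive_search(small_dataset, "gA", max_inputs=1, top_m=5,
                                 lag=1)
        assert "gA" in res1.candidates

    def test_search_space_cap_refusal_includes_estimate(self, small_dataset):
        with pytest.raises(SearchSpaceError, match="max_inputs"):
            exhaustive_search(small_dataset, "gA", max_inputs=3,
                              model_cap=1000)

    def test_missing_time_points_dropped_listwise(self, rng):
        norm = rng.uniform(-0.8, 0.8, size=(3, 10))
        norm[1, 4] = np.nan  # one missing spot for candidate c1
        ds = dataset_from_normalized(norm, ["out", "c1", "c2"])
        res = exhaustive_search(ds, "out", ["c1", "c2"], max_inputs=1,
                                top_m=5)
        assert res.dropped_times == (4,)

    def test_homolog_pair_merged_before_fuzzification(self, rng):
        norm = rng.uniform(-0.8, 0.8, size=(4, 10))
        norm[1] = np.maximum(norm[2], norm[3])  # output copies the merge
        ds = dataset_from_normalized(norm, ["decoy", "out", "h1", "h2"])
        res = exhaustive_search(
            ds, "out", max_inputs=1, top_m=5,
            homolog_map={"h1/h2": ("h1", "h2")},
        )
        assert res.best.inputs == ("h1/h2",)
        assert res.best.rules == (ACTIVATION,)
        assert res.best.fitness == pytest.approx(1.0, abs=1e-9)


class TestAlternativeFrequency:
    def test_top1_is_indicator_of_best_models_inputs(self, small_dataset):
        res = exhaustive_search(small_dataset, "gA", max_inputs=2, top_m=50)
        f1 = alternative_frequency(res, 1)
        assert all(f1[c] == (1 if c in res.best.inputs else 0)
                   for c in res.candidates)

    def test_ubiquitous_input_counts_top_m(self, rng):
        norm = rng.uniform(-0.8, 0.8, size=(2, 10))
        ds = dataset_from_normalized(norm, ["out", "only"])
        res = exhaustive_search(ds, "out", ["only"], max_inputs=1, top_m=20)
        assert res.input_frequency["only"] == 20

    def test_requesting_more_than_stored_is_an_error(self, small_dataset):
        res = exhaustive_search(small_dataset, "gA", max_inputs=1, top_m=10)
        with pytest.raises(DataValidationError):
            alternative_frequency(res, 1000)


class TestEdgesAndSerialization:
    @pytest.mark.parametrize(
        ("rule", "sign"),
        [
            (ACTIVATION, "positive"),
            (INHIBITION, "negative"),
            ((2, 2, 2), "biphasic"),
            ((3, 1, 3), "biphasic"),
            ((1, 1, 1), "biphasic"),
            ((2, 2, 3), "positive"),  # saturating activation
        ],
    )
    def test_rule_sign_classification(self, rule, sign):
        assert rule_sign(rule) == sign

    def test_model_edges_rows(self):
        m = NodeModel(output="out", inputs=("a", "b"),
                      rules=(ACTIVATION, INHIBITION))
        assert model_edges([m]) == [("a", "out", "positive"),
                                    ("b", "out", "negative")]

    def test_save_load_round_trip(self, tmp_path, small_dataset):
        res = exhaustive_search(small_dataset, "gA", max_inputs=2, top_m=10)
        path = tmp_path / "fit.json"
        save_search_results([res], path, homolog_map={"x/y": ("x", "y")})
        best, hmap, payload = load_models(path)
        assert best == [res.best]
        assert hmap == {"x/y": ("x", "y")}
        stored = payload["results"][0]
        assert stored["input_frequency"] == res.input_frequency
        assert len(stored["models"]) == 10
        json.dumps(payload)  # schema is plain JSON
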