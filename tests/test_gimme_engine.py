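import numpy as np
import pytest

from metcoherence.expression_mapping import threshold_pattern
from metcoherence.gimme_engine import (DegenerateObjectiveError, fba_max,
                                       gimme, normalized_inconsistency,
                                       usage_frequency)
from metcoherence.media import Medium, apply_medium
from metcoherence.model_core import (INTERNAL_INF, add_objective_drain)

from conftest import build_model, chain_model, parallel_model, pattern_for
from oracles import fba_by_enumeration, gimme_by_enumeration


class TestFbaMax:
    def test_chain_optimum_equals_uptake_bound(self):
        v_max, flux = fba_max(chain_model(uptake=10.0))
        assert v_max == pytest.approx(10.0, abs=1e-8)
        assert flux["R1"] == pytest.approx(10.0, abs=1e-6)
        assert flux["EX_A"] == pytest.approx(-10.0, abs=1e-6)

    def test_dead_end_blocks_objective(self):
        model = build_model(
            {"A": "c", "B": "c", "D": "c"},
            [("EX_A", {"A": -1}, -10.0, INTERNAL_INF, None, True),
             ("R1", {"A": -1, "B": 1, "D": 1}, 0, INTERNAL_INF, None, False)])
        model = add_objective_drain(model, "B")
        v_max, _ = fba_max(model)
        assert v_max == pytest.approx(0.0, abs=1e-9)

    def test_all_blocked_medium_gives_zero(self):
        model = chain_model()
        blocked = apply_medium(model, Medium(bounds={"EX_A": (0.0, 0.0)}))
        v_max, _ = fba_max(blocked)
        assert v_max == pytest.approx(0.0, abs=1e-9)

    def test_matches_vertex_enumeration_on_toy(self):
        for model in (chain_model(), parallel_model()):
            ours, _ = fba_max(model)
            assert ours == pytest.approx(fba_by_enumeration(model), abs=1e-6)


class TestGimme:
    def test_single_absent_chain_gives_w_l_vmax(self):
        """One absent reaction on the only path: I = w * l * v_max exactly."""
        model = chain_model(uptake=10.0)
        pattern = pattern_for(model, {"R1": 1.0})
        result = gimme(model, pattern, level=0.8)
        assert result.inconsistency == pytest.approx(1.0 * 0.8 * 10.0,
                                                     abs=1e-6)
        assert [rid for rid, _, _ in result.inconsistency_vector] == ["R1"]
        assert result.objective_flux >= 0.8 * 10.0 - 1e-8

    def test_all_present_gives_zero_and_empty_vector(self):
        model = chain_model()
        result = gimme(model, pattern_for(model, {}), level=0.8)
        assert result.inconsistency == pytest.approx(0.0, abs=1e-9)
        assert result.inconsistency_vector == []

    def test_flux_routed_through_present_parallel_path(self):
        model = parallel_model()
        pattern = pattern_for(model, {"R_left": 2.0})
        result = gimme(model, pattern, level=0.8)
        assert result.inconsistency == pytest.approx(0.0, abs=1e-9)
        assert abs(result.flux["R_left"]) <= 1e-6
        assert result.flux["R_right"] >= 0.8 * 10.0 - 1e-6

    def test_degenerate_objective_raises(self):
        model = chain_model()
        blocked = apply_medium(model, Medium(bounds={"EX_A": (0.0, 0.0)}))
        with pytest.raises(DegenerateObjectiveError):
            gimme(blocked, pattern_for(model, {"R1": 1.0}), level=0.8)

    def test_inconsistency_vector_sums_to_objective(self, cohort_frame):
        for result in cohort_frame.attrs["results"][:10]:
            total = sum(w * f for _, f, w in result.inconsistency_vector)
            assert total == pytest.approx(result.inconsistency,
                                          rel=1e-6, abs=1e-6)

    def test_uniform_weight_mode(self):
        model = chain_model()
        pattern = pattern_for(model, {"R1": 0.25})
        weighted = gimme(model, pattern, level=0.8, weight_mode="deficit")
        uniform = gimme(model, pattern, level=0.8, weight_mode="uniform")
        assert weighted.inconsistency == pytest.approx(0.25 * 8.0, abs=1e-6)
        assert uniform.inconsistency == pytest.approx(8.0, abs=1e-6)

    @pytest.mark.parametrize("absent", [
        {"R1": 1.0},
        {"R1": 0.5, "R2": 2.0},
        {"R2": 0.3},
    ])
    def test_matches_vertex_enumeration_chain(self, absent):
        model = chain_model()
        pattern = pattern_for(model, absent)
        ours = gimme(model, pattern, level=0.8).inconsistency
        oracle = gimme_by_enumeration(model, pattern, level=0.8)
        assert ours == pytest.approx(oracle, abs=1e-6)

    @pytest.mark.parametrize("absent", [
        {"R_left": 1.0},
        {"R_left": 1.0, "R_right": 0.2},
        {"R_right": 1.5},
    ])
    def test_matches_vertex_enumeration_parallel(self, absent):
        model = parallel_model()
        pattern = pattern_for(model, absent)
        ours = gimme(model, pattern, level=0.8).inconsistency
        oracle = gimme_by_enumeration(model, pattern, level=0.8)
        assert ours == pytest.approx(oracle, abs=1e-6)

    def test_monotone_in_threshold(self, toy_model, toy_medium,
                                   cohort_analysis):
        """Lowering t shrinks the penalty terms, so I never increases."""
        constrained = cohort_analysis.constrained
        v_max = cohort_analysis.v_max
        rvals = cohort_analysis.reaction_values[0]
        previous = None
        for t in (2.6, 2.2, 1.8, 1.4, 1.0, 0.6):
            pattern = threshold_pattern(rvals, t)
            result = gimme(constrained, pattern, level=0.8, v_max=v_max)
            if previous is not None:
                assert result.inconsistency <= previous + 1e-8
            previous = result.inconsistency

    def test_zero_iff_present_path_exists(self):
        # absent reaction off the only path: I must be zero
        model = parallel_model()
        result = gimme(model, pattern_for(model, {"R_left": 1.0}), level=0.8)
        assert result.inconsistency == pytest.approx(0.0, abs=1e-9)
        # absent reaction on every path: I must be positive
        chain = chain_model()
        result = gimme(chain, pattern_for(chain, {"R2": 0.7}), level=0.8)
        assert result.inconsistency > 0


class TestNormalization:
    def test_arithmetic(self):
        model = chain_model()
        result = gimme(model, pattern_for(model, {"R1": 1.0}), level=0.8)
        assert normalized_inconsistency(result) == pytest.approx(
            result.inconsistency / result.objective_flux)

    def test_zero_inconsistency_normalizes_to_zero(self):
        model = chain_model()
        result = gimme(model, pattern_for(model, {}), level=0.8)
        assert normalized_inconsistency(result) == pytest.approx(0.0)

    def test_scaling_exchange_bounds_preserves_normalized_value(self):
        base = chain_model(uptake=10.0)
        pattern = pattern_for(base, {"R1": 1.0})
        reference = gimme(base, pattern, level=0.8)
        for c in (0.5, 2.0, 10.0):
            scaled = gimme(chain_model(uptake=10.0 * c), pattern, level=0.8)
            assert scaled.inconsistency == pytest.approx(
                c * reference.inconsistency, rel=1e-8)
            assert normalized_inconsistency(scaled) == pytest.approx(
                normalized_inconsistency(reference), abs=1e-8)


class TestUsageFrequency:
    def test_fraction_of_nonzero_flux(self):
        model = parallel_model()
        results = []
        for absent in ({"R_left": 1.0}, {"R_left": 1.0}, {"R_left": 1.0},
                       {"R_right": 1.0}, {"R_right": 1.0}, {"R_right": 1.0},
                       {"R_right": 1.0}, {"R_right": 1.0}, {"R_right": 1.0},
                       {"R_right": 1.0}):
            results.append(gimme(model, pattern_for(model, absent), level=0.8))
        assert usage_frequency(results, "R_left") == pytest.approx(0.7)
        assert usage_frequency(results, "ART_OBJ_B") == 1.0

    def test_unknown_reaction_warns_and_returns_zero(self, caplog):
        model = chain_model()
        results = [gimme(model, pattern_for(model, {}), level=0.8)]
        with caplog.at_level("WARNING"):
            assert usage_frequency(results, "missing") == 0.0
        assert "missing" in caplog.text
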