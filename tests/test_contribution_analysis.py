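import numpy as np
import pandas as pd
import pytest

from metcoherence.contribution_analysis import (MarkerAnalysis, MarkerConfig,
                                                assign_groups, cohort_table,
                                                classify_specificity,
                                                contribution_strength,
                                                contribution_table,
                                                topological_markers)
from metcoherence.expression_mapping import threshold_pattern
from metcoherence.media import Medium
from metcoherence.model_core import INTERNAL_INF, add_objective_drain

from conftest import build_model, chain_model, pattern_for


class TestAssignGroups:
    def test_below_mean_is_lig(self):
        assert assign_groups([5, 6, 7], [4]) == ["LIG"]

    def test_above_mean_is_hig(self):
        assert assign_groups([5, 6, 7], [8]) == ["HIG"]

    def test_tie_resolves_to_hig(self):
        assert assign_groups([5, 6, 7], [6]) == ["HIG"]

    def test_partition_is_exact(self):
        rng = np.random.default_rng(0)
        cases = rng.normal(10, 4, 37).tolist()
        labels = assign_groups([9.0, 11.0], cases)
        assert len(labels) == 37
        assert set(labels) <= {"LIG", "HIG"}

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            assign_groups([], [1.0])

    def test_cohort_table_keeps_control(self):
        table = cohort_table({"c1": 5.0, "c2": 7.0},
                             {"a1": 2.0, "a2": 9.0})
        assert (table.loc[table.cohort == "control", "group"]
                == "control").all()
        assert table.set_index("sample_id").loc["a1", "group"] == "LIG"
        assert table.set_index("sample_id").loc["a2", "group"] == "HIG"


class TestContributionStrength:
    def test_fraction_of_vectors(self):
        vectors = [{"R1"}] * 3 + [{"R2"}] * 7
        assert contribution_strength(vectors, "R1") == pytest.approx(0.3)
        assert contribution_strength(vectors, "R2") == pytest.approx(0.7)
        assert contribution_strength(vectors, "R3") == 0.0

    def test_all_vectors(self):
        assert contribution_strength([{"R"}, {"R"}], "R") == 1.0

    def test_vector_members_carry_flux(self, cohort_frame):
        """Every reaction in a sample's vector has nonzero flux there."""
        for result in cohort_frame.attrs["results"]:
            for rid, absflux, weight in result.inconsistency_vector:
                assert abs(result.flux[rid]) > 1e-9
                assert weight > 0


class TestSpecificity:
    def _table(self, rows):
        frame = pd.DataFrame(
            rows, columns=["strength_control", "strength_LIG",
                           "strength_HIG"])
        frame.index = [f"R{i}" for i in range(len(rows))]
        return frame

    def test_examples(self):
        table = self._table([
            (1.0, 1.0, 1.0),    # everywhere strong -> unspecific
            (0.9, 0.05, 0.9),   # collapses in LIG -> specific
            (0.2, 0.25, 0.3),   # neither -> unlabeled
        ])
        labels = classify_specificity(table)
        assert list(labels) == ["unspecific", "specific", ""]

    def test_thresholds_are_configurable(self):
        table = self._table([(0.8, 0.8, 0.8)])
        assert classify_specificity(table, s_unspecific=0.7).iloc[0] == \
            "unspecific"

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            classify_specificity(pd.DataFrame({"strength_control": [1.0]}))


class TestContributionTable:
    def test_groups_and_bounds(self, cohort_frame):
        results = cohort_frame.attrs["results"]
        by_group = {}
        for result, label in zip(results, cohort_frame["planted"]):
            by_group.setdefault(label, []).append(result)
        table = contribution_table(by_group)
        for group in by_group:
            strengths = table[f"strength_{group}"]
            usages = table[f"usage_{group}"]
            assert ((strengths >= 0) & (strengths <= 1)).all()
            assert ((usages >= 0) & (usages <= 1)).all()
        # artificial reactions never appear as contributors
        assert not any(rid.startswith("ART_") for rid in table.index)


def knockout_fixture():
    """Chain with a bypass: R_main is the sole producer of the precursor."""
    model = build_model(
        {"A": "c", "B": "c", "C": "c"},
        [("EX_A", {"A": -1}, -10.0, INTERNAL_INF, None, True),
         ("R_main", {"A": -1, "B": 1}, 0, INTERNAL_INF, "g1", False),
         ("R_last", {"B": -1, "C": 1}, 0, INTERNAL_INF, "g2", False)])
    return add_objective_drain(model, "C")


class TestMarkers:
    def test_bottleneck_on_sole_path(self):
        model = knockout_fixture()
        medium = Medium(bounds={"EX_A": (-10.0, INTERNAL_INF)})
        patterns = [pattern_for(model, {})]
        rvals = [{rid: (3.0 if model.reactions[rid].gpr else None)
                  for rid in model.reactions}]
        markers = topological_markers(model, "R_main", patterns, rvals,
                                      medium, excluded_metabolites=())
        assert "BN" in markers

    def test_exchange_adjacent_reaction_is_cil(self):
        model = knockout_fixture()
        medium = Medium(bounds={"EX_A": (-10.0, INTERNAL_INF)})
        patterns = [pattern_for(model, {})]
        rvals = [{rid: (3.0 if model.reactions[rid].gpr else None)
                  for rid in model.reactions}]
        analysis = MarkerAnalysis(model, medium, patterns, rvals,
                                  excluded_metabolites=())
        assert "CIL" in analysis.markers("R_main")
        assert "COL" in analysis.markers("R_last")

    def test_chain_disruptor_needs_present_flanks(self):
        model = chain_model(gprs=("g1", "g2"))
        # make the middle of a 2-step chain absent while flanks are present:
        # R1 absent, EX_A (upstream, no GPR -> present) and R2 present
        medium = Medium(bounds={"EX_A": (-10.0, INTERNAL_INF)})
        patterns = [pattern_for(model, {"R1": 1.0}, sample_id=f"s{i}")
                    for i in range(4)]
        rvals = [{rid: (1.0 if rid == "R1" else
                        (3.0 if model.reactions[rid].gpr else None))
                  for rid in model.reactions} for _ in range(4)]
        analysis = MarkerAnalysis(model, medium, patterns, rvals,
                                  excluded_metabolites=())
        assert "CD" in analysis.markers("R1")
        # a present reaction is never a chain disruptor
        assert "CD" not in analysis.markers("R2")

    def test_bn_gone_when_bypass_restores_level(self):
        """A parallel present path lifting v_max above l*v_max clears BN."""
        model = build_model(
            {"A": "c", "B": "c", "C": "c"},
            [("EX_A", {"A": -1}, -10.0, INTERNAL_INF, None, True),
             ("R_main", {"A": -1, "B": 1}, 0, INTERNAL_INF, "g1", False),
             ("R_bypass", {"A": -1, "B": 1}, 0, INTERNAL_INF, "g3", False),
             ("R_last", {"B": -1, "C": 1}, 0, INTERNAL_INF, "g2", False)])
        model = add_objective_drain(model, "C")
        medium = Medium(bounds={"EX_A": (-10.0, INTERNAL_INF)})
        patterns = [pattern_for(model, {})]
        rvals = [{rid: (3.0 if model.reactions[rid].gpr else None)
                  for rid in model.reactions}]
        analysis = MarkerAnalysis(model, medium, patterns, rvals,
                                  excluded_metabolites=())
        assert "BN" not in analysis.markers("R_main")
        assert "BN" in analysis.markers("R_last")

    def test_unknown_reaction_rejected(self):
        model = knockout_fixture()
        medium = Medium(bounds={"EX_A": (-10.0, INTERNAL_INF)})
        patterns = [pattern_for(model, {})]
        rvals = [{rid: None for rid in model.reactions}]
        analysis = MarkerAnalysis(model, medium, patterns, rvals,
                                  excluded_metabolites=())
        with pytest.raises(KeyError):
            analysis.markers("nope")
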