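import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from metcoherence.expression_mapping import threshold_pattern
from metcoherence.comparison import CohortAnalysis
from metcoherence.media import reference_medium
from metcoherence.model_core import (INTERNAL_INF, MetabolicModel, Reaction,
                                     add_objective_drain, parse_gpr)
from metcoherence.synthetic_data import (SyntheticSpec, default_media_config,
                                         generate_cohort, generate_toy_model)

settings.register_profile(
    "default", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


def build_model(metabolites, reactions, objective=None):
    """Small helper: reactions as (id, stoich, lb, ub, gpr_text, exchange)."""
    model = MetabolicModel(metabolites=dict(metabolites), reactions={})
    for rid, stoich, lb, ub, gpr, exchange in reactions:
        model.add_reaction(Reaction(
            id=rid, stoichiometry=dict(stoich), lower_bound=lb,
            upper_bound=ub, gpr=parse_gpr(gpr), is_exchange=exchange))
    model.objective_reaction = objective
    model.validate()
    return model


def chain_model(uptake=10.0, gprs=("g1", "g2")):
    """Linear chain EX_A -> A -(R1)-> B -(R2)-> C -> drain(C) objective."""
    model = build_model(
        {"A": "c", "B": "c", "C": "c"},
        [
            ("EX_A", {"A": -1}, -uptake, INTERNAL_INF, None, True),
            ("R1", {"A": -1, "B": 1}, 0.0, INTERNAL_INF, gprs[0], False),
            ("R2", {"B": -1, "C": 1}, 0.0, INTERNAL_INF, gprs[1], False),
        ])
    return add_objective_drain(model, "C")


def parallel_model(uptake=10.0):
    """Two parallel routes A -> B, one per gene, plus objective drain on B."""
    model = build_model(
        {"A": "c", "B": "c"},
        [
            ("EX_A", {"A": -1}, -uptake, INTERNAL_INF, None, True),
            ("R_left", {"A": -1, "B": 1}, 0.0, INTERNAL_INF, "g_left", False),
            ("R_right", {"A": -1, "B": 1}, 0.0, INTERNAL_INF, "g_right", False),
        ])
    return add_objective_drain(model, "B")


def pattern_for(model, absent_weights, t=2.0, sample_id="s"):
    """Presence pattern where listed reactions are absent with given deficits."""
    values = {}
    for rid, rxn in model.reactions.items():
        if rxn.gpr is None:
            values[rid] = None
        elif rid in absent_weights:
            values[rid] = t - absent_weights[rid]
        else:
            values[rid] = t + 1.0
    return threshold_pattern(values, t, sample_id=sample_id)


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticSpec(seed=1)


@pytest.fixture(scope="session")
def toy_model(default_spec):
    return generate_toy_model(default_spec)


@pytest.fixture(scope="session")
def cohort(toy_model, default_spec):
    return generate_cohort(toy_model, default_spec)


@pytest.fixture(scope="session")
def toy_medium(toy_model):
    return reference_medium(toy_model, default_media_config(toy_model))


@pytest.fixture(scope="session")
def cohort_analysis(toy_model, cohort, toy_medium):
    profiles, _ = cohort
    return CohortAnalysis(toy_model, profiles, toy_medium)


@pytest.fixture(scope="session")
def cohort_frame(cohort_analysis, cohort, default_spec):
    """Default-settings cohort scores with GimmeResults and planted labels."""
    _, truth = cohort
    frame = cohort_analysis.scores(default_spec.threshold, 0.8,
                                   n_null=1000, seed=0, keep_results=True)
    frame["planted"] = [truth["groups"][s] for s in frame["sample_id"]]
    return frame
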