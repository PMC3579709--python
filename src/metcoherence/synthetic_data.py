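"""Synthetic metabolic models and expression cohorts with planted structure.

The generator builds a small two-compartment model (cytosol ``c``,
mitochondrion ``m``) that exhibits, at toy scale, every feature the
analysis relies on:

* uptake exchanges for two carbon sources and several minor nutrients,
  plus an always-available set (oxygen, protons, phosphate, water,
  sulfate);
* a main biosynthetic pathway from carbon uptake through the mitochondrion
  to a terminal product ``P_c``, whose artificial drain is the objective;
* a second carbon entry that bypasses the upper main pathway, and a
  capacity-limited alternative cytosolic route to the product — so the
  final step is a genuine bottleneck while the LP has routing choices;
* an ATP/ADP energy cycle coupling the mitochondrial pathway to an
  oxygen-consuming regeneration reaction;
* water hubs in both compartments touching >30% of reactions (the currency
  metabolites removed before network projection);
* a dead-end side branch, GPR-less transport/alternative reactions, and
  one reaction for each topological marker (BN, CD, JBT, CIL, COL, IP).

The cohort generator plants three expression states on this model:
*control* (main pathway expressed, everything else silent, a chain
disruptor and a just-below-threshold gene always absent, the energy gene
borderline), *LIG-like* (control plus an elevated energy gene, hence lower
inconsistency) and *HIG-like* (control with a random large fraction of
pathway genes pushed below threshold, hence higher inconsistency and a
fragmented active subnetwork).  Expression values are log-signal
intensities with a bimodal present/absent structure (means 3.0 and 1.0,
sd 0.4) around the default threshold t = 2.

Ground truth (planted labels, marker reactions, gene roles) is returned
alongside and can be written as JSON for assertion-based tests.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np

from .expression_mapping import ExpressionProfile, write_expression_tsv
from .media import MediaConfig, reference_medium, save_medium_json
from .model_core import (INTERNAL_INF, MetabolicModel, Reaction,
                         add_objective_drain, parse_gpr, write_sbml_model)

__all__ = [
    "SyntheticSpec",
    "generate_toy_model",
    "default_media_config",
    "generate_cohort",
    "write_fixture_dir",
]

ALWAYS_AVAILABLE = ("EX_o2", "EX_h", "EX_pi", "EX_h2o", "EX_so4")


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study conditions.

    Expression scale: log-signal units, planted so the default analysis
    settings (t = 2, l = 0.8) work unchanged.
    """

    # cohort sizes
    n_control: int = 20
    n_lig: int = 20
    n_hig: int = 20
    # expression structure (log-signal units)
    present_mean: float = 3.0
    absent_mean: float = 1.0
    noise_sd: float = 0.4
    threshold: float = 2.0
    jbt_mean: float = 1.7       # just-below-threshold planted gene
    jbt_sd: float = 0.05
    energy_mean: float = 1.6    # borderline energy gene (control/HIG)
    energy_sd: float = 0.2
    energy_mean_lig: float = 3.0  # elevated energy gene in LIG
    energy_sd_lig: float = 0.3
    cd_mean: float = 1.0        # chain-disruptor gene, firmly absent
    cd_sd: float = 0.1
    push_prob: float = 0.6      # per-gene push-below-threshold rate in HIG
    # model structure
    n_side_chains: int = 10     # two-step nutrient -> byproduct side branches
    main_chain_extra: int = 6   # extra expressed steps in the main chain
    n_isolated: int = 3         # scattered genes expressed outside LIG
    alt_capacity: float = 2.0   # flux cap of the alternative route
    uptake_carbon: float = 10.0
    uptake_minor: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_control, self.n_lig, self.n_hig) < 1:
            raise ValueError("cohort sizes must be >= 1")
        if not (self.present_mean > self.threshold > self.absent_mean):
            raise ValueError("need present mean > threshold > absent mean")
        if self.noise_sd <= 0:
            raise ValueError("noise sd must be positive")
        if self.n_side_chains < 1 or self.main_chain_extra < 0 \
                or self.n_isolated < 0:
            raise ValueError("invalid pathway structure")
        if self.alt_capacity <= 0 or self.uptake_carbon <= 0:
            raise ValueError("capacities must be positive")


# gene roles, used by the cohort generator and recorded as ground truth
_PRESENT_MAIN = ["g_m1a", "g_m2", "g_m3a", "g_m3b", "g_t1", "g_m4",
                 "g_t2", "g_m5"]
_ABSENT_BACKGROUND = ["g_m1b", "g_a1", "g_ip", "g_dead"]


def generate_toy_model(spec: SyntheticSpec) -> MetabolicModel:
    """Deterministically build the toy model described in the module docs.

    The construction uses no randomness, so repeated calls (and the SBML
    they write) are identical for a given spec.
    """
    spec.validate()
    mets: dict[str, str] = {}
    for mid in ["A_c", "B_c", "B1_c", "B2_c", "C_c", "E_c", "P_c",
                "X1_c", "X2_c", "X3_c", "DEAD_c",
                "h2o_c", "h_c", "pi_c", "o2_c", "so4_c"]:
        mets[mid] = "c"
    for i in range(spec.n_side_chains):
        mets[f"N{i + 1}_c"] = "c"
        mets[f"M{i + 1}_c"] = "c"
    mets["S1_c"] = "c"
    mets["S2_c"] = "c"
    for k in range(spec.n_isolated):
        mets[f"U{k + 1}_c"] = "c"
        mets[f"V{k + 1}_c"] = "c"
    for j in range(spec.main_chain_extra):
        mets[f"CX{j + 1}_c"] = "c"
    for mid in ["C_m", "D_m", "E_m", "atp_m", "adp_m", "pi_m", "o2_m",
                "h2o_m"]:
        mets[mid] = "m"

    model = MetabolicModel(metabolites=mets, reactions={}, id="toy_model")

    def rxn(rid, stoich, gpr=None, lb=0.0, ub=INTERNAL_INF, exchange=False):
        model.add_reaction(Reaction(
            id=rid, stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
            gpr=parse_gpr(gpr), is_exchange=exchange))

    # exchanges (bounds here are placeholders; media set the real ones)
    for mid in ["A_c", "B2_c", "o2_c", "h_c", "pi_c", "h2o_c", "so4_c",
                "S1_c", "S2_c"] + [f"N{i + 1}_c"
                                   for i in range(spec.n_side_chains)]:
        rxn(f"EX_{mid[:-2]}", {mid: -1.0}, lb=-INTERNAL_INF, exchange=True)

    # main pathway: carbon -> product, through the mitochondrion
    rxn("R_GLC", {"A_c": -1, "B_c": 1, "h_c": 1}, "g_m1a or g_m1b")
    rxn("R_CD", {"B_c": -1, "h2o_c": -1, "B1_c": 1}, "g_cd")
    rxn("R_B2", {"B2_c": -1, "B1_c": 1}, "g_m2")
    # optional extra expressed steps between B1 and C (chain length knob)
    chain_in = "B1_c"
    for j in range(spec.main_chain_extra):
        nxt = f"CX{j + 1}_c"
        rxn(f"R_X{j + 1}", {chain_in: -1, nxt: 1}, f"g_x{j + 1}")
        chain_in = nxt
    rxn("R_PK", {chain_in: -1, "C_c": 1}, "g_m3a and g_m3b")
    rxn("T_C", {"C_c": -1, "C_m": 1}, "g_t1")
    rxn("R_M1", {"C_m": -1, "atp_m": -1, "h2o_m": -1,
                 "D_m": 1, "adp_m": 1, "pi_m": 1}, "g_m4")
    rxn("R_JBT", {"D_m": -1, "E_m": 1, "h2o_m": 1}, "g_jbt")
    rxn("T_E", {"E_m": -1, "E_c": 1}, "g_t2")
    rxn("R_FIN", {"E_c": -1, "P_c": 1, "h_c": 1}, "g_m5")

    # energy cycle: ATP regeneration consumes oxygen
    rxn("R_E", {"adp_m": -1, "pi_m": -1, "o2_m": -0.5,
                "atp_m": 1, "h2o_m": 1}, "g_e")
    rxn("T_O2", {"o2_c": -1, "o2_m": 1})
    rxn("T_PI", {"pi_c": -1, "pi_m": 1})
    rxn("T_H2O", {"h2o_c": -1, "h2o_m": 1}, lb=-INTERNAL_INF)

    # capacity-limited alternative route, largely invisible to the GPRs
    rxn("RA1", {"A_c": -1, "X1_c": 1}, "g_a1", ub=spec.alt_capacity)
    rxn("RA2", {"X1_c": -1, "X2_c": 1, "h2o_c": 1})
    rxn("R_IP", {"X2_c": -1, "X3_c": 1}, "g_ip")
    rxn("RA3", {"X3_c": -1, "P_c": 1, "h2o_c": 1})

    # silent two-step side branches (off-pathway gene islands) and a dead end
    side_products = ["S1_c", "S2_c"]
    for i in range(spec.n_side_chains):
        first = {f"N{i + 1}_c": -1, f"M{i + 1}_c": 1, "h_c": 1}
        if i == 2:
            first["so4_c"] = -1
        rxn(f"R_S{i + 1}a", first, f"g_o{i + 1}a")
        extra = {"h2o_c": -1} if i % 2 == 0 else {}
        rxn(f"R_S{i + 1}b",
            {f"M{i + 1}_c": -1, side_products[i % 2]: 1, **extra},
            f"g_o{i + 1}b")
    rxn("R_SC", {"S1_c": -1, "h2o_c": -1, "S2_c": 1}, "g_oc")
    rxn("R_DEAD", {"C_c": -1, "DEAD_c": 1, "h2o_c": 1}, "g_dead")

    # scattered reactions whose substrates touch nothing else: their genes
    # are isolated nodes of the gene network (housekeeping-like)
    for k in range(spec.n_isolated):
        rxn(f"R_ISO{k + 1}", {f"U{k + 1}_c": -1, f"V{k + 1}_c": 1},
            f"g_iso{k + 1}")

    model = add_objective_drain(model, "P_c")
    model.metadata["roles"] = _gene_roles(spec)
    model.metadata["nutrient_exchanges"] = {
        "EX_A": spec.uptake_carbon, "EX_B2": spec.uptake_carbon,
        **{f"EX_N{i + 1}": spec.uptake_minor
           for i in range(spec.n_side_chains)},
    }
    model.validate()
    return model


def _gene_roles(spec: SyntheticSpec) -> dict[str, list[str]]:
    present = list(_PRESENT_MAIN) + [f"g_x{j + 1}"
                                     for j in range(spec.main_chain_extra)]
    background = list(_ABSENT_BACKGROUND) + ["g_oc"] + \
        [f"g_o{i + 1}{suffix}" for i in range(spec.n_side_chains)
         for suffix in ("a", "b")]
    return {
        "present_main": present,
        "absent_background": sorted(set(background)),
        "chain_disruptor": ["g_cd"],
        "just_below_threshold": ["g_jbt"],
        "energy": ["g_e"],
        "isolated_nonlig": [f"g_iso{k + 1}"
                            for k in range(spec.n_isolated)],
    }


def default_media_config(model: MetabolicModel) -> MediaConfig:
    """Reference-medium configuration matching the generator's exchanges."""
    nutrients = model.metadata.get("nutrient_exchanges", {})
    return MediaConfig(
        nutrient_uptake=dict(nutrients),
        oxygen_exchange="EX_o2",
        always_available=ALWAYS_AVAILABLE,
    )


def generate_cohort(model: MetabolicModel, spec: SyntheticSpec
                    ) -> tuple[list[ExpressionProfile], dict]:
    """Seeded expression cohort plus ground truth for the planted structure."""
    spec.validate()
    roles = model.metadata.get("roles") or _gene_roles(spec)
    rng = np.random.default_rng(spec.seed)
    genes = sorted(model.genes())

    def draw_sample(sample_id: str, state: str) -> ExpressionProfile:
        values: dict[str, float] = {}
        pushed = set()
        if state == "HIG":
            pushed = {g for g in roles["present_main"]
                      if rng.random() < spec.push_prob}
        for gene in genes:
            if gene in roles["chain_disruptor"]:
                mean, sd = spec.cd_mean, spec.cd_sd
            elif gene in roles["just_below_threshold"]:
                mean, sd = spec.jbt_mean, spec.jbt_sd
            elif gene in roles["energy"]:
                if state == "LIG":
                    mean, sd = spec.energy_mean_lig, spec.energy_sd_lig
                else:
                    mean, sd = spec.energy_mean, spec.energy_sd
            elif gene in roles.get("isolated_nonlig", ()):
                # scattered housekeeping-like genes: expressed in the
                # control baseline (and HIG), silent in the focused LIG state
                if state == "LIG":
                    mean, sd = spec.absent_mean, spec.noise_sd
                else:
                    mean, sd = spec.present_mean, spec.noise_sd
            elif gene in roles["present_main"] and gene not in pushed:
                mean, sd = spec.present_mean, spec.noise_sd
            else:
                mean, sd = spec.absent_mean, spec.noise_sd
            values[gene] = float(rng.normal(mean, sd))
        return ExpressionProfile(sample_id=sample_id, values=values)

    profiles: list[ExpressionProfile] = []
    groups: dict[str, str] = {}
    for i in range(spec.n_control):
        sid = f"ctrl_{i:02d}"
        profiles.append(draw_sample(sid, "control"))
        groups[sid] = "control"
    planted = ["LIG"] * spec.n_lig + ["HIG"] * spec.n_hig
    for i, state in enumerate(planted):
        sid = f"case_{i:02d}"
        profiles.append(draw_sample(sid, state))
        groups[sid] = state

    truth = {
        "seed": spec.seed,
        "threshold": spec.threshold,
        "objective_reaction": model.objective_reaction,
        "groups": groups,
        "planted_markers": {
            "BN": "R_FIN", "CD": "R_CD", "JBT": "R_JBT",
            "CIL": "R_GLC", "COL": "T_E", "IP": "R_IP",
        },
        "unspecific_contributors": ["R_CD", "R_JBT"],
        "specific_contributors": ["R_E", "R_IP"],
        "dead_end_metabolite": "DEAD_c",
        "gene_roles": roles,
        "spec": dataclasses.asdict(spec),
    }
    return profiles, truth


def write_fixture_dir(spec: SyntheticSpec, directory: str) -> dict[str, str]:
    """Write model SBML, expression TSV, medium JSON and truth JSON.

    Returns the mapping of artifact name to file path.
    """
    os.makedirs(directory, exist_ok=True)
    model = generate_toy_model(spec)
    profiles, truth = generate_cohort(model, spec)
    config = default_media_config(model)
    medium = reference_medium(model, config)
    paths = {
        "model": os.path.join(directory, "model.xml"),
        "expression": os.path.join(directory, "expression.tsv"),
        "medium": os.path.join(directory, "medium.json"),
        "media_config": os.path.join(directory, "media_config.json"),
        "truth": os.path.join(directory, "truth.json"),
    }
    write_sbml_model(model, paths["model"])
    write_expression_tsv(profiles, paths["expression"])
    save_medium_json(medium, paths["medium"])
    with open(paths["media_config"], "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2)
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2)
    return paths
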