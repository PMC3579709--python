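"""Decompose inconsistency into per-reaction contributions and classify them.

A cohort is split against the control group's mean inconsistency: samples
below the mean form the low-inconsistency group (LIG), samples at or above
it the high-inconsistency group (HIG).  For each group, a reaction's
*contribution strength* is the fraction of that group's inconsistency
vectors containing it, and its *usage frequency* the fraction of samples
in which it carries flux.

Reactions contributing strongly in every group are *unspecific* (they tend
to expose reconstruction gaps rather than biology); reactions whose
strength differs strongly between groups are *specific*.  Each contributor
is further annotated with topological markers:

====  ==========================================================
JBT   expression just below the threshold across samples
CD    chain disruptor: absent but flanked by present neighbours
CIL   close to the input layer (uptake-enabled exchanges)
COL   close to the output layer (the objective reaction)
IP    invisible path: mostly GPR-less neighbourhood
BN    bottleneck: knockout breaks the required objective level
====  ==========================================================

The markers are independent predicates; a reaction may carry several.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import fmean, median
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import coherence_engine, gimme_engine, media as media_mod
from .expression_mapping import PresencePattern
from .gimme_engine import GimmeResult
from .media import Medium
from .model_core import MetabolicModel, ModelError

__all__ = [
    "MarkerConfig",
    "assign_groups",
    "cohort_table",
    "contribution_strength",
    "contribution_table",
    "classify_specificity",
    "MarkerAnalysis",
    "topological_markers",
]

ALL_MARKERS = ("BN", "IP", "CD", "CIL", "COL", "JBT")


@dataclass
class MarkerConfig:
    """Thresholds operationalising the verbal marker criteria."""

    q_jbt: float = 0.95        # min absent fraction for JBT
    jbt_margin: float = 0.5    # log-units below t for the JBT median
    q_cd: float = 0.5          # min sample fraction for the CD predicate
    d_layer: int = 2           # reaction steps for CIL/COL
    r_ip: int = 1              # neighbourhood radius for IP
    q_ip: float = 0.5          # min GPR-less fraction among IP neighbours
    level: float = 0.8         # objective level for the BN knockout test
    s_unspecific: float = 0.9  # min strength in every group for unspecific
    delta_specific: float = 0.5  # min pairwise strength gap for specific


def assign_groups(control_inconsistencies: Sequence[float],
                  case_inconsistencies: Sequence[float]) -> list[str]:
    """Label each case sample LIG or HIG against the control mean.

    LIG: I strictly below the control mean; HIG otherwise (ties resolve to
    HIG by convention).
    """
    if len(control_inconsistencies) == 0 or len(case_inconsistencies) == 0:
        raise ValueError("both groups must be non-empty")
    pivot = fmean(control_inconsistencies)
    return ["LIG" if value < pivot else "HIG"
            for value in case_inconsistencies]


def cohort_table(control: Mapping[str, float],
                 cases: Mapping[str, float]) -> pd.DataFrame:
    """Per-sample cohort/group assignment table from inconsistency values."""
    labels = assign_groups(list(control.values()), list(cases.values()))
    rows = [{"sample_id": sid, "cohort": "control", "inconsistency": value,
             "group": "control"} for sid, value in control.items()]
    rows += [{"sample_id": sid, "cohort": "case", "inconsistency": value,
              "group": group}
             for (sid, value), group in zip(cases.items(), labels)]
    return pd.DataFrame(rows)


def contribution_strength(vectors: Sequence[Iterable[str]],
                          reaction_id: str) -> float:
    """Fraction of inconsistency vectors containing the reaction."""
    if not vectors:
        raise ValueError("empty vector list")
    hits = sum(1 for vec in vectors if reaction_id in set(vec))
    return hits / len(vectors)


def contribution_table(results_by_group: Mapping[str, Sequence[GimmeResult]],
                       eps_flux: float = gimme_engine.EPS_FLUX) -> pd.DataFrame:
    """Reaction x group strengths and usage frequencies.

    Rows cover every reaction appearing in at least one group's
    inconsistency vectors; columns are ``strength_<group>`` and
    ``usage_<group>``.
    """
    if not results_by_group:
        raise ValueError("no groups supplied")
    contributing: set[str] = set()
    for results in results_by_group.values():
        for res in results:
            contributing |= res.contributing_reactions()
    rows = []
    for rid in sorted(contributing):
        row: dict[str, object] = {"reaction_id": rid}
        for group, results in results_by_group.items():
            vectors = [res.contributing_reactions() for res in results]
            row[f"strength_{group}"] = contribution_strength(vectors, rid)
            row[f"usage_{group}"] = gimme_engine.usage_frequency(
                results, rid, eps_flux)
        rows.append(row)
    return pd.DataFrame(rows).set_index("reaction_id")


def classify_specificity(table: pd.DataFrame,
                         groups: Sequence[str] = ("control", "LIG", "HIG"),
                         s_unspecific: float = 0.9,
                         delta_specific: float = 0.5) -> pd.Series:
    """Label each contributing reaction unspecific/specific/unlabeled.

    Unspecific: strength >= s_unspecific in *every* group.  Specific: the
    largest pairwise strength difference between groups >= delta_specific.
    Everything else stays unlabeled (empty string).
    """
    cols = [f"strength_{g}" for g in groups]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"missing strength columns: {missing}")
    strengths = table[cols].to_numpy(dtype=float)
    labels = np.where(
        strengths.min(axis=1) >= s_unspecific, "unspecific",
        np.where(strengths.max(axis=1) - strengths.min(axis=1)
                 >= delta_specific, "specific", ""))
    return pd.Series(labels, index=table.index, name="specificity")


class MarkerAnalysis:
    """Topological marker predicates over one model/medium/cohort context.

    Precomputes the directed reaction graph (currency metabolites excluded,
    reversible reactions bidirectional), layer distances and the FBA
    maximum, then evaluates the six marker predicates per reaction.
    """

    def __init__(self, model: MetabolicModel, medium: Medium,
                 patterns: Sequence[PresencePattern],
                 reaction_values: Sequence[Mapping[str, float | None]],
                 objective_reaction: str | None = None,
                 excluded_metabolites: Iterable[str] | None = None,
                 currency_fraction: float = 0.04,
                 config: MarkerConfig | None = None):
        if len(patterns) != len(reaction_values):
            raise ValueError("patterns and reaction_values must align")
        self.model = model
        self.medium = medium
        self.patterns = list(patterns)
        self.reaction_values = list(reaction_values)
        self.objective = objective_reaction or model.objective_reaction
        if self.objective is None:
            raise ModelError("marker analysis needs an objective reaction")
        self.config = config or MarkerConfig()
        if excluded_metabolites is None:
            excluded_metabolites = coherence_engine.remove_currency_metabolites(
                model, currency_fraction)
        self.excluded = set(excluded_metabolites)
        self.digraph = coherence_engine.reaction_adjacency(
            model, self.excluded, directed=True, include_artificial=True)
        self.graph = self.digraph.to_undirected(as_view=False)
        self.constrained = media_mod.apply_medium(model, medium)
        self.v_max, _ = gimme_engine.fba_max(self.constrained, self.objective)
        # layer distances (in reaction steps)
        sources = [rid for rid in medium.uptake_enabled()
                   if rid in self.digraph]
        self.dist_from_input = _multi_source_distance(self.digraph, sources)
        self.dist_to_output = nx.shortest_path_length(
            self.digraph.reverse(copy=False), source=self.objective) \
            if self.objective in self.digraph else {}
        self._knockout_cache: dict[str, float] = {}

    # -- individual predicates ------------------------------------------

    def _absent_fraction(self, rid: str) -> float:
        return fmean(0.0 if p.is_present(rid) else 1.0 for p in self.patterns)

    def just_below_threshold(self, rid: str) -> bool:
        cfg = self.config
        if self._absent_fraction(rid) < cfg.q_jbt:
            return False
        values = [rv[rid] for rv in self.reaction_values
                  if rv.get(rid) is not None]
        if not values:
            return False
        t = self.patterns[0].threshold
        med = median(values)
        return t - cfg.jbt_margin <= med < t

    def chain_disruptor(self, rid: str) -> bool:
        if rid not in self.digraph:
            return False
        ups = [r for r in self.digraph.predecessors(rid)
               if not self.model.reactions[r].artificial and r != rid]
        downs = [r for r in self.digraph.successors(rid)
                 if not self.model.reactions[r].artificial and r != rid]
        if not ups or not downs:
            return False
        hits = 0
        for pattern in self.patterns:
            if pattern.is_present(rid):
                continue
            if any(pattern.is_present(u) for u in ups) and \
                    any(pattern.is_present(d) for d in downs):
                hits += 1
        return hits / len(self.patterns) >= self.config.q_cd

    def close_to_input(self, rid: str) -> bool:
        return self.dist_from_input.get(rid, np.inf) <= self.config.d_layer

    def close_to_output(self, rid: str) -> bool:
        return self.dist_to_output.get(rid, np.inf) <= self.config.d_layer

    def invisible_path(self, rid: str) -> bool:
        if rid not in self.graph:
            return False
        ego = nx.ego_graph(self.graph, rid, radius=self.config.r_ip)
        neighbours = [
            r for r in ego.nodes
            if r != rid
            and not self.model.reactions[r].artificial
            and not self.model.reactions[r].is_exchange]
        if not neighbours:
            return False
        gprless = sum(1 for r in neighbours
                      if self.model.reactions[r].gpr is None)
        return gprless / len(neighbours) >= self.config.q_ip

    def bottleneck(self, rid: str) -> bool:
        if self.v_max <= gimme_engine.EPS_FLUX:
            return False
        if rid not in self._knockout_cache:
            knocked = self.constrained.copy()
            rxn = knocked.reactions[rid]
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
            try:
                v_ko, _ = gimme_engine.fba_max(knocked, self.objective)
            except gimme_engine.InfeasibleProblemError:
                v_ko = 0.0
            self._knockout_cache[rid] = v_ko
        return self._knockout_cache[rid] < \
            self.config.level * self.v_max - gimme_engine.EPS_FLUX

    def markers(self, reaction_id: str) -> set[str]:
        if reaction_id not in self.model.reactions:
            raise KeyError(f"unknown reaction {reaction_id!r}")
        out = set()
        if self.bottleneck(reaction_id):
            out.add("BN")
        if self.invisible_path(reaction_id):
            out.add("IP")
        if self.chain_disruptor(reaction_id):
            out.add("CD")
        if self.close_to_input(reaction_id):
            out.add("CIL")
        if self.close_to_output(reaction_id):
            out.add("COL")
        if self.just_below_threshold(reaction_id):
            out.add("JBT")
        return out

    def annotate(self, reaction_ids: Iterable[str]) -> pd.Series:
        return pd.Series({rid: ";".join(sorted(self.markers(rid)))
                          for rid in reaction_ids}, name="markers")


def _multi_source_distance(digraph: nx.DiGraph,
                           sources: Sequence[str]) -> dict[str, int]:
    dist: dict[str, int] = {}
    for src in sources:
        for node, d in nx.shortest_path_length(digraph, source=src).items():
            if node not in dist or d < dist[node]:
                dist[node] = d
    return dist


def topological_markers(model: MetabolicModel, reaction_id: str,
                        patterns: Sequence[PresencePattern],
                        reaction_values: Sequence[Mapping[str, float | None]],
                        medium: Medium,
                        objective_reaction: str | None = None,
                        excluded_metabolites: Iterable[str] | None = None,
                        config: MarkerConfig | None = None) -> set[str]:
    """Marker set for one reaction (convenience wrapper over MarkerAnalysis).

    Prefer :class:`MarkerAnalysis` when annotating many reactions — the
    graph, distances and knockout LPs are cached there.
    """
    analysis = MarkerAnalysis(model, medium, patterns, reaction_values,
                              objective_reaction=objective_reaction,
                              excluded_metabolites=excluded_metabolites,
                              config=config)
    return analysis.markers(reaction_id)
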