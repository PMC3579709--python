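"""Metabolic coherence: gene-network projection and connectivity z-score.

The stoichiometric model is projected onto an undirected *gene network*:
two reactions are adjacent when they share a metabolite that survived
currency removal, and two genes are adjacent when they occur in the GPR of
the same reaction or of adjacent reactions.  Currency metabolites (ATP,
water, protons, ...) are removed beforehand as the top 4% of metabolites by
reaction-degree within each compartment — left in place, these hubs would
connect essentially everything and erase pathway structure.

For a sample, the genes above threshold induce a subgraph; the coherence
ratio is the fraction of induced nodes with at least one induced neighbour.
The metabolic coherence MC is the z-score of that ratio against a null of
uniformly drawn equal-size node subsets:

    MC = (ratio - mu) / sigma

with mu and sigma the mean and population (1/N) standard deviation of the
null ratios.  ``exact_null`` enumerates all subsets instead of sampling and
serves as the oracle on small graphs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import networkx as nx
import numpy as np

from .model_core import MetabolicModel, ModelError

__all__ = [
    "MCResult",
    "remove_currency_metabolites",
    "project_gene_network",
    "connected_ratio",
    "metabolic_coherence",
    "exact_null",
    "reaction_adjacency",
]


@dataclass
class MCResult:
    """Coherence ratio with its null statistics and z-score."""

    ratio: float
    mu: float
    sigma: float
    mc: float
    n_null: int
    subset_size: int
    seed: int | None = None
    degenerate: bool = False


def remove_currency_metabolites(model: MetabolicModel,
                                fraction: float = 0.04) -> set[str]:
    """Top-degree metabolites per compartment, to exclude from projection.

    Within each compartment the ceil(fraction * n) metabolites of highest
    reaction-degree are marked; degree ties at the cutoff break by
    metabolite id (lexicographic) for reproducibility.  Artificial
    (drain/objective) reactions do not count towards degree.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    if fraction == 0.0:
        return set()
    degree = model.metabolite_degree(include_artificial=False)
    by_compartment: dict[str, list[str]] = {}
    for met, comp in model.metabolites.items():
        by_compartment.setdefault(comp, []).append(met)
    excluded: set[str] = set()
    for comp, mets in by_compartment.items():
        k = math.ceil(fraction * len(mets))
        ranked = sorted(mets, key=lambda m: (-degree[m], m))
        excluded.update(ranked[:k])
    return excluded


def reaction_adjacency(model: MetabolicModel,
                       excluded_metabolites: Iterable[str] = (),
                       directed: bool = False,
                       include_artificial: bool = False) -> nx.Graph:
    """Reaction graph: nodes are reactions, edges are shared metabolites.

    Undirected (default): an edge whenever two reactions share a
    non-excluded metabolite.  Directed variant: an edge R1 -> R2 whenever R1
    produces a non-excluded metabolite that R2 consumes (reversible
    reactions act in both directions).
    """
    excluded = set(excluded_metabolites)
    graph: nx.Graph = nx.DiGraph() if directed else nx.Graph()
    producers: dict[str, set[str]] = {}
    consumers: dict[str, set[str]] = {}
    for rid, rxn in model.reactions.items():
        if rxn.artificial and not include_artificial:
            continue
        graph.add_node(rid)
        for met, coef in rxn.stoichiometry.items():
            if met in excluded:
                continue
            if coef > 0 or rxn.reversible:
                producers.setdefault(met, set()).add(rid)
            if coef < 0 or rxn.reversible:
                consumers.setdefault(met, set()).add(rid)
    for met in set(producers) | set(consumers):
        if directed:
            for src in producers.get(met, ()):
                for dst in consumers.get(met, ()):
                    if src != dst:
                        graph.add_edge(src, dst)
        else:
            touching = sorted(producers.get(met, set()) | consumers.get(met, set()))
            for a, b in combinations(touching, 2):
                graph.add_edge(a, b)
    return graph


def project_gene_network(model: MetabolicModel,
                         excluded_metabolites: Iterable[str] = (),
                         directed_reactions: bool = False) -> nx.Graph:
    """Project the model to an undirected simple graph over gene ids.

    Genes are adjacent when their reactions coincide or are adjacent in the
    reaction graph (one reaction step; currency metabolites excluded).  All
    genes appearing in any GPR become nodes, including isolated ones.
    ``directed_reactions`` switches the underlying reaction adjacency to the
    product-of-one-is-substrate-of-other variant (sensitivity analysis).
    """
    gene_sets = {rid: rxn.gpr.genes()
                 for rid, rxn in model.reactions.items()
                 if rxn.gpr is not None and not rxn.artificial}
    if not gene_sets:
        raise ModelError("model has no GPR rules; gene network undefined")
    rxn_graph = reaction_adjacency(model, excluded_metabolites,
                                   directed=directed_reactions)
    network = nx.Graph()
    for genes in gene_sets.values():
        network.add_nodes_from(genes)
        for a, b in combinations(sorted(genes), 2):
            network.add_edge(a, b)
    pairs = (rxn_graph.edges() if not directed_reactions
             else ((u, v) for u, v in rxn_graph.edges()))
    for r1, r2 in pairs:
        for a in gene_sets.get(r1, ()):
            for b in gene_sets.get(r2, ()):
                if a != b:
                    network.add_edge(a, b)
    return network


def connected_ratio(network: nx.Graph, node_subset: Iterable[str]) -> float:
    """Fraction of subset nodes with >= 1 neighbour inside the subset.

    Returns NaN (undefined marker) for an empty subset.
    """
    subset = set(node_subset)
    if not subset:
        return float("nan")
    missing = subset - set(network.nodes)
    if missing:
        raise ValueError(f"subset nodes not in network: {sorted(missing)[:5]}")
    connected = sum(
        1 for node in subset
        if any(neigh in subset for neigh in network.neighbors(node)))
    return connected / len(subset)


def _null_ratios(adjacency: np.ndarray, k: int, n_null: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Connected ratios of n_null uniform k-subsets (vectorised)."""
    n = adjacency.shape[0]
    # rank random keys to sample k indices without replacement per draw
    keys = rng.random((n_null, n))
    idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
    mask = np.zeros((n_null, n), dtype=bool)
    np.put_along_axis(mask, idx, True, axis=1)
    neighbour_counts = mask.astype(np.int32) @ adjacency
    connected = ((neighbour_counts > 0) & mask).sum(axis=1)
    return connected / k


def metabolic_coherence(network: nx.Graph,
                        active_genes: Iterable[str],
                        n_null: int = 1000,
                        seed: int | None = None,
                        rng: np.random.Generator | None = None) -> MCResult:
    """MC z-score of the active-gene subgraph against the random-subset null.

    The intersection of active genes with the network's nodes forms the
    subset; n_null uniform subsets of the same size provide mu and sigma
    (population 1/N formula).  sigma = 0 yields MC = 0 with the degenerate
    flag set.  An empty intersection raises ValueError (undefined).
    """
    nodes = sorted(network.nodes)
    subset = set(active_genes) & set(nodes)
    if not subset:
        raise ValueError("no active genes intersect the network (MC undefined)")
    if rng is None:
        rng = np.random.default_rng(seed)
    ratio = connected_ratio(network, subset)
    k = len(subset)
    adjacency = nx.to_numpy_array(network, nodelist=nodes, dtype=np.int32)
    ratios = _null_ratios(adjacency, k, n_null, rng)
    mu = float(ratios.mean())
    sigma = float(ratios.std(ddof=0))
    if sigma == 0.0:
        return MCResult(ratio=ratio, mu=mu, sigma=sigma, mc=0.0,
                        n_null=n_null, subset_size=k, seed=seed,
                        degenerate=True)
    return MCResult(ratio=ratio, mu=mu, sigma=sigma,
                    mc=(ratio - mu) / sigma, n_null=n_null,
                    subset_size=k, seed=seed)


def exact_null(network: nx.Graph, subset_size: int) -> tuple[float, float]:
    """Exact null (mu, sigma) by enumerating every subset of the given size.

    Population sigma over all C(n, k) subsets; feasible for small graphs
    only, used as the sampling oracle.
    """
    nodes = sorted(network.nodes)
    if not 0 < subset_size <= len(nodes):
        raise ValueError("subset size out of range")
    neighbours = {node: set(network.neighbors(node)) for node in nodes}
    ratios = []
    for combo in combinations(nodes, subset_size):
        subset = set(combo)
        connected = sum(1 for node in combo if neighbours[node] & subset)
        ratios.append(connected / subset_size)
    arr = np.asarray(ratios)
    return float(arr.mean()), float(arr.std(ddof=0))
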