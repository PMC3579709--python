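"""FBA and the GIMME inconsistency LP.

Flux balance analysis (FBA) maximises the objective reaction's flux v_obj
subject to steady state (S v = 0) and the flux bounds.  GIMME then asks for
the cheapest way to keep the objective at a fraction l of that maximum
while penalising flux through reactions whose expression fell below the
threshold:

    minimise    sum_{i absent} w_i |v_i|
    subject to  S v = 0,  lb <= v <= ub,  v_obj >= l * v_max

with deficit weights w_i = max(0, t - x_i) taken from the presence pattern
(a uniform-weight mode w_i = 1 is available).  The optimum is the
*inconsistency* I; the absent reactions that carry flux in the solution
form the *inconsistency vector* ("reinserted" reactions).  Absolute fluxes
are linearised by splitting every reversible reaction into a forward and a
backward non-negative variable, so the whole problem is a single LP solved
with HiGHS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .expression_mapping import PresencePattern
from .model_core import MetabolicModel, ModelError

__all__ = [
    "EPS_FLUX",
    "FluxDistribution",
    "GimmeResult",
    "DegenerateObjectiveError",
    "InfeasibleProblemError",
    "fba_max",
    "gimme",
    "normalized_inconsistency",
    "usage_frequency",
]

#: Solver-noise floor below which a flux counts as zero.
EPS_FLUX = 1e-6

_LINPROG_OPTIONS = {
    "presolve": True,
    "primal_feasibility_tolerance": 1e-9,
    "dual_feasibility_tolerance": 1e-9,
}

FluxDistribution = dict[str, float]


class DegenerateObjectiveError(ModelError):
    """FBA maximum is zero, so the GIMME level constraint is undefined."""


class InfeasibleProblemError(ModelError):
    """The LP has no feasible solution under the given constraints."""


@dataclass
class GimmeResult:
    """Outcome of one GIMME optimisation.

    ``inconsistency_vector`` lists (reaction id, |flux|, deficit weight) for
    the absent reactions carrying flux above :data:`EPS_FLUX`; their
    weighted sum equals ``inconsistency`` up to solver tolerance.
    """

    inconsistency: float
    objective_flux: float
    v_max: float
    level: float
    flux: FluxDistribution
    inconsistency_vector: list[tuple[str, float, float]]
    weight_mode: str = "deficit"
    sample_id: str = ""

    @property
    def normalized_inconsistency(self) -> float:
        return normalized_inconsistency(self)

    def contributing_reactions(self) -> set[str]:
        return {rid for rid, _, _ in self.inconsistency_vector}


class _SplitLP:
    """Split-variable (v = v_f - v_b) LP data for a model."""

    def __init__(self, model: MetabolicModel):
        S, met_ids, rxn_ids = model.stoichiometric_matrix()
        self.rxn_ids = rxn_ids
        self.n_rxns = len(rxn_ids)
        # columns: forward copies then backward copies of reversible reactions
        rev_idx = [j for j, rid in enumerate(rxn_ids)
                   if model.reactions[rid].reversible]
        self.rev_idx = rev_idx
        self.back_col_of = {j: self.n_rxns + k for k, j in enumerate(rev_idx)}
        blocks = [S] + ([-S[:, rev_idx]] if rev_idx else [])
        self.A_eq = sparse.hstack(blocks, format="csr") if rev_idx else S
        self.n_vars = self.n_rxns + len(rev_idx)
        bounds = []
        for rid in rxn_ids:
            rxn = model.reactions[rid]
            bounds.append((max(0.0, rxn.lower_bound), max(0.0, rxn.upper_bound)))
        for j in rev_idx:
            rxn = model.reactions[rxn_ids[j]]
            # a negative upper bound forces backward flux
            bounds.append((max(0.0, -rxn.upper_bound), -rxn.lower_bound))
        self.bounds = bounds
        self.obj_col = None
        if model.objective_reaction is not None:
            self.obj_col = rxn_ids.index(model.objective_reaction)

    def net_flux(self, x: np.ndarray) -> FluxDistribution:
        flux = {}
        for j, rid in enumerate(self.rxn_ids):
            v = x[j]
            if j in self.back_col_of:
                v -= x[self.back_col_of[j]]
            flux[rid] = float(v)
        return flux

    def total_flux_cols(self, j: int) -> list[int]:
        cols = [j]
        if j in self.back_col_of:
            cols.append(self.back_col_of[j])
        return cols


def _solve(c, lp: _SplitLP, A_ub=None, b_ub=None):
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=lp.A_eq,
                  b_eq=np.zeros(lp.A_eq.shape[0]), bounds=lp.bounds,
                  method="highs", options=_LINPROG_OPTIONS)
    if res.status == 2:
        raise InfeasibleProblemError(f"LP infeasible: {res.message}")
    if not res.success:
        raise InfeasibleProblemError(f"LP failed: {res.message}")
    return res


def fba_max(model: MetabolicModel,
            objective_reaction: str | None = None
            ) -> tuple[float, FluxDistribution]:
    """Maximum achievable objective flux and a witnessing flux distribution."""
    work = model
    if objective_reaction is not None:
        if objective_reaction not in model.reactions:
            raise ModelError(f"unknown objective reaction {objective_reaction!r}")
        work = model.copy()
        work.objective_reaction = objective_reaction
    if work.objective_reaction is None:
        raise ModelError("model has no objective reaction")
    lp = _SplitLP(work)
    c = np.zeros(lp.n_vars)
    c[lp.obj_col] = -1.0
    if lp.obj_col in lp.back_col_of:
        c[lp.back_col_of[lp.obj_col]] = 1.0
    res = _solve(c, lp)
    flux = lp.net_flux(res.x)
    return -float(res.fun), flux


def gimme(model: MetabolicModel,
          pattern: PresencePattern,
          objective_reaction: str | None = None,
          level: float = 0.8,
          weight_mode: str = "deficit",
          v_max: float | None = None,
          eps_flux: float = EPS_FLUX) -> GimmeResult:
    """Run the GIMME LP against a presence pattern.

    Parameters
    ----------
    level:
        Fraction l in (0, 1] of the FBA maximum that the objective flux
        must reach (as an inequality, v_obj >= l * v_max).
    weight_mode:
        ``"deficit"`` uses w_i = max(0, t - x_i) from the pattern;
        ``"uniform"`` penalises every absent reaction with weight 1
        (the literal sum-of-fluxes reading).
    v_max:
        FBA maximum, recomputed when not supplied.

    Raises
    ------
    DegenerateObjectiveError
        When the FBA maximum is (numerically) zero.
    """
    if not 0.0 < level <= 1.0:
        raise ValueError(f"level must be in (0, 1], got {level}")
    if weight_mode not in ("deficit", "uniform"):
        raise ValueError(f"unknown weight mode {weight_mode!r}")
    work = model
    if objective_reaction is not None:
        work = model.copy()
        work.objective_reaction = objective_reaction
    if work.objective_reaction is None:
        raise ModelError("model has no objective reaction")
    if v_max is None:
        v_max, _ = fba_max(work)
    if v_max <= eps_flux:
        raise DegenerateObjectiveError(
            f"FBA maximum is {v_max:.3g}; GIMME undefined for a blocked objective")

    lp = _SplitLP(work)
    c = np.zeros(lp.n_vars)
    weights: dict[str, float] = {}
    for j, rid in enumerate(lp.rxn_ids):
        rxn = work.reactions[rid]
        if rxn.artificial or pattern.is_present(rid):
            continue
        w = 1.0 if weight_mode == "uniform" else pattern.weight(rid)
        if w <= 0.0:
            continue
        weights[rid] = w
        for col in lp.total_flux_cols(j):
            c[col] = w

    # v_obj >= l * v_max  as  -v_obj <= -l * v_max
    row = np.zeros(lp.n_vars)
    row[lp.obj_col] = -1.0
    if lp.obj_col in lp.back_col_of:
        row[lp.back_col_of[lp.obj_col]] = 1.0
    res = _solve(c, lp, A_ub=row[None, :], b_ub=np.array([-level * v_max]))

    flux = lp.net_flux(res.x)
    vector = []
    for rid, w in weights.items():
        j = lp.rxn_ids.index(rid)
        total = sum(res.x[col] for col in lp.total_flux_cols(j))
        if total > eps_flux:
            vector.append((rid, float(total), float(w)))
    return GimmeResult(
        inconsistency=float(res.fun),
        objective_flux=flux[work.objective_reaction],
        v_max=float(v_max),
        level=float(level),
        flux=flux,
        inconsistency_vector=vector,
        weight_mode=weight_mode,
        sample_id=pattern.sample_id,
    )


def normalized_inconsistency(result: GimmeResult) -> float:
    """I divided by the achieved objective flux; NaN when that flux is zero."""
    if abs(result.objective_flux) <= EPS_FLUX:
        return float("nan")
    return result.inconsistency / result.objective_flux


def usage_frequency(results: Sequence[GimmeResult], reaction_id: str,
                    eps_flux: float = EPS_FLUX) -> float:
    """Fraction of results in which the reaction carries flux above eps."""
    if not results:
        raise ValueError("empty result list")
    if all(reaction_id not in r.flux for r in results):
        import logging
        logging.getLogger(__name__).warning(
            "usage_frequency: unknown reaction %r", reaction_id)
        return 0.0
    hits = sum(1 for r in results if abs(r.flux.get(reaction_id, 0.0)) > eps_flux)
    return hits / len(results)
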