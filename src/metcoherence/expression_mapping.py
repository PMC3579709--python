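"""Map gene expression onto reactions and threshold into presence patterns.

Per-gene log-signal intensities are evaluated through each reaction's GPR
rule with AND -> min and OR -> max, yielding a per-reaction expression
value.  A threshold ``t`` then splits reactions into present (value >= t)
and absent (value < t) with a *deficit* weight ``t - value`` that later
scales the flux penalty in the inconsistency LP.  Reactions without a GPR
rule are conservatively assumed expressed (present, deficit 0).

Genes present in the model but not measured in a profile are imputed with
the profile-wide median value (logged once per profile); the median avoids
creating spurious absence calls from missing probes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .model_core import MetabolicModel

__all__ = [
    "ExpressionProfile",
    "PresencePattern",
    "read_expression_tsv",
    "write_expression_tsv",
    "reaction_expression",
    "threshold_pattern",
    "active_genes",
    "write_pattern_tsv",
]

logger = logging.getLogger(__name__)

#: Marker for reactions without a GPR rule ("expression not observable").
MISSING = None


@dataclass
class ExpressionProfile:
    """One sample's log-signal intensities, gene id -> value."""

    sample_id: str
    values: dict[str, float]

    def __post_init__(self):
        for gene, value in self.values.items():
            if not gene:
                raise ValueError("empty gene id in expression profile")
            if not np.isfinite(value):
                raise ValueError(
                    f"non-finite expression for gene {gene!r} "
                    f"in sample {self.sample_id!r}")

    @property
    def median(self) -> float:
        return float(np.median(list(self.values.values())))


@dataclass
class PresencePattern:
    """Binary reaction presence/absence state with deficit weights.

    ``present[r]`` is True iff the reaction's expression value reached the
    threshold (or the reaction has no GPR).  ``deficit[r]`` is
    ``max(0, t - value)`` and is zero exactly for present reactions.
    """

    sample_id: str
    threshold: float
    present: dict[str, bool] = field(default_factory=dict)
    deficit: dict[str, float] = field(default_factory=dict)

    def is_present(self, reaction_id: str) -> bool:
        # reactions unknown to the pattern (e.g. artificial drains added
        # later) count as present, mirroring the no-GPR convention
        return self.present.get(reaction_id, True)

    def weight(self, reaction_id: str) -> float:
        return self.deficit.get(reaction_id, 0.0)

    def absent_reactions(self) -> list[str]:
        return [r for r, p in self.present.items() if not p]


def read_expression_tsv(path: str) -> list[ExpressionProfile]:
    """Read a TSV with gene ids in the first column, one column per sample."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return [
        ExpressionProfile(sample_id=str(col),
                          values={str(g): float(v)
                                  for g, v in frame[col].items()})
        for col in frame.columns
    ]


def write_expression_tsv(profiles: Iterable[ExpressionProfile],
                         path: str) -> None:
    frame = pd.DataFrame({p.sample_id: pd.Series(p.values) for p in profiles})
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t")


def reaction_expression(profile: ExpressionProfile,
                        model: MetabolicModel) -> dict[str, float | None]:
    """Evaluate each reaction's GPR over the profile (AND->min, OR->max).

    Reactions without a GPR map to ``None`` (the missing marker).  Model
    genes absent from the profile are imputed with the profile median.
    """
    values = dict(profile.values)
    unmeasured = model.genes() - values.keys()
    if unmeasured:
        median = profile.median
        logger.info(
            "sample %s: %d model gene(s) not measured, imputed with "
            "profile median %.3f", profile.sample_id, len(unmeasured), median)
        for gene in unmeasured:
            values[gene] = median
    out: dict[str, float | None] = {}
    for rid, rxn in model.reactions.items():
        out[rid] = MISSING if rxn.gpr is None else rxn.gpr.evaluate(values)
    return out


def threshold_pattern(reaction_values: Mapping[str, float | None],
                      t: float,
                      sample_id: str = "") -> PresencePattern:
    """Threshold per-reaction expression into a presence/absence pattern.

    A value >= t is present (boundary ties resolve to present); a value < t
    is absent with deficit ``t - value``; the missing marker (no GPR) is
    present with deficit zero.
    """
    if not np.isfinite(t):
        raise ValueError("threshold must be finite")
    pattern = PresencePattern(sample_id=sample_id, threshold=float(t))
    for rid, value in reaction_values.items():
        if value is None or value >= t:
            pattern.present[rid] = True
            pattern.deficit[rid] = 0.0
        else:
            pattern.present[rid] = False
            pattern.deficit[rid] = float(t - value)
    return pattern


def active_genes(profile: ExpressionProfile, t: float) -> set[str]:
    """Genes whose expression reaches the threshold."""
    return {g for g, v in profile.values.items() if v >= t}


def write_pattern_tsv(pattern: PresencePattern, path: str) -> None:
    frame = pd.DataFrame({
        "reaction_id": list(pattern.present),
        "state": ["present" if pattern.present[r] else "absent"
                  for r in pattern.present],
        "deficit": [pattern.deficit[r] for r in pattern.present],
    })
    frame.to_csv(path, sep="\t", index=False)
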