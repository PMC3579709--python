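"""Correlating metabolic coherence with inconsistency across a cohort.

``CohortAnalysis`` is the shared driver: given a model, a medium and a set
of expression profiles it computes, per sample, the GIMME inconsistency I
(and its objective-flux-normalised variant) and the metabolic coherence MC
at a threshold t and level l.  On top of it sit

* ``pearson_one_tailed`` / ``spearman_rho`` — the correlation statistics,
  with the one-tailed p-value of the t statistic under the negative-
  association alternative (the working hypothesis is anticorrelation);
* ``threshold_sweep`` — recompute the cohort and its MC/I correlation on a
  grid of thresholds;
* ``media_sweep`` — distribution of correlation coefficients over random
  growth media, using normalised I (MC does not depend on the medium).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import coherence_engine, expression_mapping, gimme_engine, media
from .expression_mapping import ExpressionProfile
from .gimme_engine import DegenerateObjectiveError, GimmeResult
from .media import MediaConfig, Medium
from .model_core import MetabolicModel

__all__ = [
    "SweepResult",
    "CohortAnalysis",
    "pearson_one_tailed",
    "spearman_rho",
    "threshold_sweep",
    "media_sweep",
]

logger = logging.getLogger(__name__)


def pearson_one_tailed(x: Sequence[float],
                       y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r with the one-tailed (negative alternative) p-value.

    p is the lower-tail probability of t = r sqrt((n-2)/(1-r^2)) under a
    Student-t distribution with n-2 degrees of freedom.  Zero variance in
    either input yields (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return float("nan"), float("nan")
    res = stats.pearsonr(x, y, alternative="less")
    return float(res.statistic), float(res.pvalue)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (average ranks for ties); NaN if constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


@dataclass
class SweepResult:
    """Per-grid-point correlations for a swept parameter."""

    parameter: str
    table: pd.DataFrame  # columns: value, r, p, rho, n, n_excluded

    @property
    def grid(self) -> np.ndarray:
        return self.table["value"].to_numpy()

    def argbest(self) -> float:
        """Grid value with the most negative Pearson r (NaN rows ignored)."""
        valid = self.table.dropna(subset=["r"])
        if valid.empty:
            return float("nan")
        return float(valid.loc[valid["r"].idxmin(), "value"])


class CohortAnalysis:
    """Precomputes the medium-applied model, FBA maximum, gene network and
    per-sample reaction expression, then scores the cohort at any (t, l).

    Null statistics for MC depend only on the subset size, so they are
    cached per size (same base seed) — scoring a threshold grid reuses
    them across samples.
    """

    def __init__(self, model: MetabolicModel, profiles: Sequence[ExpressionProfile],
                 medium: Medium, currency_fraction: float = 0.04,
                 objective_reaction: str | None = None,
                 network=None):
        self.model = model
        self.profiles = list(profiles)
        self.medium = medium
        self.objective = objective_reaction or model.objective_reaction
        self.constrained = media.apply_medium(model, medium)
        self.v_max, _ = gimme_engine.fba_max(self.constrained, self.objective)
        self.excluded_metabolites = coherence_engine.remove_currency_metabolites(
            model, currency_fraction)
        self.network = network if network is not None else \
            coherence_engine.project_gene_network(model, self.excluded_metabolites)
        self.reaction_values = [
            expression_mapping.reaction_expression(p, model)
            for p in self.profiles]

    def scores(self, t: float, level: float, n_null: int = 1000,
               seed: int = 0, weight_mode: str = "deficit",
               constrained: MetabolicModel | None = None,
               v_max: float | None = None,
               keep_results: bool = False) -> pd.DataFrame:
        """Per-sample I, normalised I, v_obj and MC at threshold t, level l.

        Samples that are degenerate at this threshold (no active gene
        intersects the network) get NaN MC; a blocked objective (v_max = 0)
        raises upstream.  Each sample's MC null is an independent draw with
        a seed derived from the base seed and the sample index, so repeated
        calls are reproducible.  When ``keep_results`` is set the
        GimmeResult objects are attached under ``frame.attrs["results"]``.
        """
        constrained = constrained if constrained is not None else self.constrained
        v_max = v_max if v_max is not None else self.v_max
        rows = []
        results: list[GimmeResult | None] = []
        for index, (profile, rvals) in enumerate(
                zip(self.profiles, self.reaction_values)):
            pattern = expression_mapping.threshold_pattern(
                rvals, t, sample_id=profile.sample_id)
            result = gimme_engine.gimme(
                constrained, pattern, objective_reaction=self.objective,
                level=level, weight_mode=weight_mode, v_max=v_max)
            active = expression_mapping.active_genes(profile, t)
            subset = active & set(self.network.nodes)
            if subset:
                mc_result = coherence_engine.metabolic_coherence(
                    self.network, subset, n_null=n_null,
                    seed=(seed + index) % 2**31)
                ratio, mc = mc_result.ratio, mc_result.mc
            else:
                ratio, mc = float("nan"), float("nan")
                logger.info("sample %s: no active gene in network at t=%.3g",
                            profile.sample_id, t)
            rows.append({
                "sample_id": profile.sample_id,
                "inconsistency": result.inconsistency,
                "normalized_inconsistency": result.normalized_inconsistency,
                "objective_flux": result.objective_flux,
                "ratio": ratio,
                "mc": mc,
            })
            results.append(result)
        frame = pd.DataFrame(rows)
        if keep_results:
            frame.attrs["results"] = results
        return frame


def _correlate(frame: pd.DataFrame, value_col: str) -> dict:
    valid = frame.dropna(subset=["mc", value_col])
    n = len(valid)
    out = {"r": float("nan"), "p": float("nan"), "rho": float("nan"),
           "n": n, "n_excluded": len(frame) - n}
    if n >= 3:
        x = valid["mc"].to_numpy()
        y = valid[value_col].to_numpy()
        if np.std(x) > 0 and np.std(y) > 0:
            out["r"], out["p"] = pearson_one_tailed(x, y)
            out["rho"] = spearman_rho(x, y)
    return out


def threshold_sweep(analysis: CohortAnalysis, t_grid: Sequence[float],
                    level: float = 0.95, n_null: int = 1000,
                    seed: int = 0,
                    weight_mode: str = "deficit") -> SweepResult:
    """MC/I correlation at each threshold of the grid (raw I)."""
    if len(t_grid) == 0:
        raise ValueError("empty threshold grid")
    rows = []
    for t in t_grid:
        try:
            frame = analysis.scores(t, level, n_null=n_null, seed=seed,
                                    weight_mode=weight_mode)
            record = _correlate(frame, "inconsistency")
        except DegenerateObjectiveError:
            record = {"r": float("nan"), "p": float("nan"),
                      "rho": float("nan"), "n": 0,
                      "n_excluded": len(analysis.profiles)}
        rows.append({"value": float(t), **record})
    return SweepResult(parameter="threshold", table=pd.DataFrame(rows))


def level_sweep(analysis: CohortAnalysis, l_grid: Sequence[float],
                t: float = 1.9, n_null: int = 1000, seed: int = 0,
                weight_mode: str = "deficit") -> SweepResult:
    """MC/I correlation at each objective level of the grid."""
    rows = []
    for level in l_grid:
        frame = analysis.scores(t, level, n_null=n_null, seed=seed,
                                weight_mode=weight_mode)
        rows.append({"value": float(level),
                     **_correlate(frame, "inconsistency")})
    return SweepResult(parameter="level", table=pd.DataFrame(rows))


def media_sweep(analysis: CohortAnalysis, config: MediaConfig,
                n_media: int = 100, seed: int = 0, t: float = 1.9,
                level: float = 0.95, n_null: int = 1000,
                weight_mode: str = "deficit",
                max_retries_per_medium: int = 50) -> pd.DataFrame:
    """Correlation distribution over random growth media.

    Normalised inconsistency is used so values stay comparable across
    media of different capacity; MC is medium-independent.  Media
    for which the objective is blocked are skipped, logged and resampled up
    to the retry cap.  Returns one row per accepted medium with its
    selected-exchange fraction.
    """
    rng = np.random.default_rng(seed)
    rows = []
    mc_frame: pd.DataFrame | None = None
    attempts_left = n_media * max_retries_per_medium
    accepted = 0
    while accepted < n_media and attempts_left > 0:
        attempts_left -= 1
        medium = media.random_medium(analysis.model, rng, config,
                                     label=f"random_{accepted}")
        constrained = media.apply_medium(analysis.model, medium)
        try:
            v_max, _ = gimme_engine.fba_max(constrained, analysis.objective)
        except gimme_engine.InfeasibleProblemError:
            v_max = 0.0
        if v_max <= gimme_engine.EPS_FLUX:
            logger.info("random medium infeasible for the objective, resampled")
            continue
        frame = analysis.scores(t, level, n_null=n_null, seed=seed,
                                weight_mode=weight_mode,
                                constrained=constrained, v_max=v_max)
        if mc_frame is None:
            mc_frame = frame[["sample_id", "mc"]]
        record = _correlate(frame, "normalized_inconsistency")
        rows.append({"medium": medium.label,
                     "fraction": medium.meta.get("fraction"),
                     "v_max": v_max, **record})
        accepted += 1
    if accepted < n_media:
        raise RuntimeError(
            f"only {accepted}/{n_media} feasible media within the retry cap")
    return pd.DataFrame(rows)
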