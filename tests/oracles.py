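"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's LP/statistics code paths:

* ``lp_min_by_vertex_enumeration`` — minimises a linear objective over a
  polytope {A x = b, lb <= x <= ub} by enumerating basic feasible
  solutions (every LP optimum is attained at one);
* ``gimme_by_enumeration`` — builds the split-variable GIMME polytope
  directly from a model and a presence pattern and minimises the weighted
  penalty by vertex enumeration;
* ``pearson_definition`` / ``spearman_definition`` / ``one_tailed_p_definition``
  — the textbook formulas, computed term by term.
"""

from itertools import combinations, product

import numpy as np

from metcoherence.model_core import MetabolicModel


def lp_min_by_vertex_enumeration(c, A_eq, b_eq, lower, upper, tol=1e-9):
    """Minimum of c.x over {A_eq x = b_eq, lower <= x <= upper}.

    Enumerates basic solutions: every choice of rank(A) basic columns with
    the remaining variables pinned to one of their bounds.  Returns
    (min value, argmin vertex).
    """
    A = np.atleast_2d(np.asarray(A_eq, dtype=float))
    b = np.asarray(b_eq, dtype=float)
    c = np.asarray(c, dtype=float)
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    n = A.shape[1]
    r = np.linalg.matrix_rank(A)
    best = None
    best_x = None
    for basic in combinations(range(n), r):
        B = A[:, basic]
        if np.linalg.matrix_rank(B) < r:
            continue
        nonbasic = [j for j in range(n) if j not in basic]
        for bound_choice in product((0, 1), repeat=len(nonbasic)):
            x = np.empty(n)
            for j, side in zip(nonbasic, bound_choice):
                x[j] = lower[j] if side == 0 else upper[j]
            rhs = b - A[:, nonbasic] @ x[nonbasic] if nonbasic else b.copy()
            sol, residual, *_ = np.linalg.lstsq(B, rhs, rcond=None)
            x[list(basic)] = sol
            if np.max(np.abs(A @ x - b)) > 1e-7:
                continue
            if np.any(x < lower - tol) or np.any(x > upper + tol):
                continue
            value = float(c @ x)
            if best is None or value < best - 0.0:
                best, best_x = value, x.copy()
    if best is None:
        raise ValueError("polytope empty (no basic feasible solution)")
    return best, best_x


def _split_system(model: MetabolicModel):
    """Split-variable steady-state system, built independently."""
    met_ids = list(model.metabolites)
    rxn_ids = list(model.reactions)
    met_index = {m: i for i, m in enumerate(met_ids)}
    cols = []          # (reaction id, sign)
    lower, upper = [], []
    for rid in rxn_ids:
        rxn = model.reactions[rid]
        cols.append((rid, +1))
        lower.append(max(0.0, rxn.lower_bound))
        upper.append(max(0.0, rxn.upper_bound))
        if rxn.lower_bound < 0:
            cols.append((rid, -1))
            lower.append(max(0.0, -rxn.upper_bound))
            upper.append(-rxn.lower_bound)
    A = np.zeros((len(met_ids), len(cols)))
    for j, (rid, sign) in enumerate(cols):
        for met, coef in model.reactions[rid].stoichiometry.items():
            A[met_index[met], j] = sign * coef
    return A, cols, np.array(lower), np.array(upper)


def fba_by_enumeration(model: MetabolicModel):
    """FBA maximum by vertex enumeration (maximise = minimise negated)."""
    A, cols, lower, upper = _split_system(model)
    b = np.zeros(A.shape[0])
    c = np.array([
        -sign if rid == model.objective_reaction else 0.0
        for rid, sign in cols])
    value, _ = lp_min_by_vertex_enumeration(c, A, b, lower, upper)
    return -value


def gimme_by_enumeration(model: MetabolicModel, pattern, level: float,
                         v_max: float | None = None):
    """GIMME optimum by vertex enumeration on the explicit polytope."""
    if v_max is None:
        v_max = fba_by_enumeration(model)
    A, cols, lower, upper = _split_system(model)
    m, n = A.shape
    # slack turns v_obj >= level*v_max into an equality row
    obj_row = np.array([
        sign if rid == model.objective_reaction else 0.0
        for rid, sign in cols])
    A_full = np.zeros((m + 1, n + 1))
    A_full[:m, :n] = A
    A_full[m, :n] = obj_row
    A_full[m, n] = -1.0
    b = np.zeros(m + 1)
    b[m] = level * v_max
    lower = np.append(lower, 0.0)
    upper = np.append(upper, np.inf if v_max == 0 else 10 * max(
        abs(v_max), 1.0) * max(1.0, np.max(upper[np.isfinite(upper)])))
    c = np.zeros(n + 1)
    for j, (rid, _) in enumerate(cols):
        rxn = model.reactions[rid]
        if rxn.artificial or pattern.is_present(rid):
            continue
        c[j] = pattern.weight(rid)
    value, _ = lp_min_by_vertex_enumeration(c, A_full, b, lower, upper)
    return value


def pearson_definition(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mx, my = x.mean(), y.mean()
    num = ((x - mx) * (y - my)).sum()
    den = np.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())
    return num / den


def one_tailed_p_definition(r, n):
    """Lower-tail Student-t probability of t = r sqrt((n-2)/(1-r^2)).

    Closed form: the t CDF written out through the regularised incomplete
    beta function — derived here from the definition, not taken from
    scipy.stats.
    """
    from scipy.special import betainc

    t = r * np.sqrt((n - 2) / (1 - r * r))
    df = n - 2
    tail = 0.5 * betainc(df / 2.0, 0.5, df / (df + t * t))
    return float(tail if t < 0 else 1.0 - tail)


def one_tailed_p_by_quadrature(r, n):
    """Same probability by numerical integration of the t density."""
    from math import gamma, pi, sqrt

    t = r * sqrt((n - 2) / (1 - r * r))
    df = n - 2
    norm = gamma((df + 1) / 2.0) / (sqrt(df * pi) * gamma(df / 2.0))
    # x = tan(u) maps the real line to a finite interval
    u = np.linspace(-pi / 2 + 1e-9, np.arctan(t), 200001)
    x = np.tan(u)
    integrand = norm * (1.0 + x * x / df) ** (-(df + 1) / 2.0) / np.cos(u) ** 2
    return float(np.trapezoid(integrand, u))


def _average_ranks(values):
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values))
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and \
                values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_definition(x, y):
    return pearson_definition(_average_ranks(x), _average_ranks(y))
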