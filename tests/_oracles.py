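"""Independent brute-force oracles used to cross-check the package.

Deliberately naive implementations with no code shared with the
library's solution paths: vertex enumeration for small LPs,
scipy.linprog (HiGHS) for per-reaction flux ranges, an active-set
KKT enumeration for small convex QPs, and direct rank arithmetic for
Spearman correlation.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog
from scipy.stats import rankdata


def extract_lp(model):
    """Dense S, bounds, and column ids from a COBRA model (row by row)."""
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    cols = [r.id for r in model.reactions]
    S = np.zeros((len(met_index), len(cols)))
    lb = np.zeros(len(cols))
    ub = np.zeros(len(cols))
    for j, rxn in enumerate(model.reactions):
        lb[j], ub[j] = rxn.lower_bound, rxn.upper_bound
        for met, coeff in rxn.metabolites.items():
            S[met_index[met.id], j] = coeff
    return S, lb, ub, cols


def vertex_enumeration_max(S, lb, ub, c):
    """Maximize c'x over {Sx=0, lb<=x<=ub} by enumerating basic feasible solutions."""
    m0, n = S.shape
    rank = np.linalg.matrix_rank(S)
    best = -np.inf
    for basis in itertools.combinations(range(n), rank):
        B = S[:, basis]
        if np.linalg.matrix_rank(B) < rank:
            continue
        nonbasis = [j for j in range(n) if j not in basis]
        for bounds_choice in itertools.product(*[(lb[j], ub[j]) for j in nonbasis]):
            x = np.zeros(n)
            for j, v in zip(nonbasis, bounds_choice):
                if not np.isfinite(v):
                    break
                x[j] = v
            else:
                rhs = -S[:, nonbasis] @ x[nonbasis]
                sol, *_ = np.linalg.lstsq(B, rhs, rcond=None)
                if np.max(np.abs(B @ sol - rhs)) > 1e-8:
                    continue
                x[list(basis)] = sol
                if np.all(x >= lb - 1e-9) and np.all(x <= ub + 1e-9):
                    best = max(best, float(c @ x))
    return best


def linprog_minmax(S, lb, ub, obj, extra_A=None, extra_b=None):
    """(min, max) of obj'x over {Sx=0, bounds, extra_A x <= extra_b}."""
    n = S.shape[1]
    bounds = [(l if np.isfinite(l) else None, u if np.isfinite(u) else None) for l, u in zip(lb, ub)]
    vals = []
    for sign in (1.0, -1.0):
        res = linprog(
            sign * np.asarray(obj), A_eq=S, b_eq=np.zeros(S.shape[0]),
            A_ub=extra_A, b_ub=extra_b, bounds=bounds, method="highs",
        )
        if not res.success:
            raise RuntimeError(f"linprog oracle failed: {res.message}")
        vals.append(sign * res.fun)
    return vals[0], vals[1]


def kkt_qp_nonneg_budget(c, d, w, budget):
    """Solve min sum_i c_i (p_i - d_i)^2 s.t. w'p <= budget, p >= 0.

    Brute-force active-set enumeration: every combination of
    {budget constraint active} x {each variable pinned at zero} is
    solved through its KKT linear system and checked for primal and
    dual feasibility; the best feasible stationary point is returned.
    """
    c = np.asarray(c, float)
    d = np.asarray(d, float)
    w = np.asarray(w, float)
    n = len(c)
    best, best_obj = None, np.inf
    for budget_active in (False, True):
        for zero_mask in itertools.product((False, True), repeat=n):
            zero = np.array(zero_mask)
            free = ~zero
            p = np.zeros(n)
            mu = 0.0  # multiplier of the budget constraint
            if budget_active:
                # stationarity on free vars: 2c(p-d) + mu*w = 0
                # with w'p = budget
                idx = np.where(free)[0]
                if len(idx) == 0:
                    if abs(budget) > 1e-12:
                        continue
                else:
                    cf, df, wf = c[idx], d[idx], w[idx]
                    if np.any(cf <= 0):
                        continue  # zero-weight vars handled by non-active branch
                    denom = float(np.sum(wf * wf / (2 * cf)))
                    if denom <= 0:
                        continue
                    mu = (float(wf @ df) - budget) / denom
                    p[idx] = df - mu * wf / (2 * cf)
            else:
                p[free] = d[free]
            # primal feasibility
            if np.any(p < -1e-9) or float(w @ p) > budget + 1e-9:
                continue
            # dual feasibility: mu >= 0; pinned vars need gradient >= 0
            if mu < -1e-9:
                continue
            grad = 2 * c * (p - d) + mu * w
            if np.any(grad[zero] < -1e-9):
                continue
            obj = float(np.sum(c * (p - d) ** 2))
            if obj < best_obj - 1e-15:
                best_obj, best = obj, p.copy()
    return best, best_obj


def brute_spearman(x, y):
    """Spearman rho by explicit average ranks + Pearson formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    if len(x) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rx = rankdata(x)
    ry = rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def brute_metabolite_degrees(model, merge=False):
    """Independent O(M*R) recount of metabolite connectivity."""
    from pcgem.gem_core import base_metabolite_id, is_pseudo_reaction

    keys = {base_metabolite_id(m) if merge else m.id for m in model.metabolites}
    out = {}
    for key in keys:
        seen = set()
        for rxn in model.reactions:
            if is_pseudo_reaction(rxn):
                continue
            if any(
                (base_metabolite_id(m2) if merge else m2.id) == key and c != 0
                for m2, c in rxn.metabolites.items()
            ):
                seen.add(rxn.id)
        out[key] = len(seen)
    return out
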