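"""Independent brute-force oracles used to freeze expected values.

Everything here is deliberately naive and kept separate from the library
code paths it checks: exhaustive vertex enumeration for small LPs, dense
loop-based stoichiometric-matrix construction, quadratic-time complete
linkage, exact hypergeometric tails via integer combinatorics, and a
hand-rolled Benjamini-Hochberg step-up.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


# ---------------------------------------------------------------------------
# LP vertex enumeration
# ---------------------------------------------------------------------------

def enumerate_vertices(S, b, lb, ub, tol=1e-9):
    """All vertices of {v : S v = b, lb <= v <= ub} (finite bounds).

    A vertex fixes at least n - rank(S) variables at a bound; enumerate
    every basic/nonbasic split and bound assignment, solve the square-ish
    system for the basic part, keep feasible solutions.  Exponential — for
    tiny networks only.
    """
    S = np.asarray(S, dtype=float)
    b = np.asarray(b, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    m, n = S.shape
    r = np.linalg.matrix_rank(S) if m else 0
    vertices = []
    seen = set()

    def record(v):
        if not (np.all(v >= lb - 1e-7) and np.all(v <= ub + 1e-7)):
            return
        if m and np.max(np.abs(S @ v - b)) > 1e-6:
            return
        key = tuple(np.round(v, 7))
        if key not in seen:
            seen.add(key)
            vertices.append(np.clip(v, lb, ub))

    if r == 0:
        # box: vertices are all bound combinations
        for corner in itertools.product(*[(l, u) for l, u in zip(lb, ub)]):
            record(np.array(corner))
        return vertices

    for basic in itertools.combinations(range(n), r):
        SB = S[:, basic]
        if np.linalg.matrix_rank(SB) < r:
            continue
        nonbasic = [j for j in range(n) if j not in basic]
        for corner in itertools.product(
            *[(lb[j], ub[j]) for j in nonbasic]
        ):
            rhs = b - S[:, nonbasic] @ np.array(corner) if nonbasic else b
            vB, res, *_ = np.linalg.lstsq(SB, rhs, rcond=None)
            v = np.empty(n)
            v[list(basic)] = vB
            v[nonbasic] = corner
            record(v)
    return vertices


def brute_force_fba(model, sense="max"):
    """FBA objective by exhaustive vertex enumeration; returns (Z, vertex)."""
    from fluxomix.gem_model import build_stoichiometric_matrix

    smat = build_stoichiometric_matrix(model)
    S = smat.values.toarray()
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    c = np.array([model.objective.get(r.id, 0.0) for r in model.reactions])
    verts = enumerate_vertices(S, np.zeros(S.shape[0]), lb, ub)
    if not verts:
        return None, None
    vals = [c @ v for v in verts]
    idx = int(np.argmax(vals)) if sense == "max" else int(np.argmin(vals))
    return vals[idx], verts[idx]


def brute_force_pfba_l1(model, sense="max"):
    """Minimum total absolute flux over the vertices of the optimal face."""
    from fluxomix.gem_model import build_stoichiometric_matrix

    z_star, _ = brute_force_fba(model, sense)
    smat = build_stoichiometric_matrix(model)
    S = smat.values.toarray()
    c = np.array([model.objective.get(r.id, 0.0) for r in model.reactions])
    S_aug = np.vstack([S, c])
    b_aug = np.concatenate([np.zeros(S.shape[0]), [z_star]])
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    verts = enumerate_vertices(S_aug, b_aug, lb, ub)
    return min(np.abs(v).sum() for v in verts), z_star


def dense_stoichiometric_matrix(model):
    """Loop-based dense construction of S from the reaction list."""
    met_ids = [m.id for m in model.metabolites]
    out = np.zeros((len(met_ids), len(model.reactions)))
    for j, rxn in enumerate(model.reactions):
        for mid, coef in rxn.stoichiometry.items():
            out[met_ids.index(mid), j] += coef
    return out


# ---------------------------------------------------------------------------
# Clustering / ordering oracles
# ---------------------------------------------------------------------------

def complete_linkage_leaf_order(X, labels):
    """Naive O(n^3) complete-linkage agglomeration; leaf order with the
    earlier-formed (lower-id) cluster placed left, as scipy orders leaves.
    Assumes pairwise distances are unique."""
    n = len(labels)
    clusters = {i: [i] for i in range(n)}
    members = {i: (labels[i],) for i in range(n)}
    dist = {
        (i, j): float(np.linalg.norm(X[i] - X[j]))
        for i in range(n) for j in range(i + 1, n)
    }

    def cdist(a, b):
        return max(
            dist[(min(i, j), max(i, j))]
            for i in clusters[a] for j in clusters[b]
        )

    trees = {i: labels[i] for i in range(n)}
    next_id = n
    active = list(range(n))
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                d = cdist(a, b)
                if best is None or d < best[0]:
                    best = (d, min(a, b), max(a, b))
        _, a, b = best
        clusters[next_id] = clusters[a] + clusters[b]
        trees[next_id] = (trees[a], trees[b])   # lower id on the left
        active = [x for x in active if x not in (a, b)] + [next_id]
        next_id += 1

    order = []

    def walk(node):
        if isinstance(node, tuple):
            walk(node[0])
            walk(node[1])
        else:
            order.append(node)

    walk(trees[next_id - 1])
    return order


# ---------------------------------------------------------------------------
# Exact combinatorics
# ---------------------------------------------------------------------------

def hypergeom_tail_exact(overlap, N, K, n):
    """P(X >= overlap) by exact rational pmf summation."""
    total = Fraction(0)
    denom = math.comb(N, n)
    for x in range(overlap, min(K, n) + 1):
        total += Fraction(math.comb(K, x) * math.comb(N - K, n - x), denom)
    return float(total)


def bh_stepup_by_hand(pvalues):
    """Benjamini-Hochberg step-up, written out longhand."""
    p = list(pvalues)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    q = [0.0] * n
    prev = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = n - rank_from_end
        val = min(prev, p[idx] * n / rank)
        q[idx] = val
        prev = val
    return q
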