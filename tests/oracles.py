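"""Independent oracles used by the test suite.

Each oracle is deliberately implemented apart from the package code it
checks: GPR trees are built and evaluated as plain nested tuples, LP
optima come from exhaustive vertex enumeration of the bounded polytope,
and the exact two-sample Kolmogorov–Smirnov p-value is computed by
integer lattice-path counting.
"""

import itertools
from math import comb

import numpy as np

# -- GPR / RAS oracle --------------------------------------------------


def random_gpr_tuple(rng, genes, max_depth=4):
    """Random GPR as nested tuples ('and'|'or', [children]) or ('gene', id)."""
    if max_depth == 0 or rng.random() < 0.4:
        return ("gene", genes[rng.integers(len(genes))])
    op = "and" if rng.random() < 0.5 else "or"
    n_children = int(rng.integers(2, 4))
    children = [random_gpr_tuple(rng, genes, max_depth - 1) for _ in range(n_children)]
    return (op, children)


def tuple_to_text(node):
    if node[0] == "gene":
        return node[1]
    parts = [f"({tuple_to_text(c)})" for c in node[1]]
    return f" {node[0]} ".join(parts)


def eval_tuple(node, expr):
    """Brute-force RAS on the tuple form: or=sum, and=min, absent dropped."""
    if node[0] == "gene":
        return expr.get(node[1])
    vals = [v for v in (eval_tuple(c, expr) for c in node[1]) if v is not None]
    if not vals:
        return None
    return sum(vals) if node[0] == "or" else min(vals)


# -- LP vertex enumeration ---------------------------------------------


def enumerate_vertices(S, lb, ub, tol=1e-7):
    """All vertices of {v : S v = 0, lb <= v <= ub} by active-set enumeration.

    A vertex has at least n - rank(S) bounds active; every size-(n-rank)
    subset of bounds whose normals complete the row space to full rank
    pins exactly one candidate, which is kept if feasible.
    """
    S = np.asarray(S, float)
    lb = np.asarray(lb, float)
    ub = np.asarray(ub, float)
    m, n = S.shape
    rank = np.linalg.matrix_rank(S) if m else 0
    k = n - rank
    vertices = []
    for idx in itertools.combinations(range(n), k):
        free = [j for j in range(n) if j not in idx]
        A = S[:, free]
        if np.linalg.matrix_rank(A) < len(free):
            continue
        for vals in itertools.product(*[(lb[j], ub[j]) for j in idx]):
            b = -S[:, list(idx)] @ np.array(vals)
            sol, *_ = np.linalg.lstsq(A, b, rcond=None)
            v = np.zeros(n)
            v[list(idx)] = vals
            v[free] = sol
            if m and np.max(np.abs(S @ v)) > tol:
                continue
            if (v < lb - tol).any() or (v > ub + tol).any():
                continue
            vertices.append(v)
    if not vertices:
        return np.empty((0, n))
    return np.unique(np.round(np.array(vertices), 9), axis=0)


def vertex_fba_optimum(S, lb, ub, c):
    """Maximum of c·v over the polytope via its vertices."""
    verts = enumerate_vertices(S, lb, ub)
    assert len(verts), "polytope has no vertices (infeasible fixture?)"
    return float(np.max(verts @ np.asarray(c, float)))


def vertex_fva(S, lb, ub, c=None, at_optimum=False, tol=1e-6):
    """Per-reaction min/max over vertices; optionally only over the optimal face.

    Valid for flux variability at optimum fraction 0 (whole polytope)
    and fraction 1 (the optimal face is a face, so its vertices are
    polytope vertices); intermediate fractions cut the polytope and
    create new vertices, so enumeration does not apply there.
    """
    verts = enumerate_vertices(S, lb, ub)
    if at_optimum:
        values = verts @ np.asarray(c, float)
        verts = verts[values >= values.max() - tol]
    return verts.min(axis=0), verts.max(axis=0)


# -- exact two-sample KS -----------------------------------------------


def exact_ks_pvalue(x, y):
    """Exact two-sided two-sample KS p-value by lattice-path counting.

    Under H0 all interleavings of the pooled (tie-free) sample are
    equally likely; P(D >= d) is one minus the fraction of monotone
    lattice paths from (0,0) to (n1,n2) that keep
    |i*n2 - j*n1| < d*n1*n2 throughout (integer arithmetic).
    """
    x = np.sort(np.asarray(x, float))
    y = np.sort(np.asarray(y, float))
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    assert len(np.unique(pooled)) == n1 + n2, "oracle requires tie-free data"
    # observed statistic as an integer: max |i*n2 - j*n1|
    i = j = 0
    h_obs = 0
    while i < n1 or j < n2:
        if j >= n2 or (i < n1 and x[i] < y[j]):
            i += 1
        else:
            j += 1
        h_obs = max(h_obs, abs(i * n2 - j * n1))
    # count paths with max |i*n2 - j*n1| < h_obs
    counts = {(0, 0): 1}
    for _ in range(n1 + n2):
        nxt = {}
        for (i, j), ways in counts.items():
            for (a, b) in ((i + 1, j), (i, j + 1)):
                if a > n1 or b > n2:
                    continue
                if abs(a * n2 - b * n1) >= h_obs:
                    continue
                nxt[(a, b)] = nxt.get((a, b), 0) + ways
        counts = nxt
    good = counts.get((n1, n2), 0)
    return 1.0 - good / comb(n1 + n2, n1)
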