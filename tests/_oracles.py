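"""Independent oracles used across the test suite.

These deliberately avoid the package's own code paths: dense Gaussian
conditioning from a path-sharing covariance, entropic OT by generic
constrained minimization, exact transport by atom-splitting assignment,
and least-squares tree fitting by exhaustive topology enumeration.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment, linprog, minimize


# ---------------------------------------------------------------------------
# Gaussian tree model
# ---------------------------------------------------------------------------

def path_sharing_covariance(tree, reference, D=1.0, span_floor=0.0):
    """Covariance of node states relative to a reference leaf.

    Each edge contributes an independent increment of variance D*span; the
    covariance of two nodes is D times the summed span of the edges shared
    by their paths from the reference.
    """
    g = tree.graph.to_undirected(as_view=True)
    nodes = [v for v in tree.graph.nodes if v != reference]
    paths = {v: nx.shortest_path(g, reference, v) for v in nodes}

    def edges_of(path):
        return {frozenset(e) for e in zip(path[:-1], path[1:])}

    span = {frozenset((u, v)): max(tree.edge_span(u, v), span_floor)
            for u, v in tree.graph.edges}
    C = np.zeros((len(nodes), len(nodes)))
    esets = {v: edges_of(paths[v]) for v in nodes}
    for i, a in enumerate(nodes):
        for j, b in enumerate(nodes):
            shared = esets[a] & esets[b]
            C[i, j] = D * sum(span[e] for e in shared)
    return C, nodes


def dense_conditional(tree, Y_by_cell, model, reference=None):
    """Brute-force Gaussian conditioning for ancestor states at t1.

    Builds the explicit joint covariance of all nodes relative to a
    reference leaf, conditions on the observed leaves with the standard
    covariance formulas, and reads off the t1-node means/variances.
    Returns (means dict node->vector, variances dict node->scalar,
    ancestors dict cell->node), for the augmented tree.
    """
    from treeot.ancestors import insert_time_slice

    aug, anc = insert_time_slice(tree, model.t1)
    leaves = aug.leaves()
    if reference is None:
        reference = leaves[0]
    floor = 1e-9 * (model.t2 - model.t1)
    C, nodes = path_sharing_covariance(aug, reference, model.D, floor)
    idx = {v: i for i, v in enumerate(nodes)}
    y0 = np.asarray(Y_by_cell[aug.leaf_cells[reference]], float)
    obs = [v for v in leaves if v != reference]
    unobs = [v for v in nodes if v not in obs]
    O = [idx[v] for v in obs]
    U = [idx[v] for v in unobs]
    means, variances = {}, {}
    if O:
        Yrel = np.stack([np.asarray(Y_by_cell[aug.leaf_cells[v]], float) - y0
                         for v in obs])
        Coo = C[np.ix_(O, O)]
        Cuo = C[np.ix_(U, O)]
        sol = np.linalg.solve(Coo, Yrel)
        mu = Cuo @ sol
        cond = C[np.ix_(U, U)] - Cuo @ np.linalg.solve(Coo, Cuo.T)
    else:
        mu = np.zeros((len(U), np.size(y0)))
        cond = C[np.ix_(U, U)]
    for k, v in enumerate(unobs):
        means[v] = mu[k] + y0
        variances[v] = cond[k, k]
    return means, variances, anc


def random_timed_tree(rng, n_leaves, t2=1.0, t_root=0.0):
    """Random rooted binary tree: leaves at t2, random division times.

    Grown by repeatedly grafting a new leaf onto a uniformly chosen edge
    at a uniform time along it, which produces arbitrary (non-ultrametric
    internal) division-time structure while keeping all leaves at t2.
    """
    from treeot.tree import LineageTree

    g = nx.DiGraph()
    g.add_node("r", time=t_root)
    g.add_node("L0", time=t2)
    g.add_node("L1", time=t2)
    g.add_edge("r", "L0")
    g.add_edge("r", "L1")
    nxt = [2]
    while sum(1 for v in g if g.out_degree(v) == 0) < n_leaves:
        edges = list(g.edges)
        u, v = edges[int(rng.integers(len(edges)))]
        tu, tv = g.nodes[u]["time"], g.nodes[v]["time"]
        if tv - tu < 1e-6:
            continue
        t = float(rng.uniform(tu + 1e-9, tv - 1e-9))
        w = f"i{nxt[0]}"
        leaf = f"L{nxt[0]}"
        nxt[0] += 1
        g.remove_edge(u, v)
        g.add_node(w, time=t)
        g.add_node(leaf, time=t2)
        g.add_edge(u, w)
        g.add_edge(w, v)
        g.add_edge(w, leaf)
    return LineageTree(g, "r")


# ---------------------------------------------------------------------------
# Optimal transport
# ---------------------------------------------------------------------------

def entropic_ot_minimize(C, a, b, eps):
    """Entropic OT by direct constrained minimization (SLSQP), independent
    of Sinkhorn.  Returns the optimal coupling matrix."""
    n, m = C.shape

    def fun(x):
        x = np.clip(x, 1e-300, None)
        return float((x * C.ravel()).sum() + eps * (x * np.log(x)).sum())

    def jac(x):
        x = np.clip(x, 1e-300, None)
        return C.ravel() + eps * (np.log(x) + 1.0)

    cons = []
    for i in range(n):
        A = np.zeros(n * m)
        A[i * m:(i + 1) * m] = 1.0
        cons.append({"type": "eq", "fun": (lambda x, A=A, t=a[i]: A @ x - t),
                     "jac": lambda x, A=A: A})
    for j in range(m - 1):
        A = np.zeros(n * m)
        A[j::m] = 1.0
        cons.append({"type": "eq", "fun": (lambda x, A=A, t=b[j]: A @ x - t),
                     "jac": lambda x, A=A: A})
    x0 = np.outer(a, b).ravel()
    res = minimize(fun, x0, jac=jac, method="SLSQP", bounds=[(1e-12, 1)] * (n * m),
                   constraints=cons, options={"maxiter": 2000, "ftol": 1e-16})
    return res.x.reshape(n, m)


def exact_ot_cost(C, a, b):
    """Exact (unregularized) transport cost by linear programming."""
    n, m = C.shape
    Aeq = []
    for i in range(n):
        row = np.zeros(n * m)
        row[i * m:(i + 1) * m] = 1
        Aeq.append(row)
    for j in range(m - 1):
        row = np.zeros(n * m)
        row[j::m] = 1
        Aeq.append(row)
    rhs = np.concatenate([a, b[:-1]])
    res = linprog(C.ravel(), A_eq=np.array(Aeq), b_eq=rhs, bounds=(0, None),
                  method="highs")
    assert res.success
    return float(res.fun)


def w2sq_by_assignment(mu, nu, X, Y, denom):
    """Exact squared W2 for weights that are multiples of 1/denom, by
    splitting mass into equal atoms and solving an assignment problem."""
    mu = np.asarray(mu, float) / np.sum(mu)
    nu = np.asarray(nu, float) / np.sum(nu)
    ka = np.rint(mu * denom).astype(int)
    kb = np.rint(nu * denom).astype(int)
    assert ka.sum() == denom and kb.sum() == denom
    A = np.repeat(np.arange(len(mu)), ka)
    B = np.repeat(np.arange(len(nu)), kb)
    X = np.atleast_2d(X)
    Y = np.atleast_2d(Y)
    C = ((X[A][:, None, :] - Y[B][None, :, :]) ** 2).sum(-1)
    r, c = linear_sum_assignment(C)
    return float(C[r, c].sum() / denom)


# ---------------------------------------------------------------------------
# Trees from distances
# ---------------------------------------------------------------------------

def best_quartet_tree(D):
    """Least-squares fit of all three unrooted 4-leaf topologies.

    Returns (topology, edge lengths) where topology is the pair grouped
    with leaf 0, e.g. (0,1)|(2,3) encoded as the partner of leaf 0.
    """
    best = None
    for partner in (1, 2, 3):
        others = [k for k in (1, 2, 3) if k != partner]
        # unknowns: 4 leaf edges + internal edge
        # path(i,j) = li + lj (+ internal if across the split)
        rows, y = [], []
        for i, j in itertools.combinations(range(4), 2):
            r = np.zeros(5)
            r[i] = r[j] = 1
            same = ({i, j} == {0, partner}) or ({i, j} == set(others))
            if not same:
                r[4] = 1
            rows.append(r)
            y.append(D[i, j])
        sol, res, *_ = np.linalg.lstsq(np.array(rows), np.array(y), rcond=None)
        sse = float(((np.array(rows) @ sol - y) ** 2).sum())
        if best is None or sse < best[0]:
            best = (sse, partner, sol)
    return best[1], best[2]


def leaf_split_set(graph_undirected, leaves):
    """Set of nontrivial leaf bipartitions induced by edges (topology key)."""
    splits = set()
    g = graph_undirected
    all_leaves = frozenset(leaves)
    for u, v in g.edges:
        h = g.copy()
        h.remove_edge(u, v)
        comp = nx.node_connected_component(h, u)
        side = frozenset(l for l in leaves if l in comp)
        if 1 < len(side) < len(leaves) - 1:
            splits.add(frozenset((side, all_leaves - side)))
    return splits
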