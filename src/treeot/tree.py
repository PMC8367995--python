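"""Lineage trees: data structure, barcode distances, neighbor joining, ultrametric correction.

A :class:`LineageTree` is a rooted tree whose nodes carry absolute times
(in experiment units since a configurable origin, usually the start of
barcoding).  Leaves correspond to sampled cells.  Synchronized sampling
implies the tree should be ultrametric: every leaf sits at the common
sampling time.  Trees reconstructed from noisy barcode distances are not
ultrametric, so :func:`root_and_correct` projects the raw branch lengths
onto the ultrametric cone by a quadratic program and rescales them to
absolute time.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import networkx as nx
import numpy as np
from scipy.optimize import LinearConstraint, minimize

__all__ = [
    "LineageTree",
    "barcode_distance_matrix",
    "neighbor_join",
    "midpoint_root",
    "root_and_correct",
    "fit_tree",
    "read_newick",
    "write_newick",
]


class TreeError(ValueError):
    """Raised for structurally invalid tree inputs."""


@dataclass
class LineageTree:
    """Rooted lineage tree with absolute node times.

    Parameters
    ----------
    graph
        Directed graph, edges parent -> child.  Every node has a ``time``
        attribute (absolute time); leaves may carry ``state`` (ndarray) and
        ``barcode`` attributes.
    root
        Identifier of the unique root node.
    leaf_cells
        Mapping leaf node id -> cell id (row identifier in the state
        matrix).  Defaults to the identity on leaves.
    """

    graph: nx.DiGraph
    root: object
    leaf_cells: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.leaf_cells:
            self.leaf_cells = {v: v for v in self.leaves()}
        self.validate()

    # -- structure ---------------------------------------------------------
    def validate(self) -> None:
        g = self.graph
        if self.root not in g:
            raise TreeError(f"root {self.root!r} not in graph")
        roots = [v for v in g if g.in_degree(v) == 0]
        if roots != [self.root] and set(roots) != {self.root}:
            raise TreeError(f"expected exactly one root, found {roots}")
        if not nx.is_arborescence(g):
            raise TreeError("graph is not a rooted tree (arborescence)")
        for u, v in g.edges:
            tu, tv = g.nodes[u].get("time"), g.nodes[v].get("time")
            if tu is None or tv is None:
                continue
            if tv < tu - 1e-12 * max(1.0, abs(tu)):
                raise TreeError(f"child {v!r} earlier than parent {u!r}")

    def leaves(self) -> list:
        return [v for v in self.graph if self.graph.out_degree(v) == 0]

    def parent(self, v):
        preds = list(self.graph.predecessors(v))
        return preds[0] if preds else None

    def time(self, v) -> float:
        return self.graph.nodes[v]["time"]

    def n_leaves(self) -> int:
        return len(self.leaves())

    def copy(self) -> "LineageTree":
        return LineageTree(self.graph.copy(), self.root, dict(self.leaf_cells))

    def edge_span(self, u, v) -> float:
        return abs(self.time(v) - self.time(u))

    def depths(self) -> dict:
        """Root-to-node time depth for every node."""
        t0 = self.time(self.root)
        return {v: self.time(v) - t0 for v in self.graph}

    def pairwise_leaf_distances(self, order: Sequence | None = None) -> np.ndarray:
        """Tree (path-length) distance matrix between leaves, in time units.

        For an ultrametric tree this equals ``2*(t_leaf - t_mrca)`` for each
        pair.
        """
        leaves = list(order) if order is not None else self.leaves()
        ug = self.graph.to_undirected(as_view=True)
        n = len(leaves)
        D = np.zeros((n, n))
        lengths = dict(
            nx.all_pairs_dijkstra_path_length(
                ug, weight=lambda u, v, d: self.edge_span(u, v)
            )
        )
        for i, a in enumerate(leaves):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = lengths[a][leaves[j]]
        return D

    def is_ultrametric(self, rtol: float = 1e-9) -> bool:
        t0 = self.time(self.root)
        depths = [self.time(v) - t0 for v in self.leaves()]
        scale = max(abs(d) for d in depths) or 1.0
        return (max(depths) - min(depths)) <= rtol * scale


# ---------------------------------------------------------------------------
# Barcode distances
# ---------------------------------------------------------------------------

def barcode_distance_matrix(barcodes: np.ndarray) -> np.ndarray:
    """Pairwise Hamming distances (counts of differing sites) between barcodes.

    Parameters
    ----------
    barcodes
        Integer array, cells x sites; 0 marks an unmutated site, 1..S a
        mutated state.

    Returns
    -------
    Symmetric nonnegative integer-valued matrix with zero diagonal.
    """
    B = np.asarray(barcodes)
    if B.ndim != 2:
        raise ValueError("barcode matrix must be 2-dimensional (cells x sites)")
    if B.shape[0] < 2:
        raise ValueError("need at least two barcodes")
    # all sites compared; no missing-data code
    diff = B[:, None, :] != B[None, :, :]
    return diff.sum(axis=2).astype(float)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_join(distances: np.ndarray, leaf_ids: Sequence | None = None) -> nx.Graph:
    """Classic neighbor joining on a distance matrix.

    Returns an unrooted binary tree as an undirected graph with a ``length``
    attribute on every edge.  Ties in the Q-matrix minimization are broken
    at the lowest (row, col) index, and negative branch-length estimates are
    kept (downstream ultrametric correction imposes nonnegativity).
    """
    D = np.asarray(distances, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[1] != n:
        raise ValueError("distance matrix must be square")
    if n < 2:
        raise ValueError("need at least two leaves")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if (D < -1e-12).any():
        raise ValueError("distances must be nonnegative")
    if leaf_ids is None:
        leaf_ids = list(range(n))
    leaf_ids = list(leaf_ids)
    if len(leaf_ids) != n:
        raise ValueError("leaf_ids length must match distance matrix")

    g = nx.Graph()
    g.add_nodes_from(leaf_ids)
    if n == 2:
        mid = _fresh_id(leaf_ids, 0)
        g.add_edge(leaf_ids[0], mid, length=D[0, 1] / 2.0)
        g.add_edge(leaf_ids[1], mid, length=D[0, 1] / 2.0)
        return g

    active = list(leaf_ids)
    D = D.copy()
    counter = 0
    while len(active) > 3:
        m = len(active)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest (row, col) among minima, row-major
        i, j = np.unravel_index(int(np.argmin(Q)), Q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        new = _fresh_id(leaf_ids, counter)
        counter += 1
        g.add_edge(active[i], new, length=li)
        g.add_edge(active[j], new, length=lj)
        d_new = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = d_new[keep]
        D2[-1, -1] = 0.0
        D = D2
        active = [active[k] for k in keep] + [new]

    # final three taxa: closed-form star
    d12, d13, d23 = D[0, 1], D[0, 2], D[1, 2]
    center = _fresh_id(leaf_ids, counter)
    g.add_edge(active[0], center, length=0.5 * (d12 + d13 - d23))
    g.add_edge(active[1], center, length=0.5 * (d12 + d23 - d13))
    g.add_edge(active[2], center, length=0.5 * (d13 + d23 - d12))
    return g


def _fresh_id(leaf_ids, counter):
    cand = f"_nj{counter}"
    taken = set(map(str, leaf_ids))
    while cand in taken:
        cand += "_"
    return cand


# ---------------------------------------------------------------------------
# Rooting and ultrametric correction
# ---------------------------------------------------------------------------

def midpoint_root(unrooted: nx.Graph, root_id: str = "_root") -> nx.DiGraph:
    """Root an unrooted tree at the midpoint of its longest leaf-to-leaf path.

    Returns a directed (parent -> child) graph whose edges keep their raw
    ``length`` attributes.  If the midpoint falls on an existing node, that
    node becomes the root; otherwise a new degree-2 node is inserted.
    """
    leaves = [v for v in unrooted if unrooted.degree(v) == 1]
    if len(leaves) < 2:
        raise TreeError("need at least two leaves to midpoint-root")
    wl = lambda u, v, d: d["length"]
    best = (-np.inf, None, None)
    dist = dict(nx.all_pairs_dijkstra_path_length(unrooted, weight=wl))
    for i, a in enumerate(leaves):
        for b in leaves[i + 1:]:
            if dist[a][b] > best[0]:
                best = (dist[a][b], a, b)
    total, a, b = best
    path = nx.shortest_path(unrooted, a, b, weight=wl)
    half = total / 2.0
    acc = 0.0
    root = None
    g = unrooted.copy()
    for u, v in zip(path[:-1], path[1:]):
        length = g[u][v]["length"]
        if acc + length >= half or (u, v) == (path[-2], path[-1]):
            frac = 0.0 if length <= 0 else (half - acc) / length
            frac = min(max(frac, 0.0), 1.0)
            if frac <= 1e-12:
                root = u
            elif frac >= 1 - 1e-12:
                root = v
            else:
                root = root_id
                g.remove_edge(u, v)
                g.add_edge(u, root, length=length * frac)
                g.add_edge(root, v, length=length * (1 - frac))
            break
        acc += length
    directed = nx.bfs_tree(g, root)
    for u, v in directed.edges:
        directed[u][v]["length"] = g[u][v]["length"]
    return directed


def root_and_correct(
    tree: nx.Graph | nx.DiGraph | LineageTree,
    sampling_time: float,
    root_time: float = 0.0,
) -> LineageTree:
    """Project raw branch lengths onto the ultrametric cone and assign times.

    Solves the quadratic program

        minimize   sum_e (x_e - raw_e)^2
        subject to sum_{e in path(root, leaf)} x_e = h   for every leaf,
                   x_e >= 0,  h >= 0

    (equal root-to-leaf path sums, i.e. synchronized sampling), then rescales
    so every leaf depth equals ``sampling_time - root_time`` and assigns node
    times ``root_time + depth``.

    Accepts an unrooted graph (midpoint-rooted first), a rooted directed
    graph with ``length`` edge attributes, or a :class:`LineageTree` (whose
    edge spans are taken as raw lengths).
    """
    if sampling_time <= root_time:
        raise ValueError("sampling_time must exceed root_time")
    if isinstance(tree, LineageTree):
        directed = nx.DiGraph()
        directed.add_nodes_from(tree.graph.nodes)
        for u, v in tree.graph.edges:
            directed.add_edge(u, v, length=tree.edge_span(u, v))
        root = tree.root
        leaf_cells = dict(tree.leaf_cells)
    elif isinstance(tree, nx.DiGraph):
        directed, leaf_cells = tree.copy(), {}
        roots = [v for v in directed if directed.in_degree(v) == 0]
        if len(roots) != 1:
            raise TreeError("rooted input must have exactly one root")
        root = roots[0]
    else:
        directed = midpoint_root(tree)
        leaf_cells = {}
        root = next(v for v in directed if directed.in_degree(v) == 0)

    edges = list(directed.edges)
    raw = np.array([directed[u][v]["length"] for u, v in edges], dtype=float)
    leaves = [v for v in directed if directed.out_degree(v) == 0]
    E = len(edges)
    eidx = {e: k for k, e in enumerate(edges)}

    # path incidence: rows = leaves, cols = edges (+1 col for -h)
    A = np.zeros((len(leaves), E + 1))
    for r, leaf in enumerate(leaves):
        v = leaf
        while v != root:
            u = next(directed.predecessors(v))
            A[r, eidx[(u, v)]] = 1.0
            v = u
    A[:, -1] = -1.0

    x = _ultrametric_qp(raw, A)
    lengths, h = x[:-1], x[-1]

    if h <= 1e-12 * max(1.0, np.abs(raw).sum()):
        # degenerate all-zero raw lengths: fall back to uniform edge times
        # proportional to topological depth
        depth = {root: 0}
        maxd = 0
        for u, v in nx.bfs_edges(directed, root):
            depth[v] = depth[u] + 1
            maxd = max(maxd, depth[v])
        # equalize: every leaf gets depth maxd by stretching its last edge
        span = sampling_time - root_time
        times = {}
        for v in directed:
            if directed.out_degree(v) == 0:
                times[v] = sampling_time
            else:
                times[v] = root_time + span * depth[v] / max(maxd, 1)
    else:
        scale = (sampling_time - root_time) / h
        times = {root: root_time}
        for u, v in nx.bfs_edges(directed, root):
            times[v] = times[u] + scale * max(lengths[eidx[(u, v)]], 0.0)

    out = nx.DiGraph()
    for v in directed:
        out.add_node(v, time=float(times[v]), **{
            k: val for k, val in directed.nodes[v].items() if k != "time"
        })
    out.add_edges_from(directed.edges)
    return LineageTree(out, root, leaf_cells)


def _ultrametric_qp(raw: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Solve min ||x[:-1] - raw||^2 s.t. A @ x = 0, x >= 0."""
    E = raw.size
    n = E + 1
    h0 = max(float(np.abs(raw).max(initial=0.0)) * A.shape[1], 1.0)
    # feasible start: uniform lengths summing to equal depths
    depth_counts = A[:, :-1].sum(axis=1)
    h_start = depth_counts.max()
    x0 = np.empty(n)
    x0[:-1] = 1.0
    x0[-1] = h_start

    def fun(x):
        d = x[:-1] - raw
        return float(d @ d)

    def jac(x):
        gr = np.zeros_like(x)
        gr[:-1] = 2.0 * (x[:-1] - raw)
        return gr

    cons = LinearConstraint(A, 0.0, 0.0)
    bounds = [(0.0, None)] * n
    res = minimize(
        fun, x0, jac=jac, method="SLSQP", bounds=bounds,
        constraints=[{"type": "eq", "fun": lambda x: A @ x, "jac": lambda x: A}],
        options={"maxiter": 1000, "ftol": 1e-14},
    )
    if not res.success or np.abs(A @ res.x).max() > 1e-6:
        res = minimize(
            fun, x0, jac=jac, method="trust-constr", bounds=bounds,
            constraints=[cons], options={"maxiter": 5000, "gtol": 1e-12, "xtol": 1e-14},
        )
    x = np.maximum(res.x, 0.0)
    return x


def fit_tree(
    barcodes: np.ndarray,
    sampling_time: float,
    root_time: float = 0.0,
    cell_ids: Sequence | None = None,
) -> LineageTree:
    """Barcodes -> Hamming distances -> neighbor joining -> ultrametric tree.

    Convenience pipeline producing a timed lineage tree for the late sample
    from observed barcodes alone.
    """
    n = np.asarray(barcodes).shape[0]
    ids = list(cell_ids) if cell_ids is not None else list(range(n))
    D = barcode_distance_matrix(barcodes)
    unrooted = neighbor_join(D, ids)
    tree = root_and_correct(unrooted, sampling_time, root_time)
    tree.leaf_cells = {v: v for v in tree.leaves()}
    return tree


# ---------------------------------------------------------------------------
# Newick I/O (via dendropy)
# ---------------------------------------------------------------------------

def _to_dendropy(tree: LineageTree) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace()
    dt = dendropy.Tree(taxon_namespace=taxa)

    def build(node_id, dnode):
        for child in tree.graph.successors(node_id):
            c = dnode.new_child()
            c.edge.length = tree.edge_span(node_id, child)
            if tree.graph.out_degree(child) == 0:
                c.taxon = taxa.new_taxon(str(child))
            else:
                c.label = str(child)
            build(child, c)

    dt.seed_node.label = str(tree.root)
    build(tree.root, dt.seed_node)
    return dt


def write_newick(tree: LineageTree, path) -> None:
    """Write a timed lineage tree to Newick (branch lengths mandatory)."""
    dt = _to_dendropy(tree)
    s = dt.as_string(schema="newick", suppress_rooting=True,
                     suppress_internal_node_labels=False)
    with open(path, "w") as fh:
        fh.write(s)


def read_newick(path_or_handle, root_time: float = 0.0) -> LineageTree:
    """Parse a Newick file into a :class:`LineageTree`.

    Node times are assigned as ``root_time + cumulative branch length``.
    Missing branch lengths default to 0.  Malformed input raises a parse
    error carrying dendropy's position information.
    """
    if hasattr(path_or_handle, "read"):
        data = path_or_handle.read()
    else:
        with open(path_or_handle) as fh:
            data = fh.read()
    try:
        dt = dendropy.Tree.get(data=data, schema="newick",
                               suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ValueError(f"malformed Newick: {exc}") from exc

    g = nx.DiGraph()
    counter = [0]

    def name_of(dnode):
        if dnode.taxon is not None:
            return dnode.taxon.label
        if dnode.label:
            return dnode.label
        counter[0] += 1
        return f"_n{counter[0]}"

    names = {}

    def build(dnode, time):
        nid = names.setdefault(id(dnode), name_of(dnode))
        g.add_node(nid, time=time)
        for c in dnode.child_nodes():
            bl = c.edge.length or 0.0
            cid = names.setdefault(id(c), name_of(c))
            build(c, time + bl)
            g.add_edge(nid, cid)

    build(dt.seed_node, root_time)
    root = names[id(dt.seed_node)]
    return LineageTree(g, root)


def newick_string(tree: LineageTree) -> str:
    buf = io.StringIO()
    dt = _to_dendropy(tree)
    return dt.as_string(schema="newick", suppress_rooting=True,
                        suppress_internal_node_labels=False).strip()
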