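"""Ancestor-state inference on a lineage tree via a Gaussian graphical model.

Under a purely diffusive model, the difference in cell state across each
edge of the lineage tree is an independent Gaussian with variance
proportional to the time elapsed along the edge (variance ``D * |t_u -
t_v|`` per coordinate).  Conditional on the observed late-time leaf
states, the state of every unobserved node — in particular the ancestor of
each late cell at the early sampling time ``t1`` — is Gaussian with a mean
and per-coordinate variance computable from the tree alone.

The precision matrix of node states (relative to an arbitrary reference
leaf) is the graph Laplacian of the tree with edge weights ``1/(D*span)``;
anchoring on the reference removes the Laplacian's null space and makes it
positive definite.  Conditioning on the observed leaves is the standard
Gaussian formula on the partitioned precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .tree import LineageTree, TreeError

__all__ = [
    "DiffusionModel",
    "AncestorEstimate",
    "insert_time_slice",
    "build_precision",
    "estimate_ancestors",
]


@dataclass(frozen=True)
class DiffusionModel:
    """Isotropic diffusion with constant D between sampling times t1 < t2.

    ``D`` has units of state-units^2 per time.  Because every conditional
    variance is proportional to D, changing D rescales the transport cost
    uniformly and is absorbed into the entropy parameter; the default D=1
    is therefore a convention, not a fitted quantity.
    """

    D: float = 1.0
    t1: float = 0.0
    t2: float = 1.0

    def __post_init__(self):
        if self.D <= 0:
            raise ValueError("diffusion constant D must be positive")
        if self.t2 <= self.t1:
            raise ValueError("t2 must exceed t1")


@dataclass
class AncestorEstimate:
    """Conditional law of each late cell's ancestor at t1.

    Attributes
    ----------
    means : (n_late, d) array
        Conditional mean state of each late cell's t1 ancestor.
    variances : (n_late,) array
        Per-coordinate (isotropic) conditional variance; positive.
    ancestor_nodes : list
        The t1 ancestor node id for each late cell; cells sharing a node
        share means and variances exactly.
    cell_ids : list
        Late-cell identifiers, aligned with rows of ``means``.
    """

    means: np.ndarray
    variances: np.ndarray
    ancestor_nodes: list
    cell_ids: list

    def __post_init__(self):
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.variances = np.asarray(self.variances, dtype=float)
        if (self.variances <= 0).any():
            raise ValueError("ancestor variances must be positive")

    def to_frames(self):
        import pandas as pd

        means = pd.DataFrame(self.means, index=self.cell_ids)
        var = pd.DataFrame({"variance": self.variances,
                            "ancestor_node": [str(a) for a in self.ancestor_nodes]},
                           index=self.cell_ids)
        return means, var


# ---------------------------------------------------------------------------
# Step 2: add t1 ancestor nodes
# ---------------------------------------------------------------------------

def insert_time_slice(tree: LineageTree, t1: float, rtol: float = 1e-9):
    """Insert one node at time ``t1`` on every root-to-leaf path.

    Returns ``(augmented_tree, ancestors)`` where ``ancestors`` maps each
    leaf's cell id to its t1-ancestor node.  Lineages whose divergence from
    a relative happens after t1 share the ancestor node; a node lying
    exactly at t1 is reused rather than duplicated.
    """
    leaf_times = [tree.time(v) for v in tree.leaves()]
    t2 = min(leaf_times)
    if t1 >= t2:
        raise ValueError(f"t1={t1} must precede every leaf time (min {t2})")
    if t1 < tree.time(tree.root) - rtol * max(1.0, abs(t1)):
        raise ValueError(
            f"t1={t1} precedes the root time {tree.time(tree.root)}: "
            "no in-tree ancestor exists at t1"
        )

    aug = tree.copy()
    g = aug.graph
    tol = rtol * max(1.0, abs(t1))
    k = 0
    for u, v in list(g.edges):
        tu, tv = g.nodes[u]["time"], g.nodes[v]["time"]
        if tu < t1 - tol and tv > t1 + tol:
            mid = f"_t1slice{k}"
            k += 1
            g.remove_edge(u, v)
            g.add_node(mid, time=float(t1))
            g.add_edge(u, mid)
            g.add_edge(mid, v)

    ancestors = {}
    for leaf in aug.leaves():
        v = leaf
        anc = None
        while v is not None:
            if abs(g.nodes[v]["time"] - t1) <= tol:
                anc = v
                break
            v = aug.parent(v)
        if anc is None:  # root strictly above t1 yet no crossing: cannot happen
            raise TreeError("no t1 node found on a root-to-leaf path")
        ancestors[aug.leaf_cells[leaf]] = anc
    return aug, ancestors


# ---------------------------------------------------------------------------
# Steps 3-4: precision matrix and conditioning
# ---------------------------------------------------------------------------

def _edge_weight(span: float, model: DiffusionModel, floor: float) -> float:
    return 1.0 / (model.D * max(span, floor))


def build_precision(tree: LineageTree, model: DiffusionModel, reference):
    """Anchored tree-Laplacian precision over all nodes except ``reference``.

    Edge (u, v) contributes weight ``1/(D*|t_u - t_v|)``; the matrix is the
    weighted graph Laplacian (diagonal = weighted degree, off-diagonal =
    -weight) with the reference leaf's row and column deleted, which makes
    it symmetric positive definite on a connected tree.  Zero spans are
    clamped to ``1e-9*(t2-t1)``.

    Returns ``(Lambda, nodes)`` with ``nodes`` the ordered non-reference
    node list indexing the matrix.
    """
    g = tree.graph
    if reference not in g:
        raise ValueError(f"reference node {reference!r} not in tree")
    und = g.to_undirected(as_view=True)
    if not nx.is_connected(und):
        raise RuntimeError("augmented tree is disconnected")
    nodes = [v for v in g.nodes if v != reference]
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    floor = 1e-9 * (model.t2 - model.t1)
    L = np.zeros((n, n))
    for u, v in g.edges:
        w = _edge_weight(tree.edge_span(u, v), model, floor)
        iu, iv = idx.get(u), idx.get(v)
        if iu is not None:
            L[iu, iu] += w
        if iv is not None:
            L[iv, iv] += w
        if iu is not None and iv is not None:
            L[iu, iv] -= w
            L[iv, iu] -= w
    return L, nodes


def estimate_ancestors(
    tree: LineageTree,
    late_states: np.ndarray,
    model: DiffusionModel,
    cell_ids=None,
    reference=None,
) -> AncestorEstimate:
    """Condition the tree Gaussian model on observed leaf states.

    Parameters
    ----------
    tree
        Augmented lineage tree containing one node at ``model.t1`` on every
        root-to-leaf path (see :func:`insert_time_slice`); leaves observed
        at t2.
    late_states
        (n_late, d) observed states, rows aligned with ``cell_ids``
        (default: ``tree.leaf_cells`` values in leaf iteration order).
    model
        Diffusion model supplying D and the time slice t1.
    reference
        Observed leaf used to anchor the model; defaults to the first leaf
        in input order.  The result is invariant to this choice.

    Returns
    -------
    AncestorEstimate with per-late-cell conditional means and isotropic
    variances at t1.
    """
    Y = np.atleast_2d(np.asarray(late_states, dtype=float))
    aug, anc = insert_time_slice(tree, model.t1) if not _has_slice(tree, model.t1) \
        else (tree, _slice_ancestors(tree, model.t1))
    leaves = aug.leaves()
    if cell_ids is None:
        cell_ids = [aug.leaf_cells[v] for v in leaves]
    cell_ids = list(cell_ids)
    if len(cell_ids) != Y.shape[0]:
        raise ValueError("late_states rows must match cell_ids")
    cell_row = {c: i for i, c in enumerate(cell_ids)}
    leaf_of_cell = {aug.leaf_cells[v]: v for v in leaves}
    missing = [c for c in cell_ids if c not in leaf_of_cell]
    if missing:
        raise ValueError(f"cells without a leaf in the tree: {missing[:5]}")

    if reference is None:
        reference = leaf_of_cell[cell_ids[0]]
    y0 = Y[cell_row[aug.leaf_cells[reference]]]

    L, nodes = build_precision(aug, model, reference)
    idx = {v: i for i, v in enumerate(nodes)}
    observed = [v for v in leaves if v != reference]
    unobserved = [v for v in nodes if aug.graph.out_degree(v) > 0]

    O = [idx[v] for v in observed]
    U = [idx[v] for v in unobserved]
    d = Y.shape[1]

    if U:
        Luu = L[np.ix_(U, U)]
        c, low = cho_factor(Luu)
        if O:
            Luo = L[np.ix_(U, O)]
            Yrel = np.stack([Y[cell_row[aug.leaf_cells[v]]] - y0 for v in observed])
            mu_rel = -cho_solve((c, low), Luo @ Yrel)
        else:
            mu_rel = np.zeros((len(U), d))
        Suu_diag = np.diag(cho_solve((c, low), np.eye(len(U))))
        mean_of = {v: mu_rel[k] + y0 for k, v in enumerate(unobserved)}
        var_of = {v: Suu_diag[k] for k, v in enumerate(unobserved)}
    else:
        mean_of, var_of = {}, {}

    means = np.empty((len(cell_ids), d))
    variances = np.empty(len(cell_ids))
    anc_nodes = []
    floor = 1e-9 * (model.t2 - model.t1)
    for c in cell_ids:
        a = anc[c]
        anc_nodes.append(a)
        if a in mean_of:
            means[cell_row[c]] = mean_of[a]
            variances[cell_row[c]] = var_of[a]
        elif a == reference:
            # degenerate single-lineage tree: ancestor node is the reference
            means[cell_row[c]] = y0
            variances[cell_row[c]] = model.D * max(model.t2 - model.t1, floor)
        else:  # ancestor node is itself an observed leaf (cannot arise for t1<t2)
            means[cell_row[c]] = Y[cell_row[c]]
            variances[cell_row[c]] = model.D * floor
    return AncestorEstimate(means, variances, anc_nodes, cell_ids)


def _has_slice(tree: LineageTree, t1: float, rtol: float = 1e-9) -> bool:
    tol = rtol * max(1.0, abs(t1))
    g = tree.graph
    for leaf in tree.leaves():
        v, found = leaf, False
        while v is not None:
            if abs(g.nodes[v]["time"] - t1) <= tol:
                found = True
                break
            v = tree.parent(v)
        if not found:
            return False
    return True


def _slice_ancestors(tree: LineageTree, t1: float, rtol: float = 1e-9) -> dict:
    tol = rtol * max(1.0, abs(t1))
    out = {}
    for leaf in tree.leaves():
        v = leaf
        while abs(tree.graph.nodes[v]["time"] - t1) > tol:
            v = tree.parent(v)
        out[tree.leaf_cells[leaf]] = v
    return out
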