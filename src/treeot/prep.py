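"""Preparation of lineage-annotated real-style time courses.

This module turns a table of cells — each with an estimated developmental
time, a (possibly partial) lineage label, and a state vector — plus a
reference lineage tree into the inputs the coupling estimators expect:
per-time-bin state matrices, a late-sample lineage tree with reference
division times, and a ground-truth coupling linking early cells to their
labeled descendants.

Lineage labels follow an a/p nomenclature: a node's name is its parent's
name plus one character, ``a`` (anterior) or ``p`` (posterior).  A
wildcard character ``x`` in a label matches either daughter, expressing
partial annotation (e.g. two symmetric sublineages not distinguishable
from expression).  Three strategies resolve partial labels: drop them
(``complete_only``), restrict to a well-annotated sublineage collapsing
designated symmetric branches (``sublineage``), or impute uniformly at
random among the consistent nodes (``impute``).

No real reference tree ships with the package; `synthetic_reference_tree`
generates a synthetic stand-in with the same nomenclature so the whole
pipeline runs offline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .coupling import Coupling
from .tree import LineageTree

__all__ = [
    "AnnotatedCellTable",
    "synthetic_reference_tree",
    "resolve_label",
    "assign_time_bins",
    "apply_strategy",
    "remove_pre_birth",
    "reference_ground_truth",
    "labels_to_tree",
    "preprocess_states",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("cell", "time", "label")


@dataclass
class AnnotatedCellTable:
    """Cells with developmental times, lineage labels and state vectors.

    ``table`` must have columns ``cell`` (id), ``time`` (estimated
    developmental time, minutes, >= 0) and ``label`` (lineage label,
    possibly containing ``x`` wildcards); ``states`` is an aligned
    (n_cells, d) array.
    """

    table: pd.DataFrame
    states: np.ndarray

    def __post_init__(self):
        missing = [c for c in REQUIRED_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if (self.table["time"] < 0).any():
            raise ValueError("developmental times must be nonnegative")
        self.states = np.atleast_2d(np.asarray(self.states, dtype=float))
        if self.states.shape[0] != len(self.table):
            raise ValueError("states rows must match table rows")

    def subset(self, mask) -> "AnnotatedCellTable":
        mask = np.asarray(mask)
        return AnnotatedCellTable(self.table[mask].reset_index(drop=True),
                                  self.states[mask])

    def __len__(self):
        return len(self.table)

    def to_tsv(self, path):
        df = self.table.copy()
        for k in range(self.states.shape[1]):
            df[f"s{k}"] = self.states[:, k]
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path):
        df = pd.read_csv(path, sep="\t")
        scols = [c for c in df.columns if c.startswith("s") and c[1:].isdigit()]
        return cls(df.drop(columns=scols), df[scols].to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# Synthetic reference tree
# ---------------------------------------------------------------------------

def synthetic_reference_tree(n_generations: int = 5, t_max: float = 450.0,
                             root_name: str = "R", seed: int = 0) -> LineageTree:
    """A synthetic binary reference tree with a/p names and noisy division times.

    Node times are birth times; generation g divides around
    ``t_max * (g+1) / (n_generations+1)`` with small jitter, so sampling
    windows can fall before or after individual births (exercising the
    pre-birth filter).  This is a synthetic stand-in for an organism's
    known invariant lineage, not real data.
    """
    rng = np.random.default_rng(seed)
    g = nx.DiGraph()
    g.add_node(root_name, time=0.0)
    frontier = [root_name]
    for gen in range(1, n_generations + 1):
        base = t_max * gen / (n_generations + 1)
        nxt = []
        for parent in frontier:
            t_div = float(np.clip(base + rng.normal(0, 0.03 * t_max),
                                  g.nodes[parent]["time"] + 1.0, t_max - 1.0))
            for suffix in "ap":
                child = parent + suffix
                g.add_node(child, time=t_div)
                g.add_edge(parent, child)
            nxt.extend([parent + "a", parent + "p"])
        frontier = nxt
    return LineageTree(g, root_name)


def resolve_label(label: str, reference: LineageTree) -> list:
    """All reference-tree node names consistent with a possibly-partial label.

    ``x`` matches either ``a`` or ``p`` at its position; any other
    character must match exactly.  Returns [] for labels absent from the
    tree.
    """
    names = set(map(str, reference.graph.nodes))
    out = [""]
    for ch in label:
        if ch == "x":
            out = [p + c for p in out for c in "ap"]
        else:
            out = [p + ch for p in out]
    return sorted(n for n in out if n in names)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def assign_time_bins(table: AnnotatedCellTable, bin_edges) -> dict:
    """Split cells into time bins; each bin's sampling time is its end edge.

    Bins are right-closed: a cell with time in ``(e_{k-1}, e_k]`` belongs
    to the bin ending at ``e_k`` (a cell exactly on an edge joins the bin
    that edge ends).  Cells outside ``(e_0, e_last]`` are dropped.

    Returns an ordered dict ``bin_end -> AnnotatedCellTable`` with a
    ``sampling_time`` column added.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or (np.diff(edges) <= 0).any():
        raise ValueError("bin_edges must be strictly increasing, length >= 2")
    t = table.table["time"].to_numpy()
    # right-closed: searchsorted with side='left' maps e_k to bin k
    idx = np.searchsorted(edges, t, side="left")
    out = {}
    for k in range(1, edges.size):
        mask = (idx == k) & (t > edges[0]) & (t <= edges[-1])
        sub = table.subset(mask)
        sub.table["sampling_time"] = edges[k]
        out[float(edges[k])] = sub
    return out


def apply_strategy(table: AnnotatedCellTable, reference: LineageTree,
                   strategy: str, seed: int = 0,
                   sublineage_root: str | None = None,
                   collapse: dict | None = None) -> AnnotatedCellTable:
    """Resolve partial lineage annotations by one of three strategies.

    * ``complete_only`` — keep only cells whose label has no wildcard and
      names a reference-tree node.
    * ``sublineage`` — keep cells whose label lies under
      ``sublineage_root`` after first applying the ``collapse`` mapping
      (symmetric branches treated as identical, e.g. ``{"Rpa": "Rpx"}``
      applied as a prefix rewrite); remaining wildcards must resolve
      uniquely after collapsing.
    * ``impute`` — replace each wildcard label by a uniformly random
      consistent node (seeded, deterministic).

    Labels that resolve to no node are dropped with a log entry.
    """
    rng = np.random.default_rng(seed)
    labels = table.table["label"].astype(str).tolist()
    keep = np.zeros(len(labels), dtype=bool)
    newlab = list(labels)

    if strategy == "complete_only":
        for i, lab in enumerate(labels):
            keep[i] = "x" not in lab and lab in reference.graph
    elif strategy == "sublineage":
        if sublineage_root is None:
            raise ValueError("sublineage strategy requires sublineage_root")
        collapse = collapse or {}
        for i, lab in enumerate(labels):
            for src, dst in collapse.items():
                if lab.startswith(src):
                    lab = dst + lab[len(src):]
            if not lab.startswith(sublineage_root):
                continue
            opts = resolve_label(lab, reference)
            if not opts:
                logger.warning("label %r resolves to no node; dropped", lab)
                continue
            # after collapsing, the designated symmetric pair maps to one
            # representative; pick the lexicographically first option
            newlab[i] = opts[0]
            keep[i] = True
    elif strategy == "impute":
        for i, lab in enumerate(labels):
            opts = resolve_label(lab, reference)
            if not opts:
                if lab in reference.graph:
                    opts = [lab]
                else:
                    logger.warning("label %r resolves to no node; dropped", lab)
                    continue
            newlab[i] = opts[int(rng.integers(len(opts)))]
            keep[i] = True
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    out = table.subset(keep)
    out.table["label"] = [newlab[i] for i in np.nonzero(keep)[0]]
    return out


def remove_pre_birth(table: AnnotatedCellTable,
                     reference: LineageTree) -> AnnotatedCellTable:
    """Drop cells whose sampling time precedes their node's birth time."""
    if "sampling_time" not in table.table.columns:
        raise ValueError("assign_time_bins must run first (sampling_time)")
    births = np.array([
        reference.time(lab) if lab in reference.graph else np.inf
        for lab in table.table["label"]
    ])
    keep = table.table["sampling_time"].to_numpy() >= births
    dropped = int((~keep).sum())
    if dropped:
        logger.info("removed %d cells sampled before their birth time", dropped)
    return table.subset(keep)


def _is_ancestor_or_self(reference: LineageTree, a: str, b: str) -> bool:
    v = b
    while v is not None:
        if v == a:
            return True
        v = reference.parent(v)
    return False


def reference_ground_truth(early_labels, late_labels,
                           reference: LineageTree) -> Coupling:
    """Forward ground-truth coupling from lineage labels.

    ``gamma*[i, j] = 1 / (n_early * n_desc(i))`` when early cell i's node
    is an ancestor-or-self of late cell j's node, else 0 (a label that
    persists across bins couples to itself).  Early cells with no labeled
    descendants get zero rows (logged), so the row marginal is uniform on
    ancestors-with-descendants.
    """
    early = list(map(str, early_labels))
    late = list(map(str, late_labels))
    n, m = len(early), len(late)
    G = np.zeros((n, m))
    # ancestors-or-self of each late node, resolved once
    anc_sets = []
    for lab in late:
        s = set()
        v = lab
        while v is not None:
            s.add(v)
            v = reference.parent(v) if v in reference.graph else None
        anc_sets.append(s)
    for i, lab in enumerate(early):
        hits = [j for j in range(m) if lab in anc_sets[j]]
        if not hits:
            logger.info("early cell %d (%s) has no labeled descendants", i, lab)
            continue
        G[i, hits] = 1.0 / (n * len(hits))
    return Coupling(G, G.sum(axis=1), G.sum(axis=0),
                    {"cost": "reference_ground_truth"})


def labels_to_tree(late_labels, reference: LineageTree, t1: float,
                   t2: float, cell_ids=None) -> LineageTree:
    """Induced lineage tree for the late sample from its lineage labels.

    The tree topology is the MRCA closure of the labeled reference nodes;
    each internal node carries the reference division time (the birth time
    of its children).  Cells become leaves at time ``t2``; multiple cells
    sharing a label hang as a zero-span fan under that label's position
    (spans are clamped downstream).
    """
    late = list(map(str, late_labels))
    if cell_ids is None:
        cell_ids = [f"cell{j}" for j in range(len(late))]
    cell_ids = list(cell_ids)
    for lab in late:
        if lab not in reference.graph:
            raise ValueError(f"label {lab!r} not in reference tree")

    targets = sorted(set(late))

    def path_to_root(v):
        out = [v]
        while reference.parent(out[-1]) is not None:
            out.append(reference.parent(out[-1]))
        return out[::-1]

    # MRCA closure: union of pairwise MRCAs and targets
    closure = set(targets)
    paths = {v: path_to_root(v) for v in targets}
    for i, a in enumerate(targets):
        for b in targets[i + 1:]:
            pa, pb = paths[a], paths[b]
            k = 0
            while k < min(len(pa), len(pb)) and pa[k] == pb[k]:
                k += 1
            closure.add(pa[k - 1])
    root = min(closure, key=lambda v: len(paths.get(v) or path_to_root(v)))
    # connect each closure node to its nearest strict ancestor in the closure
    g = nx.DiGraph()

    def division_time(v):
        kids = list(reference.graph.successors(v))
        return reference.time(kids[0]) if kids else t2

    for v in closure:
        g.add_node(v, time=min(division_time(v), t2))
    for v in closure:
        if v == root:
            continue
        u = reference.parent(v)
        while u not in closure:
            u = reference.parent(u)
        g.add_edge(u, v)

    leaf_cells = {}
    for j, lab in enumerate(late):
        leaf = f"_leaf_{cell_ids[j]}"
        g.add_node(leaf, time=float(t2))
        g.add_edge(lab, leaf)
        leaf_cells[leaf] = cell_ids[j]

    tree = LineageTree(g, root, leaf_cells)
    if tree.time(root) > t1:
        logger.warning("induced tree root (t=%.3g) is later than t1=%.3g",
                       tree.time(root), t1)
    return tree


def preprocess_states(counts, n_components: int = 50) -> np.ndarray:
    """Library-size normalize, log1p, and project to principal components.

    Follows the standard scRNA-seq recipe (median-count normalization and
    log transform via scanpy, PCA via exact SVD).  The sign of each
    component is fixed so its largest-magnitude loading is positive,
    making the embedding deterministic.  Output dimension is
    ``min(n_components, n_cells - 1, rank)``.
    """
    import anndata as ad
    import scanpy as sc

    X = np.asarray(counts, dtype=float)
    adata = ad.AnnData(X.copy())
    sc.pp.normalize_total(adata)
    sc.pp.log1p(adata)
    Z = np.asarray(adata.X) if not hasattr(adata.X, "toarray") else adata.X.toarray()
    Z = Z - Z.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size and s[0] > 0 else 0
    k = min(n_components, rank)
    comps = Vt[:k]
    flip = np.sign(comps[np.arange(k), np.abs(comps).argmax(axis=1)])
    flip[flip == 0] = 1.0
    return (U[:, :k] * s[:k]) * flip
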