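"""Lineage-annotated table preparation: bins, strategies, ground truth."""

import numpy as np
import pandas as pd
import pytest

from treeot.ancestors import DiffusionModel, estimate_ancestors
from treeot.prep import (AnnotatedCellTable, apply_strategy, assign_time_bins,
                         labels_to_tree, preprocess_states,
                         reference_ground_truth, remove_pre_birth,
                         resolve_label, synthetic_reference_tree)
from conftest import make_tree


@pytest.fixture
def reference():
    return synthetic_reference_tree(n_generations=4, t_max=450.0, seed=0)


def table_from(labels, times=None, d=2, rng=None):
    n = len(labels)
    times = times if times is not None else [200.0] * n
    states = (rng.normal(size=(n, d)) if rng is not None
              else np.zeros((n, d)))
    df = pd.DataFrame({"cell": [f"c{i}" for i in range(n)],
                       "time": times, "label": labels})
    return AnnotatedCellTable(df, states)


# ---------------------------------------------------------------------------
# label resolution and reference tree
# ---------------------------------------------------------------------------

def test_reference_tree_structure(reference):
    assert reference.time("R") == 0.0
    leaves = reference.leaves()
    assert len(leaves) == 16
    assert all(len(name) == 5 for name in leaves)  # R + 4 generations


def test_resolve_label_wildcards(reference):
    assert resolve_label("Rap", reference) == ["Rap"]
    assert resolve_label("Rxp", reference) == ["Rap", "Rpp"]
    assert resolve_label("Rxx", reference) == ["Raa", "Rap", "Rpa", "Rpp"]
    assert resolve_label("Zap", reference) == []


# ---------------------------------------------------------------------------
# time bins
# ---------------------------------------------------------------------------

def test_time_bins_examples(rng):
    tbl = table_from(["Ra"] * 4, times=[200.0, 210.0, 260.0, 100.0], rng=rng)
    bins = assign_time_bins(tbl, (130, 210, 270))
    # cell at 200 and cell exactly at the 210 edge both land in bin 210
    assert list(bins[210.0].table["time"]) == [200.0, 210.0]
    assert list(bins[270.0].table["time"]) == [260.0]
    assert all((b.table["sampling_time"] == end).all()
               for end, b in bins.items() if len(b))
    # cell at 100 is outside the binned range
    assert sum(len(b) for b in bins.values()) == 3


def test_time_bins_match_direct_histogram(rng):
    times = rng.uniform(100, 500, size=200)
    tbl = table_from(["Ra"] * 200, times=times, rng=rng)
    edges = np.array([130.0, 210.0, 270.0, 330.0, 390.0, 450.0])
    bins = assign_time_bins(tbl, edges)
    for k in range(1, len(edges)):
        expected = int(((times > edges[k - 1]) & (times <= edges[k])).sum())
        assert len(bins[edges[k]]) == expected


def test_time_bins_validation(rng):
    with pytest.raises(ValueError):
        assign_time_bins(table_from(["Ra"], rng=rng), [200.0])
    with pytest.raises(ValueError):
        assign_time_bins(table_from(["Ra"], rng=rng), [300.0, 200.0])


# ---------------------------------------------------------------------------
# annotation strategies
# ---------------------------------------------------------------------------

def test_complete_only_keeps_exact_drops_partial(reference, rng):
    tbl = table_from(["Rap", "Rxp", "Rpppp", "bogus"], rng=rng)
    out = apply_strategy(tbl, reference, "complete_only")
    assert list(out.table["label"]) == ["Rap", "Rpppp"]


def test_sublineage_filters_and_collapses(reference, rng):
    tbl = table_from(["Rpa", "Rpp", "Raa", "Rpapa"], rng=rng)
    out = apply_strategy(tbl, reference, "sublineage",
                         sublineage_root="Rp", collapse={"Rpp": "Rpa"})
    # Raa is outside the sublineage; Rpp is collapsed onto Rpa
    assert list(out.table["label"]) == ["Rpa", "Rpa", "Rpapa"]


def test_impute_uniform_over_consistent_nodes(reference, rng):
    """A two-way wildcard resolves to each option with frequency 1/2 up to
    binomial error across seeds."""
    tbl = table_from(["Rxp"], rng=rng)
    picks = [apply_strategy(tbl, reference, "impute", seed=s).table["label"][0]
             for s in range(1000)]
    frac = np.mean([p == "Rap" for p in picks])
    assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / 1000)
    assert set(picks) == {"Rap", "Rpp"}


def test_impute_deterministic_given_seed(reference, rng):
    tbl = table_from(["Rxx", "Rxp", "Rpx"] * 5, rng=rng)
    a = apply_strategy(tbl, reference, "impute", seed=7).table["label"]
    b = apply_strategy(tbl, reference, "impute", seed=7).table["label"]
    assert list(a) == list(b)


def test_unknown_strategy_raises(reference, rng):
    with pytest.raises(ValueError):
        apply_strategy(table_from(["Ra"], rng=rng), reference, "magic")


# ---------------------------------------------------------------------------
# pre-birth filter
# ---------------------------------------------------------------------------

def test_remove_pre_birth_examples():
    ref = make_tree([("R", "Ra"), ("R", "Rp")],
                    {"R": 0.0, "Ra": 250.0, "Rp": 190.0}, "R")
    df = pd.DataFrame({"cell": ["a", "b"], "time": [205.0, 205.0],
                       "label": ["Ra", "Rp"],
                       "sampling_time": [210.0, 210.0]})
    tbl = AnnotatedCellTable(df, np.zeros((2, 2)))
    out = remove_pre_birth(tbl, ref)
    # born at 250 but binned at 210 -> dropped; born 190 -> kept
    assert list(out.table["label"]) == ["Rp"]


def test_remove_pre_birth_matches_direct_filter(reference, rng):
    labels = list(rng.choice(list(reference.graph.nodes), size=100))
    times = rng.uniform(0, 450, size=100)
    df = pd.DataFrame({"cell": range(100), "time": times, "label": labels,
                       "sampling_time": times})
    tbl = AnnotatedCellTable(df, np.zeros((100, 1)))
    out = remove_pre_birth(tbl, reference)
    expected = sum(t >= reference.time(l) for t, l in zip(times, labels))
    assert len(out) == expected


# ---------------------------------------------------------------------------
# reference ground truth
# ---------------------------------------------------------------------------

def test_ground_truth_single_ancestor(reference):
    g = reference_ground_truth(["Ra"], ["Raa", "Rap"], reference)
    np.testing.assert_allclose(g.matrix, [[0.5, 0.5]])


def test_ground_truth_two_ancestors(reference):
    g = reference_ground_truth(["Ra", "Rp"], ["Raa", "Rap", "Rpa"], reference)
    np.testing.assert_allclose(g.matrix,
                               [[0.25, 0.25, 0.0], [0.0, 0.0, 0.5]])


def test_ground_truth_ancestor_or_self(reference):
    g = reference_ground_truth(["Ra"], ["Ra"], reference)
    np.testing.assert_allclose(g.matrix, [[1.0]])


def test_ground_truth_matches_loop_oracle(reference, rng):
    nodes = list(reference.graph.nodes)
    early = list(rng.choice(nodes, size=6))
    late = list(rng.choice(reference.leaves(), size=9))
    g = reference_ground_truth(early, late, reference).matrix

    def is_anc(a, b):
        v = b
        while v is not None:
            if v == a:
                return True
            v = reference.parent(v)
        return False

    for i, e in enumerate(early):
        nd = sum(is_anc(e, l) for l in late)
        for j, l in enumerate(late):
            expected = 1.0 / (6 * nd) if (nd and is_anc(e, l)) else 0.0
            assert g[i, j] == pytest.approx(expected)


def test_ground_truth_row_marginal_uniform_on_ancestors(reference):
    g = reference_ground_truth(["Ra", "Rp", "Raaaa"],
                               ["Rpa", "Rpp"], reference)
    rows = g.matrix.sum(axis=1)
    np.testing.assert_allclose(rows, [0.0, 1 / 3, 0.0])


# ---------------------------------------------------------------------------
# labels -> tree
# ---------------------------------------------------------------------------

def test_sister_labels_make_cherry_at_reference_division(reference):
    tree = labels_to_tree(["Raa", "Rap"], reference, t1=100.0, t2=300.0)
    assert tree.root == "Ra"
    # divergence at the reference division time of Ra (birth of its kids)
    assert tree.time("Ra") == pytest.approx(reference.time("Raa"))
    assert tree.n_leaves() == 2
    for leaf in tree.leaves():
        assert tree.time(leaf) == 300.0


def test_single_cell_single_lineage(reference):
    tree = labels_to_tree(["Rapa"], reference, t1=100.0, t2=300.0)
    assert tree.n_leaves() == 1


def test_duplicate_labels_fan_out(reference):
    tree = labels_to_tree(["Raa", "Raa", "Raa"], reference, 100.0, 300.0,
                          cell_ids=["u", "v", "w"])
    assert tree.n_leaves() == 3
    assert sorted(tree.leaf_cells.values()) == ["u", "v", "w"]


def test_induced_mrca_times_match_reference(reference, rng):
    leaves = list(rng.choice(reference.leaves(), size=6, replace=False))
    tree = labels_to_tree(leaves, reference, t1=100.0, t2=460.0)
    # MRCA time between cells equals the reference MRCA division time
    import networkx as nx
    und_i = tree.graph.to_undirected(as_view=True)
    und_r = reference.graph.to_undirected(as_view=True)
    for a in leaves[:3]:
        for b in leaves[3:]:
            la = f"_leaf_cell{leaves.index(a)}"
            lb = f"_leaf_cell{leaves.index(b)}"
            p_i = nx.shortest_path(und_i, la, lb)
            mrca_i = min(p_i, key=lambda v: tree.time(v))
            p_r = nx.shortest_path(und_r, a, b)
            mrca_r = min(p_r, key=lambda v: reference.time(v))
            kids = list(reference.graph.successors(mrca_r))
            assert tree.time(mrca_i) == pytest.approx(reference.time(kids[0]))


def test_labels_tree_feeds_ancestor_inference(reference, rng):
    labels = ["Raaaa", "Raaap", "Rppap", "Rppap"]
    tree = labels_to_tree(labels, reference, t1=200.0, t2=460.0,
                          cell_ids=list("wxyz"))
    Y = rng.normal(size=(4, 3))
    model = DiffusionModel(D=1.0, t1=200.0, t2=460.0)
    est = estimate_ancestors(tree, Y, model, cell_ids=list("wxyz"))
    assert est.means.shape == (4, 3)
    assert (est.variances > 0).all()
    # the two cells with identical labels share a t1 ancestor
    assert est.ancestor_nodes[2] == est.ancestor_nodes[3]


# ---------------------------------------------------------------------------
# state preprocessing
# ---------------------------------------------------------------------------

def test_pca_of_rank2_data_keeps_two_components(rng):
    """Cells that are library-scaled copies of three prototypes give a
    normalized log matrix of centered rank 2: the embedding keeps exactly
    two components and reconstructs all pairwise distances."""
    protos = rng.poisson(20.0, size=(3, 12)).astype(float) + 1
    rows = []
    for i in range(30):
        rows.append(protos[i % 3] * rng.uniform(0.5, 2.0))
    counts = np.array(rows)
    Z = preprocess_states(counts, n_components=50)
    assert Z.shape == (30, 2)  # min(50, rank) components survive
    # full-space distances of the normalized log matrix are reproduced
    lib = counts.sum(axis=1, keepdims=True)
    L = np.log1p(counts / lib * np.median(lib))
    for i in range(0, 30, 7):
        for j in range(1, 30, 11):
            d_full = np.linalg.norm(L[i] - L[j])
            d_emb = np.linalg.norm(Z[i] - Z[j])
            assert d_emb == pytest.approx(d_full, abs=1e-8)


def test_pca_explained_variance_matches_eigendecomposition(rng):
    counts = rng.poisson(10.0, size=(40, 15)).astype(float)
    Z = preprocess_states(counts, n_components=5)
    # reproduce the pipeline's normalized log matrix
    lib = counts.sum(axis=1, keepdims=True)
    norm = counts / lib * np.median(lib)
    L = np.log1p(norm)
    Lc = L - L.mean(axis=0, keepdims=True)
    evals = np.sort(np.linalg.eigvalsh(Lc.T @ Lc))[::-1]
    np.testing.assert_allclose((Z ** 2).sum(axis=0), evals[:5], rtol=1e-8)


def test_pca_sign_convention_is_deterministic(rng):
    counts = rng.poisson(8.0, size=(25, 10)).astype(float)
    Z1 = preprocess_states(counts, n_components=4)
    Z2 = preprocess_states(counts.copy(), n_components=4)
    np.testing.assert_array_equal(Z1, Z2)
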