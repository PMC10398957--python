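import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from sklearn.metrics import adjusted_rand_score

from astrotraj.containers import ExpressionMatrix
from astrotraj.clustering import (
    annotate_clusters,
    bh_adjust,
    build_knn_graph,
    cluster_flow_table,
    cluster_sweep,
    connected_components,
    rank_sum_test,
    wilcoxon_markers,
)


def expr_from(values):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        [f"g{j}" for j in range(values.shape[1])],
        [f"n{i}" for i in range(values.shape[0])],
    )


# ---------------------------------------------------------------- graphs


def test_collinear_points_union_symmetrization():
    expr = expr_from([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]])
    graph = build_knn_graph(expr, n_pcs=1, k=1)
    adj = graph.distances.toarray()
    assert np.allclose(adj, adj.T)
    # the end points both choose the middle; the union keeps both edges
    assert adj[0, 1] > 0 and adj[1, 2] > 0 and adj[0, 2] == 0


def test_two_separated_blobs_form_two_components(rng):
    a = rng.normal(0, 0.1, size=(30, 5))
    b = rng.normal(50, 0.1, size=(30, 5))
    graph = build_knn_graph(expr_from(np.vstack([a, b])), n_pcs=3, k=4)
    labels = connected_components(graph)
    assert len(np.unique(labels)) == 2
    assert len(np.unique(labels[:30])) == 1


def test_knn_graph_rejects_bad_k():
    expr = expr_from(np.eye(4))
    with pytest.raises(ValueError):
        build_knn_graph(expr, n_pcs=2, k=0)
    with pytest.raises(ValueError):
        build_knn_graph(expr, n_pcs=2, k=4)


# ------------------------------------------------------------- clustering


def test_cluster_sweep_columns_and_determinism(rng):
    pts = np.vstack([rng.normal(0, 0.3, (40, 4)), rng.normal(5, 0.3, (40, 4))])
    graph = build_knn_graph(expr_from(pts), n_pcs=3, k=5)
    res = [0.1, 0.5, 1.0]
    a = cluster_sweep(graph, res, seed=1)
    b = cluster_sweep(graph, res, seed=1)
    assert list(a.columns) == res
    assert a.equals(b)
    assert a.notna().all().all()


def test_cluster_sweep_requires_resolutions(rng):
    graph = build_knn_graph(expr_from(rng.normal(size=(10, 3))), n_pcs=2, k=2)
    with pytest.raises(ValueError):
        cluster_sweep(graph, [], seed=0)


def test_planted_populations_recovered_at_some_resolution(small_run):
    """Four planted populations are recovered (ARI >= 0.9) at one of
    the swept resolutions."""
    dataset, result = small_run
    truth = dataset.truth.nuclei.set_index("nucleus_id")["population"]
    truth = truth.loc[result.nucleus_labels.index]
    aris = [
        adjusted_rand_score(truth, result.cluster_assignments[c])
        for c in result.cluster_assignments.columns
    ]
    assert max(aris) >= 0.9


def test_doublet_nuclei_land_in_doublet_clusters(small_report):
    assert small_report["doublet_capture"] >= 0.9


# ---------------------------------------------------------- rank-sum test


def exact_rank_sum_oracle(x, y):
    """Exhaustive enumeration of group assignments (midranks)."""
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[: n1].sum()
    ws = [ranks[list(c)].sum() for c in itertools.combinations(range(len(pooled)), n1)]
    ws = np.array(ws)
    lo = np.mean(ws <= w_obs + 1e-9)
    hi = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(lo, hi))


def test_rank_sum_separated_groups_exact_p():
    w, p = rank_sum_test(np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0]))
    assert w == 6.0
    assert p == pytest.approx(0.1)


def test_rank_sum_identical_groups_p_one():
    _, p = rank_sum_test(np.array([2.0, 2.0, 2.0]), np.array([2.0, 2.0, 2.0]))
    assert p == 1.0


def test_rank_sum_matches_exhaustive_enumeration(rng):
    for _ in range(25):
        n1, n2 = rng.integers(2, 7, size=2)
        x = rng.integers(0, 5, size=n1).astype(float)
        y = rng.integers(0, 5, size=n2).astype(float)
        _, p = rank_sum_test(x, y)
        assert p == pytest.approx(exact_rank_sum_oracle(x, y), abs=1e-12)


def test_rank_sum_large_sample_matches_scipy_asymptotics(rng):
    x = rng.normal(0, 1, size=40)
    y = rng.normal(0.5, 1, size=35)
    _, p = rank_sum_test(x, y)
    ref = scipy.stats.ranksums(x, y).pvalue
    assert p == pytest.approx(ref, rel=1e-9)


# ------------------------------------------------------------------- BH


def bh_oracle(p):
    """Step-up formula applied longhand."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        val = min(prev, p[idx] * m / rank)
        q[idx] = val
        prev = val
    return np.minimum(q, 1.0)


def test_bh_adjust_examples():
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    assert bh_adjust([0.2]) == pytest.approx([0.2])
    assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)


def test_bh_adjust_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


def test_bh_adjust_matches_brute_force(rng):
    for _ in range(100):
        p = rng.uniform(size=rng.integers(1, 40))
        assert np.allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)


# ----------------------------------------------------- markers, labels


def test_wilcoxon_markers_shape_and_q_dominates_p(rng):
    vals = rng.normal(size=(40, 12))
    vals[:20, 0] += 3.0
    labels = np.array([0] * 20 + [1] * 20)
    table = wilcoxon_markers(expr_from(vals), labels)
    assert len(table) == 24  # gene x cluster
    assert (table["q"] >= table["p"] - 1e-12).all()
    top = table[(table["cluster"] == 0)].nsmallest(1, "p")
    assert top["gene"].iloc[0] == "g0"
    assert top["logfc"].iloc[0] > 0


def test_wilcoxon_markers_single_cluster_errors(rng):
    vals = rng.normal(size=(10, 3))
    with pytest.raises(ValueError):
        wilcoxon_markers(expr_from(vals), np.zeros(10, dtype=int))


def make_marker_table(rows):
    return pd.DataFrame(rows, columns=["cluster", "gene", "logfc", "statistic", "p", "q"])


def test_annotate_clusters_panel_rules():
    panels = {"protoplasmic": ["SLC1A2"], "fibrous": ["GFAP"], "neuron": ["SNAP25"], "oligo": ["PLP1"]}
    table = make_marker_table(
        [
            (0, "SLC1A2", 2.0, 0, 1e-6, 1e-5),
            (0, "SNAP25", -0.5, 0, 1e-3, 1e-2),
            (1, "SNAP25", 2.5, 0, 1e-8, 1e-6),
            (1, "SLC1A2", 1.0, 0, 1e-4, 1e-3),
            (2, "GFAP", 0.8, 0, 0.5, 0.9),
        ]
    )
    out = annotate_clusters(table, panels).set_index("cluster")["label"]
    assert out[0] == "protoplasmic"
    assert out[1] == "doublet_neuron"  # doublet panel outscores astrocyte panel
    assert out[2] == "unassigned"  # no significant marker


def test_annotate_clusters_requires_panels():
    with pytest.raises(ValueError):
        annotate_clusters(make_marker_table([]), {})


def test_annotate_clusters_noise_scores_stay_unassigned():
    panels = {"protoplasmic": ["SLC1A2"], "fibrous": ["GFAP"]}
    table = make_marker_table([(0, "SLC1A2", 0.05, 0, 1e-4, 1e-3)])
    out = annotate_clusters(table, panels)
    assert out["label"].iloc[0] == "unassigned"


# ------------------------------------------------------------ flow table


def test_flow_table_single_cluster_single_edge():
    assignments = pd.DataFrame({0.1: [0] * 7, 0.5: [0] * 7})
    flow = cluster_flow_table(assignments)
    assert len(flow) == 1
    assert flow["n"].iloc[0] == 7


def test_flow_table_weights_sum_to_n(small_run):
    _, result = small_run
    flow = result.flow_table
    n = len(result.cluster_assignments)
    for (a, b), sub in flow.groupby(["resolution_from", "resolution_to"]):
        assert sub["n"].sum() == n


def test_flow_table_splitting_cluster_has_two_outgoing_edges():
    assignments = pd.DataFrame({1: [0, 0, 0, 0, 1, 1], 2: [0, 0, 2, 2, 1, 1]})
    flow = cluster_flow_table(assignments)
    out_edges = flow[flow["label_from"] == 0]
    assert len(out_edges) == 2
    assert out_edges["n"].sum() == 4


def test_flow_table_needs_two_resolutions():
    with pytest.raises(ValueError):
        cluster_flow_table(pd.DataFrame({0.1: [0, 0]}))
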