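"""Neighbor-graph clustering, marker detection, and cluster annotation.

Nuclei are embedded in PC space, connected by a symmetrized kNN graph,
and partitioned with Leiden modularity optimization across a sweep of
resolutions. Per-cluster markers come from a cluster-vs-rest Wilcoxon
rank-sum test with Benjamini-Hochberg correction; clusters are then
labeled by marker-panel scores, with doublet panels (neuron, oligo)
taking precedence over astrocyte panels when they score higher. A
cluster-flow table summarizes how assignments split across adjacent
resolutions (the table behind a Sankey diagram).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix
from .qc import pca_embed

__all__ = [
    "NeighborGraph",
    "build_knn_graph",
    "cluster_sweep",
    "wilcoxon_markers",
    "rank_sum_test",
    "bh_adjust",
    "annotate_clusters",
    "cluster_flow_table",
    "connected_components",
]

EXACT_MAX_GROUP = 6  # exact rank-sum enumeration up to this group size


@dataclass
class NeighborGraph:
    """Symmetric kNN graph with Euclidean distances in PC space."""

    distances: sp.csr_matrix  # symmetric, zero diagonal
    pcs: np.ndarray
    k: int
    n_pcs: int

    @property
    def n_nodes(self) -> int:
        return self.distances.shape[0]

    def to_igraph(self) -> igraph.Graph:
        coo = sp.triu(self.distances, k=1).tocoo()
        g = igraph.Graph(
            n=self.n_nodes,
            edges=list(zip(coo.row.tolist(), coo.col.tolist())),
            edge_attrs={"distance": coo.data.tolist()},
        )
        return g


def build_knn_graph(expr: ExpressionMatrix | np.ndarray, n_pcs: int = 50, k: int = 30) -> NeighborGraph:
    """kNN graph on the PC embedding, symmetrized by edge union.

    A directed kNN edge in either orientation yields one undirected edge
    carrying the Euclidean distance.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    values = expr.values if isinstance(expr, ExpressionMatrix) else np.asarray(expr)
    n = values.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of nuclei ({n})")
    pcs = pca_embed(values, n_pcs)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    dist, idx = nn.kneighbors(pcs)
    rows = np.repeat(np.arange(n), k)
    cols = idx[:, 1:].ravel()
    vals = dist[:, 1:].ravel()
    directed = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    sym = directed.maximum(directed.T)  # union; distances are symmetric anyway
    sym.setdiag(0)
    sym.eliminate_zeros()
    return NeighborGraph(sym.tocsr(), pcs, k=k, n_pcs=pcs.shape[1])


def connected_components(graph: NeighborGraph) -> np.ndarray:
    """Component label per node."""
    _, labels = sp.csgraph.connected_components(graph.distances, directed=False)
    return labels


def cluster_sweep(
    graph: NeighborGraph, resolutions: list[float], seed: int = 0
) -> pd.DataFrame:
    """Leiden modularity clustering at each resolution.

    Returns a nuclei x resolution table of integer labels; columns are
    the resolution values in the given order.
    """
    if not resolutions:
        raise ValueError("resolutions must be non-empty")
    if graph.n_nodes == 0:
        raise ValueError("empty graph")
    g = graph.to_igraph()
    out = {}
    for res in resolutions:
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=res,
            seed=seed,
            n_iterations=2,
        )
        out[res] = np.asarray(part.membership)
    return pd.DataFrame(out)


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p by enumerating all rank splits.

    Uses midranks, so ties are handled the same way as the large-sample
    path. Two-sided p = min(1, 2 * min(P(W <= w), P(W >= w))) under the
    permutation null with margins fixed.
    """
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    lo = hi = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        w = ranks[list(combo)].sum()
        lo += w <= w_obs + 1e-9
        hi += w >= w_obs - 1e-9
        total += 1
    return min(1.0, 2.0 * min(lo / total, hi / total))


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (statistic W, p).

    W is the rank sum of ``x`` using midranks. Groups with min size at
    most 6 are tested by exact enumeration of rank splits; larger groups
    use the normal approximation with tie correction.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    w = float(ranks[:n1].sum())
    if min(n1, n2) <= EXACT_MAX_GROUP:
        return w, _exact_rank_sum_p(x, y)
    n = n1 + n2
    mean_w = n1 * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_w == 0:
        return w, 1.0
    z = (w - mean_w) / np.sqrt(var_w)
    return w, float(2.0 * scipy.stats.norm.sf(abs(z)))


def bh_adjust(pvals: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    if np.any((pvals < 0) | (pvals > 1)) or np.any(~np.isfinite(pvals)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def _tie_terms(values: np.ndarray) -> np.ndarray:
    """Per-gene sum of c^3 - c over tied-value runs (vectorized)."""
    n, g = values.shape
    sorted_vals = np.sort(values, axis=0)
    new_run = np.vstack([np.ones((1, g), bool), np.diff(sorted_vals, axis=0) != 0])
    flat = new_run.ravel(order="F")  # runs never cross column boundaries
    starts = np.flatnonzero(flat)
    lengths = np.diff(np.append(starts, n * g)).astype(float)
    tie_term = np.zeros(g)
    np.add.at(tie_term, starts // n, lengths**3 - lengths)
    return tie_term


def _vectorized_rank_sum(
    ranks: np.ndarray, tie_term: np.ndarray, in_group: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Tie-corrected normal-approximation rank-sum across gene columns."""
    n = ranks.shape[0]
    n1 = int(in_group.sum())
    n2 = n - n1
    w = ranks[in_group].sum(axis=0)
    mean_w = n1 * (n + 1) / 2.0
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (w - mean_w) / np.sqrt(var_w)
    p = np.where(var_w > 0, 2.0 * scipy.stats.norm.sf(np.abs(z)), 1.0)
    return w, p


def wilcoxon_markers(expr: ExpressionMatrix, labels: np.ndarray) -> pd.DataFrame:
    """Cluster-vs-rest Wilcoxon rank-sum markers with BH correction.

    Returns one row per (cluster, gene): natural-log fold change (mean
    difference of log expression), rank-sum statistic, raw p and BH q
    (adjusted within each cluster's gene list).
    """
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if clusters.size < 2:
        raise ValueError("need at least two clusters for cluster-vs-rest testing")
    counts = pd.Series(labels).value_counts()
    if (counts < 2).any():
        raise ValueError("every cluster needs at least two nuclei")
    # pooled ranks and tie corrections are shared by every cluster-vs-rest split
    large = counts.min() > EXACT_MAX_GROUP and (len(labels) - counts).min() > EXACT_MAX_GROUP
    if large:
        ranks = scipy.stats.rankdata(expr.values, axis=0)
        tie_term = _tie_terms(expr.values)
    frames = []
    for cluster in clusters:
        in_group = labels == cluster
        n1, n2 = int(in_group.sum()), int((~in_group).sum())
        if min(n1, n2) <= EXACT_MAX_GROUP:
            stats_p = [
                rank_sum_test(expr.values[in_group, j], expr.values[~in_group, j])
                for j in range(expr.n_genes)
            ]
            w = np.array([s for s, _ in stats_p])
            p = np.array([q for _, q in stats_p])
        else:
            w, p = _vectorized_rank_sum(ranks, tie_term, in_group)
        logfc = expr.values[in_group].mean(axis=0) - expr.values[~in_group].mean(axis=0)
        frames.append(
            pd.DataFrame(
                {
                    "cluster": cluster,
                    "gene": expr.gene_ids,
                    "logfc": logfc,
                    "statistic": w,
                    "p": p,
                    "q": bh_adjust(p),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


#: marker panels considered astrocyte singlets vs doublet indicators
ASTRO_PANELS = ("protoplasmic", "fibrous")
DOUBLET_PANEL_LABELS = {"neuron": "doublet_neuron", "oligo": "doublet_oligo"}


def annotate_clusters(
    markers: pd.DataFrame,
    panels: dict[str, list[str]],
    q_threshold: float = 0.05,
    min_score: float = 0.25,
) -> pd.DataFrame:
    """Label each cluster by its best-scoring marker panel.

    Panel score = mean log-fold-change of the panel's genes among the
    cluster's significant markers (q below threshold). Doublet panels
    (neuron/oligo) take precedence whenever they outscore the best
    astrocyte panel. Clusters with no significant panel gene, or whose
    best score falls below ``min_score`` (so noise-level fold changes in
    a homogeneous dataset do not assign identities), are ``unassigned``.
    """
    if not panels or all(len(v) == 0 for v in panels.values()):
        raise ValueError("marker panels must be non-empty")
    rows = []
    for cluster, sub in markers.groupby("cluster"):
        sig = sub[sub["q"] < q_threshold]
        scores: dict[str, float] = {}
        for panel, genes in panels.items():
            hit = sig[sig["gene"].isin(genes)]
            if len(hit):
                scores[panel] = float(hit["logfc"].mean())
        if not scores or max(scores.values()) < min_score:
            label = "unassigned"
        else:
            astro_best = max(
                (scores[p] for p in ASTRO_PANELS if p in scores), default=-np.inf
            )
            doublet_scores = {
                p: s for p, s in scores.items() if p in DOUBLET_PANEL_LABELS
            }
            best_doublet = max(doublet_scores, key=doublet_scores.get, default=None)
            if best_doublet is not None and doublet_scores[best_doublet] > astro_best:
                label = DOUBLET_PANEL_LABELS[best_doublet]
            elif np.isfinite(astro_best):
                label = max(
                    (p for p in ASTRO_PANELS if p in scores), key=lambda p: scores[p]
                )
            else:
                best = max(scores, key=scores.get)
                label = DOUBLET_PANEL_LABELS.get(best, best)
        row = {"cluster": cluster, "label": label}
        row.update({f"score_{p}": scores.get(p, np.nan) for p in panels})
        rows.append(row)
    return pd.DataFrame(rows)


def cluster_flow_table(assignments: pd.DataFrame) -> pd.DataFrame:
    """Edge table of nucleus flows between adjacent clustering resolutions.

    Rows: (resolution_from, label_from, resolution_to, label_to, n).
    Edge weights out of any node sum to the node's size, so the table
    plugs directly into Sankey plotters.
    """
    if assignments.shape[1] < 2:
        raise ValueError("need at least two resolutions for a flow table")
    frames = []
    cols = list(assignments.columns)
    for a, b in zip(cols[:-1], cols[1:]):
        grouped = (
            assignments.groupby([a, b], observed=True).size().reset_index(name="n")
        )
        grouped.columns = ["label_from", "label_to", "n"]
        grouped.insert(0, "resolution_to", b)
        grouped.insert(0, "resolution_from", a)
        frames.append(grouped)
    return pd.concat(frames, ignore_index=True)
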