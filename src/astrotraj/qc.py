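"""Quality control and normalization.

Gene and nucleus filters follow the usual droplet snRNA-seq recipe:
drop genes detected in too few nuclei (default 30) and drop nuclei whose
detected-gene count exceeds a doublet-suspicious bound (default 2500,
direction configurable). Counts are depth-normalized to a common target
sum and natural-log transformed. An optional kNN smoother averages each
nucleus with its neighbors in PC space and serves as a deterministic,
desk-scale denoiser producing the "denoised expression" the downstream
trajectory regressions expect.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .containers import CountMatrix, ExpressionMatrix

__all__ = [
    "filter_genes_min_nuclei",
    "filter_nuclei_gene_count",
    "normalize_log",
    "knn_smooth",
    "pca_embed",
]

DEFAULT_MIN_NUCLEI = 30
DEFAULT_MAX_GENES = 2500


def filter_genes_min_nuclei(counts: CountMatrix, min_nuclei: int = DEFAULT_MIN_NUCLEI) -> CountMatrix:
    """Keep genes with nonzero counts in at least ``min_nuclei`` nuclei."""
    if min_nuclei < 0:
        raise ValueError("min_nuclei must be >= 0")
    detected = np.asarray((counts.values > 0).sum(axis=0)).ravel()
    return counts.subset_genes(detected >= min_nuclei)


def filter_nuclei_gene_count(
    counts: CountMatrix,
    max_genes: int = DEFAULT_MAX_GENES,
    keep: str = "below",
    inclusive: bool = False,
) -> CountMatrix:
    """Filter nuclei by their number of detected genes.

    ``keep="below"`` retains nuclei expressing fewer than ``max_genes``
    genes (the doublet-removal direction); ``keep="above"`` inverts the
    rule. ``inclusive`` makes the bound non-strict.
    """
    if max_genes <= 0:
        raise ValueError("max_genes must be > 0")
    if keep not in ("below", "above"):
        raise ValueError("keep must be 'below' or 'above'")
    n_expressed = np.asarray((counts.values > 0).sum(axis=1)).ravel()
    if keep == "below":
        mask = n_expressed <= max_genes if inclusive else n_expressed < max_genes
    else:
        mask = n_expressed >= max_genes if inclusive else n_expressed > max_genes
    return counts.subset_nuclei(mask)


def normalize_log(counts: CountMatrix, target_sum: float | None = None) -> ExpressionMatrix:
    """Depth-normalize each nucleus to ``target_sum`` and apply ln(1 + x).

    ``target_sum`` defaults to the median library size, keeping the
    transform scale-free. A nucleus with zero total counts cannot be
    normalized and raises with its identifier.
    """
    totals = np.asarray(counts.values.sum(axis=1)).ravel().astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"cannot normalize nuclei with zero total counts: "
            f"{list(counts.nucleus_ids[zero[:5]])}"
        )
    if target_sum is None:
        target_sum = float(np.median(totals))
    if target_sum <= 0:
        raise ValueError("target_sum must be positive")
    dense = np.asarray(counts.values.todense(), dtype=float)
    dense *= (target_sum / totals)[:, None]
    np.log1p(dense, out=dense)
    return ExpressionMatrix(
        dense,
        counts.gene_ids,
        counts.nucleus_ids,
        normalized=True,
        logged=True,
        target_sum=target_sum,
    )


def pca_embed(values: np.ndarray, n_pcs: int, seed: int = 0) -> np.ndarray:
    """Deterministic PCA embedding of a nuclei x genes matrix.

    Randomized SVD with a fixed seed for large matrices (an exact solver
    below 500 nuclei), so embeddings are reproducible at any size.
    """
    n_pcs = min(n_pcs, min(values.shape) - 1)
    if n_pcs < 1:
        raise ValueError("need at least 2 nuclei and 2 genes for a PC embedding")
    solver = "full" if min(values.shape) < 500 else "randomized"
    pca = PCA(n_components=n_pcs, svd_solver=solver, random_state=seed)
    return pca.fit_transform(values)


def knn_smooth(expr: ExpressionMatrix, k: int = 15, n_pcs: int = 50) -> ExpressionMatrix:
    """Replace each nucleus by the mean of itself and its k nearest
    neighbors in top-``n_pcs`` PC space.

    ``k = 0`` is the identity. This is the package's denoising stage: a
    deterministic neighborhood average standing where an iterative
    cluster-and-denoise model would sit in a GPU pipeline.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return expr
    n = expr.n_nuclei
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of nuclei ({n})")
    pcs = pca_embed(expr.values, n_pcs)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs)  # idx[:, 0] is the nucleus itself
    # sparse averaging operator keeps memory at O(n * (k+1)) instead of
    # materializing an n x (k+1) x genes cube
    rows = np.repeat(np.arange(n), k + 1)
    weights = np.full(n * (k + 1), 1.0 / (k + 1))
    averager = sp.csr_matrix((weights, (rows, idx.ravel())), shape=(n, n))
    smoothed = averager @ expr.values
    return ExpressionMatrix(
        smoothed,
        expr.gene_ids,
        expr.nucleus_ids,
        normalized=expr.normalized,
        logged=expr.logged,
        smoothed=True,
        smooth_k=k,
        target_sum=expr.target_sum,
    )
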