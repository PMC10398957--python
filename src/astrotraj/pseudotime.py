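"""Diffusion maps and diffusion pseudotime (DPT).

A Gaussian kernel with per-node adaptive bandwidth is placed on the kNN
graph's distances; the row-normalized kernel defines a random walk whose
nontrivial eigenpairs give the diffusion components. Pseudotime of a
nucleus is the Euclidean distance between its scaled diffusion-map
representation (eigenvectors weighted by lambda / (1 - lambda)) and the
root's, rescaled so the farthest nucleus sits at 1.

The root is chosen as the nucleus minimizing a layout axis; by default
the first diffusion component, sign-fixed so that the end with the
highest homeostatic-panel expression is negative. This replaces a
force-directed-layout axis with a deterministic equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg

from .clustering import NeighborGraph

__all__ = [
    "DiffusionMap",
    "PseudotimeResult",
    "diffusion_map",
    "select_root",
    "root_axis",
    "diffusion_pseudotime",
]

_DISCONNECT_TOL = 1e-10


@dataclass
class DiffusionMap:
    """Nontrivial eigenpairs of the diffusion operator.

    ``eigenvalues`` are descending with the trivial lambda_1 = 1 removed;
    ``eigenvectors`` has one column per retained component.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    k: int
    n_comps: int

    def __post_init__(self) -> None:
        if np.any(np.abs(self.eigenvalues) > 1 + 1e-8):
            raise ValueError("diffusion eigenvalues must have magnitude <= 1")

    @property
    def n_nuclei(self) -> int:
        return self.eigenvectors.shape[0]

    def scaled_representation(self) -> np.ndarray:
        """Eigenvectors scaled by lambda / (1 - lambda) (DPT metric)."""
        lam = self.eigenvalues
        if np.any(1 - lam <= _DISCONNECT_TOL):
            raise ValueError(
                "nontrivial eigenvalue equal to 1: the graph is disconnected; "
                "subset the analysis population to its largest connected component"
            )
        return self.eigenvectors * (lam / (1 - lam))[None, :]


@dataclass
class PseudotimeResult:
    """Per-nucleus pseudotime in [0, 1] with provenance."""

    t: np.ndarray
    root: str
    nucleus_ids: np.ndarray
    axis: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "nucleus_id": self.nucleus_ids,
                "t": self.t,
                "is_root": self.nucleus_ids == self.root,
            }
        )


def _adaptive_kernel(graph: NeighborGraph) -> sp.csr_matrix:
    """Gaussian kernel on kNN distances with per-node bandwidths.

    sigma_i = distance to the ceil(k/2)-th neighbor; K_ij =
    exp(-d_ij^2 / (sigma_i * sigma_j)), symmetric with unit diagonal.
    """
    d = graph.distances
    n = d.shape[0]
    half_k = max(1, graph.k // 2)
    sigma = np.empty(n)
    for i in range(n):
        row = d.data[d.indptr[i] : d.indptr[i + 1]]
        if row.size == 0:
            sigma[i] = 1.0
        else:
            srt = np.sort(row)
            sigma[i] = srt[min(half_k - 1, srt.size - 1)]
    sigma = np.maximum(sigma, 1e-12)
    coo = d.tocoo()
    vals = np.exp(-(coo.data**2) / (sigma[coo.row] * sigma[coo.col]))
    kernel = sp.csr_matrix((vals, (coo.row, coo.col)), shape=d.shape)
    kernel = kernel.maximum(kernel.T)
    kernel = kernel + sp.identity(n, format="csr")
    return kernel


def transition_matrix(graph: NeighborGraph) -> sp.csr_matrix:
    """Row-stochastic transition matrix of the diffusion random walk."""
    kernel = _adaptive_kernel(graph)
    deg = np.asarray(kernel.sum(axis=1)).ravel()
    inv = sp.diags(1.0 / deg)
    return (inv @ kernel).tocsr()


def diffusion_map(graph: NeighborGraph, n_comps: int = 15) -> DiffusionMap:
    """Top nontrivial eigenpairs of the diffusion operator.

    Eigenpairs are computed on the symmetric conjugate
    D^{-1/2} K D^{-1/2}; right eigenvectors of the walk are recovered as
    D^{-1/2} v and unit-normalized. Raises if the graph is disconnected
    (a second unit eigenvalue), instructing a subset to the largest
    component.
    """
    if n_comps < 1:
        raise ValueError("n_comps must be >= 1")
    kernel = _adaptive_kernel(graph)
    n = kernel.shape[0]
    n_comps = min(n_comps, n - 2)
    deg = np.asarray(kernel.sum(axis=1)).ravel()
    d_inv_sqrt = sp.diags(1.0 / np.sqrt(deg))
    sym = (d_inv_sqrt @ kernel @ d_inv_sqrt).tocsr()
    # deterministic start vector (close to the stationary eigenvector)
    v0 = np.sqrt(deg / deg.sum())
    vals, vecs = sp.linalg.eigsh(sym, k=n_comps + 1, which="LA", v0=v0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if vals[1] >= 1 - _DISCONNECT_TOL:
        raise ValueError(
            "diffusion operator has a repeated unit eigenvalue: the graph is "
            "disconnected; subset the analysis population to its largest "
            "connected component"
        )
    # drop the trivial pair, convert to walk eigenvectors
    psi = d_inv_sqrt @ vecs[:, 1:]
    psi /= np.linalg.norm(psi, axis=0, keepdims=True)
    # canonical sign: largest-magnitude entry positive
    flip = psi[np.abs(psi).argmax(axis=0), np.arange(psi.shape[1])] < 0
    psi[:, flip] *= -1.0
    return DiffusionMap(np.clip(vals[1:], -1.0, 1.0), psi, k=graph.k, n_comps=n_comps)


def root_axis(dmap: DiffusionMap, homeostatic_score: np.ndarray) -> np.ndarray:
    """First diffusion component, sign-fixed against a homeostatic score.

    The axis is oriented so its low end is where homeostatic expression
    is highest (the trajectory start): if the component correlates
    positively with the score it is flipped.
    """
    axis = dmap.eigenvectors[:, 0].copy()
    score = np.asarray(homeostatic_score, dtype=float)
    if score.shape != axis.shape:
        raise ValueError("homeostatic score must align with nuclei")
    corr = np.corrcoef(axis, score)[0, 1]
    if np.isfinite(corr) and corr > 0:
        axis = -axis
    return axis


def select_root(
    axis: np.ndarray,
    candidates: np.ndarray,
    homeostatic_score: np.ndarray | None = None,
    nucleus_ids: np.ndarray | None = None,
) -> int:
    """Index of the root nucleus: the candidate minimizing the axis.

    Ties are broken by the highest homeostatic-panel score, then by the
    lowest nucleus identifier.
    """
    candidates = np.asarray(candidates)
    if candidates.size == 0:
        raise ValueError("candidate set is empty")
    axis = np.asarray(axis, dtype=float)
    cand_axis = axis[candidates]
    best = cand_axis.min()
    tied = candidates[np.abs(cand_axis - best) <= 1e-12]
    if tied.size > 1 and homeostatic_score is not None:
        scores = np.asarray(homeostatic_score, dtype=float)[tied]
        tied = tied[np.abs(scores - scores.max()) <= 1e-12]
    if tied.size > 1 and nucleus_ids is not None:
        ids = np.asarray(nucleus_ids, dtype=object)[tied]
        return int(tied[np.argsort(ids.astype(str), kind="mergesort")[0]])
    return int(tied[0])


def diffusion_pseudotime(
    dmap: DiffusionMap, root: int, nucleus_ids: np.ndarray | None = None
) -> PseudotimeResult:
    """Diffusion pseudotime from a root nucleus, normalized to [0, 1]."""
    rep = dmap.scaled_representation()
    if not 0 <= root < dmap.n_nuclei:
        raise ValueError(f"root index {root} outside [0, {dmap.n_nuclei})")
    t = np.linalg.norm(rep - rep[root], axis=1)
    t_max = t.max()
    if t_max > 0:
        t = t / t_max
    if nucleus_ids is None:
        nucleus_ids = np.array([str(i) for i in range(dmap.n_nuclei)], dtype=object)
    return PseudotimeResult(
        t=t, root=str(nucleus_ids[root]), nucleus_ids=np.asarray(nucleus_ids, dtype=object)
    )
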