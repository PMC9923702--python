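"""Expression-matrix preprocessing and diffusion-map embedding.

Trajectory inference operates on a low-dimensional embedding
``X = [x_1, ..., x_N] \\in R^{D x N}`` of the cells rather than on raw
expression.  This module provides the standard path from a genes-by-cells
expression matrix to that embedding: removal of all-zero genes, size-factor
normalisation for read depth, an optional PCA pre-reduction for very wide
matrices, a density filter for isolated cells, and the diffusion-map
spectral embedding itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "Embedding",
    "filter_zero_genes",
    "size_factor_normalize",
    "density_filter_cells",
    "reduce_dimensions",
    "diffusion_map",
]


@dataclass
class ExpressionMatrix:
    """Genes-by-cells expression matrix with identifiers.

    Parameters
    ----------
    values
        Real matrix of shape ``(m, N)`` holding (nonnegative) expression
        levels, genes as rows and cells as columns.
    gene_ids, cell_ids
        Unique identifiers for rows and columns.
    time_labels
        Optional per-cell experimental time labels (ordinal or real),
        used for root selection and evaluation.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    time_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        m, n = self.values.shape
        if m < 1 or n < 2:
            raise ValueError(f"need at least 1 gene and 2 cells, got {m}x{n}")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains NaN entries")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if len(self.gene_ids) != m:
            raise ValueError("gene_ids length does not match number of rows")
        if len(self.cell_ids) != n:
            raise ValueError("cell_ids length does not match number of columns")
        if len(set(self.gene_ids)) != m:
            raise ValueError("gene_ids are not unique")
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell_ids are not unique")
        if self.time_labels is not None:
            self.time_labels = np.asarray(self.time_labels)
            if self.time_labels.shape[0] != n:
                raise ValueError("time_labels length does not match cells")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


@dataclass
class Embedding:
    """D-dimensional per-cell coordinates, columns aligned to cells."""

    coords: np.ndarray
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2:
            raise ValueError("embedding coordinates must be a 2-D matrix")
        if not np.isfinite(self.coords).all():
            raise ValueError("embedding contains non-finite coordinates")
        self.cell_ids = [str(c) for c in self.cell_ids]
        if len(self.cell_ids) != self.coords.shape[1]:
            raise ValueError("cell_ids length does not match columns")

    @property
    def D(self) -> int:
        return self.coords.shape[0]

    @property
    def n_cells(self) -> int:
        return self.coords.shape[1]


def filter_zero_genes(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Drop genes with zero expression across all cells.

    Gene order is preserved; raises if every gene is all-zero.
    """
    keep = np.any(expr.values != 0, axis=1)
    if not keep.any():
        raise ValueError("all genes have zero expression across all cells")
    if keep.all():
        return ExpressionMatrix(
            expr.values.copy(), list(expr.gene_ids), list(expr.cell_ids),
            expr.time_labels,
        )
    return ExpressionMatrix(
        expr.values[keep],
        [g for g, k in zip(expr.gene_ids, keep) if k],
        list(expr.cell_ids),
        expr.time_labels,
    )


def size_factor_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each cell by a library-size factor so column totals are equal.

    The size factor of cell *i* is its column total divided by the median
    column total, so normalised totals all equal the median of the input
    totals (read-depth adjustment).
    """
    totals = expr.values.sum(axis=0)
    bad = np.flatnonzero(totals <= 0)
    if bad.size:
        raise ValueError(
            f"cell {expr.cell_ids[bad[0]]!r} has non-positive total expression"
        )
    factors = totals / np.median(totals)
    return ExpressionMatrix(
        expr.values / factors, list(expr.gene_ids), list(expr.cell_ids),
        expr.time_labels,
    )


def density_filter_cells(
    coords: Embedding,
    n_probe: int = 100,
    quantile: float = 0.90,
    min_neighbors: int = 40,
) -> tuple[Embedding, np.ndarray]:
    """Remove low-density cells.

    A global radius is set to the given quantile of the pooled distances
    from every cell to each of its ``n_probe`` nearest neighbours; cells
    with fewer than ``min_neighbors`` other cells within that radius are
    dropped.  Returns the filtered embedding and the surviving indices.
    """
    n = coords.n_cells
    if n <= n_probe:
        raise ValueError(f"need more than n_probe={n_probe} cells, got {n}")
    pts = coords.coords.T
    nn = NearestNeighbors(n_neighbors=n_probe + 1).fit(pts)
    dist, _ = nn.kneighbors(pts)
    threshold = float(np.quantile(dist[:, 1:], quantile))
    counts = np.array(
        [len(idx) - 1 for idx in nn.radius_neighbors(pts, radius=threshold,
                                                     return_distance=False)]
    )
    kept = np.flatnonzero(counts >= min_neighbors)
    logger.info(
        "density filter: radius=%.4g, removed %d of %d cells",
        threshold, n - kept.size, n,
    )
    filtered = Embedding(
        coords.coords[:, kept], [coords.cell_ids[i] for i in kept]
    )
    return filtered, kept


def diffusion_map(
    matrix: np.ndarray,
    target_D: int,
    sigma: float | None = None,
    cell_ids: list[str] | None = None,
) -> Embedding:
    """Diffusion-map embedding of the columns of ``matrix``.

    Builds a Gaussian kernel ``w(x, y) = exp(-||x-y||^2 / (2 sigma^2))``
    on pairwise Euclidean distances (``sigma`` defaults to the median
    pairwise distance), applies anisotropic (alpha = 1) density
    normalisation, row-normalises to a Markov transition operator and
    returns eigenvectors ``2 .. target_D+1`` of that operator, each scaled
    by its eigenvalue.  The trivial constant eigenvector (eigenvalue 1) is
    excluded.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("input must be a features x cells matrix")
    n = X.shape[1]
    if n < target_D + 2:
        raise ValueError(f"need at least target_D + 2 = {target_D + 2} cells")
    if not np.isfinite(X).all():
        raise ValueError("diffusion map input contains non-finite values")

    cond = pdist(X.T)
    if sigma is None:
        sigma = float(np.median(cond))
    if sigma <= 0:
        raise ValueError(
            "kernel bandwidth is zero (all cells coincide); "
            "the kernel is rank-deficient"
        )
    d2 = squareform(cond) ** 2
    K = np.exp(-d2 / (2.0 * sigma**2))

    # alpha = 1 anisotropic normalisation removes sampling-density effects
    q = K.sum(axis=1)
    K1 = K / np.outer(q, q)
    dvec = K1.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(dvec)
    A = K1 * np.outer(inv_sqrt, inv_sqrt)  # symmetric conjugate of P

    m = A.shape[0]
    lo = m - (target_D + 1)
    evals, evecs = eigh(A, subset_by_index=[lo, m - 1])
    evals = evals[::-1]
    evecs = evecs[:, ::-1]
    # map back to eigenvectors of the transition operator P = D^-1 K1
    phi = evecs * inv_sqrt[:, None]
    # deterministic sign: largest-magnitude component positive
    coords = np.empty((target_D, n))
    for j in range(target_D):
        v = phi[:, j + 1]
        s = np.sign(v[np.argmax(np.abs(v))]) or 1.0
        coords[j] = evals[j + 1] * s * v
    if cell_ids is None:
        cell_ids = [f"cell_{i}" for i in range(n)]
    return Embedding(coords, cell_ids)


def reduce_dimensions(
    expr: ExpressionMatrix,
    target_D: int = 2,
    pca_predim: int | None = None,
    sigma: float | None = None,
) -> Embedding:
    """Embed cells in ``target_D`` dimensions via (optional PCA then)
    diffusion maps."""
    n = expr.n_cells
    if target_D >= n:
        raise ValueError(f"target_D={target_D} must be smaller than N={n}")
    if n < target_D + 2:
        raise ValueError("too few cells for the requested dimension")
    mat = expr.values
    if pca_predim is not None:
        ncomp = min(pca_predim, expr.n_genes, n)
        pca = PCA(n_components=ncomp, svd_solver="auto", random_state=0)
        mat = pca.fit_transform(mat.T).T
        logger.info("PCA pre-reduction to %d components", ncomp)
    return diffusion_map(mat, target_D, sigma=sigma, cell_ids=list(expr.cell_ids))
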