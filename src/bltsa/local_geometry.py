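"""Per-cell local tangent geometry: tip / branching / intermediate calls.

Cells on a one-dimensional differentiation arm have neighbourhoods that are
well fit by a line; cells at a junction need two or more directions; cells
at the ends of the trajectory see all their neighbours on one side.  These
three situations are scored by (i) a *nonlinearity* ratio of squared
singular values of the centred neighbourhood and (ii) a *direction
consistency* statistic over neighbour pairs, and thresholded into the
categories branching, tip and intermediate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .preprocess import Embedding

logger = logging.getLogger(__name__)

__all__ = [
    "LocalTangentModel",
    "knn_neighborhoods",
    "fit_local_tangent",
    "nonlinearity_score",
    "identify_branching_cells",
    "consistency_score",
    "identify_tip_cells",
    "select_root",
]


@dataclass
class LocalTangentModel:
    """Best-fit d-dimensional affine subspace to one cell's neighbourhood.

    ``basis`` (D x d, orthonormal) spans the tangent space at the cell;
    ``local_coords`` (d x k) are the centred coordinates of the
    neighbourhood along that basis; ``singular_values`` come from the SVD
    of the centred neighbourhood matrix.
    """

    cell_index: int
    neighbor_indices: np.ndarray
    mean: np.ndarray
    basis: np.ndarray
    local_coords: np.ndarray
    singular_values: np.ndarray
    degenerate: bool = False


def knn_neighborhoods(coords: Embedding | np.ndarray, k: int) -> list[np.ndarray]:
    """k-nearest neighbourhoods (self included) under Euclidean distance.

    Ties are broken by ascending cell index for determinism.  The cell
    itself always occupies the first slot of its neighbourhood.
    """
    X = coords.coords if isinstance(coords, Embedding) else np.asarray(coords)
    n = X.shape[1]
    if k < 2 or k > n:
        raise ValueError(f"k={k} out of range [2, {n}]")
    dist = cdist(X.T, X.T)
    order = np.argsort(dist, axis=1, kind="stable")
    out = []
    for i in range(n):
        row = order[i]
        others = row[row != i][: k - 1]
        out.append(np.concatenate(([i], others)))
    return out


def fit_local_tangent(
    coords: Embedding | np.ndarray, Ni: np.ndarray, d: int,
    cell_index: int | None = None,
) -> LocalTangentModel:
    """Fit the rank-d tangent model of a neighbourhood by SVD.

    Minimises ``||Xi - (xbar e^T + U Theta)||_F^2`` over orthonormal
    ``U`` (D x d) and ``Theta`` (d x k): ``U`` is the first d left
    singular vectors of the centred ``Xi`` and ``Theta`` the first d rows
    of ``Sigma V^T``.
    """
    X = coords.coords if isinstance(coords, Embedding) else np.asarray(coords)
    Ni = np.asarray(Ni, dtype=int)
    k = Ni.size
    if k < d + 1:
        raise ValueError(f"neighbourhood of size {k} too small for d={d}")
    Xi = X[:, Ni]
    D = Xi.shape[0]
    xbar = Xi.mean(axis=1)
    Xc = Xi - xbar[:, None]
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if s[0] <= 1e-300:
        # all neighbourhood points coincide
        basis = np.eye(D)[:, :d]
        theta = np.zeros((d, k))
        return LocalTangentModel(
            cell_index if cell_index is not None else int(Ni[0]),
            Ni, xbar, basis, theta, s, degenerate=True,
        )
    # deterministic sign convention per singular vector
    for j in range(min(D, k)):
        col = U[:, j]
        sgn = np.sign(col[np.argmax(np.abs(col))]) or 1.0
        U[:, j] *= sgn
        Vt[j] *= sgn
    basis = U[:, :d]
    theta = s[:d, None] * Vt[:d]
    return LocalTangentModel(
        cell_index if cell_index is not None else int(Ni[0]),
        Ni, xbar, basis, theta, s,
    )


def nonlinearity_score(model: LocalTangentModel, d: int = 1) -> float:
    """Squared-singular-value ratio ``sigma_{d+1}^2 / (sigma_1^2+...+sigma_d^2)``.

    Near zero for neighbourhoods with strong d-dimensional linear
    structure; large at junctions where no single direction fits.
    """
    s = model.singular_values
    if s.size < d + 1:
        raise ValueError(f"model has {s.size} singular values, need {d + 1}")
    denom = float(np.sum(s[:d] ** 2))
    if denom <= 0.0:
        logger.debug("degenerate neighbourhood at cell %d", model.cell_index)
        return 0.0
    return float(s[d] ** 2 / denom)


def identify_branching_cells(
    scores: np.ndarray, percentile: float = 0.80
) -> tuple[np.ndarray, float]:
    """Flag cells whose nonlinearity strictly exceeds the upper percentile.

    Returns the boolean mask and the realised threshold (linear
    interpolation percentile); at the 0.80 default roughly the top 20 % of
    cells are flagged.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise ValueError("need at least two cells")
    delta_b = float(np.quantile(scores, percentile))
    return scores > delta_b, delta_b


def consistency_score(
    coords: Embedding | np.ndarray,
    i: int,
    Ni: np.ndarray,
    norm: str = "full",
) -> float:
    """Direction consistency of cell *i* within its neighbourhood.

    Over all unordered pairs {p, q} of neighbours (i itself excluded),
    counts the pairs with ``(x_p - x_i)^T (x_q - x_i) >= 0`` (same side of
    i).  With ``norm='full'`` the count is scaled by ``2 / (k (k-1))``
    where k = |Ni|, so the maximum is ``(k-2)/k``; ``norm='pairs'``
    divides by the actual pair count ``(k-1)(k-2)/2`` instead.
    """
    X = coords.coords if isinstance(coords, Embedding) else np.asarray(coords)
    Ni = np.asarray(Ni, dtype=int)
    k = Ni.size
    if k < 3:
        raise ValueError("neighbourhood must contain at least 3 cells")
    if i not in Ni:
        raise ValueError(f"cell {i} not in its own neighbourhood")
    nb = Ni[Ni != i]
    diffs = X[:, nb] - X[:, i][:, None]
    G = diffs.T @ diffs
    iu = np.triu_indices(nb.size, k=1)
    same = int(np.count_nonzero(G[iu] >= 0.0))
    if norm == "full":
        return 2.0 * same / (k * (k - 1))
    if norm == "pairs":
        npairs = (k - 1) * (k - 2) // 2
        return same / npairs if npairs else 0.0
    raise ValueError(f"unknown consistency norm {norm!r}")


def identify_tip_cells(
    consistencies: np.ndarray,
    branching_mask: np.ndarray,
    delta_t: float = 0.9,
    k: int | None = None,
    norm: str = "full",
) -> np.ndarray:
    """Tips are non-branching cells with consistency above ``delta_t``."""
    consistencies = np.asarray(consistencies, dtype=float)
    branching_mask = np.asarray(branching_mask, dtype=bool)
    if k is not None and norm == "full" and (k - 2) / k <= delta_t:
        raise ValueError(
            f"with k={k} the maximum attainable consistency (k-2)/k = "
            f"{(k - 2) / k:.3f} does not exceed delta_t={delta_t}; "
            "increase k or lower delta_t"
        )
    return (consistencies > delta_t) & ~branching_mask


def select_root(
    tips: np.ndarray,
    time_labels: np.ndarray | None = None,
    seed: int = 0,
) -> int:
    """Pick the pseudotime origin among the tip cells.

    With experimental time labels, the tip at the earliest label wins
    (ties broken by lowest cell index); otherwise a seeded uniform draw.
    """
    tips = np.asarray(tips, dtype=bool)
    tip_idx = np.flatnonzero(tips)
    if tip_idx.size == 0:
        raise ValueError(
            "no tip cells found; lower delta_t, increase k, or pass an "
            "explicit root cell"
        )
    if time_labels is not None:
        labels = [time_labels[j] for j in tip_idx]
        best = min(range(tip_idx.size), key=lambda a: (labels[a], tip_idx[a]))
        return int(tip_idx[best])
    rng = np.random.default_rng(seed)
    return int(rng.choice(tip_idx))
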