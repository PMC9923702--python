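"""Branch discovery: spectral clustering plus iterative junction assignment.

Non-branching cells sit on well-separated one-dimensional arms and cluster
stably, so they are clustered first (normalised spectral clustering with a
median-bandwidth Gaussian affinity, branch count selected by silhouette).
Junction (branching) cells are then absorbed greedily, each being added to
the branch minimising the average of its tangent distance and Euclidean
distance to the branch's nearest anchor cells; the absorbed cell's
neighbourhood and tangent model are updated so it can anchor later
assignments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .alignment import adaptive_neighborhood_size
from .local_geometry import LocalTangentModel, fit_local_tangent
from .preprocess import Embedding

logger = logging.getLogger(__name__)

__all__ = [
    "BranchLabeling",
    "gaussian_affinity",
    "cluster_nonbranching",
    "branch_distance",
    "assign_branching_cells",
    "redistribute_neighborhoods",
]


@dataclass
class BranchLabeling:
    """Per-cell branch assignment.

    ``labels`` holds a branch index in ``0..n_branches-1`` per cell, or -1
    while a branching cell is still unassigned.  ``assignment_order``
    records the greedy absorption sequence as (cell, branch) pairs.
    """

    n_branches: int
    labels: np.ndarray
    root_branch: int | None = None
    assignment_order: list[tuple[int, int]] = field(default_factory=list)
    silhouettes: dict[int, float] = field(default_factory=dict)

    def is_complete(self) -> bool:
        return bool(np.all(self.labels >= 0))


def gaussian_affinity(
    coords: Embedding | np.ndarray, indices: np.ndarray | None = None
) -> np.ndarray:
    """Gaussian similarity matrix with median-distance bandwidth.

    ``A[p, q] = exp(-||x_p - x_q||^2 / (2 sigma^2))`` with sigma the
    median off-diagonal pairwise distance among the selected cells;
    diagonal zeroed.
    """
    X = coords.coords if isinstance(coords, Embedding) else np.asarray(coords)
    if indices is not None:
        X = X[:, np.asarray(indices, dtype=int)]
    if X.shape[1] < 2:
        raise ValueError("need at least two cells")
    cond = pdist(X.T)
    sigma = float(np.median(cond))
    if sigma <= 0:
        raise ValueError("all selected cells coincide; affinity undefined")
    A = np.exp(-squareform(cond) ** 2 / (2.0 * sigma**2))
    np.fill_diagonal(A, 0.0)
    return A


def _spectral_embed(A: np.ndarray, n_components: int) -> np.ndarray:
    """Row-normalised leading eigenvectors of D^{-1/2} A D^{-1/2}."""
    deg = A.sum(axis=1)
    deg = np.maximum(deg, 1e-12)  # guards isolated vertices
    inv_sqrt = 1.0 / np.sqrt(deg)
    Asym = A * np.outer(inv_sqrt, inv_sqrt)
    m = Asym.shape[0]
    _, vecs = eigh(Asym, subset_by_index=[m - n_components, m - 1])
    emb = vecs[:, ::-1]
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    return emb / np.maximum(norms, 1e-12)


def cluster_nonbranching(
    coords: Embedding | np.ndarray,
    nonbranching: np.ndarray,
    candidate_L: range | list[int] = range(2, 9),
    seed: int = 0,
    n_init: int = 20,
) -> BranchLabeling:
    """Cluster the non-branching cells and select the branch count.

    For each candidate L, normalised spectral clustering (symmetric
    normalised Laplacian, L leading eigenvectors, row normalisation,
    seeded k-means) is run and scored by the mean silhouette coefficient
    on the embedding coordinates; the best L wins (ties to the smaller L).
    Returns a partial labeling: branching cells keep label -1.
    """
    X = coords.coords if isinstance(coords, Embedding) else np.asarray(coords)
    n = X.shape[1]
    nonbranching = np.asarray(nonbranching, dtype=int)
    m = nonbranching.size
    cands = sorted(set(int(L) for L in candidate_L if 2 <= L < m))
    if not cands:
        raise ValueError(f"no feasible candidate branch count for {m} cells")
    pts = X[:, nonbranching].T
    A = gaussian_affinity(X, nonbranching)

    best_L, best_sil, best_labels = None, -np.inf, None
    sils: dict[int, float] = {}
    for L in cands:
        emb = _spectral_embed(A, L)
        km = KMeans(n_clusters=L, n_init=n_init, random_state=seed).fit(emb)
        sub = km.labels_
        if len(np.unique(sub)) < 2:
            continue
        sil = float(silhouette_score(pts, sub))
        sils[L] = sil
        logger.info("spectral clustering L=%d: silhouette %.4f", L, sil)
        if sil > best_sil + 1e-12:
            best_L, best_sil, best_labels = L, sil, sub
    if best_labels is None:
        raise RuntimeError("spectral clustering failed for all candidate L")

    labels = np.full(n, -1, dtype=int)
    labels[nonbranching] = best_labels
    return BranchLabeling(n_branches=best_L, labels=labels, silhouettes=sils)


def branch_distance(
    coords: Embedding | np.ndarray,
    models: dict[int, LocalTangentModel] | list[LocalTangentModel],
    i: int,
    branch_cells: np.ndarray,
    n_anchor: int,
) -> float:
    """Average of tangent and Euclidean distance from cell *i* to a branch.

    The anchors are the ``n_anchor`` branch cells closest to x_i (all when
    the branch is smaller).  Tangent distance of anchor j is
    ``||(I - U_j U_j^T)(x_i - x_j)||``.
    """
    X = coords.coords if isinstance(coords, Embedding) else np.asarray(coords)
    branch_cells = np.asarray(branch_cells, dtype=int)
    if branch_cells.size == 0:
        raise ValueError("branch is empty")
    xi = X[:, i]
    diffs = X[:, branch_cells] - xi[:, None]
    dists = np.linalg.norm(diffs, axis=0)
    order = np.argsort(dists, kind="stable")
    anchors = branch_cells[order[:n_anchor]]
    d_e = float(dists[order[:n_anchor]].mean())
    resid = 0.0
    for j in anchors:
        Uj = models[j].basis
        v = xi - X[:, j]
        resid += float(np.linalg.norm(v - Uj @ (Uj.T @ v)))
    d_t = resid / anchors.size
    return 0.5 * (d_t + d_e)


def assign_branching_cells(
    coords: Embedding | np.ndarray,
    models: dict[int, LocalTangentModel] | list[LocalTangentModel],
    labeling: BranchLabeling,
    branching: np.ndarray,
    n_anchor: int,
    neighborhoods: list[np.ndarray] | None = None,
    d: int = 1,
) -> BranchLabeling:
    """Greedily absorb branching cells into their closest branch.

    At every step the globally smallest (cell, branch) distance wins, so
    branches grow outward from confident cells; after each absorption the
    cell's neighbourhood is restricted to its original neighbours inside
    the chosen branch (itself included) and its tangent model is refit,
    making it usable as an anchor for later assignments.  Distances are
    recomputed as branches grow.
    """
    X = coords.coords if isinstance(coords, Embedding) else np.asarray(coords)
    labels = labeling.labels.copy()
    pending = list(np.asarray(branching, dtype=int))
    order: list[tuple[int, int]] = list(labeling.assignment_order)
    L = labeling.n_branches

    while pending:
        best = None  # (distance, cell, branch) with tie-break on branch, cell
        members = [np.flatnonzero(labels == l) for l in range(L)]
        for i in pending:
            for l in range(L):
                if members[l].size == 0:
                    continue
                dist = branch_distance(X, models, i, members[l], n_anchor)
                key = (dist, i, l)
                if best is None or key < best:
                    best = key
        if best is None:
            raise RuntimeError("no populated branch to absorb cells into")
        dist, i, l = best
        labels[i] = l
        order.append((i, l))
        pending.remove(i)
        # update neighbourhood and tangent model of the absorbed cell
        if neighborhoods is not None:
            Ni = neighborhoods[i]
            new_Ni = np.array(
                [j for j in Ni if j == i or labels[j] == l], dtype=int
            )
            if new_Ni.size < d + 1:
                same = np.flatnonzero(labels == l)
                same = same[same != i]
                dd = np.linalg.norm(X[:, same] - X[:, i][:, None], axis=0)
                near = same[np.argsort(dd, kind="stable")[:n_anchor]]
                new_Ni = np.concatenate(([i], near))
                logger.info(
                    "cell %d: updated neighbourhood too small, fell back to "
                    "%d nearest same-branch cells", i, near.size,
                )
            neighborhoods[i] = new_Ni
            models[i] = fit_local_tangent(X, new_Ni, d, cell_index=i)

    root_branch = labeling.root_branch
    return BranchLabeling(
        n_branches=L, labels=labels, root_branch=root_branch,
        assignment_order=order, silhouettes=labeling.silhouettes,
    )


def redistribute_neighborhoods(
    coords: Embedding | np.ndarray,
    labeling: BranchLabeling,
    k_range: tuple[int, int],
    d: int = 1,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Rebuild neighbourhoods within each cell's own branch plus the root branch.

    Each cell draws its neighbours from the eligible pool (same-branch or
    root-branch cells), with the neighbourhood size chosen adaptively in
    ``k_range`` by the tangent-fit ratio.  Returns the neighbourhoods and
    the chosen sizes.
    """
    X = coords.coords if isinstance(coords, Embedding) else np.asarray(coords)
    if not labeling.is_complete():
        raise ValueError("labeling must be complete before redistribution")
    if labeling.root_branch is None:
        raise ValueError("root branch is not set")
    n = X.shape[1]
    kmin, kmax = k_range
    labels = labeling.labels
    rb = labeling.root_branch
    neighborhoods: list[np.ndarray] = []
    chosen = np.empty(n, dtype=int)
    pools = {
        l: np.flatnonzero((labels == l) | (labels == rb))
        for l in range(labeling.n_branches)
    }
    for i in range(n):
        pool = pools[labels[i]]
        dd = np.linalg.norm(X[:, pool] - X[:, i][:, None], axis=0)
        order = np.argsort(dd, kind="stable")
        sorted_pool = pool[order]
        # self is at distance zero; make sure it is first
        selfpos = int(np.flatnonzero(sorted_pool == i)[0])
        if selfpos != 0:
            sorted_pool = np.concatenate(
                ([i], np.delete(sorted_pool, selfpos))
            )
        if sorted_pool.size < kmin:
            logger.info(
                "cell %d: eligible pool %d below kmin=%d, using whole pool",
                i, sorted_pool.size, kmin,
            )
            ki = sorted_pool.size
        else:
            ki = adaptive_neighborhood_size(X, sorted_pool, i, (kmin, kmax), d=d)
        neighborhoods.append(sorted_pool[:ki])
        chosen[i] = ki
    return neighborhoods, chosen
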