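"""Global alignment of local tangent coordinates into pseudotime.

Each cell's neighbourhood contributes local one-dimensional coordinates
Theta_i; the alignment matrix ``W_i = (I - e e^T/k)(I - Theta_i^+ Theta_i)``
penalises global coordinates that are not an affine image of Theta_i.  The
global coordinate vector minimising the summed penalty is an eigenvector of
``B = sum_i S_i W_i W_i^T S_i^T`` for a small eigenvalue.  The constant
vector is always a 0-eigenvector of B (every W_i annihilates constants) and
carries no ordering information, so it is deflated and the smallest
remaining eigenvector taken, then oriented so the root cell sits at the low
end and rescaled affinely to [0, 1].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.sparse.linalg import lobpcg

logger = logging.getLogger(__name__)

__all__ = [
    "PseudotimeResult",
    "adaptive_neighborhood_size",
    "local_alignment_matrix",
    "assemble_global_matrix",
    "solve_pseudotime",
]

_DENSE_LIMIT = 2000


@dataclass
class PseudotimeResult:
    """Per-cell pseudotime in [0, 1] with solver diagnostics."""

    tau: np.ndarray
    root: int
    eigenvalues: np.ndarray
    chosen_k: np.ndarray | None = None


def adaptive_neighborhood_size(
    coords: np.ndarray,
    eligible_sorted: np.ndarray,
    i: int,
    k_range: tuple[int, int],
    d: int = 1,
) -> int:
    """Choose the neighbourhood size minimising the tangent-fit ratio.

    For each candidate k in ``k_range`` the first k cells of
    ``eligible_sorted`` (which must be ordered by distance to cell *i*,
    self first) form the window; the score is
    ``r(k) = sigma_{d+1} / sqrt(sigma_1^2 + ... + sigma_d^2)`` of the
    centred window.  Smallest k wins ties, so exactly linear data returns
    ``kmin``.
    """
    kmin, kmax = k_range
    if kmin < d + 2:
        raise ValueError(f"kmin={kmin} must be at least d+2={d + 2}")
    if kmax < kmin:
        raise ValueError("kmax must be >= kmin")
    eligible_sorted = np.asarray(eligible_sorted, dtype=int)
    m = eligible_sorted.size
    if m < kmin:
        logger.info("cell %d: pool of %d below kmin=%d", i, m, kmin)
        return m
    hi = min(kmax, m)
    pts = coords[:, eligible_sorted[:hi]]
    D = pts.shape[0]
    # cumulative first and second moments -> scatter matrix per window size
    S1 = np.cumsum(pts, axis=1)
    outer = pts[:, None, :] * pts[None, :, :]
    S2 = np.cumsum(outer, axis=2)
    best_k, best_r = kmin, np.inf
    for k in range(kmin, hi + 1):
        mean = S1[:, k - 1] / k
        scatter = S2[:, :, k - 1] - k * np.outer(mean, mean)
        ev = np.linalg.eigvalsh(scatter)[::-1]  # descending, = sigma_j^2
        ev = np.maximum(ev, 0.0)
        denom = float(np.sum(ev[:d]))
        if denom <= 0.0:
            r = 0.0
        elif ev.size <= d:
            r = 0.0
        else:
            r = float(np.sqrt(ev[d] / denom))
        if r < best_r - 1e-15:
            best_r, best_k = r, k
    return best_k


def local_alignment_matrix(theta: np.ndarray, k: int | None = None) -> np.ndarray:
    """Alignment matrix ``W = (I - e e^T / k)(I - Theta^+ Theta)``.

    ``Theta^+`` is the Moore-Penrose pseudo-inverse (SVD, singular values
    below 1e-12 of the largest treated as zero).  For centred Theta the
    result annihilates both the constant vector and the rows of Theta.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    kk = theta.shape[1]
    if k is None:
        k = kk
    elif k != kk:
        raise ValueError(f"theta has {kk} columns, expected k={k}")
    pinv = np.linalg.pinv(theta, rcond=1e-12)
    M = np.eye(k) - pinv @ theta
    return M - M.mean(axis=0, keepdims=True)


def assemble_global_matrix(
    neighborhoods: list[np.ndarray],
    W_list: list[np.ndarray],
    n_cells: int,
) -> np.ndarray:
    """Scatter-add ``sum_i S_i W_i W_i^T S_i^T`` into a dense N x N matrix."""
    covered = np.zeros(n_cells, dtype=bool)
    B = np.zeros((n_cells, n_cells))
    for Ni, Wi in zip(neighborhoods, W_list):
        Ni = np.asarray(Ni, dtype=int)
        if Wi.shape != (Ni.size, Ni.size):
            raise ValueError("alignment matrix does not match neighbourhood")
        covered[Ni] = True
        B[np.ix_(Ni, Ni)] += Wi @ Wi.T
    if not covered.all():
        missing = np.flatnonzero(~covered)
        raise ValueError(
            f"{missing.size} cells belong to no neighbourhood "
            f"(first: {missing[:5].tolist()})"
        )
    return 0.5 * (B + B.T)


def solve_pseudotime(
    B: np.ndarray,
    root: int,
    d: int = 1,
    eig_raw: bool = False,
    seed: int = 0,
    n_eigenvalues: int = 5,
) -> PseudotimeResult:
    """Extract pseudotime from the global alignment matrix.

    Deflates the constant direction (unless ``eig_raw``), takes the
    eigenvector of the smallest remaining eigenvalue, orients it so the
    root cell lies at the low end, and rescales affinely to [0, 1].
    """
    B = np.asarray(B, dtype=float)
    n = B.shape[0]
    if B.shape != (n, n):
        raise ValueError("B must be square")
    if not (0 <= root < n):
        raise ValueError(f"root index {root} out of range")
    scale = float(np.abs(B).max())
    if scale <= 0.0:
        raise ValueError("no geometry to align: B is identically zero")

    if n <= _DENSE_LIMIT:
        if eig_raw:
            evals_all, evecs = eigh(B, subset_by_index=[0, min(d, n - 1)])
            v = evecs[:, 0]
            gap = evals_all[1] - evals_all[0] if evals_all.size > 1 else np.inf
        else:
            shift = max(1.0, float(np.trace(B)))
            C = B + shift * np.ones((n, n)) / n
            evals_all, evecs = eigh(C, subset_by_index=[0, min(1, n - 1)])
            v = evecs[:, 0]
            gap = evals_all[1] - evals_all[0] if evals_all.size > 1 else np.inf
        if gap < 1e-10 * max(scale, 1.0):
            warnings.warn(
                "smallest alignment eigenvalue is nearly degenerate; "
                "pseudotime may be ill-determined", RuntimeWarning,
            )
        eigenvalues = np.linalg.eigvalsh(B)[: min(n_eigenvalues, n)]
    else:
        rng = np.random.default_rng(seed)
        X0 = rng.standard_normal((n, d))
        ones = np.ones((n, 1)) / np.sqrt(n)
        constraint = None if eig_raw else ones
        vals, vecs = lobpcg(
            B, X0, Y=constraint, largest=False, tol=1e-10, maxiter=500,
        )
        v = vecs[:, 0]
        eigenvalues = np.sort(vals)[: min(n_eigenvalues, d)]

    # orient: the root (a trajectory endpoint) belongs at the low end
    if (v[root] - v.min()) > (v.max() - v[root]):
        v = -v
    lo, hi = float(v.min()), float(v.max())
    if hi - lo <= 1e-12 * max(1.0, abs(hi), abs(lo)):
        raise ValueError(
            "alignment eigenvector is constant; no geometry to align"
        )
    tau = (v - lo) / (hi - lo)
    return PseudotimeResult(tau=tau, root=int(root),
                            eigenvalues=np.asarray(eigenvalues))
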