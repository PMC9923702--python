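"""Synthetic branching-trajectory generators and evaluation helpers.

Three regimes are covered:

* a fully geometric trifurcation — a straight root segment at y = 1 for
  x in [0, 1] splitting at (1, 1) into three arms on x in [1, 3]
  (``y = 0.75 + 0.25 x^1.75``, ``y = 1.25 - 0.25 x^1.75`` and ``y = 1``),
  with additive uniform noise on the vertical coordinate;
* sigmoid-mean Gaussian expression bifurcations, with per-gene standard
  deviations built from ``1.5 * Pois(3)`` or ``2 / Gamma(2, 2)`` draws and
  negative expression truncated to zero;
* a tree-structured kinetic regime with three branching events, in which
  per-gene two-state promoter rates (on/off switching, synthesis,
  degradation) are perturbed on each tree edge and cells interpolate the
  resulting steady-state means along the edges.  This is a simplified
  kinetic stand-in, not a full transcriptional-bursting simulator.

Ground-truth pseudotime and branch labels ship with every dataset, plus
the Pearson/Spearman evaluation metrics and the rank-window expression
smoother used for marker-gene curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SimulatedTrajectory",
    "simulate_geometric_trifurcation",
    "simulate_sigmoid_bifurcation",
    "simulate_kinetic_tree",
    "correlation_metrics",
    "smooth_expression_along_pseudotime",
]


@dataclass
class SimulatedTrajectory:
    """Simulated dataset with ground truth.

    ``matrix`` is features x cells (2-D coordinates for the geometric
    regime, genes otherwise); ``true_tau`` the ground-truth progression
    parameter; ``true_branch`` per-cell branch labels.
    """

    matrix: np.ndarray
    true_tau: np.ndarray
    true_branch: np.ndarray
    regime: str
    seed: int
    cell_ids: list[str]
    feature_ids: list[str]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[1]


def _cell_ids(n: int) -> list[str]:
    return [f"cell_{i:04d}" for i in range(n)]


def simulate_geometric_trifurcation(
    n_root: int = 100,
    n_per_branch: int = 100,
    noise_high: float = 0.6,
    seed: int = 0,
    noise_axes: str = "y",
) -> SimulatedTrajectory:
    """Geometric trifurcation: a root segment splitting into three arms.

    Root cells sit at (x, 1) with x equally spaced on [0, 1]; each arm has
    x equally spaced on [1, 3] and y given by ``0.75 + 0.25 x^1.75``,
    ``1.25 - 0.25 x^1.75`` or the constant 1 (all three meet the root at
    (1, 1)).  Uniform [0, noise_high] noise perturbs the vertical
    coordinate; the horizontal ordinates are the design grid and stay
    exact, preserving the equal spacing between neighbouring cells
    (``noise_axes='both'`` adds independent noise to x as well).
    Ground-truth pseudotime is the horizontal coordinate x.
    """
    if noise_high < 0:
        raise ValueError("noise_high must be nonnegative")
    if noise_axes not in ("y", "both"):
        raise ValueError(f"unknown noise_axes {noise_axes!r}")
    rng = np.random.default_rng(seed)
    x_root = np.linspace(0.0, 1.0, n_root)
    xb = np.linspace(1.0, 3.0, n_per_branch)
    curves = [
        0.75 + 0.25 * xb**1.75,
        1.25 - 0.25 * xb**1.75,
        np.ones(n_per_branch),
    ]
    xs = np.concatenate([x_root] + [xb] * 3)
    ys = np.concatenate([np.ones(n_root)] + curves)
    coords = np.vstack([xs, ys])
    n = coords.shape[1]
    if noise_high > 0:
        noise = rng.uniform(0.0, noise_high, size=(2, n))
        if noise_axes == "y":
            noise[0] = 0.0
        coords = coords + noise
    branch = np.array(
        ["root"] * n_root
        + ["b1"] * n_per_branch
        + ["b2"] * n_per_branch
        + ["b3"] * n_per_branch
    )
    return SimulatedTrajectory(
        matrix=coords,
        true_tau=xs.copy(),
        true_branch=branch,
        regime="geometric_trifurcation",
        seed=seed,
        cell_ids=_cell_ids(n),
        feature_ids=["x", "y"],
    )


def _gamma_sd(rng: np.random.Generator, n: int, cap: float | None = 6.0) -> np.ndarray:
    """Per-gene standard deviations ``2 / Gamma(shape 2, rate 2)``.

    Zero draws are rejected (division guard).  The inverse-gamma law is
    heavy-tailed: a single small draw can produce a standard deviation an
    order of magnitude above every gene mean, which would reduce the whole
    dataset to that one gene's noise, so the result is clipped at ``cap``
    (the bulk of the distribution — median 2.4 — is unaffected).
    """
    g = rng.gamma(shape=2.0, scale=0.5, size=n)
    while np.any(g <= 0):
        g[g <= 0] = rng.gamma(shape=2.0, scale=0.5, size=int((g <= 0).sum()))
    sd = 2.0 / g
    if cap is not None:
        np.minimum(sd, cap, out=sd)
    return sd


def simulate_sigmoid_bifurcation(
    n_cells: int = 200,
    n_genes: int = 40,
    dispersion: str = "pois",
    seed: int = 0,
    noise_scale: float = 1.0,
    tau_grid: bool = False,
) -> SimulatedTrajectory:
    """Bifurcating expression data with sigmoid gene means.

    Cells receive progression values tau ~ U[0, 1] (or an equally spaced
    grid with ``tau_grid``) and split into two branches at tau = 0.5.
    Gene g on branch b follows
    ``mean = base_g + amp_{g,b} * (logistic(w_g (tau - 0.5)) - 0.5)``,
    which passes through ``base_g`` at the switch for every branch, so
    the trunk joins both branch curves continuously.  Per-gene standard
    deviations are drawn once as ``1.5 * Pois(3)`` (``dispersion='pois'``)
    or ``2 / Gamma(2, 2)`` (``dispersion='gamma'``, heavy tail clipped —
    see :func:`_gamma_sd`).  Expression is Gaussian around the mean with
    negatives truncated to 0.
    """
    if n_genes < 2:
        raise ValueError("need at least two genes")
    if dispersion not in ("pois", "gamma"):
        raise ValueError(f"unknown dispersion {dispersion!r}")
    rng = np.random.default_rng(seed)
    tau = (
        np.linspace(0.0, 1.0, n_cells)
        if tau_grid
        else np.sort(rng.uniform(0.0, 1.0, n_cells))
    )
    post = tau > 0.5
    arm = rng.integers(1, 3, size=n_cells)  # branch index after the switch
    branch = np.where(post, np.char.add("b", arm.astype(str)), "trunk")

    base = rng.uniform(4.0, 10.0, n_genes)
    steep = rng.uniform(6.0, 20.0, n_genes) * rng.choice([-1.0, 1.0], n_genes)
    # amplitude row 0: trunk; rows 1, 2: the post-switch branches
    amp = rng.uniform(6.0, 16.0, (3, n_genes)) * rng.choice(
        [-1.0, 1.0], (3, n_genes)
    )
    which = np.where(post, arm, 0)
    logistic = 1.0 / (1.0 + np.exp(-np.outer(steep, tau - 0.5)))
    means = base[:, None] + amp[which, :].T * (logistic - 0.5)

    if dispersion == "pois":
        sd = 1.5 * rng.poisson(3, n_genes).astype(float)
    else:
        sd = _gamma_sd(rng, n_genes)
    sd = sd * noise_scale
    expr = rng.normal(means, sd[:, None]) if noise_scale > 0 else means.copy()
    np.maximum(expr, 0.0, out=expr)
    return SimulatedTrajectory(
        matrix=expr,
        true_tau=tau,
        true_branch=branch,
        regime="sigmoid_bifurcation",
        seed=seed,
        cell_ids=_cell_ids(n_cells),
        feature_ids=[f"gene_{j:03d}" for j in range(n_genes)],
    )


# lineage tree with three branching events (at M, A and B) and four leaves;
# the root edge makes the pseudotime origin a geometric trajectory tip
_TREE_EDGES = [
    ("root", "M"),
    ("M", "A"), ("M", "B"),
    ("A", "A1"), ("A", "A2"),
    ("B", "B1"), ("B", "B2"),
]
_NODE_TIME = {"root": 0.0, "M": 1.0, "A": 2.0, "B": 2.0,
              "A1": 3.0, "A2": 3.0, "B1": 3.0, "B2": 3.0}
_FATE_NODES = ("root", "M")  # edges leaving these carry full reprogramming


def simulate_kinetic_tree(
    n_cells: int = 499,
    n_genes: int = 100,
    seed: int = 0,
    noise_sd: float = 0.3,
    frac_perturbed_leaf: float = 0.5,
) -> SimulatedTrajectory:
    """Tree-structured kinetic regime with three branching events.

    The lineage tree is root -> M, M -> (A, B), A -> (A1, A2),
    B -> (B1, B2): three branching events and four leaf branches.  Each
    gene carries two-state promoter rates (k_on, k_off, synthesis s,
    degradation 1).  On the trunk and first-split edges every gene's
    switching and synthesis rates are perturbed multiplicatively
    (branch-wide expression programs at the fate decision); on the
    terminal-split edges a fraction ``frac_perturbed_leaf`` of genes is
    perturbed.  A cell at position t on an edge interpolates the
    steady-state means ``s * k_on / (k_on + k_off)`` of the edge's
    endpoints plus Gaussian noise with standard deviation
    ``noise_sd * sqrt(mean + 1)``.  Ground-truth pseudotime is the
    distance from the root node.
    """
    rng = np.random.default_rng(seed)
    k_on = rng.uniform(0.1, 1.0, n_genes)
    k_off = rng.uniform(0.1, 1.0, n_genes)
    synth = rng.uniform(10.0, 100.0, n_genes)

    rates = {"root": (k_on, k_off, synth)}
    for parent, child in _TREE_EDGES:
        kon, koff, s = (a.copy() for a in rates[parent])
        frac = 1.0 if parent in _FATE_NODES else frac_perturbed_leaf
        hit = rng.random(n_genes) < frac
        nhit = int(hit.sum())
        kon[hit] *= rng.lognormal(0.0, 0.6, nhit)
        s[hit] *= rng.lognormal(0.0, 1.2, nhit)
        rates[child] = (kon, koff, s)
    node_mean = {v: s * kon / (kon + koff) for v, (kon, koff, s) in rates.items()}

    n_edges = len(_TREE_EDGES)
    per_edge = np.full(n_edges, n_cells // n_edges)
    per_edge[: n_cells % n_edges] += 1
    expr = np.empty((n_genes, n_cells))
    tau = np.empty(n_cells)
    branch = np.empty(n_cells, dtype=object)
    pos = 0
    for (parent, child), m in zip(_TREE_EDGES, per_edge):
        t = np.sort(rng.uniform(0.0, 1.0, m))
        mu = (1.0 - t) * node_mean[parent][:, None] + t * node_mean[child][:, None]
        if noise_sd > 0:
            mu = mu + rng.normal(0.0, noise_sd * np.sqrt(mu + 1.0))
        expr[:, pos : pos + m] = np.maximum(mu, 0.0)
        tau[pos : pos + m] = _NODE_TIME[parent] + t * (
            _NODE_TIME[child] - _NODE_TIME[parent]
        )
        branch[pos : pos + m] = f"{parent}-{child}"
        pos += m
    return SimulatedTrajectory(
        matrix=expr,
        true_tau=tau,
        true_branch=branch.astype(str),
        regime="kinetic_tree",
        seed=seed,
        cell_ids=_cell_ids(n_cells),
        feature_ids=[f"gene_{j:03d}" for j in range(n_genes)],
    )


def correlation_metrics(
    inferred: np.ndarray, truth: np.ndarray
) -> tuple[float, float]:
    """Pearson and Spearman correlation of inferred vs true pseudotime."""
    inferred = np.asarray(inferred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if inferred.shape != truth.shape or inferred.ndim != 1:
        raise ValueError("inputs must be 1-D arrays of equal length")
    if inferred.size < 3:
        raise ValueError("need at least three cells")
    if np.ptp(inferred) == 0 or np.ptp(truth) == 0:
        raise ValueError("correlation undefined for a constant input")
    pcc = float(stats.pearsonr(inferred, truth).statistic)
    srcc = float(stats.spearmanr(inferred, truth).statistic)
    return pcc, srcc


def smooth_expression_along_pseudotime(
    expr_gene: np.ndarray, tau: np.ndarray, half_window: int = 10
) -> np.ndarray:
    """Rank-window smoother along the pseudotime ordering.

    Cells are sorted by tau (ties broken by cell index) and each value is
    replaced by the mean over the up-to-``half_window`` preceding and
    following positions plus itself, truncating the window at the ends.
    The result is returned in the original cell order.
    """
    expr_gene = np.asarray(expr_gene, dtype=float)
    tau = np.asarray(tau, dtype=float)
    n = expr_gene.size
    order = np.lexsort((np.arange(n), tau))
    vals = expr_gene[order]
    csum = np.concatenate(([0.0], np.cumsum(vals)))
    out_sorted = np.empty(n)
    for pos in range(n):
        lo = max(0, pos - half_window)
        hi = min(n, pos + half_window + 1)
        out_sorted[pos] = (csum[hi] - csum[lo]) / (hi - lo)
    out = np.empty(n)
    out[order] = out_sorted
    return out
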