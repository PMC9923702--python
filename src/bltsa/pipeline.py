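"""End-to-end pseudotime inference pipeline.

``run_bltsa`` chains the three stages — tip/branching cell identification
from local tangent fits, branch clustering with iterative junction
absorption, and global tangent-space alignment — on top of the
preprocessing/embedding step, and returns pseudotime, branch labels and
per-cell annotations.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from . import alignment, branching, local_geometry, preprocess
from .config import PipelineConfig
from .preprocess import Embedding, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["run_bltsa", "embed"]


def embed(expr: ExpressionMatrix, config: PipelineConfig) -> Embedding:
    """Preprocess an expression matrix and embed it in config.D dimensions.

    With ``use_diffusion`` off the matrix rows are taken to be coordinates
    already (requires exactly D rows) and preprocessing is skipped.
    """
    if not config.use_diffusion:
        if expr.n_genes != config.D:
            raise ValueError(
                f"diffusion bypass requires a {config.D}-row coordinate "
                f"matrix, got {expr.n_genes} rows"
            )
        return Embedding(expr.values.copy(), list(expr.cell_ids))
    mat = preprocess.filter_zero_genes(expr)
    if config.normalize:
        mat = preprocess.size_factor_normalize(mat)
    if config.log1p:
        mat = ExpressionMatrix(
            np.log1p(mat.values), list(mat.gene_ids), list(mat.cell_ids),
            mat.time_labels,
        )
    return preprocess.reduce_dimensions(
        mat, target_D=config.D, pca_predim=config.pca_predim,
        sigma=config.diffusion_sigma,
    )


def _tip_groups(tips: np.ndarray, neighborhoods: list[np.ndarray]) -> int:
    """Number of connected components of tip cells in the kNN graph."""
    tip_idx = np.flatnonzero(tips)
    if tip_idx.size == 0:
        return 0
    pos = {c: a for a, c in enumerate(tip_idx)}
    rows, cols = [], []
    for c in tip_idx:
        for j in neighborhoods[c]:
            if j in pos:
                rows.append(pos[c])
                cols.append(pos[j])
    adj = csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(tip_idx.size, tip_idx.size)
    )
    ncomp, _ = connected_components(adj, directed=False)
    return int(ncomp)


def run_bltsa(
    data: ExpressionMatrix | Embedding,
    config: PipelineConfig | None = None,
) -> tuple[alignment.PseudotimeResult, branching.BranchLabeling, pd.DataFrame]:
    """Run the full pipeline and return (pseudotime, branches, annotations).

    ``data`` may be a raw expression matrix (preprocessed and embedded
    according to the config) or a precomputed low-dimensional embedding.
    """
    config = config or PipelineConfig()
    config.validate()

    if isinstance(data, Embedding):
        emb = data
        time_labels = None
    else:
        time_labels = data.time_labels
        emb = embed(data, config)
    X = emb.coords
    n = emb.n_cells
    if config.k > n:
        raise ValueError(f"k={config.k} exceeds the number of cells ({n})")
    if n <= config.kmax:
        logger.warning(
            "only %d cells but kmax=%d; alignment neighbourhoods will be "
            "clipped to the eligible pools", n, config.kmax,
        )

    # -- step 1: local tangent fits, branching and tip cells ---------------
    neighborhoods = local_geometry.knn_neighborhoods(X, config.k)
    models: list = [
        local_geometry.fit_local_tangent(X, Ni, config.d, cell_index=i)
        for i, Ni in enumerate(neighborhoods)
    ]
    nonlin = np.array(
        [local_geometry.nonlinearity_score(m, config.d) for m in models]
    )
    branching_mask, delta_b = local_geometry.identify_branching_cells(
        nonlin, config.delta_b_percentile
    )
    consistency = np.array(
        [
            local_geometry.consistency_score(
                X, i, neighborhoods[i], norm=config.consistency_norm
            )
            for i in range(n)
        ]
    )
    tips = local_geometry.identify_tip_cells(
        consistency, branching_mask, config.delta_t, k=config.k,
        norm=config.consistency_norm,
    )
    logger.info(
        "step 1: delta_b=%.4g -> %d branching cells, %d tip cells",
        delta_b, int(branching_mask.sum()), int(tips.sum()),
    )

    if config.root is not None:
        try:
            root = emb.cell_ids.index(str(config.root))
        except ValueError:
            raise ValueError(f"root cell {config.root!r} not found") from None
        if not tips[root]:
            logger.warning("requested root %r is not a tip cell", config.root)
    else:
        root = local_geometry.select_root(tips, time_labels, seed=config.seed)
    logger.info("root cell: %s (index %d)", emb.cell_ids[root], root)

    # -- step 2: cluster non-branching cells, absorb branching cells -------
    nonbranching = np.flatnonzero(~branching_mask)
    if config.n_branches is not None:
        candidates = [config.n_branches]
    else:
        lo, hi = config.candidate_branches
        if config.tighten_by_tips:
            T = _tip_groups(tips, neighborhoods)
            if T >= 2:
                lo, hi = max(2, T - 1), T + 1
                logger.info(
                    "found %d tip groups; branch count candidates %d..%d",
                    T, lo, hi,
                )
        candidates = range(lo, hi + 1)
    labeling = branching.cluster_nonbranching(
        X, nonbranching, candidates, seed=config.seed
    )
    logger.info("selected %d branches (silhouettes: %s)",
                labeling.n_branches,
                {k: round(v, 4) for k, v in labeling.silhouettes.items()})

    n_anchor = config.n_anchor or config.k
    labeling = branching.assign_branching_cells(
        X, models, labeling, np.flatnonzero(branching_mask), n_anchor,
        neighborhoods=neighborhoods, d=config.d,
    )
    labeling.root_branch = int(labeling.labels[root])
    logger.info("root branch: %d", labeling.root_branch)

    # -- step 3: redistribute neighbourhoods and align ---------------------
    new_nbhds, chosen_k = branching.redistribute_neighborhoods(
        X, labeling, (config.kmin, config.kmax), d=config.d
    )
    Ws = []
    for i, Ni in enumerate(new_nbhds):
        model = local_geometry.fit_local_tangent(X, Ni, config.d, cell_index=i)
        Ws.append(alignment.local_alignment_matrix(model.local_coords))
    B = alignment.assemble_global_matrix(new_nbhds, Ws, n)
    result = alignment.solve_pseudotime(
        B, root, d=config.d, eig_raw=config.eig_raw, seed=config.seed
    )
    result.chosen_k = chosen_k

    category = np.where(
        branching_mask, "branching", np.where(tips, "tip", "intermediate")
    )
    annotations = pd.DataFrame(
        {
            "cell_id": emb.cell_ids,
            "nonlinearity": nonlin,
            "consistency": consistency,
            "category": category,
            "is_root": np.arange(n) == root,
        }
    )
    return result, labeling, annotations
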