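"""Reading and writing expression matrices and pipeline artifacts.

Dense matrices are genes-as-rows CSV/TSV with the gene identifier in the
first column and cell identifiers in the header.  Sparse matrices use
MatrixMarket triplets with ``genes.tsv`` / ``barcodes.tsv`` sidecar files
next to the ``.mtx``.  All writes go through a temp-file rename so readers
never see partial output.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .preprocess import Embedding, ExpressionMatrix

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_time_labels",
    "write_embedding",
    "write_pseudotime",
    "write_branches",
    "write_annotations",
]


def _atomic_write(path: Path, writer) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_matrix(
    path: str | Path, metadata: str | Path | None = None
) -> ExpressionMatrix:
    """Read a genes x cells matrix from .tsv/.csv/.mtx (with sidecars)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tsv", ".csv", ".txt"):
        sep = "," if suffix == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        values = df.to_numpy(dtype=float)
        gene_ids = [str(g) for g in df.index]
        cell_ids = [str(c) for c in df.columns]
    elif suffix == ".mtx":
        mat = spio.mmread(path)
        genes_file = path.parent / "genes.tsv"
        barcodes_file = path.parent / "barcodes.tsv"
        for f in (genes_file, barcodes_file):
            if not f.exists():
                raise FileNotFoundError(f"missing sidecar file {f}")
        gene_ids = genes_file.read_text().split()
        cell_ids = barcodes_file.read_text().split()
        values = np.asarray(mat.todense(), dtype=float)
        if values.shape != (len(gene_ids), len(cell_ids)):
            raise ValueError(
                f"matrix {path.name} is {values.shape} but sidecars give "
                f"{len(gene_ids)} genes x {len(cell_ids)} cells"
            )
    else:
        raise ValueError(f"unsupported matrix format {suffix!r}")

    time_labels = None
    if metadata is not None:
        time_labels = read_time_labels(metadata, cell_ids)
    return ExpressionMatrix(values, gene_ids, cell_ids, time_labels)


def read_time_labels(path: str | Path, cell_ids: list[str]) -> np.ndarray:
    """Read per-cell time labels from a metadata TSV with a ``time`` column."""
    meta = pd.read_csv(path, sep="\t", index_col=0)
    if "time" not in meta.columns:
        raise ValueError(f"metadata file {path} has no 'time' column")
    missing = [c for c in cell_ids if c not in meta.index]
    if missing:
        raise ValueError(
            f"metadata file {path} is missing {len(missing)} cells "
            f"(first: {missing[:3]})"
        )
    return meta.loc[cell_ids, "time"].to_numpy()


def write_matrix(path: str | Path, expr: ExpressionMatrix) -> None:
    """Write a matrix as dense TSV/CSV or MatrixMarket + sidecars."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tsv", ".csv", ".txt"):
        sep = "," if suffix == ".csv" else "\t"
        df = pd.DataFrame(expr.values, index=expr.gene_ids,
                          columns=expr.cell_ids)
        _atomic_write(path, lambda tmp: df.to_csv(tmp, sep=sep))
    elif suffix == ".mtx":
        coo = sparse.coo_matrix(expr.values)

        def _mm(tmp: str) -> None:
            # pass a handle: mmwrite would append '.mtx' to the temp name
            with open(tmp, "wb") as fh:
                spio.mmwrite(fh, coo)

        _atomic_write(path, _mm)
        _atomic_write(
            path.parent / "genes.tsv",
            lambda tmp: Path(tmp).write_text("\n".join(expr.gene_ids) + "\n"),
        )
        _atomic_write(
            path.parent / "barcodes.tsv",
            lambda tmp: Path(tmp).write_text("\n".join(expr.cell_ids) + "\n"),
        )
    else:
        raise ValueError(f"unsupported matrix format {suffix!r}")


def _write_df(path: str | Path, df: pd.DataFrame) -> None:
    _atomic_write(Path(path), lambda tmp: df.to_csv(tmp, sep="\t", index=False))


def write_embedding(path: str | Path, emb: Embedding) -> None:
    cols = {"cell_id": emb.cell_ids}
    for j in range(emb.D):
        cols[f"dim{j + 1}"] = emb.coords[j]
    _write_df(path, pd.DataFrame(cols))


def write_pseudotime(
    path: str | Path, cell_ids: list[str], tau: np.ndarray,
    branch: np.ndarray, root: int, chosen_k: np.ndarray | None = None,
) -> None:
    n = len(cell_ids)
    df = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "tau": tau,
            "branch": branch,
            "is_root": np.arange(n) == root,
            "chosen_k": chosen_k if chosen_k is not None else [pd.NA] * n,
        }
    )
    _write_df(path, df)


def write_branches(
    path: str | Path, cell_ids: list[str], labeling,
) -> None:
    n = len(cell_ids)
    rank = np.full(n, -1)
    for r, (cell, _) in enumerate(labeling.assignment_order):
        rank[cell] = r
    df = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "branch": labeling.labels,
            "is_root_branch": labeling.labels == labeling.root_branch,
            "assignment_rank": [r if r >= 0 else "NA" for r in rank],
        }
    )
    _write_df(path, df)


def write_annotations(path: str | Path, annotations: pd.DataFrame) -> None:
    _write_df(path, annotations)
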