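"""Reading and writing counts, metadata and result tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

__all__ = [
    "read_counts",
    "write_counts_mtx",
    "read_metadata",
    "write_table",
]

FLOAT_FORMAT = "%.17g"


def read_counts(
    path, features=None, barcodes=None
) -> tuple[np.ndarray, list[str], list[str]]:
    """Load a gene×cell count matrix.

    ``path`` is either a Matrix Market ``.mtx`` file (with optional
    ``features``/``barcodes`` TSVs, first column used as ids) or a dense
    CSV/TSV whose first column holds gene ids and whose header holds
    cell ids.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        mat = scipy_io.mmread(path)
        counts = np.asarray(mat.todense() if sparse.issparse(mat) else mat)
        m, n = counts.shape
        gene_ids = _read_id_column(features, m, "gene")
        cell_ids = _read_id_column(barcodes, n, "cell")
    else:
        sep = "\t" if path.suffix in (".tsv", ".txt") else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        counts = df.to_numpy()
        gene_ids = [str(g) for g in df.index]
        cell_ids = [str(c) for c in df.columns]
    if counts.ndim != 2:
        raise ValueError("counts must be a 2-D matrix")
    if len(gene_ids) != counts.shape[0] or len(cell_ids) != counts.shape[1]:
        raise ValueError("id files do not match matrix dimensions")
    if np.any(counts < 0):
        raise ValueError("negative entries in count matrix")
    return counts.astype(np.int64), gene_ids, cell_ids


def _read_id_column(path, expected: int, what: str) -> list[str]:
    if path is None:
        return [f"{what}{i}" for i in range(expected)]
    ids = pd.read_csv(path, sep="\t", header=None).iloc[:, 0].astype(str).tolist()
    if len(ids) != expected:
        raise ValueError(f"{what} id file has {len(ids)} rows, expected {expected}")
    return ids


def write_counts_mtx(outdir, counts: np.ndarray, gene_ids, cell_ids) -> None:
    """Write counts as ``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy_io.mmwrite(outdir / "matrix.mtx", sparse.coo_matrix(counts))
    pd.Series(gene_ids).to_csv(outdir / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(cell_ids).to_csv(outdir / "barcodes.tsv", sep="\t", header=False, index=False)


def read_metadata(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    meta = pd.read_csv(path, sep=sep)
    return meta


def write_table(df: pd.DataFrame, path) -> None:
    """TSV with fixed column order and 17 significant digits."""
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
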