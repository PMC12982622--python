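"""Summary statistics: the sufficient reduction for per-gene LMM fitting.

The products ``XᵀX``, ``XᵀYᵀ``, ``ZᵀX``, ``ZᵀYᵀ``, ``ZᵀZ`` plus the
per-gene squared norms ``yᵀy`` and the cell count ``n`` are sufficient
to fit the mixed model for every gene; once computed, no operation
downstream touches cell-level data.  They are additive over disjoint
cell chunks, so they can be accumulated streaming with only one chunk
of the expression matrix in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "SummaryStats",
    "log1p_transform",
    "compute_sstats",
    "merge_sstats",
    "save_sstats",
    "load_sstats",
]

DEFAULT_CHUNK_SIZE = 10_000


@dataclass
class SummaryStats:
    """Sufficient statistics shared by all genes.

    Y is gene×cell; ``XY[:, g] = Xᵀ y_g`` and ``ZY[:, g] = Zᵀ y_g``.
    """

    XX: np.ndarray          # p×p
    XY: np.ndarray          # p×m
    ZX: np.ndarray          # q×p
    ZY: np.ndarray          # q×m
    ZZ: np.ndarray          # q×q
    Ynorm: np.ndarray       # m
    n: int
    partition: tuple[int, ...]
    gene_ids: list[str]

    @property
    def p(self) -> int:
        return self.XX.shape[0]

    @property
    def q(self) -> int:
        return self.ZZ.shape[0]

    @property
    def m(self) -> int:
        return len(self.gene_ids)

    def validate(self) -> None:
        p, q, m = self.p, self.q, self.m
        assert self.XY.shape == (p, m)
        assert self.ZX.shape == (q, p)
        assert self.ZY.shape == (q, m)
        assert self.Ynorm.shape == (m,)
        assert sum(self.partition) == q
        if self.n < p:
            raise ValueError("fewer cells than fixed effects")
        if np.any(self.Ynorm < -1e-9):
            raise ValueError("negative gene squared norm")


def log1p_transform(counts: np.ndarray) -> np.ndarray:
    """Elementwise ``y = ln(1 + count)``; rejects negative counts."""
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    return np.log1p(counts.astype(float, copy=False))


def _iter_chunks(Y: np.ndarray, chunk_size: int) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    n = Y.shape[1]
    for start in range(0, n, chunk_size):
        idx = np.arange(start, min(start + chunk_size, n))
        yield Y[:, idx], idx


def compute_sstats(
    X: np.ndarray,
    Z: np.ndarray,
    Y: np.ndarray | Iterable[tuple[np.ndarray, np.ndarray]],
    gene_ids: Sequence[str] | None = None,
    partition: tuple[int, ...] | None = None,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
) -> SummaryStats:
    """Accumulate :class:`SummaryStats` over cell chunks.

    ``Y`` may be a dense gene×cell array (chunked internally over cells)
    or an iterator of ``(Y_chunk, cell_index)`` pairs whose indices
    align chunk columns with rows of X and Z.  Every cell must be
    covered exactly once.
    """
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    n, p = X.shape
    q = Z.shape[1]
    if Z.shape[0] != n:
        raise ValueError("X and Z disagree on the number of cells")
    if partition is None:
        partition = (q,) if q else ()
    if isinstance(Y, np.ndarray):
        m = Y.shape[0]
        chunks: Iterable = _iter_chunks(Y, chunk_size)
    else:
        m = None
        chunks = Y

    XY = ZY = Ynorm = None
    seen = np.zeros(n, dtype=bool)
    for Y_chunk, idx in chunks:
        Y_chunk = np.asarray(Y_chunk, dtype=float)
        idx = np.asarray(idx)
        if Y_chunk.shape[1] != idx.size:
            raise ValueError("chunk misaligned: column count != index count")
        if idx.size and (idx.min() < 0 or idx.max() >= n or seen[idx].any()):
            raise ValueError("chunk misaligned: cell indices invalid or repeated")
        seen[idx] = True
        if XY is None:
            m = Y_chunk.shape[0]
            XY = np.zeros((p, m))
            ZY = np.zeros((q, m))
            Ynorm = np.zeros(m)
        elif Y_chunk.shape[0] != m:
            raise ValueError("chunk misaligned: gene count changed")
        XY += X[idx].T @ Y_chunk.T
        ZY += Z[idx].T @ Y_chunk.T
        Ynorm += np.einsum("gc,gc->g", Y_chunk, Y_chunk)
    if XY is None or not seen.all():
        raise ValueError("cell chunks do not cover all cells")
    if gene_ids is None:
        gene_ids = [f"gene{i}" for i in range(m)]
    ss = SummaryStats(
        XX=X.T @ X,
        XY=XY,
        ZX=Z.T @ X,
        ZY=ZY,
        ZZ=Z.T @ Z,
        Ynorm=Ynorm,
        n=n,
        partition=tuple(partition),
        gene_ids=list(gene_ids),
    )
    ss.validate()
    return ss


def merge_sstats(a: SummaryStats, b: SummaryStats) -> SummaryStats:
    """Sum statistics accumulated on disjoint cell sets."""
    if a.gene_ids != b.gene_ids:
        raise ValueError("gene_ids mismatch")
    if a.partition != b.partition:
        raise ValueError("partition mismatch")
    for f in ("XX", "XY", "ZX", "ZY", "ZZ"):
        if getattr(a, f).shape != getattr(b, f).shape:
            raise ValueError(f"shape mismatch in {f}")
    return replace(
        a,
        XX=a.XX + b.XX,
        XY=a.XY + b.XY,
        ZX=a.ZX + b.ZX,
        ZY=a.ZY + b.ZY,
        ZZ=a.ZZ + b.ZZ,
        Ynorm=a.Ynorm + b.Ynorm,
        n=a.n + b.n,
    )


def save_sstats(ss: SummaryStats, path) -> None:
    """Write the statistics to a single HDF5 archive."""
    import h5py

    with h5py.File(path, "w") as f:
        for name in ("XX", "XY", "ZX", "ZY", "ZZ", "Ynorm"):
            f.create_dataset(name, data=getattr(ss, name))
        f.create_dataset("n", data=ss.n)
        f.create_dataset("partition", data=np.asarray(ss.partition, dtype=np.int64))
        f.create_dataset(
            "gene_ids", data=np.asarray(ss.gene_ids, dtype=h5py.string_dtype())
        )


def load_sstats(path) -> SummaryStats:
    import h5py

    with h5py.File(path, "r") as f:
        ss = SummaryStats(
            XX=f["XX"][()],
            XY=f["XY"][()],
            ZX=f["ZX"][()],
            ZY=f["ZY"][()],
            ZZ=f["ZZ"][()],
            Ynorm=f["Ynorm"][()],
            n=int(f["n"][()]),
            partition=tuple(int(v) for v in f["partition"][()]),
            gene_ids=[g.decode() if isinstance(g, bytes) else str(g) for g in f["gene_ids"][()]],
        )
    ss.validate()
    return ss
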