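"""Design-matrix construction for cell-level mixed models.

Builds the fixed-effect matrix ``X`` (one row per cell) and the
random-effect matrix ``Z`` (a horizontal stack of one-hot indicator
blocks, one block per grouping factor) from a cell metadata table and a
:class:`ModelSpec`.

Conventions
-----------
* Categorical terms are treatment-coded; the reference level is the
  lexicographically first level.
* An interaction term ``a:b`` emits, for every level of ``a``, one dummy
  column per non-reference level of ``b`` — so with a two-level ``b``
  each interaction coefficient is the ``b`` effect *within* that level
  of ``a``.
* ``log_libsize`` is recognised as a derived numeric column: the natural
  log of ``library_size`` (computed on the fly when absent).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ModelSpec",
    "DesignMatrices",
    "parse_fixed_formula",
    "build_fixed_matrix",
    "build_random_matrix",
    "build_designs",
    "check_estimability",
    "reduce_random_effects",
]

INTERCEPT_NAME = "(Intercept)"

_NUMERIC_KINDS = "iuf"


class DesignError(ValueError):
    """Raised for malformed model specifications or metadata."""


@dataclass
class ModelSpec:
    """Ordered fixed-effect terms plus random grouping factors.

    ``fixed_terms`` entries are term strings: ``"1"`` (intercept), a
    metadata column name, or ``"a:b"`` for an interaction of two
    categoricals.  ``random_factors`` are metadata column names; each
    contributes one variance component.
    """

    fixed_terms: list[str] = field(default_factory=lambda: ["1"])
    random_factors: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if sum(t.strip() == "1" for t in self.fixed_terms) > 1:
            raise DesignError("at most one intercept term is allowed")

    @property
    def n_components(self) -> int:
        return len(self.random_factors)


@dataclass
class DesignMatrices:
    """Fixed and random design matrices with column names and partition."""

    X: np.ndarray
    Z: np.ndarray
    x_names: list[str]
    z_names: list[str]
    partition: tuple[int, ...]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return self.Z.shape[1]


def parse_fixed_formula(formula: str, *, intercept: bool = True) -> list[str]:
    """Parse ``"log_libsize + cell_type + cell_type:condition"`` into terms.

    A leading ``0`` or ``-1`` suppresses the implicit intercept.
    """
    terms: list[str] = []
    add_intercept = intercept
    for raw in re.split(r"\+", formula):
        term = raw.strip()
        if not term:
            continue
        if term in ("0", "-1"):
            add_intercept = False
            continue
        if term == "1":
            add_intercept = True
            continue
        terms.append(term)
    if add_intercept:
        terms.insert(0, "1")
    return terms


def _column(meta: pd.DataFrame, name: str) -> pd.Series:
    if name in meta.columns:
        return meta[name]
    # derived natural-log library size
    if name in ("log_libsize", "log_library_size") and "library_size" in meta.columns:
        libsize = meta["library_size"].to_numpy(dtype=float)
        if np.any(libsize <= 0):
            raise DesignError("library_size must be positive to take logs")
        return pd.Series(np.log(libsize), index=meta.index, name=name)
    raise DesignError(f"metadata column not found: {name!r}")


def _is_numeric(s: pd.Series) -> bool:
    return s.dtype.kind in _NUMERIC_KINDS and s.dtype.kind != "b"


def _levels(s: pd.Series) -> list:
    if s.isna().any():
        raise DesignError(f"missing values in column {s.name!r}")
    return sorted(pd.unique(s).tolist())


def _dummies(s: pd.Series, levels: list) -> np.ndarray:
    arr = s.to_numpy()
    return np.column_stack([(arr == lv).astype(float) for lv in levels])


def build_fixed_matrix(
    meta: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, list[str]]:
    """Build the fixed-effect matrix ``X`` with column names.

    Terms appear in declared order.  Categorical terms are
    treatment-coded against the lexicographically first level; an
    ``a:b`` interaction emits one ``b``-dummy per level of ``a``.
    """
    n = len(meta)
    if n < 2:
        raise DesignError("need at least 2 cells")
    cols: list[np.ndarray] = []
    names: list[str] = []
    for term in spec.fixed_terms:
        term = term.strip()
        if term == "1":
            cols.append(np.ones(n))
            names.append(INTERCEPT_NAME)
        elif ":" in term:
            a_name, b_name = (t.strip() for t in term.split(":", 1))
            a, b = _column(meta, a_name), _column(meta, b_name)
            a_levels, b_levels = _levels(a), _levels(b)
            for la in a_levels:
                in_a = (a.to_numpy() == la).astype(float)
                for lb in b_levels[1:]:
                    cols.append(in_a * (b.to_numpy() == lb))
                    names.append(f"{a_name}[{la}]:{b_name}[{lb}]")
        else:
            s = _column(meta, term)
            if _is_numeric(s):
                vals = s.to_numpy(dtype=float)
                if np.ptp(vals) == 0:
                    warnings.warn(
                        f"numeric covariate {term!r} is constant", UserWarning
                    )
                cols.append(vals)
                names.append(term)
            else:
                levels = _levels(s)
                dm = _dummies(s, levels[1:])
                for j, lv in enumerate(levels[1:]):
                    cols.append(dm[:, j])
                    names.append(f"{term}[{lv}]")
    if not cols:
        raise DesignError("empty fixed-effect specification")
    X = np.column_stack(cols)
    return X, names


def build_random_matrix(
    meta: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, list[str], tuple[int, ...]]:
    """Build ``Z = [Z1, ..., ZK]`` with one one-hot block per factor."""
    n = len(meta)
    blocks: list[np.ndarray] = []
    names: list[str] = []
    partition: list[int] = []
    for factor in spec.random_factors:
        s = _column(meta, factor)
        levels = _levels(s)
        if len(levels) < 2:
            msg = f"random factor {factor!r} has a single level"
            if spec.n_components == 1:
                raise DesignError(msg + "; model unidentifiable")
            warnings.warn(msg, UserWarning)
        blocks.append(_dummies(s, levels))
        names.extend(f"{factor}[{lv}]" for lv in levels)
        partition.append(len(levels))
    Z = np.column_stack(blocks) if blocks else np.empty((n, 0))
    return Z, names, tuple(partition)


def build_designs(meta: pd.DataFrame, spec: ModelSpec) -> DesignMatrices:
    """Build, validate and bundle X and Z for a metadata table."""
    X, x_names = build_fixed_matrix(meta, spec)
    check_estimability(X, names=x_names)
    Z, z_names, partition = build_random_matrix(meta, spec)
    return DesignMatrices(X=X, Z=Z, x_names=x_names, z_names=z_names, partition=partition)


def check_estimability(
    X: np.ndarray, names: list[str] | None = None
) -> dict:
    """Check that ``X`` has full column rank.

    Returns ``{"rank": r, "p": p, "full_rank": bool}``; raises
    :class:`DesignError` naming candidate collinear columns otherwise.
    """
    p = X.shape[1]
    rank = int(np.linalg.matrix_rank(X.T @ X))
    if rank < p:
        # QR with pivoting: trailing pivots index the dependent columns
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        bad = sorted(piv[rank:].tolist())
        labels = [names[j] if names else str(j) for j in bad]
        raise DesignError(
            f"design matrix is rank deficient (rank {rank} < {p}); "
            f"collinear columns: {labels}"
        )
    return {"rank": rank, "p": p, "full_rank": True}


def reduce_random_effects(Z: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Replace ``Z`` by ``Z̃`` with rank(Z) columns and ``Z̃Z̃ᵀ = ZZᵀ``.

    Uses the eigendecomposition of the q×q Gram matrix ``ZᵀZ``:
    ``Z̃ = Z V_r`` where ``V_r`` spans the nonzero eigenspace.  Fits
    using ``Z̃`` (as a single variance component) are equivalent to fits
    using ``Z`` because the likelihood depends on Z only through ``ZZᵀ``.
    """
    if Z.size == 0 or not np.any(Z):
        raise DesignError("Z is all zeros; nothing to reduce")
    A = Z.T @ Z
    evals, evecs = np.linalg.eigh(A)
    keep = evals > tol * evals.max()
    return Z @ evecs[:, keep]
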