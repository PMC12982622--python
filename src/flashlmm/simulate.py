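"""Reference-based negative-binomial simulator of multi-subject,
multi-cell-type scRNA-seq counts, plus ROC/QQ evaluation utilities.

Per-gene NB parameters come from a reference count matrix: the mean is
the per-gene sample mean and the dispersion (size ``r``, with
``Var = μ + μ²/r``) is the method-of-moments estimate
``r = μ̂²/(s² − μ̂)`` when ``s² > μ̂``, else capped (Poisson regime).  A
synthetic reference generator removes any dependence on downloaded
data.

A designated subset of genes is differentially expressed in exactly one
target cell type: treated cells of that type have their NB mean
multiplied by ``exp(logfc)``.  Per-gene × per-subject log-normal random
effects induce intra-subject correlation; per-cell log-normal library
factors mimic depth variation.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NBParams",
    "SimDesign",
    "SimDataset",
    "mme_dispersion",
    "synth_reference",
    "simulate_dataset",
    "roc_auc",
    "qq_uniform",
]

SIZE_CAP = 1e8
SIZE_FLOOR = 1e-2


@dataclass
class NBParams:
    gene_ids: list[str]
    mu: np.ndarray
    size: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.size = np.asarray(self.size, dtype=float)
        if np.any(self.mu < 0) or np.any(self.size <= 0):
            raise ValueError("mu must be >= 0 and size > 0")


@dataclass
class SimDesign:
    """Knobs of the multi-subject multi-cell-type simulation."""

    n_cells: int = 20_000
    n_subjects: int = 25
    n_celltypes: int = 12
    n_conditions: int = 2
    n_genes: int = 6_000
    n_de: int = 480
    logfc_range: tuple[float, float] = (0.5, 1.0)
    sigma_subject: float = 0.25
    libsize_lognormal_sd: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cells, self.n_subjects, self.n_celltypes, self.n_conditions, self.n_genes) < 1:
            raise ValueError("design cardinalities must be positive")
        if self.n_de > self.n_genes:
            raise ValueError("n_de cannot exceed n_genes")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["logfc_range"] = list(self.logfc_range)
        return d


@dataclass
class SimDataset:
    counts: np.ndarray              # gene×cell, integer
    metadata: pd.DataFrame          # cell_id, subject, cell_type, condition, library_size
    truth: pd.DataFrame             # gene_id, target_cell_type, logfc
    gene_ids: list[str]
    design: SimDesign


def mme_dispersion(ref_counts: np.ndarray, gene_ids=None) -> NBParams:
    """Per-gene NB mean and method-of-moments dispersion from a reference.

    ``r = μ̂² / (s² − μ̂)`` where s² is the unbiased sample variance;
    when s² ≤ μ̂ the gene is effectively Poisson and r is set to the cap.
    """
    ref = np.asarray(ref_counts, dtype=float)
    if ref.ndim != 2 or ref.shape[1] < 2:
        raise ValueError("need a gene×cell matrix with at least 2 cells")
    mu = ref.mean(axis=1)
    s2 = ref.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        size = np.where(s2 > mu, mu**2 / (s2 - mu), SIZE_CAP)
    size = np.clip(np.nan_to_num(size, nan=SIZE_CAP, posinf=SIZE_CAP), SIZE_FLOOR, SIZE_CAP)
    if gene_ids is None:
        gene_ids = [f"gene{i}" for i in range(ref.shape[0])]
    return NBParams(gene_ids=list(gene_ids), mu=mu, size=size)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size) -> np.ndarray:
    """NB draws parameterised by mean and size r; p = r/(r + mean)."""
    mean = np.asarray(mean, dtype=float)
    r = np.broadcast_to(np.asarray(size, dtype=float), mean.shape)
    p = r / (r + mean)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if np.any(pos):
        out[pos] = rng.negative_binomial(r[pos], p[pos])
    return out


def synth_reference(
    m_genes: int,
    n_cells: int,
    seed: int = 0,
    mean_range_log10: tuple[float, float] = (-2.0, 2.0),
    size_range_log10: tuple[float, float] = (-1.0, 1.5),
    return_params: bool = False,
):
    """Synthetic NB reference: per-gene (μ, r) log-uniform, i.i.d. cells."""
    if m_genes < 1 or n_cells < 1:
        raise ValueError("m_genes and n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    mu = 10.0 ** rng.uniform(*mean_range_log10, size=m_genes)
    r = 10.0 ** rng.uniform(*size_range_log10, size=m_genes)
    counts = np.empty((m_genes, n_cells), dtype=np.int64)
    for g in range(m_genes):
        counts[g] = _nb_draw(rng, np.full(n_cells, mu[g]), r[g])
    if return_params:
        params = NBParams([f"gene{i}" for i in range(m_genes)], mu, r)
        return counts, params
    return counts


def simulate_dataset(nb: NBParams, design: SimDesign) -> SimDataset:
    """Draw a multi-subject multi-cell-type NB dataset with known DE truth.

    Gene g in cell i is NB with mean
    ``μ_g · L_i · exp(u_{g,s(i)} + β_g·1[t(i)=treated and c(i)=target_g])``
    and size r_g, where L_i is a per-cell log-normal library factor and
    u_{g,s} ~ N(0, sigma_subject²) per gene × subject.  Seeds are split
    deterministically across assignment/effects/counts streams.
    """
    usable = np.flatnonzero(nb.mu > 0)
    if usable.size < design.n_genes:
        raise ValueError("reference has too few expressed genes")
    ss = np.random.SeedSequence(design.seed)
    rng_assign, rng_effects, rng_counts = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )

    picked = rng_assign.choice(usable, size=design.n_genes, replace=False)
    mu = nb.mu[picked]
    size = nb.size[picked]
    gene_ids = [nb.gene_ids[i] for i in picked]

    n = design.n_cells
    subject = rng_assign.integers(design.n_subjects, size=n)
    celltype = rng_assign.integers(design.n_celltypes, size=n)
    condition = rng_assign.integers(design.n_conditions, size=n)
    lib = np.exp(rng_assign.normal(0.0, design.libsize_lognormal_sd, size=n))

    de_idx = rng_effects.choice(design.n_genes, size=design.n_de, replace=False)
    target_ct = rng_effects.integers(design.n_celltypes, size=design.n_de)
    logfc = rng_effects.uniform(*design.logfc_range, size=design.n_de)
    logfc *= rng_effects.choice([-1.0, 1.0], size=design.n_de)
    u = rng_effects.normal(0.0, design.sigma_subject, size=(design.n_genes, design.n_subjects))

    beta = np.zeros(design.n_genes)
    target_of = np.full(design.n_genes, -1)
    beta[de_idx] = logfc
    target_of[de_idx] = target_ct
    treated = condition == design.n_conditions - 1

    counts = np.empty((design.n_genes, n), dtype=np.int32)
    for g in range(design.n_genes):
        log_mean = np.log(mu[g] * lib) + u[g, subject]
        if beta[g] != 0.0:
            log_mean = log_mean + beta[g] * ((celltype == target_of[g]) & treated)
        counts[g] = _nb_draw(rng_counts, np.exp(log_mean), size[g])

    meta = pd.DataFrame(
        {
            "cell_id": [f"cell{i}" for i in range(n)],
            "subject": [f"s{j:02d}" for j in subject],
            "cell_type": [f"ct{j:02d}" for j in celltype],
            "condition": np.where(treated, "treated", "control"),
            "library_size": counts.sum(axis=0),
        }
    )
    truth = pd.DataFrame(
        {
            "gene_id": [gene_ids[i] for i in de_idx],
            "target_cell_type": [f"ct{j:02d}" for j in target_ct],
            "logfc": logfc,
        }
    ).sort_values("gene_id", kind="mergesort", ignore_index=True)
    return SimDataset(counts=counts, metadata=meta, truth=truth, gene_ids=gene_ids, design=design)


def roc_auc(scores, truth_labels) -> float:
    """AUC as the Mann–Whitney probability of correct ranking (ties averaged)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(truth_labels).astype(bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have the same length")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative label")
    ranks = stats.rankdata(s)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def qq_uniform(pvals, n_points: int | None = None) -> pd.DataFrame:
    """Observed vs expected −log10 p with pointwise 95% beta band.

    The i-th order statistic of m Uniform(0,1) draws is Beta(i, m−i+1);
    band columns bracket its 2.5%/97.5% quantiles.
    """
    p = np.sort(np.asarray(pvals, dtype=float))
    m = p.size
    if m == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    i = np.arange(1, m + 1)
    expected = i / (m + 1.0)
    lower = stats.beta.ppf(0.025, i, m - i + 1)
    upper = stats.beta.ppf(0.975, i, m - i + 1)
    df = pd.DataFrame(
        {
            "expected": expected,
            "observed": p,
            "band_lower": lower,
            "band_upper": upper,
        }
    )
    tiny = 1e-300
    for col in ("expected", "observed", "band_lower", "band_upper"):
        df[f"neglog10_{col}"] = -np.log10(np.clip(df[col], tiny, None))
    if n_points is not None and n_points < m:
        keep = np.unique(np.linspace(0, m - 1, n_points).astype(int))
        df = df.iloc[keep].reset_index(drop=True)
    return df
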