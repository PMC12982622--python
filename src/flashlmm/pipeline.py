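"""End-to-end differential-expression pipeline and the simulation-study driver.

``run_de`` composes: read → QC filter → log1p → design matrices →
summary statistics → per-gene fits → t-tests → BH adjustment → TSV
output.  ``run_simulation_study`` wraps the simulator around the same
model-fitting path and reports AUC, type-I error and QQ calibration.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .designs import ModelSpec, build_designs, parse_fixed_formula
from .infer import Contrast, add_fdr, t_test, RESULT_COLUMNS
from .lmmfit import FitterConfig, fit_all, fits_to_frame
from .simulate import SimDataset, SimDesign, qq_uniform, roc_auc, simulate_dataset, synth_reference
from .sstats import compute_sstats, log1p_transform

logger = logging.getLogger("flashlmm")

__all__ = [
    "QCThresholds",
    "RunConfig",
    "filter_qc",
    "run_de",
    "run_simulation_study",
    "de_analysis",
]


@dataclass
class QCThresholds:
    """Cell/gene filters; defaults mirror a typical droplet QC recipe.

    Cells are filtered first (detected features, library-size window,
    small cell types), then genes (cells expressing, counts-per-cell
    ratio computed after cell filtering).
    """

    min_features_per_cell: int = 0
    libsize_range: tuple[float, float] = (1.0, np.inf)
    min_cells_per_celltype: int = 0
    min_cells_per_gene: int = 0
    min_cpc: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.libsize_range
        if not lo < hi:
            raise ValueError("libsize_range must satisfy low < high")
        if self.min_cpc < 0:
            raise ValueError("min_cpc must be >= 0")

    @classmethod
    def kidney_defaults(cls) -> "QCThresholds":
        return cls(
            min_features_per_cell=100,
            libsize_range=(512.0, 65_536.0),
            min_cells_per_celltype=20,
            min_cells_per_gene=16,
            min_cpc=0.005,
        )


def filter_qc(
    counts: np.ndarray,
    meta: pd.DataFrame,
    thr: QCThresholds,
    gene_ids: list[str] | None = None,
):
    """Apply cell filters then gene filters; return data + report.

    Each removed cell/gene is attributed to the first rule that
    triggers, so the report counts are conserved.
    """
    n_genes, n_cells = counts.shape
    if gene_ids is None:
        gene_ids = [f"gene{i}" for i in range(n_genes)]
    libsize = counts.sum(axis=0)
    features = (counts > 0).sum(axis=0)

    cell_rule = np.zeros(n_cells, dtype=int)  # 0 keep, 1 features, 2 libsize, 3 celltype
    cell_rule[(features < thr.min_features_per_cell) & (cell_rule == 0)] = 1
    lo, hi = thr.libsize_range
    cell_rule[((libsize < lo) | (libsize > hi)) & (cell_rule == 0)] = 2
    if thr.min_cells_per_celltype > 0 and "cell_type" in meta.columns:
        provisional = meta.loc[cell_rule == 0, "cell_type"]
        small = provisional.value_counts()
        small_types = set(small[small < thr.min_cells_per_celltype].index)
        in_small = meta["cell_type"].isin(small_types).to_numpy()
        cell_rule[in_small & (cell_rule == 0)] = 3
    keep_cells = cell_rule == 0
    if not keep_cells.any():
        raise ValueError("QC removed every cell")

    counts_c = counts[:, keep_cells]
    meta_c = meta.loc[keep_cells].reset_index(drop=True)
    n_kept_cells = counts_c.shape[1]

    cells_expressing = (counts_c > 0).sum(axis=1)
    cpc = counts_c.sum(axis=1) / n_kept_cells
    gene_rule = np.zeros(n_genes, dtype=int)  # 0 keep, 1 min_cells, 2 cpc
    gene_rule[(cells_expressing < thr.min_cells_per_gene) & (gene_rule == 0)] = 1
    gene_rule[(cpc < thr.min_cpc) & (gene_rule == 0)] = 2
    keep_genes = gene_rule == 0
    if not keep_genes.any():
        raise ValueError("QC removed every gene")

    report = {
        "cells_in": int(n_cells),
        "cells_kept": int(keep_cells.sum()),
        "cells_removed_features": int((cell_rule == 1).sum()),
        "cells_removed_libsize": int((cell_rule == 2).sum()),
        "cells_removed_celltype": int((cell_rule == 3).sum()),
        "genes_in": int(n_genes),
        "genes_kept": int(keep_genes.sum()),
        "genes_removed_min_cells": int((gene_rule == 1).sum()),
        "genes_removed_cpc": int((gene_rule == 2).sum()),
    }
    kept_gene_ids = [g for g, k in zip(gene_ids, keep_genes) if k]
    return counts_c[keep_genes], meta_c, kept_gene_ids, report


@dataclass
class RunConfig:
    counts_path: str
    meta_path: str
    out_dir: str
    features_path: str | None = None
    barcodes_path: str | None = None
    fixed: str = "log_libsize + cell_type + cell_type:condition"
    random: str = "subject"
    fitter: FitterConfig = field(default_factory=FitterConfig)
    qc: QCThresholds = field(default_factory=QCThresholds)
    tested_terms: list[str] | None = None  # None -> all interaction columns
    chunk_size: int = 10_000
    seed: int = 0


def _model_spec(fixed: str, random: str) -> ModelSpec:
    random_factors = [t.strip() for t in random.split("+") if t.strip()] if random else []
    return ModelSpec(fixed_terms=parse_fixed_formula(fixed), random_factors=random_factors)


def de_analysis(
    counts: np.ndarray,
    meta: pd.DataFrame,
    gene_ids: list[str],
    spec: ModelSpec,
    fitter: FitterConfig | None = None,
    tested_terms: list[str] | None = None,
    chunk_size: int = 10_000,
):
    """Fit the LMM to log1p counts and t-test the requested coefficients.

    Returns ``(fits, results, designs)``; ``results`` has one row per
    gene per tested term with BH FDR per term.
    """
    fitter = fitter or FitterConfig()
    meta = meta.copy()
    meta["library_size"] = counts.sum(axis=0)
    dm = build_designs(meta, spec)
    Y = log1p_transform(counts)
    ss = compute_sstats(
        dm.X, dm.Z, Y, gene_ids=gene_ids, partition=dm.partition, chunk_size=chunk_size
    )
    fits = fit_all(ss, fitter)
    if tested_terms is None:
        tested = [name for name in dm.x_names if ":" in name]
    else:
        tested = [name for name in dm.x_names if any(t in name for t in tested_terms)]
    rows = []
    for name in tested:
        j = dm.x_names.index(name)
        c = Contrast.coefficient(j, dm.p, name)
        rows.extend(t_test(f, c) for f in fits)
    results = add_fdr(pd.DataFrame(rows, columns=RESULT_COLUMNS))
    return fits, results, dm


def run_de(config: RunConfig) -> dict:
    """Full pipeline over files; writes fits.tsv, results.tsv, qc_report.tsv."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts, gene_ids, cell_ids = fio.read_counts(
        config.counts_path, config.features_path, config.barcodes_path
    )
    meta = fio.read_metadata(config.meta_path)
    if len(meta) != counts.shape[1]:
        raise ValueError("pipeline[read]: metadata rows != matrix columns")
    logger.info("read %d genes x %d cells", *counts.shape)

    counts, meta, gene_ids, report = filter_qc(counts, meta, config.qc, gene_ids)
    logger.info("QC kept %d genes x %d cells", *counts.shape)

    spec = _model_spec(config.fixed, config.random)
    fits, results, dm = de_analysis(
        counts, meta, gene_ids, spec,
        fitter=config.fitter, tested_terms=config.tested_terms,
        chunk_size=config.chunk_size,
    )
    fio.write_table(fits_to_frame(fits, dm.x_names), out / "fits.tsv")
    fio.write_table(results, out / "results.tsv")
    fio.write_table(pd.DataFrame([report]), out / "qc_report.tsv")
    logger.info("pipeline finished in %.1fs", time.time() - t0)
    return {"fits": fits, "results": results, "qc_report": report, "designs": dm}


def min_interaction_pvalues(results: pd.DataFrame, gene_ids: list[str]) -> np.ndarray:
    """Per-gene DE score: minimum p across interaction terms (NaN-safe)."""
    inter = results[results["term"].str.contains(":")]
    by_gene = inter.groupby("gene_id")["p_value"].min()
    return by_gene.reindex(gene_ids).to_numpy()


def run_simulation_study(
    design: SimDesign,
    fitter: FitterConfig | None = None,
    out_dir: str | None = None,
    reference=None,
    dataset: SimDataset | None = None,
    alpha_grid=(0.01, 0.05, 0.1),
) -> dict:
    """Simulate, fit the interaction model, and score calibration/power.

    Genes are ranked by their minimum interaction-term p-value; AUC is
    computed against the designated-DE truth labels.  Type-I error and
    the QQ table use the pooled interaction p-values of null genes.
    """
    if dataset is None:
        if reference is None:
            # Mean floor 10^-1.6 mimics an expression-filtered droplet
            # reference; genes far below it carry no detectable signal
            # at these cell counts and only dilute the ROC.
            reference = synth_reference(
                max(2 * design.n_genes, design.n_genes + 100),
                2_000,
                seed=design.seed + 7,
                mean_range_log10=(-1.6, 2.0),
            )
        from .simulate import mme_dispersion

        nb = mme_dispersion(reference) if isinstance(reference, np.ndarray) else reference
        dataset = simulate_dataset(nb, design)
    spec = _model_spec("log_libsize + cell_type + cell_type:condition", "subject")
    fits, results, dm = de_analysis(
        dataset.counts, dataset.metadata, dataset.gene_ids, spec, fitter=fitter
    )
    is_de = np.isin(dataset.gene_ids, dataset.truth["gene_id"])
    minp = min_interaction_pvalues(results, dataset.gene_ids)
    valid = np.isfinite(minp)
    auc = np.nan
    if is_de[valid].any() and (~is_de[valid]).any():
        auc = roc_auc(-np.log10(np.clip(minp[valid], 1e-300, None)), is_de[valid])

    null_genes = set(np.asarray(dataset.gene_ids)[~is_de])
    inter = results[results["term"].str.contains(":")]
    null_p = inter.loc[inter["gene_id"].isin(null_genes), "p_value"].dropna().to_numpy()
    type1 = {float(a): float(np.mean(null_p < a)) for a in alpha_grid}
    qq = qq_uniform(null_p, n_points=2_000)

    metrics = {"auc": float(auc), "type1_error": type1, "n_null_pvals": int(null_p.size)}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fio.write_table(results, out / "results.tsv")
        fio.write_table(qq, out / "qq.tsv")
        fio.write_table(
            pd.DataFrame([{"auc": auc, **{f"type1_at_{a}": v for a, v in type1.items()}}]),
            out / "metrics.tsv",
        )
    return {"metrics": metrics, "qq": qq, "results": results, "fits": fits, "dataset": dataset}
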