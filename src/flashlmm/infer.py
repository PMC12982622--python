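"""Hypothesis tests on fitted genes and multiple-testing adjustment.

Fixed effects and contrasts use t-statistics with residual degrees of
freedom (n − p).  Variance components are tested off the boundary:
because θ_k = σ²γ_k may be negative, H0: θ_k ≤ 0 vs H1: θ_k > 0 is an
interior-point problem and a one-sided z-test applies; nested random
structures are compared by a χ² likelihood-ratio test.  Per-term FDR is
Benjamini–Hochberg across genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lmmfit import GeneFit

__all__ = [
    "Contrast",
    "t_test",
    "z_test_varcomp",
    "lrt_varcomp",
    "bh_adjust",
    "test_fixed_effects",
    "add_fdr",
]

RESULT_COLUMNS = [
    "gene_id",
    "term",
    "estimate",
    "se",
    "statistic",
    "df",
    "p_value",
    "fdr",
    "test_kind",
]


@dataclass
class Contrast:
    name: str
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1 or not np.any(self.weights):
            raise ValueError("contrast needs at least one nonzero weight")

    @classmethod
    def coefficient(cls, index: int, p: int, name: str | None = None) -> "Contrast":
        w = np.zeros(p)
        w[index] = 1.0
        return cls(name or f"beta_{index}", w)


def _row(gene_id, term, estimate, se, statistic, df, p, kind) -> dict:
    return {
        "gene_id": gene_id,
        "term": term,
        "estimate": estimate,
        "se": se,
        "statistic": statistic,
        "df": df,
        "p_value": p,
        "fdr": np.nan,
        "test_kind": kind,
    }


def t_test(fit: GeneFit, contrast: Contrast) -> dict:
    """Two-sided t-test of ``cᵀβ = 0`` with df = n − p."""
    c = contrast.weights
    if c.size != fit.beta.size:
        raise ValueError("contrast length does not match number of coefficients")
    if not fit.ok:
        return _row(fit.gene_id, contrast.name, np.nan, np.nan, np.nan, fit.df_resid, np.nan, "t")
    est = float(c @ fit.beta)
    var = float(c @ fit.cov_beta @ c)
    se = np.sqrt(var) if var > 0 else 0.0
    if se == 0.0:
        return _row(fit.gene_id, contrast.name, est, np.nan, np.nan, fit.df_resid, np.nan, "t")
    t = est / se
    p = 2.0 * stats.t.sf(abs(t), df=fit.df_resid)
    return _row(fit.gene_id, contrast.name, est, se, t, fit.df_resid, p, "t")


def z_test_varcomp(fit: GeneFit, k: int = 0) -> dict:
    """One-sided z-test of H0: θ_k ≤ 0 vs H1: θ_k > 0."""
    term = f"theta_{k + 1}"
    if not fit.ok or not np.isfinite(fit.se_theta[k]) or fit.se_theta[k] <= 0:
        return _row(fit.gene_id, term, np.nan, np.nan, np.nan, np.inf, np.nan, "z")
    z = fit.theta[k] / fit.se_theta[k]
    p = stats.norm.sf(z)
    return _row(fit.gene_id, term, fit.theta[k], fit.se_theta[k], z, np.inf, p, "z")


def lrt_varcomp(fit_full: GeneFit, fit_reduced: GeneFit) -> dict:
    """χ² LRT of nested random structures (df = ΔK), clipped at 0.

    REML log-likelihoods are comparable only when both fits share the
    same fixed part — enforced by matching coefficient counts.
    """
    if fit_full.gene_id != fit_reduced.gene_id:
        raise ValueError("LRT requires fits of the same gene")
    if fit_full.method != fit_reduced.method:
        raise ValueError("LRT requires the same estimation criterion")
    if fit_full.method == "reml" and fit_full.beta.size != fit_reduced.beta.size:
        raise ValueError("REML LRT requires identical fixed-effect structure")
    df = fit_full.theta.size - fit_reduced.theta.size
    if df <= 0:
        raise ValueError("models are not nested (full model must add components)")
    term = "random_effects"
    if not (fit_full.ok and fit_reduced.ok):
        return _row(fit_full.gene_id, term, np.nan, np.nan, np.nan, df, np.nan, "lrt")
    stat = max(0.0, 2.0 * (fit_full.loglik - fit_reduced.loglik))
    p = stats.chi2.sf(stat, df=df)
    return _row(fit_full.gene_id, term, stat, np.nan, stat, df, p, "lrt")


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR; NaNs are ignored and reinserted."""
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[mask] = res
    return out


def test_fixed_effects(
    fits: list[GeneFit], term_indices: dict[str, int], p: int
) -> pd.DataFrame:
    """t-test each named coefficient across genes; BH-adjust per term."""
    rows = []
    for name, j in term_indices.items():
        c = Contrast.coefficient(j, p, name)
        rows.extend(t_test(f, c) for f in fits)
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return add_fdr(df)


def add_fdr(results: pd.DataFrame) -> pd.DataFrame:
    """BH adjustment applied within each (term, test_kind) across genes."""
    results = results.copy()
    for _, idx in results.groupby(["term", "test_kind"]).groups.items():
        results.loc[idx, "fdr"] = bh_adjust(results.loc[idx, "p_value"].to_numpy())
    return results
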