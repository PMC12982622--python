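# flashlmm

Fast, memory-light linear mixed-effects models (LMMs) for per-gene
single-cell differential expression, fitted entirely from
low-dimensional **summary statistics**, plus a companion multi-subject
multi-cell-type negative-binomial scRNA-seq simulator.

## What it does

For each gene the model is `y = Xβ + Zb + ε` on `y = log(1 + counts)`,
with fixed effects `X` (e.g. log library size, cell type, and
cell-type × condition interactions) and one-hot random-effect blocks
`Z` (e.g. subject). Instead of touching the n-cell data during
estimation, the package precomputes

```
XᵀX, XᵀYᵀ, ZᵀX, ZᵀYᵀ, ZᵀZ, per-gene yᵀy, n
```

once (streaming over cell chunks), after which every per-gene REML/ML
fit costs `O(p³ + q³)` — independent of the number of cells. The
covariance `H = I + Σ γ_k Z_k Z_kᵀ` is handled through

```
H⁻¹    = I − Z (I_q + ΓA)⁻¹ Γ Zᵀ      (A = ZᵀZ)
log|H| = log|I_q + ΓA|
```

and γ is maximised by Fisher scoring with step-halving. Variance
components are reparameterised as `θ_k = σ²γ_k` with
`γ_k > −1/λ_max(ZᵀZ)`, so θ may be negative and the null `θ_k = 0` is
an interior point: fixed effects get t-tests, variance components get
one-sided z-tests and χ² likelihood-ratio tests, with
Benjamini–Hochberg FDR across genes per term. A dense `O(n³)`
reference fitter (`dense_reference_fit`) provides an independent
verification path used by the test-suite oracles.

The simulator draws NB counts with per-gene means taken from a
reference and method-of-moments dispersions
(`r = μ̂²/(s² − μ̂)` when `s² > μ̂`), assigns subjects / cell types /
conditions uniformly, adds per-gene×subject log-normal random effects
and per-cell library factors, and spikes designated cell-type-specific
DE genes with known log fold changes. A synthetic reference generator
removes any dependence on downloaded data.

## Layout

| module | contents |
|---|---|
| `flashlmm.designs` | model spec, fixed/random design matrices, estimability check, PCA-equivalent reduction of Z |
| `flashlmm.sstats` | log1p transform, chunked summary-statistics accumulation/merge, HDF5 archive |
| `flashlmm.lmmfit` | per-gene REML/ML fitting, scores/information, dense reference oracle |
| `flashlmm.infer` | t / z / LRT tests, BH adjustment |
| `flashlmm.simulate` | NB simulator, synthetic reference, ROC/AUC, QQ utilities |
| `flashlmm.pipeline` | QC filtering, end-to-end DE run, simulation-study driver |
| `flashlmm.cli` | `flashlmm` command-line interface |

## CLI

```bash
# simulate a dataset (Matrix Market counts + metadata + DE truth)
flashlmm simulate --out simdir/ --seed 1 --n-cells 20000 --n-genes 6000 --n-de 480

# end-to-end DE analysis
flashlmm run --counts simdir/matrix.mtx --features simdir/features.tsv \
    --barcodes simdir/barcodes.tsv --meta simdir/metadata.tsv \
    --fixed "log_libsize + cell_type + cell_type:condition" --random subject \
    --method reml --out outdir/

# two-stage: precompute the archive, then fit from it alone
flashlmm sstats --counts simdir/matrix.mtx --features simdir/features.tsv \
    --barcodes simdir/barcodes.tsv --meta simdir/metadata.tsv --out ss.h5
flashlmm fit --sstats ss.h5 --out fits.tsv

# simulation study: AUC, type-I error grid, QQ table
flashlmm simstudy --out metrics/ --seed 1
```

QC thresholds (feature counts, library-size window, counts-per-cell
ratio, per-cell-type minimum) are flags on `flashlmm run`; all default
to pass-through.

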