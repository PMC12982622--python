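"""Per-gene ML/REML estimation of the linear mixed model from summary statistics.

Model: ``y = Xβ + Zb + ε`` with ``b_k ~ N(0, σ_k² I)`` blockwise and
``ε ~ N(0, σ² I)``.  With variance ratios ``γ_k = σ_k²/σ²`` the marginal
covariance is ``σ² H`` where ``H = I + Σ_k γ_k Z_k Z_kᵀ``.  H stays
positive-definite for ``γ_k > −1/λ_max`` (λ_max the largest eigenvalue
of ``ZᵀZ``), which lets the reparameterised variance components
``θ_k = σ² γ_k`` go negative, so the null ``θ_k = 0`` is an interior
point of the parameter space.

All per-gene quantities are evaluated through two identities that
reduce every product to p- and q-dimensional blocks of the summary
statistics, with ``A = ZᵀZ`` and ``Γ = blockdiag(γ_k I_{q_k})``::

    H⁻¹    = I − Z (I_q + ΓA)⁻¹ Γ Zᵀ
    log|H| = log|I_q + ΓA|

so the cost of a fit is O(p³ + q³) per iteration, independent of the
number of cells.  Optimisation is Fisher scoring on γ with step-halving
and boundary clipping; accepted steps never decrease the (profiled)
log-likelihood.

:func:`dense_reference_fit` is an independent O(n²)–O(n³) verification
path that never touches the identities above; it exists for tests and
validation only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, lu_factor, lu_solve

from .sstats import SummaryStats

__all__ = [
    "FitterConfig",
    "GeneFit",
    "lambda_max",
    "gls_quadratics",
    "profile_loglik",
    "score_and_information",
    "fit_gene",
    "fit_all",
    "dense_profile_loglik",
    "dense_reference_fit",
    "fits_to_frame",
]

LOG2PI = float(np.log(2.0 * np.pi))

Method = Literal["ml", "reml"]


class BoundaryError(ArithmeticError):
    """γ outside the region where H is positive-definite."""


class DegenerateGene(ArithmeticError):
    """Zero-variance or otherwise unusable gene."""


@dataclass
class FitterConfig:
    method: Method = "reml"
    max_iter: int = 200
    tol_loglik: float = 1e-8
    tol_grad: float = 1e-4
    boundary_eps: float = 1e-8
    gamma_init: float = 0.0
    dense_oracle_max_n: int = 3000

    def __post_init__(self) -> None:
        self.method = self.method.lower()  # type: ignore[assignment]
        if self.method not in ("ml", "reml"):
            raise ValueError("method must be 'ml' or 'reml'")
        for name in ("tol_loglik", "tol_grad", "boundary_eps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class GeneFit:
    gene_id: str
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float
    gamma: np.ndarray
    theta: np.ndarray
    se_theta: np.ndarray
    loglik: float
    method: str
    n_iter: int
    converged: bool
    df_resid: int
    n: int
    message: str = ""
    loglik_trace: list = field(default_factory=list)

    @property
    def se_beta(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov_beta), 0.0, None))

    @property
    def ok(self) -> bool:
        return self.converged and np.all(np.isfinite(self.beta))


def _na_fit(gene_id: str, p: int, K: int, n: int, method: str, message: str) -> GeneFit:
    return GeneFit(
        gene_id=gene_id,
        beta=np.full(p, np.nan),
        cov_beta=np.full((p, p), np.nan),
        sigma2=np.nan,
        gamma=np.full(K, np.nan),
        theta=np.full(K, np.nan),
        se_theta=np.full(K, np.nan),
        loglik=np.nan,
        method=method,
        n_iter=0,
        converged=False,
        df_resid=n - p,
        n=n,
        message=message,
    )


def lambda_max(ZZ: np.ndarray) -> float:
    """Largest eigenvalue of the Gram matrix ``ZᵀZ``."""
    ZZ = np.asarray(ZZ, dtype=float)
    if ZZ.size == 0:
        return 0.0
    if not np.allclose(ZZ, ZZ.T, atol=1e-8 * max(1.0, np.abs(ZZ).max())):
        raise ValueError("ZZ must be symmetric")
    return float(np.linalg.eigvalsh(ZZ)[-1])


def _expand_gamma(gamma: np.ndarray, partition: Sequence[int]) -> np.ndarray:
    gamma = np.atleast_1d(np.asarray(gamma, dtype=float))
    if gamma.size != len(partition):
        raise ValueError("gamma length must equal the number of variance components")
    return np.repeat(gamma, partition)


def _woodbury_weight(ZZ: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, float]:
    """Return ``W = (I + ΓA)⁻¹Γ`` (symmetrised) and ``log|I + ΓA|``.

    W is symmetric in exact arithmetic; averaging with its transpose
    suppresses rounding asymmetry from the LU solve.
    """
    q = ZZ.shape[0]
    if q == 0:
        return np.empty((0, 0)), 0.0
    M = np.eye(q) + g[:, None] * ZZ
    lu, piv = lu_factor(M)
    diag = np.diag(lu)
    if np.any(diag == 0):
        raise BoundaryError("I + ΓZᵀZ is singular: γ at or beyond −1/λmax")
    logdet = float(np.sum(np.log(np.abs(diag))))
    sign = np.prod(np.sign(diag)) * (-1) ** (np.sum(piv != np.arange(q)) % 2)
    if sign <= 0:
        raise BoundaryError("I + ΓZᵀZ is not positive: γ beyond −1/λmax")
    W = lu_solve((lu, piv), np.diag(g))
    return 0.5 * (W + W.T), logdet


def gls_quadratics(ss: SummaryStats, gamma, gene_index: int, need_z: bool = True) -> dict:
    """All H⁻¹-weighted products needed for one gene at one γ.

    Every entry equals its dense counterpart computed with the explicit
    ``H = I + ZΓZᵀ``, but costs O(p³ + q³) from the summary statistics.
    ``need_z=False`` skips the q×q Z-weighted blocks (only required for
    scores/information), leaving the likelihood evaluation at O(q³)
    for the factorisation plus O(q²p) products.
    """
    g = _expand_gamma(gamma, ss.partition)
    W, logdetH = _woodbury_weight(ss.ZZ, g)
    ZX, ZZ = ss.ZX, ss.ZZ
    zy = ss.ZY[:, gene_index]
    WZX = W @ ZX
    Wzy = W @ zy
    out = {
        "XHiX": ss.XX - ZX.T @ WZX,
        "XHiy": ss.XY[:, gene_index] - ZX.T @ Wzy,
        "yHiy": float(ss.Ynorm[gene_index] - zy @ Wzy),
        "logdetH": logdetH,
    }
    if need_z:
        out["ZHiZ"] = ZZ - ZZ @ W @ ZZ
        out["ZHiX"] = ZX - ZZ @ WZX
        out["ZHiy"] = zy - ZZ @ Wzy
    return out


def _beta_rss(quad: dict) -> tuple[np.ndarray, float, np.ndarray]:
    XHiX = quad["XHiX"]
    XHiX_inv = np.linalg.inv(XHiX)
    beta = XHiX_inv @ quad["XHiy"]
    rss = quad["yHiy"] - float(quad["XHiy"] @ beta)
    return beta, rss, XHiX_inv


def _loglik_from(quad: dict, rss: float, n: int, p: int, method: str) -> tuple[float, float]:
    if rss <= 0:
        raise DegenerateGene("nonpositive residual sum of squares")
    if method == "reml":
        df = n - p
        sigma2 = rss / df
        _, logdet_xhx = np.linalg.slogdet(quad["XHiX"])
        ll = -0.5 * (df * (LOG2PI + np.log(sigma2)) + quad["logdetH"] + logdet_xhx + df)
    else:
        sigma2 = rss / n
        ll = -0.5 * (n * (LOG2PI + np.log(sigma2)) + quad["logdetH"] + n)
    return float(ll), float(sigma2)


def _spectral_cache(ss: SummaryStats) -> dict:
    """Per-dataset eigenbasis of A = ZᵀZ for single-component models.

    With K = 1, rotating the q-dimensional blocks into the eigenbasis of
    A makes every γ-dependent weight diagonal, so likelihood, score and
    information evaluations cost O(q·p²) per gene instead of O(q³).
    Computed once per SummaryStats and cached on the instance.
    """
    cache = getattr(ss, "_spectral", None)
    if cache is None:
        lam, Q = np.linalg.eigh(ss.ZZ)
        cache = {"lam": lam, "RZX": Q.T @ ss.ZX, "RZY": Q.T @ ss.ZY}
        object.__setattr__(ss, "_spectral", cache)
    return cache


def _quad_k1(ss: SummaryStats, gamma: float, gene_index: int) -> dict:
    ctx = _spectral_cache(ss)
    lam = ctx["lam"]
    denom = 1.0 + gamma * lam
    if np.any(denom <= 0):
        raise BoundaryError("I + ΓZᵀZ is not positive: γ beyond −1/λmax")
    w = gamma / denom            # rotated W = (I + ΓA)⁻¹Γ diagonal
    d = gamma * lam / denom      # rotated AW diagonal
    RZX, rzy = ctx["RZX"], ctx["RZY"][:, gene_index]
    return {
        "XHiX": ss.XX - RZX.T @ (w[:, None] * RZX),
        "XHiy": ss.XY[:, gene_index] - RZX.T @ (w * rzy),
        "yHiy": float(ss.Ynorm[gene_index] - rzy @ (w * rzy)),
        "logdetH": float(np.sum(np.log(denom))),
        "_h": lam / denom,            # rotated ZᵀH⁻¹Z diagonal
        "_B": (1.0 - d)[:, None] * RZX,  # rotated ZᵀH⁻¹X
        "_v": (1.0 - d) * rzy,           # rotated ZᵀH⁻¹y
    }


def profile_loglik(ss: SummaryStats, gamma, gene_index: int, method: Method = "reml") -> dict:
    """Profiled log-likelihood (β and σ² maximised out) at a given γ.

    REML includes the ``−½log|XᵀH⁻¹X|`` term; additive constants are
    fixed across γ and across nested random structures with the same
    fixed part, so likelihood-ratio differences are valid.
    """
    gamma = np.atleast_1d(np.asarray(gamma, dtype=float))
    if len(ss.partition) == 1:
        quad = _quad_k1(ss, gamma[0], gene_index)
    else:
        quad = gls_quadratics(ss, gamma, gene_index, need_z=False)
    beta, rss, _ = _beta_rss(quad)
    ll, sigma2 = _loglik_from(quad, rss, ss.n, ss.p, method)
    return {"loglik": ll, "sigma2_hat": sigma2, "beta_hat": beta}


def _block_slices(partition: Sequence[int]) -> list[slice]:
    ends = np.cumsum(partition)
    starts = ends - np.asarray(partition)
    return [slice(int(s), int(e)) for s, e in zip(starts, ends)]


def score_and_information(
    ss: SummaryStats, gamma, gene_index: int, method: Method = "reml"
) -> dict:
    """Score ∂ℓ/∂γ_k of the profiled log-likelihood and expected information.

    ``score_k = −½ [ tr(Z_kᵀ P̃ Z_k) − ‖Z_kᵀ P y‖² / σ̂² ]`` and
    ``I_kl = ½ ‖Z_kᵀ P̃ Z_l‖_F²`` with ``P̃ = P`` under REML and
    ``P̃ = H⁻¹`` under ML; ``P = H⁻¹ − H⁻¹X(XᵀH⁻¹X)⁻¹XᵀH⁻¹``.
    """
    gamma = np.atleast_1d(np.asarray(gamma, dtype=float))
    n, p = ss.n, ss.p
    K = len(ss.partition)
    if K == 1:
        quad = _quad_k1(ss, gamma[0], gene_index)
        beta, rss, XHiX_inv = _beta_rss(quad)
        if rss <= 0:
            raise DegenerateGene("nonpositive residual sum of squares")
        sigma2 = rss / (n - p) if method == "reml" else rss / n
        h, B, v = quad["_h"], quad["_B"], quad["_v"]
        u = v - B @ beta                               # rotated Zᵀ P y
        usq = np.array([float(u @ u)])
        GBtB = XHiX_inv @ (B.T @ B)
        if method == "reml":
            # ZᵀPZ = diag(h) − B G Bᵀ in the eigenbasis
            tr_c = float(h.sum() - np.trace(GBtB))
            diag_BGBt = np.einsum("ij,ij->i", B @ XHiX_inv, B)
            frob2 = float(h @ h - 2.0 * h @ diag_BGBt + np.sum(GBtB * GBtB.T))
        else:
            tr_c = float(h.sum())
            frob2 = float(h @ h)
        tr_blocks = np.array([tr_c])
        frob_blocks = np.array([[frob2]])
    else:
        quad = gls_quadratics(ss, gamma, gene_index)
        beta, rss, XHiX_inv = _beta_rss(quad)
        if rss <= 0:
            raise DegenerateGene("nonpositive residual sum of squares")
        sigma2 = rss / (n - p) if method == "reml" else rss / n
        u = quad["ZHiy"] - quad["ZHiX"] @ beta         # Zᵀ P y
        ZPZ = quad["ZHiZ"] - quad["ZHiX"] @ XHiX_inv @ quad["ZHiX"].T
        Ctr = ZPZ if method == "reml" else quad["ZHiZ"]
        blocks = _block_slices(ss.partition)
        tr_blocks = np.array([np.trace(Ctr[b, b]) for b in blocks])
        frob_blocks = np.array(
            [[float(np.sum(Ctr[bk, bl] ** 2)) for bl in blocks] for bk in blocks]
        )
        usq = np.array([float(u[b] @ u[b]) for b in blocks])
    score = -0.5 * (tr_blocks - usq / sigma2)
    info = 0.5 * frob_blocks
    if not (np.all(np.isfinite(score)) and np.all(np.isfinite(info))):
        raise ArithmeticError(f"non-finite score/information for gene index {gene_index}")
    return {
        "score": score,
        "info": info,
        "sigma2": sigma2,
        "tr_blocks": tr_blocks,
        "frob_blocks": frob_blocks,
    }


def _theta_se_from_stats(
    tr_blocks: np.ndarray,
    frob_blocks: np.ndarray,
    gamma: np.ndarray,
    sigma2: float,
    n: int,
    p: int,
    method: str,
) -> np.ndarray:
    # SE of θ̂ = σ̂²γ̂: expected information of the full likelihood in
    # (γ, σ²), inverted, then mapped to θ by the Jacobian [σ²I | γ].
    # Equals the information computed directly in (θ, σ²) by invariance.
    K = tr_blocks.size
    nn = (n - p) if method == "reml" else n
    I = np.empty((K + 1, K + 1))
    I[:K, :K] = 0.5 * frob_blocks
    I[:K, K] = I[K, :K] = tr_blocks / (2.0 * sigma2)
    I[K, K] = nn / (2.0 * sigma2**2)
    try:
        C = np.linalg.inv(I)
    except np.linalg.LinAlgError:
        return np.full(K, np.nan)
    J = np.zeros((K, K + 1))
    J[:, :K] = sigma2 * np.eye(K)
    J[:, K] = gamma
    var = np.diag(J @ C @ J.T)
    return np.sqrt(np.clip(var, 0.0, None))


def fit_gene(ss: SummaryStats, gene_index: int, config: FitterConfig | None = None) -> GeneFit:
    """Fisher-scoring fit of one gene; never raises on bad genes.

    θ̂_k = σ̂²γ̂_k may come out negative; the search is constrained only
    by the positive-definiteness boundary γ_k > −1/λmax + ε.
    """
    config = config or FitterConfig()
    method = config.method
    p, K, n = ss.p, len(ss.partition), ss.n
    gene_id = ss.gene_ids[gene_index]
    if ss.Ynorm[gene_index] <= 0:
        return _na_fit(gene_id, p, K, n, method, "zero-expression gene")

    if K == 0:
        return _fit_ols(ss, gene_index, config)

    lmax = getattr(ss, "_lambda_max", None)
    if lmax is None:
        lmax = lambda_max(ss.ZZ)
        object.__setattr__(ss, "_lambda_max", lmax)
    lb = -1.0 / lmax + config.boundary_eps
    gamma = np.full(K, float(config.gamma_init))
    gamma = np.maximum(gamma, lb)
    try:
        cur = profile_loglik(ss, gamma, gene_index, method)
    except (DegenerateGene, BoundaryError) as exc:
        return _na_fit(gene_id, p, K, n, method, str(exc))

    converged = False
    n_iter = 0
    message = "max_iter reached"
    trace = [cur["loglik"]]
    for n_iter in range(1, config.max_iter + 1):
        try:
            si = score_and_information(ss, gamma, gene_index, method)
        except (DegenerateGene, BoundaryError, ArithmeticError) as exc:
            message = str(exc)
            break
        score, info = si["score"], si["info"]
        if np.max(np.abs(score)) <= config.tol_grad:
            converged = True
            message = "score below tolerance"
            break
        step = np.linalg.solve(info + 1e-10 * np.eye(K), score)
        alpha = 1.0
        accepted = False
        for _ in range(40):
            cand = np.maximum(gamma + alpha * step, lb)
            try:
                nxt = profile_loglik(ss, cand, gene_index, method)
            except (DegenerateGene, BoundaryError):
                alpha *= 0.5
                continue
            if nxt["loglik"] >= cur["loglik"] - 1e-13:
                delta = nxt["loglik"] - cur["loglik"]
                gamma, cur = cand, nxt
                trace.append(cur["loglik"])
                accepted = True
                if abs(delta) < config.tol_loglik:
                    converged = True
                    message = "loglik change below tolerance"
                break
            alpha *= 0.5
        if not accepted:
            converged = True  # no uphill step exists: at a (boundary) optimum
            message = "no ascent step found"
            break
        if converged:
            break

    sigma2 = cur["sigma2_hat"]
    beta = cur["beta_hat"]
    if K == 1:
        quad = _quad_k1(ss, gamma[0], gene_index)
    else:
        quad = gls_quadratics(ss, gamma, gene_index, need_z=False)
    _, _, XHiX_inv = _beta_rss(quad)
    cov_beta = sigma2 * XHiX_inv
    try:
        si = score_and_information(ss, gamma, gene_index, method)
        se_theta = _theta_se_from_stats(
            si["tr_blocks"], si["frob_blocks"], gamma, sigma2, n, p, method
        )
    except (DegenerateGene, BoundaryError, ArithmeticError):
        se_theta = np.full(K, np.nan)
    return GeneFit(
        gene_id=gene_id,
        beta=beta,
        cov_beta=0.5 * (cov_beta + cov_beta.T),
        sigma2=sigma2,
        gamma=gamma.copy(),
        theta=sigma2 * gamma,
        se_theta=se_theta,
        loglik=cur["loglik"],
        method=method,
        n_iter=n_iter,
        converged=converged,
        df_resid=n - p,
        n=n,
        message=message,
        loglik_trace=trace,
    )


def _fit_ols(ss: SummaryStats, gene_index: int, config: FitterConfig) -> GeneFit:
    """K = 0: plain (RE)ML linear model from the same statistics."""
    n, p = ss.n, ss.p
    gene_id = ss.gene_ids[gene_index]
    quad = {
        "XHiX": ss.XX,
        "XHiy": ss.XY[:, gene_index],
        "yHiy": float(ss.Ynorm[gene_index]),
        "logdetH": 0.0,
    }
    try:
        beta, rss, XHiX_inv = _beta_rss(quad)
        ll, sigma2 = _loglik_from(quad, rss, n, p, config.method)
    except (DegenerateGene, np.linalg.LinAlgError) as exc:
        return _na_fit(gene_id, p, 0, n, config.method, str(exc))
    cov = sigma2 * XHiX_inv
    return GeneFit(
        gene_id=gene_id,
        beta=beta,
        cov_beta=0.5 * (cov + cov.T),
        sigma2=sigma2,
        gamma=np.empty(0),
        theta=np.empty(0),
        se_theta=np.empty(0),
        loglik=ll,
        method=config.method,
        n_iter=0,
        converged=True,
        df_resid=n - p,
        n=n,
        message="ols",
    )


def fit_all(ss: SummaryStats, config: FitterConfig | None = None) -> list[GeneFit]:
    """Fit every gene independently, in the order of ``ss.gene_ids``."""
    config = config or FitterConfig()
    return [fit_gene(ss, i, config) for i in range(ss.m)]


# ---------------------------------------------------------------------------
# Dense verification path (tests/validation only)
# ---------------------------------------------------------------------------


def _dense_H(Z: np.ndarray, gamma: np.ndarray, partition: Sequence[int]) -> np.ndarray:
    n = Z.shape[0]
    H = np.eye(n)
    for gk, blk in zip(np.atleast_1d(gamma), _block_slices(partition)):
        Zk = Z[:, blk]
        H += gk * (Zk @ Zk.T)
    return H


def dense_profile_loglik(
    X: np.ndarray,
    Z: np.ndarray,
    y: np.ndarray,
    gamma,
    partition: Sequence[int],
    method: Method = "reml",
) -> dict:
    """Profiled log-likelihood via the explicit n×n covariance (Cholesky).

    Same criterion and constants as :func:`profile_loglik`; shares no
    code with the summary-statistics path.
    """
    n, p = X.shape
    gamma = np.atleast_1d(np.asarray(gamma, dtype=float))
    H = _dense_H(Z, gamma, partition)
    c, low = cho_factor(H, lower=True)
    logdetH = 2.0 * float(np.sum(np.log(np.diag(c))))
    Hi_X = cho_solve((c, low), X)
    Hi_y = cho_solve((c, low), y)
    XHiX = X.T @ Hi_X
    beta = np.linalg.solve(XHiX, X.T @ Hi_y)
    rss = float(y @ Hi_y) - float((X.T @ Hi_y) @ beta)
    if rss <= 0:
        raise DegenerateGene("nonpositive residual sum of squares")
    if method == "reml":
        df = n - p
        sigma2 = rss / df
        _, logdet_xhx = np.linalg.slogdet(XHiX)
        ll = -0.5 * (df * (LOG2PI + np.log(sigma2)) + logdetH + logdet_xhx + df)
    else:
        sigma2 = rss / n
        ll = -0.5 * (n * (LOG2PI + np.log(sigma2)) + logdetH + n)
    return {
        "loglik": float(ll),
        "sigma2_hat": float(sigma2),
        "beta_hat": beta,
        "logdetH": logdetH,
        "XHiX": XHiX,
    }


class _DenseEvalK1:
    """Fast single-component dense objective via one thin SVD of Z.

    ``H = I + γ U S² Uᵀ`` with Z = U S Vᵀ, so every evaluation is O(n·q)
    after one O(n q²) factorisation.  Used so the reference fit stays
    tractable at n in the thousands; algebra is plain orthogonal
    diagonalisation of the explicit covariance, not the
    summary-statistics identities.
    """

    def __init__(self, X: np.ndarray, Z: np.ndarray, y: np.ndarray, method: str):
        self.n, self.p = X.shape
        self.method = method
        U, s, _ = np.linalg.svd(Z, full_matrices=False)
        keep = s > 1e-13 * (s[0] if s.size else 1.0)
        self.U, self.s2 = U[:, keep], s[keep] ** 2
        self.UtX, self.Uty = self.U.T @ X, self.U.T @ y
        self.XtX, self.Xty, self.yty = X.T @ X, X.T @ y, float(y @ y)

    def evaluate(self, gamma: float) -> dict:
        d = gamma * self.s2 / (1.0 + gamma * self.s2)  # shrinkage weights
        if np.any(1.0 + gamma * self.s2 <= 0):
            raise BoundaryError("gamma beyond -1/lambda_max")
        XHiX = self.XtX - self.UtX.T @ (d[:, None] * self.UtX)
        XHiy = self.Xty - self.UtX.T @ (d * self.Uty)
        yHiy = self.yty - float(self.Uty @ (d * self.Uty))
        logdetH = float(np.sum(np.log1p(gamma * self.s2)))
        beta = np.linalg.solve(XHiX, XHiy)
        rss = yHiy - float(XHiy @ beta)
        if rss <= 0:
            raise DegenerateGene("nonpositive residual sum of squares")
        n, p = self.n, self.p
        if self.method == "reml":
            df = n - p
            sigma2 = rss / df
            _, logdet_xhx = np.linalg.slogdet(XHiX)
            ll = -0.5 * (df * (LOG2PI + np.log(sigma2)) + logdetH + logdet_xhx + df)
        else:
            sigma2 = rss / n
            ll = -0.5 * (n * (LOG2PI + np.log(sigma2)) + logdetH + n)
        return {"loglik": float(ll), "sigma2_hat": float(sigma2), "beta_hat": beta}


def dense_reference_fit(
    X: np.ndarray,
    Z: np.ndarray | None,
    y: np.ndarray,
    config: FitterConfig | None = None,
    partition: Sequence[int] | None = None,
    gene_id: str = "gene",
) -> GeneFit:
    """Brute-force fit with dense covariance algebra and a scipy optimiser.

    Maximises the same profiled criterion as :func:`fit_gene` but with
    explicit-H evaluations (Cholesky for K > 1, thin-SVD diagonalisation
    for K = 1) and derivative-free optimisation — an independent oracle
    for the summary-statistics path.
    """
    config = config or FitterConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n > config.dense_oracle_max_n:
        raise ValueError(f"n={n} exceeds dense_oracle_max_n={config.dense_oracle_max_n}")
    if Z is None or Z.shape[1] == 0:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        rss = float(resid @ resid)
        if config.method == "reml":
            sigma2 = rss / (n - p)
            _, ld = np.linalg.slogdet(X.T @ X)
            ll = -0.5 * ((n - p) * (LOG2PI + np.log(sigma2)) + ld + (n - p))
        else:
            sigma2 = rss / n
            ll = -0.5 * (n * (LOG2PI + np.log(sigma2)) + n)
        cov = sigma2 * np.linalg.inv(X.T @ X)
        return GeneFit(
            gene_id=gene_id, beta=beta, cov_beta=cov, sigma2=sigma2,
            gamma=np.empty(0), theta=np.empty(0), se_theta=np.empty(0),
            loglik=float(ll), method=config.method, n_iter=0, converged=True,
            df_resid=n - p, n=n, message="dense ols",
        )
    Z = np.asarray(Z, dtype=float)
    if partition is None:
        partition = (Z.shape[1],)
    K = len(partition)
    lmax = float(np.linalg.eigvalsh(Z.T @ Z)[-1])
    lb = -1.0 / lmax + config.boundary_eps
    hi = 1e4

    if K == 1:
        ev = _DenseEvalK1(X, Z, y, config.method)

        def neg(g: float) -> float:
            try:
                return -ev.evaluate(float(g))["loglik"]
            except (BoundaryError, DegenerateGene):
                return np.inf

        res = optimize.minimize_scalar(
            neg, bounds=(lb, hi), method="bounded", options={"xatol": 1e-12}
        )
        gamma = np.array([float(res.x)])
        best = ev.evaluate(gamma[0])
        n_iter = int(res.nfev)
    else:
        def neg_v(g: np.ndarray) -> float:
            try:
                return -dense_profile_loglik(X, Z, y, g, partition, config.method)["loglik"]
            except (BoundaryError, DegenerateGene, np.linalg.LinAlgError):
                return np.inf

        res = optimize.minimize(
            neg_v,
            x0=np.zeros(K),
            method="Powell",
            bounds=[(lb, hi)] * K,
            options={"xtol": 1e-12, "ftol": 1e-14, "maxiter": 10_000},
        )
        gamma = np.asarray(res.x, dtype=float)
        best = dense_profile_loglik(X, Z, y, gamma, partition, config.method)
        n_iter = int(res.nfev)

    dense = dense_profile_loglik(X, Z, y, gamma, partition, config.method)
    cov = best["sigma2_hat"] * np.linalg.inv(dense["XHiX"])
    return GeneFit(
        gene_id=gene_id,
        beta=best["beta_hat"],
        cov_beta=0.5 * (cov + cov.T),
        sigma2=best["sigma2_hat"],
        gamma=gamma,
        theta=best["sigma2_hat"] * gamma,
        se_theta=np.full(K, np.nan),
        loglik=best["loglik"],
        method=config.method,
        n_iter=n_iter,
        converged=True,
        df_resid=n - p,
        n=n,
        message="dense reference",
    )


def fits_to_frame(fits: list[GeneFit], x_names: Sequence[str] | None = None):
    """Tabulate fits, one row per gene (TSV-friendly, 17 sig. digits safe)."""
    import pandas as pd

    if not fits:
        return pd.DataFrame()
    p = fits[0].beta.size
    K = fits[0].theta.size
    if x_names is None:
        x_names = [f"b{j}" for j in range(p)]
    rows = []
    for f in fits:
        row: dict = {"gene_id": f.gene_id}
        for j, name in enumerate(x_names):
            row[f"beta_{name}"] = f.beta[j]
            row[f"se_{name}"] = f.se_beta[j]
        row["sigma2"] = f.sigma2
        for k in range(K):
            row[f"theta_{k + 1}"] = f.theta[k]
            row[f"se_theta_{k + 1}"] = f.se_theta[k]
        row.update(
            loglik=f.loglik, niter=f.n_iter, converged=f.converged, method=f.method
        )
        rows.append(row)
    return pd.DataFrame(rows)
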