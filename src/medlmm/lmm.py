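"""Single-random-effect linear mixed model via the spectral rotation trick.

The model is ``y = X b + u + e`` with ``u ~ N(0, sigma_g^2 K)`` and
``e ~ N(0, sigma_e^2 I)``, so ``var(y) = sigma_e^2 (lambda K + I)`` with
``lambda = sigma_g^2 / sigma_e^2``. Writing ``K = U diag(s) U'`` and rotating
``y`` and ``X`` by ``U'`` turns the covariance diagonal: generalized least
squares and the (restricted) likelihood then cost O(n q) per candidate
``lambda`` instead of O(n^3). The variance ratio is profiled out on a
log-spaced grid and polished by bounded scalar optimization — the approach
of the efficient mixed-model (EMMA-family) association methods.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .genotype import KinshipMatrix

__all__ = [
    "SpectralBasis",
    "LMMFit",
    "eigendecompose_kinship",
    "fit_lmm",
    "fit_lmm_rotated",
    "profile_loglik",
    "association_test",
    "association_scan",
]

#: default search grid for lambda = sigma_g^2 / sigma_e^2
LAMBDA_GRID = np.logspace(-5, 5, 100)


@dataclass
class SpectralBasis:
    """Eigendecomposition of a kinship matrix, reused across fits."""

    eigenvalues: np.ndarray  # (n,), non-negative, ascending
    rotation: np.ndarray  # (n, n), columns are eigenvectors
    source_hash: str

    @property
    def n(self) -> int:
        return self.eigenvalues.shape[0]

    def rotate(self, a: np.ndarray) -> np.ndarray:
        """Apply U' to a vector or matrix of row-dimension n."""
        return self.rotation.T @ a


@dataclass
class LMMFit:
    beta: np.ndarray
    se: np.ndarray
    lambda_: float
    sigma_g2: float
    sigma_e2: float
    loglik: float
    method: str
    df: int
    boundary: bool = False

    @property
    def beta_cov(self) -> np.ndarray:  # pragma: no cover - convenience
        raise NotImplementedError


def identity_basis(n: int) -> SpectralBasis:
    """Basis for K = I (no relatedness); used by the plain-LM code paths."""
    return SpectralBasis(np.ones(n), np.eye(n), source_hash="identity")


def eigendecompose_kinship(
    k: KinshipMatrix | np.ndarray, max_n: int = 5000, sym_tol: float = 1e-8
) -> SpectralBasis:
    """Symmetric eigendecomposition with eigenvalues clipped at zero."""
    values = k.values if isinstance(k, KinshipMatrix) else np.asarray(k, dtype=float)
    n = values.shape[0]
    if n > max_n:
        raise ValueError(f"kinship dimension {n} exceeds the configured maximum {max_n}")
    if not np.allclose(values, values.T, atol=sym_tol):
        raise ValueError("kinship matrix is not symmetric within tolerance")
    w, u = np.linalg.eigh(values)
    w = np.clip(w, 0.0, None)
    digest = hashlib.sha1(np.ascontiguousarray(values)).hexdigest()[:16]
    return SpectralBasis(eigenvalues=w, rotation=u, source_hash=digest)


def profile_loglik(
    y_rot: np.ndarray,
    x_rot: np.ndarray,
    eigenvalues: np.ndarray,
    deltas: np.ndarray,
    method: str = "REML",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Profiled log-likelihood on a batch of variance ratios.

    ``y_rot`` and ``x_rot`` must already be rotated by the eigenvector basis.
    Returns ``(loglik, beta, sigma_e2)`` with shapes (d,), (d, q), (d,). The
    batch formulation (einsum over the delta axis) is what makes permutation
    refits affordable.
    """
    deltas = np.atleast_1d(np.asarray(deltas, dtype=float))
    n, q = x_rot.shape
    w = deltas[:, None] * eigenvalues[None, :] + 1.0  # (d, n)
    winv = 1.0 / w
    xtwx = np.einsum("dn,nq,nr->dqr", winv, x_rot, x_rot)
    xtwy = np.einsum("dn,nq,n->dq", winv, x_rot, y_rot)
    beta = np.linalg.solve(xtwx, xtwy[..., None])[..., 0]
    ytwy = winv @ (y_rot**2)
    rss = ytwy - np.einsum("dq,dq->d", beta, xtwy)
    rss = np.maximum(rss, 1e-300)
    logdet_w = np.log(w).sum(axis=1)
    if method == "REML":
        dof = n - q
        sigma_e2 = rss / dof
        _, logdet_xtwx = np.linalg.slogdet(xtwx)
        _, logdet_xtx = np.linalg.slogdet(x_rot.T @ x_rot)
        ll = -0.5 * (
            dof * np.log(2.0 * np.pi * sigma_e2)
            + logdet_w
            + logdet_xtwx
            - logdet_xtx
            + dof
        )
    elif method == "ML":
        sigma_e2 = rss / n
        ll = -0.5 * (n * np.log(2.0 * np.pi * sigma_e2) + logdet_w + n)
    else:
        raise ValueError(f"method must be REML or ML, got {method!r}")
    return ll, beta, sigma_e2


def fit_lmm_rotated(
    y_rot: np.ndarray,
    x_rot: np.ndarray,
    eigenvalues: np.ndarray,
    method: str = "REML",
    grid: np.ndarray = LAMBDA_GRID,
    refine: bool = True,
) -> LMMFit:
    """Fit with pre-rotated inputs; see :func:`fit_lmm`."""
    n, q = x_rot.shape
    ll_grid, _, _ = profile_loglik(y_rot, x_rot, eigenvalues, grid, method)
    # ties (within numerical noise) broken toward smaller lambda; the profile
    # is exactly flat at K = I
    tol = 1e-8 * (1.0 + abs(float(np.max(ll_grid))))
    best = int(np.flatnonzero(ll_grid >= np.max(ll_grid) - tol)[0])
    delta = float(grid[best])
    boundary = best in (0, len(grid) - 1)
    if refine and 0 < best < len(grid) - 1:
        lo, hi = np.log10(grid[best - 1]), np.log10(grid[best + 1])

        def neg(logd: float) -> float:
            return -profile_loglik(y_rot, x_rot, eigenvalues, 10.0**logd, method)[0][0]

        res = optimize.minimize_scalar(neg, bounds=(lo, hi), method="bounded")
        if -res.fun > ll_grid[best] + tol:  # genuine improvement only
            delta = float(10.0**res.x)
    ll, beta, sigma_e2 = profile_loglik(y_rot, x_rot, eigenvalues, delta, method)
    ll, beta, sigma_e2 = float(ll[0]), beta[0], float(sigma_e2[0])
    winv = 1.0 / (delta * eigenvalues + 1.0)
    xtwx = (x_rot * winv[:, None]).T @ x_rot
    cov = sigma_e2 * np.linalg.inv(xtwx)
    se = np.sqrt(np.diag(cov))
    if boundary:
        warnings.warn(
            f"lambda estimate at the search boundary ({delta:g}); variance "
            "components may be non-identifiable (e.g. K = I)",
            RuntimeWarning,
            stacklevel=2,
        )
    return LMMFit(
        beta=beta,
        se=se,
        lambda_=delta,
        sigma_g2=delta * sigma_e2,
        sigma_e2=sigma_e2,
        loglik=ll,
        method=method,
        df=n - q,
        boundary=boundary,
    )


def fit_lmm(
    y: np.ndarray,
    fixed: np.ndarray,
    basis: SpectralBasis,
    method: str = "REML",
    grid: np.ndarray = LAMBDA_GRID,
) -> LMMFit:
    """REML/ML fit of ``y = fixed @ beta + u + e`` given a kinship basis.

    ``fixed`` must include the intercept column and have full column rank.
    """
    y = np.asarray(y, dtype=float)
    fixed = np.atleast_2d(np.asarray(fixed, dtype=float))
    if fixed.shape[0] != basis.n or y.shape[0] != basis.n:
        raise ValueError("y/fixed dimensions do not match the spectral basis")
    n, q = fixed.shape
    if n < q + 2:
        raise ValueError(f"need n >= #covariates + 2, got n={n}, q={q}")
    if np.linalg.matrix_rank(fixed) < q:
        raise ValueError("fixed-effect design matrix is rank deficient")
    return fit_lmm_rotated(basis.rotate(y), basis.rotate(fixed), basis.eigenvalues, method, grid)


def association_test(
    y: np.ndarray,
    x: np.ndarray,
    basis: SpectralBasis,
    lambda_: float,
    use_t: bool = True,
) -> tuple[float, float, float]:
    """Wald test of the SNP effect at a fixed variance ratio.

    The null-model ``lambda`` is reused for every SNP (the
    population-parameters-previously-determined approximation of
    EMMAX-style scans). Returns ``(beta, se, p)``; p is two-sided from a t
    reference with ``n - 2`` degrees of freedom (normal if ``use_t=False``).
    """
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("SNP vector is constant")
    beta, se, p = association_scan(y, x[:, None], basis, lambda_, use_t=use_t)
    return float(beta[0]), float(se[0]), float(p[0])


def association_scan(
    y: np.ndarray,
    snps: np.ndarray,
    basis: SpectralBasis,
    lambda_: float,
    use_t: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-SNP GLS Wald tests with an intercept, fixed lambda."""
    n = basis.n
    winv = 1.0 / (lambda_ * basis.eigenvalues + 1.0)
    y_rot = basis.rotate(np.asarray(y, dtype=float))
    ones_rot = basis.rotate(np.ones(n))
    g_rot = basis.rotate(np.asarray(snps, dtype=float))
    # closed-form 2-covariate GLS per SNP
    saa = float(np.sum(winv * ones_rot**2))
    say = float(np.sum(winv * ones_rot * y_rot))
    syy = float(np.sum(winv * y_rot**2))
    sab = (winv * ones_rot) @ g_rot  # (m,)
    sbb = winv @ (g_rot**2)
    sby = (winv * y_rot) @ g_rot
    det = saa * sbb - sab**2
    beta_snp = (saa * sby - sab * say) / det
    beta_int = (sbb * say - sab * sby) / det
    rss = syy - beta_int * say - beta_snp * sby
    df = n - 2
    sigma2 = np.maximum(rss, 0.0) / df
    se = np.sqrt(sigma2 * saa / det)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta_snp / se
    if use_t:
        p = 2.0 * stats.t.sf(np.abs(tstat), df)
    else:
        p = 2.0 * stats.norm.sf(np.abs(tstat))
    return beta_snp, se, p
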