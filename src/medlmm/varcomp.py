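"""Local vs global variance decomposition of expression traits.

For an expression trait ``y`` the model is::

    y = mu + u_local + u_global + eps
    u_local  ~ N(0, sigma_local^2  K_local)
    u_global ~ N(0, sigma_global^2 K_global)

where ``K_local`` is the IBS kinship over the SNPs within a window around
the gene (default +/- 15 kb of the gene body) and ``K_global`` over the
whole genome. The fraction of variance attached to the local kinship
measures cis-acting regulation; significance comes from permuting the
trait's line labels against both kinship matrices jointly, which preserves
the relatedness structure while breaking the trait-genotype link.

Two components cannot be jointly diagonalized, so the restricted likelihood
is evaluated by Cholesky factorization and maximized by Nelder-Mead over
the log variance ratios, with multiple restarts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .genotype import EmptyResultError, GenotypeMatrix, KinshipMatrix, ibs_kinship, local_window

logger = logging.getLogger(__name__)

__all__ = [
    "VarianceComponents",
    "gower_factor",
    "fit_two_vc",
    "vc_permutation_test",
    "vc_scan",
]


def gower_factor(k: np.ndarray) -> float:
    """Scale making the centered trace of ``k`` equal ``n - 1``.

    IBS matrices carry a large constant allele-sharing baseline; after this
    normalization one unit of attached variance contributes one unit of
    centered trait variance (the convention used for 'variance explained'
    in GCTA-style partitioning), so component sums are comparable with
    ``var(y)``.
    """
    k = np.asarray(k, dtype=float)
    n = k.shape[0]
    centered_trace = np.trace(k) - n * k.mean()
    if centered_trace <= 0:
        raise ValueError("kinship has no off-mean structure to scale by")
    return (n - 1) / centered_trace

_LOG_RATIO_BOUNDS = (-18.0, 9.0)
_STARTS = [(-2.3, -2.3), (0.0, -2.3), (-2.3, 0.0), (0.0, 0.0)]  # log-ratio starts


@dataclass
class VarianceComponents:
    sigma_local2: float
    sigma_global2: float
    sigma_e2: float
    frac_local: float
    frac_global: float
    loglik: float
    degenerate: bool = False
    perm_p: float | None = None
    n_perm: int = 0

    def to_dict(self) -> dict:
        return {
            "sigma_local2": self.sigma_local2,
            "sigma_global2": self.sigma_global2,
            "sigma_e2": self.sigma_e2,
            "frac_local": self.frac_local,
            "frac_global": self.frac_global,
            "loglik": self.loglik,
            "degenerate": self.degenerate,
            "perm_p": self.perm_p,
            "n_perm": self.n_perm,
        }


def _reml_neg_loglik(
    ratios: np.ndarray,
    y: np.ndarray,
    k_local: np.ndarray,
    k_global: np.ndarray | None,
) -> float:
    """-2x restricted log-likelihood profiled over the intercept and scale.

    ``ratios`` are log variance ratios (local, global) relative to the
    residual; a single-element vector fits the local component only.
    """
    n = y.shape[0]
    v_l = np.exp(np.clip(ratios[0], *_LOG_RATIO_BOUNDS))
    h = v_l * k_local + np.eye(n)
    if k_global is not None:
        v_g = np.exp(np.clip(ratios[1], *_LOG_RATIO_BOUNDS))
        h = h + v_g * k_global
    try:
        c, low = linalg.cho_factor(h, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return 1e30
    logdet_h = 2.0 * np.log(np.diag(c)).sum()
    ones = np.ones(n)
    hinv_y = linalg.cho_solve((c, low), y, check_finite=False)
    hinv_1 = linalg.cho_solve((c, low), ones, check_finite=False)
    xtx_h = ones @ hinv_1
    beta = (ones @ hinv_y) / xtx_h
    rss = max((y - beta) @ (hinv_y - beta * hinv_1), 1e-300)
    dof = n - 1
    sigma_e2 = rss / dof
    ll = -0.5 * (
        dof * np.log(2.0 * np.pi * sigma_e2)
        + logdet_h
        + np.log(xtx_h)
        - np.log(float(n))
        + dof
    )
    return -ll


def fit_two_vc(
    y: np.ndarray,
    k_local: KinshipMatrix | np.ndarray,
    k_global: KinshipMatrix | np.ndarray | None,
    n_restarts: int = 4,
    fix_global_zero: bool = False,
    scale: str | None = "gower",
) -> VarianceComponents:
    """REML fit of the local + global + residual decomposition.

    ``fix_global_zero=True`` (or ``k_global=None``) pins the global
    component at zero, reducing to the single-kinship model. Estimates are
    kept non-negative by optimizing log variance ratios. Near-identical
    kinship matrices make the split non-identifiable; the fit then carries
    ``degenerate=True``. By default each kinship is Gower-scaled (see
    :func:`gower_factor`) so component variances are on the trait-variance
    scale; ``scale=None`` fits on the raw matrices.
    """
    y = np.asarray(y, dtype=float)
    kl = k_local.values if isinstance(k_local, KinshipMatrix) else np.asarray(k_local, float)
    if k_global is None or fix_global_zero:
        kg = None
    else:
        kg = k_global.values if isinstance(k_global, KinshipMatrix) else np.asarray(k_global, float)
    if not np.any(kl):
        raise ValueError("k_local is identically zero")
    if scale == "gower":
        kl = kl * gower_factor(kl)
        if kg is not None:
            kg = kg * gower_factor(kg)
    elif scale is not None:
        raise ValueError(f"unknown kinship scaling {scale!r}")
    degenerate = False
    if kg is not None:
        rel = np.linalg.norm(kl - kg) / max(np.linalg.norm(kl), 1e-30)
        if rel < 1e-10:
            degenerate = True
            warnings.warn(
                "local and global kinship matrices coincide; the variance "
                "split is non-identifiable (boundary solution reported)",
                RuntimeWarning,
                stacklevel=2,
            )
    scale = y.std()
    if scale == 0:
        raise ValueError("trait is constant")
    ys = (y - y.mean()) / scale  # scale-free optimization; variances restored below

    best = None
    if kg is None:
        for t0 in (-2.3, 0.0, 2.3)[: max(n_restarts, 1)]:
            res = optimize.minimize_scalar(
                lambda t: _reml_neg_loglik(np.array([t]), ys, kl, None),
                bounds=_LOG_RATIO_BOUNDS,
                method="bounded",
            )
            if best is None or res.fun < best.fun:
                best = res
        ratios = np.array([best.x, -np.inf])
    else:
        for start in _STARTS[: max(n_restarts, 1)]:
            res = optimize.minimize(
                _reml_neg_loglik,
                np.asarray(start, dtype=float),
                args=(ys, kl, kg),
                method="Nelder-Mead",
                options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 400},
            )
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError("two-component REML failed to converge after restarts")
        ratios = np.clip(best.x, *_LOG_RATIO_BOUNDS)
    v_l = float(np.exp(ratios[0]))
    v_g = float(np.exp(ratios[1])) if np.isfinite(ratios[1]) else 0.0
    # recover sigma_e2 at the optimum on the standardized scale
    n = ys.shape[0]
    h = v_l * kl + np.eye(n) + (v_g * kg if kg is not None else 0.0)
    c, low = linalg.cho_factor(h, lower=True, check_finite=False)
    ones = np.ones(n)
    hinv_y = linalg.cho_solve((c, low), ys, check_finite=False)
    hinv_1 = linalg.cho_solve((c, low), ones, check_finite=False)
    beta = (ones @ hinv_y) / (ones @ hinv_1)
    rss = (ys - beta) @ (hinv_y - beta * hinv_1)
    sigma_e2 = max(rss / (n - 1), 1e-30) * scale**2
    s_l, s_g = v_l * sigma_e2, v_g * sigma_e2
    total = s_l + s_g + sigma_e2
    return VarianceComponents(
        sigma_local2=s_l,
        sigma_global2=s_g,
        sigma_e2=sigma_e2,
        frac_local=s_l / total,
        frac_global=s_g / total,
        loglik=-float(best.fun),
        degenerate=degenerate,
    )


def vc_permutation_test(
    y: np.ndarray,
    k_local: KinshipMatrix | np.ndarray,
    k_global: KinshipMatrix | np.ndarray | None,
    n_perm: int = 1000,
    seed: int = 0,
    n_restarts: int = 2,
) -> VarianceComponents:
    """Permutation significance of the local variance fraction.

    Line labels of ``y`` are permuted against both kinship matrices jointly;
    the null distribution of ``frac_local`` gives
    ``p = (1 + #{perm >= observed}) / (n_perm + 1)``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    y = np.asarray(y, dtype=float)
    obs = fit_two_vc(y, k_local, k_global, n_restarts=n_restarts)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        vc = fit_two_vc(y[rng.permutation(y.shape[0])], k_local, k_global, n_restarts=n_restarts)
        if vc.frac_local >= obs.frac_local:
            n_ge += 1
    obs.perm_p = (1.0 + n_ge) / (n_perm + 1.0)
    obs.n_perm = n_perm
    return obs


def vc_scan(
    expr: pd.DataFrame,
    gene_annotations: pd.DataFrame,
    g: GenotypeMatrix,
    flank: int = 15_000,
    explain_threshold: float = 0.1,
    k_global: KinshipMatrix | None = None,
    n_restarts: int = 2,
) -> tuple[pd.DataFrame, pd.Series]:
    """All-pairs local-variance scan across traits and gene windows.

    For every (expression trait, gene window) pair the local kinship is
    built from the SNPs within ``flank`` of the window gene and
    ``frac_local`` of that trait is estimated (the diagonal is the cis
    effect). Returns the trait x window fraction matrix and, per window,
    the count of traits whose fraction exceeds ``explain_threshold``.
    Windows without SNPs are skipped (column dropped) and logged.
    """
    if k_global is None:
        k_global = ibs_kinship(g)
    frac = pd.DataFrame(
        np.nan, index=expr.columns, columns=gene_annotations.index, dtype=float
    )
    for gene, row in gene_annotations.iterrows():
        try:
            window = local_window(g, (row["chrom"], int(row["start"]), int(row["end"])), flank)
        except EmptyResultError:
            logger.warning("no SNPs in window of %s; skipped", gene)
            frac.drop(columns=gene, inplace=True)
            continue
        kl = ibs_kinship(window)
        for trait in expr.columns:
            vc = fit_two_vc(
                expr[trait].to_numpy(dtype=float), kl, k_global, n_restarts=n_restarts
            )
            frac.loc[trait, gene] = vc.frac_local
    counts = (frac > explain_threshold).sum(axis=0)
    counts.name = f"n_traits_gt_{explain_threshold:g}"
    return frac, counts
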