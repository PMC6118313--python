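"""Mixed-model mediation: direct and expression-mediated genetic effects.

A focal SNP ``x`` may influence a phenotype ``y`` both directly and through
a mediating gene-expression level ``m``. The two-equation model is::

    M = x b1 + Z g1 + eM        (mediator equation)
    Y = x b2 + M t1 + Z g2 + eY (outcome equation)

with ``Z g`` the polygenic background, modelled as a random effect with
covariance proportional to the kinship matrix ``K = Z Z'``; the background-
to-noise ratios ``lambda1 = s1^2/sM^2`` and ``lambda2 = s2^2/sY^2`` are
estimated per equation by REML. In this no-interaction linear model the
counterfactual natural direct and indirect effects have the closed forms
``NDE = b2 (x - x*)`` and ``NIE = b1 t1 (x - x*)``, identical to the
classical pathway-analysis decomposition, and the total effect is their
sum. Significance of the indirect effect (null ``b1 = 0``) is assessed by
permuting the mediator across lines while keeping phenotype, genotype and
kinship fixed, refitting the mediator equation each time.

Omitting the kinship term (``k=None``) gives the naive linear-model (LM)
variant, whose estimates are biased when the genetic background confounds
both mediator and phenotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype import DegenerateInputError, KinshipMatrix, standardize
from .lmm import (
    LMMFit,
    SpectralBasis,
    eigendecompose_kinship,
    fit_lmm_rotated,
    identity_basis,
    profile_loglik,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MediationFit",
    "MediationEffects",
    "fit_mediation",
    "natural_effects",
    "indirect_permutation_test",
    "mediator_scan",
]

PROP_TOTAL_TOL = 1e-8


@dataclass
class MediationFit:
    """Estimates from the two mediation equations (one shared kinship basis)."""

    beta1: float
    beta2: float
    theta1: float
    se_beta1: float
    se_beta2: float
    se_theta1: float
    lambda1: float
    lambda2: float
    sigma_m2: float
    sigma_y2: float
    adjusted: bool
    cov_beta2_theta1: float = 0.0
    loglik_m: float = float("nan")
    loglik_y: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "beta1": self.beta1,
            "beta2": self.beta2,
            "theta1": self.theta1,
            "se_beta1": self.se_beta1,
            "se_beta2": self.se_beta2,
            "se_theta1": self.se_theta1,
            "lambda1": self.lambda1,
            "lambda2": self.lambda2,
            "sigma_m2": self.sigma_m2,
            "sigma_y2": self.sigma_y2,
            "adjusted": self.adjusted,
        }


@dataclass
class MediationEffects:
    """Natural effects derived from a :class:`MediationFit`."""

    nde: float
    nie: float
    total: float
    prop_mediated: float
    prop_defined: bool
    inconsistent: bool
    contrast: float = 1.0
    perm_p: float | None = None
    n_perm: int = 0

    def to_dict(self) -> dict:
        return {
            "nde": self.nde,
            "nie": self.nie,
            "total": self.total,
            "prop_mediated": self.prop_mediated,
            "prop_defined": self.prop_defined,
            "inconsistent": self.inconsistent,
            "contrast": self.contrast,
            "perm_p": self.perm_p,
            "n_perm": self.n_perm,
        }


def _prepare(
    y: np.ndarray,
    m: np.ndarray,
    x: np.ndarray,
    standardize_inputs: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    m = np.asarray(m, dtype=float)
    x = np.asarray(x, dtype=float)
    if not (y.shape == m.shape == x.shape):
        raise ValueError("y, m, x must have matching lengths")
    if np.ptp(x) == 0:
        raise DegenerateInputError("focal SNP x is constant")
    if np.ptp(m) == 0:
        raise DegenerateInputError("mediator m is constant")
    r = np.corrcoef(x, m)[0, 1]
    if abs(r) > 0.999:
        raise DegenerateInputError(
            f"x and m are collinear (|cor| = {abs(r):.4f}); direct and "
            "indirect effects are not identifiable"
        )
    if standardize_inputs:
        y, m, x = standardize(y), standardize(m), standardize(x)
    return y, m, x


def _basis_for(k: KinshipMatrix | SpectralBasis | None, n: int) -> tuple[SpectralBasis, bool]:
    if k is None:
        return identity_basis(n), False
    if isinstance(k, SpectralBasis):
        return k, True
    return eigendecompose_kinship(k), True


def _fixed_lambda_fit(y_rot: np.ndarray, x_rot: np.ndarray, ev: np.ndarray) -> LMMFit:
    """Ordinary GLS at lambda = 0 (the unadjusted LM limit)."""
    ll, beta, sigma_e2 = profile_loglik(y_rot, x_rot, ev, np.array([0.0]), "REML")
    n, q = x_rot.shape
    cov = sigma_e2[0] * np.linalg.inv(x_rot.T @ x_rot)
    return LMMFit(
        beta=beta[0],
        se=np.sqrt(np.diag(cov)),
        lambda_=0.0,
        sigma_g2=0.0,
        sigma_e2=float(sigma_e2[0]),
        loglik=float(ll[0]),
        method="REML",
        df=n - q,
    )


def fit_mediation(
    y: np.ndarray,
    m: np.ndarray,
    x: np.ndarray,
    k: KinshipMatrix | SpectralBasis | None = None,
    standardize_inputs: bool = True,
    method: str = "REML",
) -> MediationFit:
    """Fit the mediator and outcome equations.

    With ``k`` given (kinship matrix or precomputed spectral basis) each
    equation is an LMM whose variance ratio is estimated by REML; with
    ``k=None`` both equations are ordinary regressions. Inputs are each
    standardized (mean 0, population SD 1) by default so effects are on a
    common scale and the proportion mediated is scale-free.
    """
    y, m, x = _prepare(y, m, x, standardize_inputs)
    n = y.shape[0]
    basis, adjusted = _basis_for(k, n)
    ones = np.ones(n)
    xm_design = np.column_stack([ones, x])
    ym_design = np.column_stack([ones, x, m])
    if adjusted:
        xr = basis.rotate(xm_design)
        yr_design = basis.rotate(ym_design)
        fit_m = fit_lmm_rotated(basis.rotate(m), xr, basis.eigenvalues, method)
        fit_y = fit_lmm_rotated(basis.rotate(y), yr_design, basis.eigenvalues, method)
    else:
        fit_m = _fixed_lambda_fit(m, xm_design, np.ones(n))
        fit_y = _fixed_lambda_fit(y, ym_design, np.ones(n))
    # covariance between the direct effect and the mediator slope (outcome eq.)
    if adjusted:
        winv = 1.0 / (fit_y.lambda_ * basis.eigenvalues + 1.0)
        d = basis.rotate(ym_design)
        cov_y = fit_y.sigma_e2 * np.linalg.inv((d * winv[:, None]).T @ d)
    else:
        cov_y = fit_y.sigma_e2 * np.linalg.inv(ym_design.T @ ym_design)
    return MediationFit(
        beta1=float(fit_m.beta[1]),
        beta2=float(fit_y.beta[1]),
        theta1=float(fit_y.beta[2]),
        se_beta1=float(fit_m.se[1]),
        se_beta2=float(fit_y.se[1]),
        se_theta1=float(fit_y.se[2]),
        lambda1=fit_m.lambda_ if adjusted else 0.0,
        lambda2=fit_y.lambda_ if adjusted else 0.0,
        sigma_m2=fit_m.sigma_e2,
        sigma_y2=fit_y.sigma_e2,
        adjusted=adjusted,
        cov_beta2_theta1=float(cov_y[1, 2]),
        loglik_m=fit_m.loglik,
        loglik_y=fit_y.loglik,
    )


def natural_effects(fit: MediationFit, contrast: float = 1.0) -> MediationEffects:
    """Natural direct/indirect effects for an exposure contrast ``x - x*``.

    ``NDE = b2 * contrast``; ``NIE = b1 * t1 * contrast``; the proportion
    mediated is NIE / (NDE + NIE), undefined when the total effect is
    numerically zero and flagged "inconsistent" when NDE and NIE have
    opposite signs (the ratio then falls outside [0, 1]).
    """
    nde = fit.beta2 * contrast
    nie = fit.beta1 * fit.theta1 * contrast
    total = nde + nie
    defined = abs(total) > PROP_TOTAL_TOL
    prop = nie / total if defined else float("nan")
    if fit.beta1 == 0.0 and defined:
        prop = 0.0
    inconsistent = defined and (nde * nie < 0)
    return MediationEffects(
        nde=nde,
        nie=nie,
        total=total,
        prop_mediated=prop,
        prop_defined=defined,
        inconsistent=inconsistent,
        contrast=contrast,
    )


# coarse grid + two zoom rounds: cheap enough to re-estimate lambda for
# every permutation while staying within ~1% of the fine-grid optimum
_PERM_GRID = np.logspace(-5, 5, 41)


def _refit_abs_beta1(
    m_rot: np.ndarray,
    design_rot: np.ndarray,
    ev: np.ndarray,
    adjusted: bool,
) -> float:
    if not adjusted:
        _, beta, _ = profile_loglik(m_rot, design_rot, ev, np.array([0.0]), "REML")
        return abs(float(beta[0, 1]))
    grid = _PERM_GRID
    for _ in range(3):
        ll, beta, _ = profile_loglik(m_rot, design_rot, ev, grid, "REML")
        i = int(np.argmax(ll))
        best = abs(float(beta[i, 1]))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
        grid = np.logspace(np.log10(lo), np.log10(hi), 9)
    return best


def indirect_permutation_test(
    y: np.ndarray,
    m: np.ndarray,
    x: np.ndarray,
    k: KinshipMatrix | SpectralBasis | None = None,
    n_perm: int = 1500,
    seed: int = 0,
    standardize_inputs: bool = True,
) -> tuple[float, float]:
    """Permutation p-value for the indirect effect (null ``b1 = 0``).

    The mediator is permuted across lines ``n_perm`` times with phenotype,
    genotype and kinship fixed; only the mediator equation needs refitting
    because the null makes NIE vanish through ``b1``. The statistic is
    ``|b1_hat|`` and ``p = (1 + #{perm >= obs}) / (n_perm + 1)``.

    Returns ``(perm_p, observed |b1|)``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99 for a meaningful p-value")
    y, m, x = _prepare(y, m, x, standardize_inputs)
    n = y.shape[0]
    basis, adjusted = _basis_for(k, n)
    design = np.column_stack([np.ones(n), x])
    design_rot = basis.rotate(design) if adjusted else design
    ev = basis.eigenvalues
    m_rot = basis.rotate(m) if adjusted else m
    observed = _refit_abs_beta1(m_rot, design_rot, ev, adjusted)
    rng = np.random.default_rng(seed)
    n_ge = 0
    rot_t = basis.rotation.T if adjusted else None
    for _ in range(n_perm):
        perm = rng.permutation(n)
        mp = m[perm]
        mp_rot = rot_t @ mp if adjusted else mp
        stat = _refit_abs_beta1(mp_rot, design_rot, ev, adjusted)
        if stat >= observed:
            n_ge += 1
    p = (1.0 + n_ge) / (n_perm + 1.0)
    return p, observed


def mediator_scan(
    y: np.ndarray,
    expr: pd.DataFrame,
    x: np.ndarray,
    k: KinshipMatrix | SpectralBasis | None = None,
    alpha: float = 0.05,
    n_perm: int = 1500,
    seed: int = 0,
) -> pd.DataFrame:
    """Evaluate each expression trait as a candidate mediator of ``x``.

    Refits the mediation model with every column of ``expr`` in place of
    the mediator, derives the natural effects, and attaches the indirect-
    effect permutation p-value; ``significant`` flags ``perm_p <= alpha``.
    Per-candidate failures (constant or collinear mediators) are logged and
    skipped rather than aborting the scan.
    """
    if expr.shape[1] < 1:
        raise ValueError("need at least one candidate mediator")
    basis, _ = _basis_for(k, len(y))
    shared = basis if k is not None else None
    rows = []
    seeds = np.random.SeedSequence(seed).generate_state(expr.shape[1]) % (2**31)
    for j, gene in enumerate(expr.columns):
        mj = expr[gene].to_numpy(dtype=float)
        try:
            fit = fit_mediation(y, mj, x, shared)
            eff = natural_effects(fit)
            perm_p, _ = indirect_permutation_test(
                y, mj, x, shared, n_perm=n_perm, seed=int(seeds[j])
            )
        except DegenerateInputError as exc:
            logger.warning("skipping mediator %s: %s", gene, exc)
            continue
        rows.append(
            {
                "gene": gene,
                "beta1": fit.beta1,
                "beta2": fit.beta2,
                "theta1": fit.theta1,
                "nde": eff.nde,
                "nie": eff.nie,
                "total": eff.total,
                "prop_mediated": eff.prop_mediated,
                "perm_p": perm_p,
                "significant": perm_p <= alpha,
            }
        )
    return pd.DataFrame(rows).set_index("gene")
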