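"""Variance explained by the mediation model, and cross-dataset prediction.

The explained-variance partition uses the marginal r^2 for mixed models:
the variance of the fixed-effect linear predictor over the total of fixed,
kinship-attached and residual variance. It is computed for the full model
(SNP + mediator) and the SNP-only model; the mediator's SNP-independent
contribution is their difference. All variances use the population
(divisor-n) convention, so in the no-kinship limit the measure coincides
with the ordinary coefficient of determination.

Prediction transfers the fitted direct and mediator effects (b2, t1) to a
new panel of lines, assuming the genetic-background effects on mediator and
phenotype are proportional: the background is re-estimated on the target
panel as the BLUP of the random effect from an intercept-only mixed model
of the target mediator, and the predicted phenotype is
``b2 x_new + t1 m_new + background``. Whether the target panel carries any
kinship-attached mediator variance at all is tested by permutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genotype import KinshipMatrix
from .lmm import SpectralBasis, eigendecompose_kinship, fit_lmm_rotated
from .mediation import _basis_for, _prepare

__all__ = [
    "R2Partition",
    "PredictionResult",
    "partition_r2",
    "estimate_background",
    "background_permutation_test",
    "predict_phenotype",
]


@dataclass
class R2Partition:
    r2_total: float
    r2_snp: float
    r2_expression: float
    negative_expression_flag: bool

    def to_dict(self) -> dict:
        return {
            "r2_total": self.r2_total,
            "r2_snp": self.r2_snp,
            "r2_expression": self.r2_expression,
            "negative_expression_flag": self.negative_expression_flag,
        }


@dataclass
class PredictionResult:
    y_hat: np.ndarray
    r2_pred: float
    r2_model: float
    perm_p: float | None
    transferred: tuple[float, float]  # (beta2, theta1)

    def to_dict(self) -> dict:
        return {
            "r2_pred": self.r2_pred,
            "r2_model": self.r2_model,
            "perm_p": self.perm_p,
            "beta2": self.transferred[0],
            "theta1": self.transferred[1],
        }


def _marginal_r2(
    y: np.ndarray, design: np.ndarray, basis: SpectralBasis, adjusted: bool
) -> float:
    """Marginal (fixed-effects) r^2 of one LMM.

    Fixed-effect variance is the realized population variance of the linear
    predictor across lines. The kinship-attached variance counts only the
    centered structure of K (``sigma_g^2 tr(PKP)/(n-1)`` with P the
    centering projector): the constant allele-sharing baseline of an IBS
    matrix is absorbed by the intercept and contributes nothing to
    phenotypic variance across lines. Variances are normalized by the same
    divisor-n convention (REML estimates times (n-q)/n), which makes the
    no-kinship limit agree exactly with ordinary R^2.
    """
    n, q = design.shape
    if adjusted:
        fit = fit_lmm_rotated(basis.rotate(y), basis.rotate(design), basis.eigenvalues)
    else:
        from .mediation import _fixed_lambda_fit

        fit = _fixed_lambda_fit(y, design, np.ones(n))
    eta = design @ fit.beta
    var_f = eta.var()
    shrink = (n - q) / n  # REML -> divisor-n normalization
    # tr(PKP)/(n-1) from the spectral basis: tr(K) - n * mean(K)
    ev, ones_rot = basis.eigenvalues, basis.rotate(np.ones(n))
    centered_trace = ev.sum() - (ev * ones_rot**2).sum() / n
    var_g = fit.sigma_g2 * centered_trace / (n - 1) * shrink
    var_e = fit.sigma_e2 * shrink
    return float(var_f / (var_f + var_g + var_e))


def partition_r2(
    y: np.ndarray,
    m: np.ndarray,
    x: np.ndarray,
    k: KinshipMatrix | SpectralBasis | None = None,
    standardize_inputs: bool = True,
) -> R2Partition:
    """Explained-variance partition for the mediation model.

    ``r2_total`` is the marginal r^2 of the full model (SNP + mediator),
    ``r2_snp`` of the SNP-only model, and the mediator's SNP-independent
    share is defined by subtraction, ``r2_expression = r2_total - r2_snp``
    (which can come out negative in pathological fits; flagged, not
    clamped).
    """
    y, m, x = _prepare(y, m, x, standardize_inputs)
    n = y.shape[0]
    basis, adjusted = _basis_for(k, n)
    ones = np.ones(n)
    r2_total = _marginal_r2(y, np.column_stack([ones, x, m]), basis, adjusted)
    r2_snp = _marginal_r2(y, np.column_stack([ones, x]), basis, adjusted)
    r2_expr = r2_total - r2_snp
    return R2Partition(
        r2_total=r2_total,
        r2_snp=r2_snp,
        r2_expression=r2_expr,
        negative_expression_flag=r2_expr < 0,
    )


def _null_model(
    m_new: np.ndarray, basis: SpectralBasis
) -> tuple[np.ndarray, float, float]:
    """Intercept-only REML fit of the mediator; returns (BLUP, lambda, frac)."""
    n = m_new.shape[0]
    fit = fit_lmm_rotated(
        basis.rotate(m_new), basis.rotate(np.ones((n, 1))), basis.eigenvalues
    )
    resid = m_new - fit.beta[0]
    shrink = fit.lambda_ * basis.eigenvalues / (fit.lambda_ * basis.eigenvalues + 1.0)
    blup = basis.rotation @ (shrink * basis.rotate(resid))
    frac = fit.sigma_g2 / (fit.sigma_g2 + fit.sigma_e2)
    return blup, fit.lambda_, frac


def estimate_background(
    m_new: np.ndarray, k_new: KinshipMatrix | SpectralBasis
) -> np.ndarray:
    """Per-line BLUP of the polygenic background from the target mediator.

    Fits ``m_new = mu + u + e`` with ``u ~ N(0, sigma_g^2 K_new)`` by REML
    and returns ``E[u | m_new]``. With no structure (``K = I``) the variance
    ratio collapses to the boundary and the BLUP shrinks to ~0.
    """
    m_new = np.asarray(m_new, dtype=float)
    basis, _ = _basis_for(k_new, m_new.shape[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # boundary lambda is valid here
        blup, _, _ = _null_model(m_new, basis)
    return blup


def background_permutation_test(
    m_new: np.ndarray,
    k_new: KinshipMatrix | SpectralBasis,
    n_perm: int = 200,
    seed: int = 0,
) -> float:
    """One-sided permutation p for a positive background variance component.

    Permutes the target-mediator line labels against the kinship, refits the
    intercept-only model, and compares the kinship-attached variance
    fraction with the observed one.
    """
    m_new = np.asarray(m_new, dtype=float)
    basis, _ = _basis_for(k_new, m_new.shape[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        _, _, obs = _null_model(m_new, basis)
        rng = np.random.default_rng(seed)
        n_ge = 0
        for _ in range(n_perm):
            _, _, frac = _null_model(m_new[rng.permutation(m_new.shape[0])], basis)
            if frac >= obs:
                n_ge += 1
    return (1.0 + n_ge) / (n_perm + 1.0)


def predict_phenotype(
    x_new: np.ndarray,
    m_new: np.ndarray,
    transferred: tuple[float, float],
    background: np.ndarray,
    y_new: np.ndarray | None = None,
    k_new: KinshipMatrix | SpectralBasis | None = None,
    n_perm: int = 200,
    seed: int = 0,
) -> PredictionResult:
    """Predict the target phenotype from transferred (beta2, theta1).

    ``y_hat = beta2 * x_new + theta1 * m_new + background``; inputs must be
    on the training standardization convention (a warning is emitted when
    they are clearly not centered/scaled). Two accuracy measures are
    reported when ``y_new`` is provided: ``r2_pred``, the squared Pearson
    correlation of ``y_hat`` (including the background) with the observed
    phenotype, and ``r2_model``, the variance of the transferred
    fixed-effect predictor ``beta2 x + theta1 m`` over the variance of the
    observed phenotype — the explained-variation measure on the same
    marginal-r^2 scale as :func:`partition_r2`, hence directly comparable
    with the training ``r2_total``. The background variance component's
    permutation p is computed when ``k_new`` is given.
    """
    x_new = np.asarray(x_new, dtype=float)
    m_new = np.asarray(m_new, dtype=float)
    beta2, theta1 = transferred
    for name, v in (("x_new", x_new), ("m_new", m_new)):
        if abs(v.mean()) > 0.25 or not 0.5 < v.std() < 2.0:
            warnings.warn(
                f"{name} does not look standardized (mean {v.mean():.2f}, "
                f"sd {v.std():.2f}); transferred parameters assume the "
                "training standardization convention",
                RuntimeWarning,
                stacklevel=2,
            )
    fixed = beta2 * x_new + theta1 * m_new
    y_hat = fixed + np.asarray(background, dtype=float)
    r2_pred = float("nan")
    r2_model = float("nan")
    if y_new is not None:
        y_new = np.asarray(y_new, dtype=float)
        if y_hat.std() == 0:
            r2_pred = 0.0
        else:
            r2_pred = float(np.corrcoef(y_hat, y_new)[0, 1] ** 2)
        r2_model = float(fixed.var() / y_new.var())
    perm_p = None
    if k_new is not None:
        perm_p = background_permutation_test(m_new, k_new, n_perm=n_perm, seed=seed)
    return PredictionResult(
        y_hat=y_hat, r2_pred=r2_pred, r2_model=r2_model, perm_p=perm_p,
        transferred=(beta2, theta1),
    )
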