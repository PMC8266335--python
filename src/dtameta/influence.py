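"""Model diagnostics: leave-one-out influence, outliers, goodness of fit.

Influence is Cook's distance on the transformed 5-parameter scale
computed from leave-one-out refits against the full-fit observed
information.  Outliers are flagged from randomized-quantile residuals of
the two binomial margins against their marginal (prior-predictive)
distributions under the fitted model.  Goodness of fit / bivariate normality pairs the
Mahalanobis distances of the empirical-Bayes effects with chi-square(2)
plotting positions (a straight quantile-quantile relation supports the
bivariate-normal random-effects assumption).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import binom, chi2, norm

from . import bivariate_model as bm
from .study_data import StudyPanel

logger = logging.getLogger(__name__)

__all__ = ["InfluenceReport", "GofTable", "influence_analysis", "gof_normality"]


@dataclass
class InfluenceReport:
    study_id: list[str]
    cook_d: np.ndarray              # NaN where the leave-one-out refit failed
    resid_sens: np.ndarray          # randomized-quantile residuals
    resid_spec: np.ndarray
    flagged_outlier: np.ndarray     # |residual| > outlier_z on either margin
    flagged_influential: np.ndarray  # cook_d above its within-panel 0.9 quantile
    mahalanobis: np.ndarray
    chi2_quantiles: np.ndarray
    outlier_z: float
    influence_quantile: float


@dataclass
class GofTable:
    empirical: np.ndarray     # sorted squared Mahalanobis distances
    theoretical: np.ndarray   # chi-square(2) quantiles at plotting positions
    too_few_studies: bool


def _marginal_binom_cdf(count: np.ndarray, n: np.ndarray, mu: float,
                        sigma: float, n_quad: int = 41) -> np.ndarray:
    """CDF of the beta-binomial-like marginal count distribution.

    Integrates the binomial CDF over the logit-normal random effect by
    Gauss-Hermite quadrature; this is the distribution a study's count
    actually follows under the fitted hierarchical model.
    """
    z, w = np.polynomial.hermite.hermgauss(n_quad)
    x = mu + np.sqrt(2.0) * sigma * z
    wn = w / np.sqrt(np.pi)
    p = 1.0 / (1.0 + np.exp(-x))
    return binom.cdf(count[:, None], n[:, None], p[None, :]) @ wn


def _randomized_quantile(count: np.ndarray, n: np.ndarray, mu: float,
                         sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Randomized quantile residuals against the marginal count distribution.

    U is drawn uniformly between the marginal cdf just below and at the
    observed count, then mapped through the standard-normal quantile;
    under the model the residuals are exactly standard normal.  The
    marginal (prior-predictive) distribution is used rather than the
    empirical-Bayes point prediction, which tracks each study's own data
    and therefore cannot reveal outliers.
    """
    lo = _marginal_binom_cdf(count - 1, n, mu, sigma)
    hi = _marginal_binom_cdf(count, n, mu, sigma)
    u = rng.uniform(lo, hi)
    return norm.ppf(np.clip(u, 1e-12, 1 - 1e-12))


def _mahalanobis(effects: np.ndarray, p: bm.BivariateParams) -> np.ndarray:
    d = effects - np.array([p.mu_A, p.mu_B])
    Sinv = np.linalg.inv(p.cov)
    return np.einsum("ij,jk,ik->i", d, Sinv, d)


def influence_analysis(
    panel: StudyPanel,
    fit: bm.FitResult,
    n_quad: Optional[int] = None,
    seed: int = 0,
    outlier_z: float = 2.0,
    influence_quantile: float = 0.9,
) -> InfluenceReport:
    """Leave-one-out influence and outlier detection for every panel row.

    Cook's distance for row i is (theta_loo - theta_hat)' I(theta_hat)
    (theta_loo - theta_hat) on the transformed scale, with I the observed
    information of the full fit.  The randomized residual stream is
    seeded for reproducibility.
    """
    if not fit.converged:
        raise ValueError("influence analysis requires a converged fit")
    n_quad = n_quad or fit.n_quad
    K = len(panel)
    theta_hat = fit.params.to_transformed()
    if fit.vcov is not None:
        info = np.linalg.inv(fit.vcov)
    else:  # fall back: identity metric, distances still comparable
        logger.warning("no vcov: Cook's distances use an identity metric")
        info = np.eye(5)

    cook = np.full(K, np.nan)
    for i, row in enumerate(panel):
        loo = panel.drop(row.study_id)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f_i = bm.fit(loo, n_quad=n_quad, start=fit.params, compute_vcov=False)
            d = f_i.params.to_transformed() - theta_hat
            cook[i] = float(d @ info @ d)
        except Exception as e:  # refit failure: leave NaN, keep going
            logger.warning("leave-one-out refit failed for %s: %s", row.study_id, e)

    effects = bm.empirical_bayes_effects(panel, fit.params)
    tp, fp, fn, tn = panel.counts()
    rng = np.random.default_rng(seed)
    p = fit.params
    r_sens = _randomized_quantile(tp, tp + fn, p.mu_A, p.sigma_A, rng)
    r_spec = _randomized_quantile(tn, tn + fp, p.mu_B, p.sigma_B, rng)

    outlier = (np.abs(r_sens) > outlier_z) | (np.abs(r_spec) > outlier_z)
    finite = cook[np.isfinite(cook)]
    cut = np.quantile(finite, influence_quantile) if finite.size else np.nan
    influential = np.isfinite(cook) & (cook >= cut)

    d2 = _mahalanobis(effects, fit.params)
    pos = (np.arange(1, K + 1) - 0.5) / K
    return InfluenceReport(
        study_id=[r.study_id for r in panel],
        cook_d=cook,
        resid_sens=r_sens,
        resid_spec=r_spec,
        flagged_outlier=outlier,
        flagged_influential=influential,
        mahalanobis=d2,
        chi2_quantiles=chi2.ppf(pos, df=2),
        outlier_z=outlier_z,
        influence_quantile=influence_quantile,
    )


def gof_normality(panel: StudyPanel, fit: bm.FitResult) -> GofTable:
    """Quantile-quantile table for the bivariate-normality check.

    Squared Mahalanobis distances of the empirical-Bayes effects under the
    fitted random-effects distribution, sorted and paired with chi2(2)
    quantiles at plotting positions (i - 0.5)/K.
    """
    if not fit.converged:
        raise ValueError("goodness-of-fit requires a converged fit")
    p = fit.params
    if p.sigma_A <= bm.SIGMA_FLOOR * 1.01 or p.sigma_B <= bm.SIGMA_FLOOR * 1.01:
        raise ValueError("random-effects covariance is singular at the floor")
    K = len(panel)
    effects = bm.empirical_bayes_effects(panel, p)
    d2 = np.sort(_mahalanobis(effects, p))
    pos = (np.arange(1, K + 1) - 0.5) / K
    too_few = K < 5
    if too_few:
        logger.warning("only %d studies: normality check is uninformative", K)
    return GofTable(empirical=d2, theoretical=chi2.ppf(pos, df=2),
                    too_few_studies=too_few)
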