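"""Summary ROC curve: HSROC mapping, curve tracing, AUC and ellipses.

The bivariate random-effects model is algebraically equivalent to the
hierarchical summary ROC (HSROC) model; the accuracy and shape parameters

    Lambda = (sigma_B/sigma_A)^(1/2) * mu_A + (sigma_A/sigma_B)^(1/2) * mu_B
    beta   = ln(sigma_B / sigma_A)

define the summary curve

    logit(TPR) = mu_A + (sigma_A/sigma_B) * (logit(FPR) + mu_B),

which passes through the summary operating point
(1 - invlogit(mu_B), invlogit(mu_A)) by construction.  The AUC is the
trapezoidal integral of TPR over the full FPR range [0, 1] (a restricted
range around the observed FPRs is available via ``fpr_range``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import expit, logit
from scipy.stats import chi2

from .bivariate_model import BivariateParams, FitResult, SIGMA_FLOOR

logger = logging.getLogger(__name__)

__all__ = [
    "HSROCParams",
    "SROCCurve",
    "Ellipse",
    "to_hsroc",
    "from_hsroc",
    "sroc_curve",
    "auc",
    "regions",
]

_SLOPE_CAP = 1e3


@dataclass(frozen=True)
class HSROCParams:
    """Accuracy (Lambda), shape (beta) and threshold (Theta) parameters.

    Lambda and beta determine the summary curve; Theta locates the summary
    operating point along it and completes the invertible mapping from the
    bivariate means.
    """

    Lambda: float
    beta: float
    Theta: Optional[float] = None


@dataclass(frozen=True)
class SROCCurve:
    """Traced summary ROC curve on an FPR grid, with its AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    summary_point: tuple[float, float]  # (FPR, TPR)


@dataclass(frozen=True)
class Ellipse:
    """Closed boundary in (spec, sens) space."""

    spec: np.ndarray
    sens: np.ndarray


def to_hsroc(p: BivariateParams) -> HSROCParams:
    """Map bivariate parameters to the HSROC accuracy/shape pair."""
    if p.sigma_A <= SIGMA_FLOOR * 1.01 or p.sigma_B <= SIGMA_FLOOR * 1.01:
        logger.warning("sigma at floor: HSROC shape parameter is ill-determined")
    s = np.sqrt(p.sigma_B / p.sigma_A)
    lam = s * p.mu_A + p.mu_B / s
    theta = 0.5 * (s * p.mu_A - p.mu_B / s)
    return HSROCParams(Lambda=float(lam), beta=float(2.0 * np.log(s)),
                       Theta=float(theta))


def from_hsroc(h: HSROCParams, sigma_A: float, sigma_B: float) -> tuple[float, float]:
    """Invert :func:`to_hsroc` given the between-study SDs.

    With s = sqrt(sigma_B/sigma_A): Lambda = s*mu_A + mu_B/s and
    Theta = (s*mu_A - mu_B/s)/2, so mu_A = (Lambda/2 + Theta)/s and
    mu_B = (Lambda/2 - Theta)*s.
    """
    if h.Theta is None:
        raise ValueError("Theta is required to invert the HSROC mapping")
    s = np.sqrt(sigma_B / sigma_A)
    return float((0.5 * h.Lambda + h.Theta) / s), float((0.5 * h.Lambda - h.Theta) * s)


def sroc_curve(
    p: BivariateParams,
    n_grid: int = 2001,
    fpr_range: tuple[float, float] = (0.0, 1.0),
) -> SROCCurve:
    """Trace the Rutter-Gatsonis summary ROC curve on ``n_grid`` points.

    The slope sigma_A/sigma_B is capped at 1e3 to keep the trace finite
    when sigma_B sits at its floor.
    """
    if n_grid < 100:
        raise ValueError("n_grid must be >= 100")
    lo = max(fpr_range[0], 1e-12)
    hi = min(fpr_range[1], 1.0 - 1e-12)
    slope = p.sigma_A / p.sigma_B
    if slope > _SLOPE_CAP:
        logger.warning("SROC slope capped at %g (sigma_B near floor)", _SLOPE_CAP)
        slope = _SLOPE_CAP
    fpr = np.linspace(lo, hi, n_grid)
    tpr = expit(p.mu_A + slope * (logit(fpr) + p.mu_B))
    summary = (float(1.0 - expit(p.mu_B)), float(expit(p.mu_A)))
    curve = SROCCurve(fpr=fpr, tpr=tpr, auc=np.nan, summary_point=summary)
    return SROCCurve(fpr=fpr, tpr=tpr, auc=auc(curve), summary_point=summary)


def auc(curve: SROCCurve) -> float:
    """Trapezoidal area under the curve with endpoint limits (0,0), (1,1)."""
    d = np.diff(curve.tpr)
    if np.any(d < -1e-12):
        raise ValueError("curve is not monotone non-decreasing")
    fpr = np.concatenate([[0.0], curve.fpr, [1.0]])
    tpr = np.concatenate([[0.0], curve.tpr, [1.0]])
    return float(np.trapezoid(tpr, fpr))


def regions(
    fit: FitResult, level: float = 0.95, n_points: int = 361
) -> tuple[Ellipse, Ellipse]:
    """Confidence and prediction ellipses for the summary point.

    Both are Wald ellipses on the (mu_A, mu_B) plane mapped through the
    inverse logit into (spec, sens) space: the confidence ellipse uses the
    estimator covariance of the means, the prediction ellipse adds the
    between-study covariance Sigma (where a *new* study's pair is expected
    to fall).  ``level=0`` degenerates to the summary point.
    """
    if fit.vcov is None:
        raise ValueError("fit has no vcov; regions unavailable")
    if not 0.0 <= level < 1.0:
        raise ValueError("level must be in [0, 1)")
    p = fit.params
    centre = np.array([p.mu_A, p.mu_B])
    V = fit.vcov[:2, :2]
    c = chi2.ppf(level, df=2) if level > 0 else 0.0
    t = np.linspace(0.0, 2.0 * np.pi, n_points)
    circle = np.stack([np.cos(t), np.sin(t)])

    def ellipse(cov: np.ndarray) -> Ellipse:
        L = np.linalg.cholesky(cov)
        pts = centre[:, None] + np.sqrt(c) * (L @ circle)
        return Ellipse(spec=expit(pts[1]), sens=expit(pts[0]))

    return ellipse(V), ellipse(V + p.cov)
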