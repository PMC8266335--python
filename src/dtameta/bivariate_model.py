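"""Exact-binomial bivariate random-effects model for paired sens/spec pooling.

The model treats each study's latent (logit sensitivity, logit specificity)
pair as a draw from a bivariate normal with means ``(mu_A, mu_B)``,
standard deviations ``(sigma_A, sigma_B)`` and correlation ``rho``; the
observed counts are binomial given the latent probabilities, with no
normal approximation of within-study error:

    (a_i, b_i) ~ N2((mu_A, mu_B), Sigma)
    tp_i ~ Bin(tp_i + fn_i, invlogit(a_i))
    tn_i ~ Bin(tn_i + fp_i, invlogit(b_i))

The marginal likelihood integrates the latent pair out of each study's
contribution; this module evaluates that double integral by *adaptive*
Gauss-Hermite quadrature (nodes re-centred at the per-study posterior mode
and re-scaled by the local curvature), fits the five parameters by maximum
likelihood on an unconstrained transformed scale
``(mu_A, mu_B, log sigma_A, log sigma_B, atanh rho)``, and derives the
pooled summary measures (sensitivity, specificity, likelihood ratios,
diagnostic odds ratio) with delta-method Wald intervals.

Adaptive re-centring matters because a large study's integrand is a sharp
peak that may sit far from the population mean; a fixed prior-centred grid
would miss it entirely at practical node counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logit, logsumexp

from .study_data import StudyPanel

logger = logging.getLogger(__name__)

__all__ = [
    "BivariateParams",
    "FitResult",
    "SummaryMeasures",
    "loglikelihood",
    "fit",
    "summary_measures",
    "empirical_bayes_effects",
    "SIGMA_FLOOR",
]

#: lower bound for the between-study SDs; fits that hit it are flagged.
SIGMA_FLOOR = 1e-6
_RHO_BOUND = 7.0  # |atanh(rho)| bound, i.e. |rho| <= tanh(7) ~ 1 - 2e-6
_LOG_SIGMA_MAX = np.log(50.0)


@dataclass(frozen=True)
class BivariateParams:
    """Random-effects distribution on (logit sens, logit spec)."""

    mu_A: float
    mu_B: float
    sigma_A: float
    sigma_B: float
    rho: float

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.mu_A, self.mu_B, self.sigma_A, self.sigma_B, self.rho])):
            raise ValueError("parameters must be finite")
        if self.sigma_A <= 0 or self.sigma_B <= 0:
            raise ValueError("sigma_A and sigma_B must be > 0")
        if not -1 < self.rho < 1:
            raise ValueError("rho must lie strictly inside (-1, 1)")

    @property
    def cov(self) -> np.ndarray:
        off = self.rho * self.sigma_A * self.sigma_B
        return np.array([[self.sigma_A**2, off], [off, self.sigma_B**2]])

    def to_transformed(self) -> np.ndarray:
        return np.array([
            self.mu_A, self.mu_B,
            np.log(self.sigma_A), np.log(self.sigma_B),
            np.arctanh(self.rho),
        ])

    @staticmethod
    def from_transformed(theta: np.ndarray) -> "BivariateParams":
        return BivariateParams(
            mu_A=float(theta[0]), mu_B=float(theta[1]),
            sigma_A=float(np.exp(theta[2])), sigma_B=float(np.exp(theta[3])),
            rho=float(np.tanh(theta[4])),
        )


@dataclass
class FitResult:
    """ML fit of the bivariate model.

    ``vcov`` is the estimator covariance on the transformed scale
    (mu_A, mu_B, log sigma_A, log sigma_B, atanh rho); ``None`` when the
    observed information was not invertible.  ``boundary`` flags variance
    components at the floor or |rho| at its bound, where the transformed
    parameterisation degenerates.
    """

    params: BivariateParams
    vcov: Optional[np.ndarray]
    loglik: float
    n_studies: int
    converged: bool
    n_quad: int
    boundary: bool = False
    #: covariate offsets (delta_A, delta_B) for meta-regression fits.
    delta: Optional[tuple[float, float]] = None


@dataclass(frozen=True)
class SummaryMeasures:
    """Pooled accuracy measures with 95% Wald CIs (None when vcov missing)."""

    sens: float
    spec: float
    plr: float
    nlr: float
    dor: float
    sens_ci: Optional[tuple[float, float]] = None
    spec_ci: Optional[tuple[float, float]] = None
    plr_ci: Optional[tuple[float, float]] = None
    nlr_ci: Optional[tuple[float, float]] = None
    dor_ci: Optional[tuple[float, float]] = None


# --- likelihood machinery --------------------------------------------------

class _PanelArrays:
    """Pre-computed per-study quantities reused across likelihood calls."""

    def __init__(self, panel: StudyPanel):
        tp, fp, fn, tn = panel.counts()
        self.tp, self.fp, self.fn, self.tn = tp, fp, fn, tn
        self.n1 = tp + fn
        self.n2 = tn + fp
        self.lchoose1 = gammaln(self.n1 + 1) - gammaln(tp + 1) - gammaln(fn + 1)
        self.lchoose2 = gammaln(self.n2 + 1) - gammaln(tn + 1) - gammaln(fp + 1)
        # continuity-corrected observed logits: Newton start + moment starts
        self.ya = logit((tp + 0.5) / (self.n1 + 1.0))
        self.yb = logit((tn + 0.5) / (self.n2 + 1.0))
        self.K = len(tp)


def _quad_nodes(n_quad: int) -> tuple[np.ndarray, np.ndarray]:
    """Flattened 2-D Gauss-Hermite tensor grid (z_a, z_b) and log-weights.

    Log-weights already include the exp(z^2) de-weighting of the adaptive
    transform, i.e. log(w_i w_j) + z_i^2 + z_j^2.
    """
    z, w = np.polynomial.hermite.hermgauss(n_quad)
    lw = np.log(w)
    za, zb = np.meshgrid(z, z, indexing="ij")
    lw2 = lw[:, None] + lw[None, :] + za**2 + zb**2
    return np.stack([za.ravel(), zb.ravel()]), lw2.ravel()


def _precision(p: BivariateParams) -> tuple[float, float, float, float]:
    """(iaa, ibb, iab, log|Sigma|) of the random-effects covariance."""
    one_m_r2 = 1.0 - p.rho**2
    iaa = 1.0 / (p.sigma_A**2 * one_m_r2)
    ibb = 1.0 / (p.sigma_B**2 * one_m_r2)
    iab = -p.rho / (p.sigma_A * p.sigma_B * one_m_r2)
    logdet = 2.0 * (np.log(p.sigma_A) + np.log(p.sigma_B)) + np.log(one_m_r2)
    return iaa, ibb, iab, logdet


def _posterior_modes(
    arr: _PanelArrays, p: BivariateParams, mu_a: np.ndarray, mu_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-study mode of the joint (data x prior) density and its curvature.

    The objective is strictly concave in (a, b) (binomial log-likelihoods
    are concave in the logit; the Gaussian prior is concave), so a damped
    Newton iteration converges globally.  Returns the modes and the three
    entries (haa, hbb, hab) of the negative Hessian at the mode.
    """
    iaa, ibb, iab, _ = _precision(p)
    a = np.clip(arr.ya, -6, 6).copy()
    b = np.clip(arr.yb, -6, 6).copy()
    for _ in range(60):
        pa, pb = expit(a), expit(b)
        ga = arr.tp - arr.n1 * pa - (iaa * (a - mu_a) + iab * (b - mu_b))
        gb = arr.tn - arr.n2 * pb - (iab * (a - mu_a) + ibb * (b - mu_b))
        haa = arr.n1 * pa * (1 - pa) + iaa
        hbb = arr.n2 * pb * (1 - pb) + ibb
        hab = iab
        det = haa * hbb - hab * hab
        da = (hbb * ga - hab * gb) / det
        db = (haa * gb - hab * ga) / det
        np.clip(da, -2.0, 2.0, out=da)
        np.clip(db, -2.0, 2.0, out=db)
        a += da
        b += db
        if max(np.abs(ga).max(initial=0.0), np.abs(gb).max(initial=0.0)) < 1e-10:
            break
    pa, pb = expit(a), expit(b)
    haa = arr.n1 * pa * (1 - pa) + iaa
    hbb = arr.n2 * pb * (1 - pb) + ibb
    return a, b, haa, hbb, np.full_like(haa, iab)


def _study_logliks(
    arr: _PanelArrays,
    p: BivariateParams,
    nodes: np.ndarray,
    logw: np.ndarray,
    offsets: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Log marginal likelihood per study by adaptive Gauss-Hermite quadrature.

    ``offsets`` is an optional (K, 2) array of per-study shifts added to
    (mu_A, mu_B) -- the meta-regression channel.
    """
    mu_a = np.full(arr.K, p.mu_A)
    mu_b = np.full(arr.K, p.mu_B)
    if offsets is not None:
        mu_a = mu_a + offsets[:, 0]
        mu_b = mu_b + offsets[:, 1]
    iaa, ibb, iab, logdet = _precision(p)
    a0, b0, haa, hbb, hab = _posterior_modes(arr, p, mu_a, mu_b)

    # Cholesky of the inverse negative Hessian, closed form for 2x2:
    # Hinv = [[hbb, -hab], [-hab, haa]] / det
    det = haa * hbb - hab * hab
    l11 = np.sqrt(hbb / det)
    l21 = -hab / det / l11
    l22 = np.sqrt(haa / det - l21**2)

    s2 = np.sqrt(2.0)
    av = a0[:, None] + s2 * l11[:, None] * nodes[0][None, :]
    bv = b0[:, None] + s2 * (l21[:, None] * nodes[0][None, :] + l22[:, None] * nodes[1][None, :])

    # binomial terms in log space: log p = -log(1+e^-x), log(1-p) = -log(1+e^x)
    lpa = -np.logaddexp(0.0, -av)
    l1pa = -np.logaddexp(0.0, av)
    lpb = -np.logaddexp(0.0, -bv)
    l1pb = -np.logaddexp(0.0, bv)
    da = av - mu_a[:, None]
    db = bv - mu_b[:, None]
    lprior = (
        -0.5 * (iaa * da**2 + 2.0 * iab * da * db + ibb * db**2)
        - np.log(2.0 * np.pi) - 0.5 * logdet
    )
    lf = (
        arr.lchoose1[:, None] + arr.tp[:, None] * lpa + arr.fn[:, None] * l1pa
        + arr.lchoose2[:, None] + arr.tn[:, None] * lpb + arr.fp[:, None] * l1pb
        + lprior
    )
    return np.log(2.0) + np.log(l11 * l22) + logsumexp(logw[None, :] + lf, axis=1)


def loglikelihood(panel: StudyPanel, p: BivariateParams, n_quad: int = 21) -> float:
    """Exact-binomial bivariate log-likelihood of ``panel`` at ``p``.

    Evaluated by adaptive Gauss-Hermite quadrature with ``n_quad`` nodes
    per latent dimension (>= 5).
    """
    if len(panel) == 0:
        raise ValueError("panel is empty")
    if n_quad < 5:
        raise ValueError("n_quad must be >= 5")
    arr = _PanelArrays(panel)
    nodes, logw = _quad_nodes(n_quad)
    return float(_study_logliks(arr, p, nodes, logw).sum())


def empirical_bayes_effects(panel: StudyPanel, p: BivariateParams) -> np.ndarray:
    """Posterior modes of the latent (logit sens, logit spec) per study."""
    arr = _PanelArrays(panel)
    mu_a = np.full(arr.K, p.mu_A)
    mu_b = np.full(arr.K, p.mu_B)
    a, b, *_ = _posterior_modes(arr, p, mu_a, mu_b)
    return np.column_stack([a, b])


# --- fitting ---------------------------------------------------------------

def _moment_start(arr: _PanelArrays) -> np.ndarray:
    ya, yb = arr.ya, arr.yb
    sa = max(float(np.std(ya, ddof=1)) if arr.K > 1 else 0.5, 0.15)
    sb = max(float(np.std(yb, ddof=1)) if arr.K > 1 else 0.5, 0.15)
    if arr.K > 2 and np.std(ya) > 0 and np.std(yb) > 0:
        r = float(np.corrcoef(ya, yb)[0, 1])
        r = 0.0 if not np.isfinite(r) else float(np.clip(r, -0.9, 0.9))
    else:
        r = 0.0
    return np.array([ya.mean(), yb.mean(), np.log(sa), np.log(sb), np.arctanh(r)])


_BOUNDS = [
    (-20.0, 20.0), (-20.0, 20.0),
    (np.log(SIGMA_FLOOR), _LOG_SIGMA_MAX), (np.log(SIGMA_FLOOR), _LOG_SIGMA_MAX),
    (-_RHO_BOUND, _RHO_BOUND),
]


def _numeric_hessian(f, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of scalar ``f`` at ``x``."""
    n = len(x)
    h = step * (1.0 + np.abs(x))
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            if i == j:
                xp, xm = x.copy(), x.copy()
                xp[i] += h[i]
                xm[i] -= h[i]
                H[i, i] = (f(xp) - 2.0 * f0 + f(xm)) / h[i] ** 2
            else:
                xpp, xpm, xmp, xmm = x.copy(), x.copy(), x.copy(), x.copy()
                xpp[[i, j]] += [h[i], h[j]]
                xpm[[i, j]] += [h[i], -h[j]]
                xmp[[i, j]] += [-h[i], h[j]]
                xmm[[i, j]] -= [h[i], h[j]]
                H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (
                    4.0 * h[i] * h[j]
                )
    return H


def _optimize_with_restarts(nll, x0, bounds, n_params, max_restarts=3):
    """L-BFGS-B with deterministic jittered restarts.

    A successful run is preferred over a failed one even when the failed
    run stopped at a marginally lower objective; among equally successful
    runs the lower objective wins.
    """
    lo = [b[0] for b in bounds]
    hi = [b[1] for b in bounds]
    rng = np.random.default_rng(0)  # jitter is deterministic by design
    best = None
    for attempt in range(max_restarts + 1):
        xs = x0 if attempt == 0 else np.clip(
            x0 + rng.normal(0, 0.3, size=n_params), lo, hi
        )
        res = minimize(
            nll, xs, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 600, "ftol": 1e-11, "gtol": 1e-7},
        )
        if (
            best is None
            or (res.success and not best.success)
            or (res.success == best.success and res.fun < best.fun - 1e-9)
        ):
            best = res
        if best.success and attempt >= 1:
            break
        if attempt == 0 and best.success:
            break
    return best


def fit(
    panel: StudyPanel,
    n_quad: int = 21,
    start: Optional[BivariateParams] = None,
    compute_vcov: bool = True,
) -> FitResult:
    """Maximum-likelihood fit of the bivariate model.

    Quasi-Newton (L-BFGS-B) minimisation on the unconstrained transformed
    scale, with moment-estimate starting values and up to three jittered
    restarts if the first run does not converge.  ``vcov`` is the inverse
    of the numerically differentiated observed information.
    """
    if len(panel) < 2:
        raise ValueError("at least 2 studies are required for a model fit")
    if len(panel) < 4:
        warnings.warn(
            f"only {len(panel)} studies: between-study variance estimates "
            "are unstable",
            stacklevel=2,
        )
    arr = _PanelArrays(panel)
    nodes, logw = _quad_nodes(n_quad)

    def nll(theta: np.ndarray) -> float:
        p = BivariateParams.from_transformed(theta)
        return -float(_study_logliks(arr, p, nodes, logw).sum())

    x0 = start.to_transformed() if start is not None else _moment_start(arr)
    x0 = np.clip(x0, [b[0] for b in _BOUNDS], [b[1] for b in _BOUNDS])

    best = _optimize_with_restarts(nll, x0, _BOUNDS, n_params=5)
    theta = best.x
    converged = bool(best.success)
    if not converged:
        logger.warning(
            "fit did not fully converge (%s); returning best-found parameters",
            best.message,
        )

    p_hat = BivariateParams.from_transformed(theta)
    # below ~1e-4 on the logit scale the heterogeneity is indistinguishable
    # from zero and the log-sigma direction is flat
    boundary = (
        p_hat.sigma_A <= 1e-4
        or p_hat.sigma_B <= 1e-4
        or abs(theta[4]) >= _RHO_BOUND * 0.999
    )
    if boundary:
        logger.warning("fit at parameter boundary (sigma floor or |rho|->1)")

    vcov = None
    if compute_vcov:
        try:
            H = _numeric_hessian(nll, theta)
            vcov = np.linalg.inv(H)
            if not np.all(np.isfinite(vcov)) or np.any(np.diag(vcov) <= 0):
                raise np.linalg.LinAlgError("information not positive definite")
            vcov = 0.5 * (vcov + vcov.T)
        except np.linalg.LinAlgError:
            vcov = None
            warnings.warn(
                "observed information is not invertible; vcov unavailable",
                stacklevel=2,
            )

    return FitResult(
        params=p_hat,
        vcov=vcov,
        loglik=-float(best.fun),
        n_studies=len(panel),
        converged=converged,
        n_quad=n_quad,
        boundary=boundary,
    )


# --- summary measures ------------------------------------------------------

_Z95 = 1.959963984540054


def _wald(point: float, se: float) -> tuple[float, float]:
    return point - _Z95 * se, point + _Z95 * se


def summary_measures(fit_result: FitResult) -> SummaryMeasures:
    """Pooled sens/spec/PLR/NLR/DOR with delta-method 95% CIs.

    Proportions get logit-scale intervals; ratios get log-scale intervals.
    On the log scale the gradients with respect to (mu_A, mu_B) are
    closed-form: d log sens/d mu_A = 1 - sens, d log(1-spec)/d mu_B = spec,
    etc., so only the (mu_A, mu_B) block of ``vcov`` enters.
    """
    p = fit_result.params
    sens = float(expit(p.mu_A))
    spec = float(expit(p.mu_B))
    plr = sens / (1.0 - spec)
    nlr = (1.0 - sens) / spec
    dor = float(np.exp(p.mu_A + p.mu_B))

    if fit_result.vcov is None:
        return SummaryMeasures(sens=sens, spec=spec, plr=plr, nlr=nlr, dor=dor)

    V = fit_result.vcov[:2, :2]
    se_muA = float(np.sqrt(V[0, 0]))
    se_muB = float(np.sqrt(V[1, 1]))

    def ratio_ci(log_value: float, grad: np.ndarray) -> tuple[float, float]:
        se = float(np.sqrt(grad @ V @ grad))
        lo, hi = _wald(log_value, se)
        return float(np.exp(lo)), float(np.exp(hi))

    sens_ci = tuple(float(expit(v)) for v in _wald(p.mu_A, se_muA))
    spec_ci = tuple(float(expit(v)) for v in _wald(p.mu_B, se_muB))
    plr_ci = ratio_ci(np.log(plr), np.array([1.0 - sens, spec]))
    nlr_ci = ratio_ci(np.log(nlr), np.array([-sens, -(1.0 - spec)]))
    dor_ci = ratio_ci(np.log(dor), np.array([1.0, 1.0]))

    return SummaryMeasures(
        sens=sens, spec=spec, plr=plr, nlr=nlr, dor=dor,
        sens_ci=sens_ci, spec_ci=spec_ci, plr_ci=plr_ci, nlr_ci=nlr_ci,
        dor_ci=dor_ci,
    )


# --- meta-regression channel (used by the moderators module) ---------------

def fit_with_covariate(
    panel: StudyPanel,
    indicator: np.ndarray,
    n_quad: int = 21,
    start: Optional[FitResult] = None,
) -> FitResult:
    """Fit with additive (delta_A, delta_B) mean shifts for indicator==1 rows.

    Seven free parameters: the base five plus the two shifts.  Returns a
    :class:`FitResult` whose ``params`` hold the reference-level means and
    whose ``delta`` holds the shifts; ``vcov`` covers all 7 (transformed)
    parameters.
    """
    z = np.asarray(indicator, float)
    if z.shape != (len(panel),):
        raise ValueError("indicator must have one entry per panel row")
    if z.min() == z.max():
        raise ValueError("indicator must have both levels present")
    arr = _PanelArrays(panel)
    nodes, logw = _quad_nodes(n_quad)

    def nll(theta: np.ndarray) -> float:
        p = BivariateParams.from_transformed(theta[:5])
        offsets = np.column_stack([z * theta[5], z * theta[6]])
        return -float(_study_logliks(arr, p, nodes, logw, offsets=offsets).sum())

    if start is not None:
        x0 = np.concatenate([start.params.to_transformed(), [0.0, 0.0]])
    else:
        x0 = np.concatenate([_moment_start(arr), [0.0, 0.0]])
    bounds = _BOUNDS + [(-20.0, 20.0), (-20.0, 20.0)]
    x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
    best = _optimize_with_restarts(nll, x0, bounds, n_params=7)
    theta = best.x
    p_hat = BivariateParams.from_transformed(theta[:5])
    return FitResult(
        params=p_hat,
        vcov=None,
        loglik=-float(best.fun),
        n_studies=len(panel),
        converged=bool(best.success),
        n_quad=n_quad,
        boundary=abs(theta[4]) >= _RHO_BOUND * 0.999,
        delta=(float(theta[5]), float(theta[6])),
    )
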