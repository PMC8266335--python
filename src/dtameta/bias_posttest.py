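"""Publication-bias and clinical-utility tools: Deeks' test, Fagan updating,
likelihood-ratio scattergram.

Deeks' funnel-plot asymmetry test regresses the per-study log diagnostic
odds ratio on the inverse square root of the effective sample size
ESS = 4*n1*n2/(n1+n2) (n1 diseased, n2 non-diseased totals), weighting by
ESS; a slope significantly different from zero signals small-study
effects.  Fagan's nomogram is Bayes' theorem on the odds scale:
post-test odds = pre-test odds x likelihood ratio.  The scattergram
classifies a test by whether its PLR clears the conventional confirmation
line (10) and its NLR the exclusion line (0.1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import statsmodels.api as sm

from .bivariate_model import SummaryMeasures
from .study_data import StudyPanel, observed_rates

__all__ = [
    "DeeksResult",
    "FaganResult",
    "ScattergramResult",
    "deeks_test",
    "fagan",
    "scattergram",
]


@dataclass(frozen=True)
class DeeksResult:
    slope: float
    intercept: float
    t: float
    df: int
    p: float
    ess: np.ndarray


@dataclass(frozen=True)
class FaganResult:
    pretest: float
    posttest_plr: float
    posttest_nlr: float


@dataclass(frozen=True)
class ScattergramResult:
    """Quadrant classification of the pooled likelihood-ratio pair.

    ``quadrant`` is one of 'both' (confirmation and exclusion),
    'confirmation_only', 'exclusion_only', 'neither'; boundaries fall to
    the weaker category (strict inequalities).  ``study_quadrants`` labels
    the per-study points the same way when a panel was supplied.
    """

    quadrant: str
    plr_threshold: float
    nlr_threshold: float
    study_quadrants: Optional[list[str]] = None


def deeks_test(panel: StudyPanel, cc: float = 0.5) -> DeeksResult:
    """Deeks' funnel-plot asymmetry test.

    Weighted least squares of lnDOR_i on 1/sqrt(ESS_i) with weights ESS_i;
    t tests H0: slope = 0 on n-2 df.
    """
    n = len(panel)
    if n < 3:
        raise ValueError("Deeks' test requires at least 3 studies")
    lndor = np.array([observed_rates(s, cc=cc)[4] for s in panel])
    n1 = np.array([s.n_diseased for s in panel], float)
    n2 = np.array([s.n_nondiseased for s in panel], float)
    ess = 4.0 * n1 * n2 / (n1 + n2)
    x = 1.0 / np.sqrt(ess)
    if np.ptp(x) == 0.0 or np.ptp(lndor) == 0.0:
        raise ValueError("degenerate design: regressor or response has no spread")
    res = sm.WLS(lndor, sm.add_constant(x), weights=ess).fit()
    return DeeksResult(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        t=float(res.tvalues[1]),
        df=n - 2,
        p=float(res.pvalues[1]),
        ess=ess,
    )


def fagan(pretest: float, plr: float, nlr: float) -> FaganResult:
    """Post-test probabilities after a positive (PLR) or negative (NLR) result."""
    if not 0.0 < pretest < 1.0:
        raise ValueError("pretest probability must lie strictly in (0, 1)")
    if plr <= 0 or nlr <= 0:
        raise ValueError("likelihood ratios must be positive")
    odds = pretest / (1.0 - pretest)
    return FaganResult(
        pretest=pretest,
        posttest_plr=odds * plr / (1.0 + odds * plr),
        posttest_nlr=odds * nlr / (1.0 + odds * nlr),
    )


def _quadrant(plr: float, nlr: float, plr_thr: float, nlr_thr: float) -> str:
    confirm = plr > plr_thr
    exclude = nlr < nlr_thr
    if confirm and exclude:
        return "both"
    if confirm:
        return "confirmation_only"
    if exclude:
        return "exclusion_only"
    return "neither"


def scattergram(
    measures: SummaryMeasures,
    plr_threshold: float = 10.0,
    nlr_threshold: float = 0.1,
    panel: Optional[StudyPanel] = None,
    cc: float = 0.5,
) -> ScattergramResult:
    """Classify the pooled (and optionally per-study) LR pairs into quadrants."""
    if plr_threshold <= 0 or nlr_threshold <= 0:
        raise ValueError("thresholds must be positive")
    study_q = None
    if panel is not None:
        study_q = []
        for s in panel:
            sens, spec, *_ = observed_rates(s, cc=cc)
            sens = min(max(sens, 1e-12), 1 - 1e-12)
            spec = min(max(spec, 1e-12), 1 - 1e-12)
            study_q.append(
                _quadrant(sens / (1 - spec), (1 - sens) / spec,
                          plr_threshold, nlr_threshold)
            )
    return ScattergramResult(
        quadrant=_quadrant(measures.plr, measures.nlr, plr_threshold, nlr_threshold),
        plr_threshold=plr_threshold,
        nlr_threshold=nlr_threshold,
        study_quadrants=study_q,
    )
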