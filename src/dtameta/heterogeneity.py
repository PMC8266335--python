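"""Between-study heterogeneity (Cochran Q, I-squared) and threshold effect.

Q sums squared deviations of per-study logit proportions from their
inverse-variance weighted mean; I-squared expresses the excess of Q over
its degrees of freedom as a percentage of Q (floored at 0).  The threshold
effect -- studies trading sensitivity against specificity because they sit
at different positivity cutoffs -- is tested by the Spearman rank
correlation between sensitivity and the false-positive rate (1 - spec),
a positive correlation suggesting a threshold effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .study_data import StudyPanel, observed_rates

__all__ = ["HeterogeneityResult", "ThresholdResult", "cochran_q", "threshold_test"]


@dataclass(frozen=True)
class HeterogeneityResult:
    Q: float
    df: int
    p: float
    I2: float  # percentage in [0, 100]
    margin: str


@dataclass(frozen=True)
class ThresholdResult:
    r: float
    p: float
    n: int


def cochran_q(panel: StudyPanel, margin: str = "sensitivity", cc: float = 0.5) -> HeterogeneityResult:
    """Cochran's Q and I-squared for one margin on the logit scale.

    Per-study variance is the usual binomial logit variance
    (1/tp + 1/fn for sensitivity, 1/tn + 1/fp for specificity), with the
    continuity correction applied to zero-cell studies.
    """
    if margin not in ("sensitivity", "specificity"):
        raise ValueError("margin must be 'sensitivity' or 'specificity'")
    if len(panel) < 2:
        raise ValueError("Q test requires at least 2 studies")
    y, v = [], []
    for s in panel:
        _, _, lsens, lspec, _ = observed_rates(s, cc=cc)
        tp, fp, fn, tn = float(s.tp), float(s.fp), float(s.fn), float(s.tn)
        if min(tp, fp, fn, tn) == 0:
            tp, fp, fn, tn = tp + cc, fp + cc, fn + cc, tn + cc
        if margin == "sensitivity":
            y.append(lsens)
            v.append(1.0 / tp + 1.0 / fn)
        else:
            y.append(lspec)
            v.append(1.0 / tn + 1.0 / fp)
    y = np.asarray(y)
    w = 1.0 / np.asarray(v)
    ybar = float(np.sum(w * y) / np.sum(w))
    Q = float(np.sum(w * (y - ybar) ** 2))
    df = len(panel) - 1
    p = float(stats.chi2.sf(Q, df))
    I2 = float(max(0.0, (Q - df) / Q) * 100.0) if Q > 0 else 0.0
    return HeterogeneityResult(Q=Q, df=df, p=p, I2=I2, margin=margin)


def threshold_test(panel: StudyPanel, pair: str = "sens_fpr") -> ThresholdResult:
    """Spearman rank correlation test for a threshold effect.

    ``pair='sens_fpr'`` (default) correlates sensitivity with 1-specificity,
    where positive r indicates a threshold effect; ``pair='sens_spec'``
    flips the second margin's sign convention.  Ties get average ranks and
    the two-sided p comes from the t approximation on n-2 df.
    """
    if pair not in ("sens_fpr", "sens_spec"):
        raise ValueError("pair must be 'sens_fpr' or 'sens_spec'")
    n = len(panel)
    if n < 3:
        raise ValueError("threshold test requires at least 3 studies")
    sens = np.array([s.tp / (s.tp + s.fn) for s in panel])
    spec = np.array([s.tn / (s.tn + s.fp) for s in panel])
    other = 1.0 - spec if pair == "sens_fpr" else spec
    if np.all(sens == sens[0]) or np.all(other == other[0]):
        raise ValueError("correlation undefined: one margin is constant")
    r, p = stats.spearmanr(sens, other)
    return ThresholdResult(r=float(r), p=float(p), n=n)
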