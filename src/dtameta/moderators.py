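"""Subgroup refits and univariable bivariate meta-regression.

Subgroup analysis refits the full bivariate model within each level of a
dichotomised covariate and reports pooled measures plus the SROC AUC per
level.  Meta-regression adds the covariate additively to both latent
means (two extra parameters) and compares against the base model with a
likelihood-ratio test on 2 df; the drop in each between-study variance
component is reported as percentage of heterogeneity explained.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import chi2

from . import bivariate_model as bm
from . import sroc as sroc_mod
from .study_data import StudyPanel, covariate_level, subgroup_levels

logger = logging.getLogger(__name__)

__all__ = [
    "SubgroupLevel",
    "SubgroupReport",
    "MetaRegResult",
    "subgroup_analysis",
    "meta_regression",
]


@dataclass
class SubgroupLevel:
    level: str
    n_rows: int
    measures: Optional[bm.SummaryMeasures]
    auc: Optional[float]
    unstable: bool = False  # < 4 rows: variance (hence CI) estimates unreliable
    note: str = ""


@dataclass
class SubgroupReport:
    variable: str
    levels: dict[str, SubgroupLevel]
    dropped: list[str]  # study_ids with the covariate missing


@dataclass(frozen=True)
class MetaRegResult:
    covariate: str
    lr_stat: float
    p: float
    var_explained_sens: float  # percentage in [0, 100]
    var_explained_spec: float
    delta: tuple[float, float]  # additive shifts on (mu_A, mu_B)
    n_rows: int


def subgroup_analysis(panel: StudyPanel, variable: str, n_quad: int = 21) -> SubgroupReport:
    """Refit the bivariate model within each level of ``variable``.

    Levels with < 2 rows are skipped (logged); levels with 2-3 rows are
    fitted but flagged unstable, with CIs suppressed.
    """
    levels, dropped = subgroup_levels(panel, variable)
    out: dict[str, SubgroupLevel] = {}
    for lv, sub in levels.items():
        if len(sub) < 2:
            logger.info("subgroup %s=%s skipped: only %d row(s)", variable, lv, len(sub))
            out[lv] = SubgroupLevel(
                level=lv, n_rows=len(sub), measures=None, auc=None,
                note="skipped: fewer than 2 rows",
            )
            continue
        unstable = len(sub) < 4
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit_res = bm.fit(sub, n_quad=n_quad)
        meas = bm.summary_measures(fit_res)
        if unstable:
            meas = bm.SummaryMeasures(
                sens=meas.sens, spec=meas.spec, plr=meas.plr, nlr=meas.nlr,
                dor=meas.dor,
            )
        curve = sroc_mod.sroc_curve(fit_res.params)
        out[lv] = SubgroupLevel(
            level=lv, n_rows=len(sub), measures=meas, auc=curve.auc,
            unstable=unstable,
            note="point estimates only: fewer than 4 rows" if unstable else "",
        )
    return SubgroupReport(variable=variable, levels=out, dropped=dropped)


def meta_regression(panel: StudyPanel, covariate: str, n_quad: int = 21) -> MetaRegResult:
    """Univariable bivariate meta-regression on a dichotomised covariate.

    Rows with the covariate missing are dropped.  The covariate model
    shifts both latent means additively for the second (sorted) level;
    ``lr_stat = 2*(loglik_cov - loglik_base)`` is referred to chi2 on 2 df.
    """
    levels, dropped = subgroup_levels(panel, covariate)
    if len(levels) < 2:
        raise ValueError(
            f"covariate {covariate!r} has {len(levels)} non-missing level(s); "
            "need at least 2"
        )
    if len(levels) > 2:
        logger.info(
            "covariate %s has %d levels; contrasting first vs rest",
            covariate, len(levels),
        )
    if dropped:
        logger.info("meta_regression(%s): dropped %s (missing covariate)", covariate, dropped)
    keep = [r for r in panel if covariate_level(r, covariate) is not None]
    sub = StudyPanel(keep, label=f"{panel.label}[{covariate}]")
    level_names = sorted(levels)
    z = np.array(
        [0.0 if covariate_level(r, covariate) == level_names[0] else 1.0 for r in sub],
        float,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        base = bm.fit(sub, n_quad=n_quad, compute_vcov=False)
        cov = bm.fit_with_covariate(sub, z, n_quad=n_quad, start=base)
    if not base.converged:
        raise RuntimeError("base-model fit did not converge")
    if not cov.converged:
        raise RuntimeError("covariate-model fit did not converge")
    lr = 2.0 * (cov.loglik - base.loglik)
    if lr < -1e-6:
        logger.warning("negative LR statistic %.3g clipped to 0", lr)
    lr = max(lr, 0.0)

    def explained(s_base: float, s_cov: float) -> float:
        return float(np.clip(100.0 * (s_base**2 - s_cov**2) / s_base**2, 0.0, 100.0))

    return MetaRegResult(
        covariate=covariate,
        lr_stat=float(lr),
        p=float(chi2.sf(lr, df=2)),
        var_explained_sens=explained(base.params.sigma_A, cov.params.sigma_A),
        var_explained_spec=explained(base.params.sigma_B, cov.params.sigma_B),
        delta=cov.delta,
        n_rows=len(sub),
    )
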