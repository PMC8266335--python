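"""Synthetic study-panel generator with the model's assumed structure.

Each synthetic study draws its latent (logit sens, logit spec) pair from
the bivariate normal, its arm sizes from independent log-uniform
distributions, and its counts binomially given the latent probabilities --
exactly the generative process the pooling model assumes.  Optional
extras: an additive covariate shift on the means for a random subset of
studies (for meta-regression power/type-I studies), a publication
selection rule whose inclusion probability increases with the observed
lnDOR (small-study effects), and an explicit positivity-threshold
mechanism that couples sensitivity and the false-positive rate.

Defaults mirror the bundled prostate-DWI panel: means near logit(0.80)
and logit(0.86), between-study SDs 0.5, negative correlation -0.4, and
arm sizes log-uniform on [30, 600].  The latent draws are attached to the
returned panel (``panel.latents``) so that tests can check distributional
properties without deconvolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import expit

from .study_data import Study2x2, StudyPanel

__all__ = ["SyntheticConfig", "CovariateEffect", "SelectionRule",
           "generate", "generate_threshold_panel"]

_MAX_ATTEMPTS = 100_000


@dataclass(frozen=True)
class CovariateEffect:
    """Additive mean shift for a random fraction of studies.

    Studies assigned to the second level (probability ``p_level``) get
    (mu_A + shift_A, mu_B + shift_B); the level is recorded in the rows'
    ``design`` covariate (prospective = reference, retrospective = shifted)
    so downstream subgrouping works unchanged.
    """

    shift_A: float = 0.0
    shift_B: float = 0.0
    p_level: float = 0.5


@dataclass(frozen=True)
class SelectionRule:
    """Inclusion probability expit(strength * (lnDOR - center))."""

    strength: float = 1.0
    center: float = 0.0


@dataclass(frozen=True)
class SyntheticConfig:
    K: int = 30
    mu_A: float = 1.4
    mu_B: float = 1.8
    sigma_A: float = 0.5
    sigma_B: float = 0.5
    rho: float = -0.4
    #: log-uniform bounds on the diseased / non-diseased arm totals
    arm_range_diseased: tuple[int, int] = (30, 600)
    arm_range_nondiseased: tuple[int, int] = (30, 600)
    covariate: Optional[CovariateEffect] = None
    selection: Optional[SelectionRule] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.sigma_A < 0 or self.sigma_B < 0:
            raise ValueError("sigmas must be >= 0")
        if not -1 < self.rho < 1:
            raise ValueError("rho must lie in (-1, 1)")
        for lo, hi in (self.arm_range_diseased, self.arm_range_nondiseased):
            if not (1 <= lo <= hi):
                raise ValueError("arm ranges must satisfy 1 <= lo <= hi")


def _log_uniform(rng: np.random.Generator, lo: int, hi: int, size: int) -> np.ndarray:
    u = rng.uniform(math.log(lo), math.log(hi), size)
    return np.clip(np.rint(np.exp(u)).astype(int), lo, hi)


def _draw_latents(rng: np.random.Generator, cfg: SyntheticConfig, size: int) -> np.ndarray:
    cov = np.array([
        [cfg.sigma_A**2, cfg.rho * cfg.sigma_A * cfg.sigma_B],
        [cfg.rho * cfg.sigma_A * cfg.sigma_B, cfg.sigma_B**2],
    ])
    z = rng.standard_normal((size, 2))
    if cfg.sigma_A > 0 and cfg.sigma_B > 0:
        L = np.linalg.cholesky(cov)
        z = z @ L.T
    else:
        z = z * np.array([cfg.sigma_A, cfg.sigma_B])
    return z + np.array([cfg.mu_A, cfg.mu_B])


def _generate(cfg: SyntheticConfig, cutoff_sd: float = 0.0) -> StudyPanel:
    # two independent child streams so that adding the threshold mechanism
    # (or setting its strength to zero) never perturbs the base draws
    base_seed, cut_seed = np.random.SeedSequence(cfg.seed).spawn(2)
    rng = np.random.default_rng(base_seed)
    rng_cut = np.random.default_rng(cut_seed)

    rows: list[Study2x2] = []
    latents = np.empty((cfg.K, 2))
    attempts = 0
    k = 0
    while k < cfg.K:
        attempts += 1
        if attempts > _MAX_ATTEMPTS:
            raise RuntimeError(
                f"could not generate {cfg.K} studies in {_MAX_ATTEMPTS} attempts "
                "(selection rule too strict or arms degenerate)"
            )
        ab = _draw_latents(rng, cfg, 1)[0]
        level = 0
        if cfg.covariate is not None:
            level = int(rng.uniform() < cfg.covariate.p_level)
            if level:
                ab = ab + np.array([cfg.covariate.shift_A, cfg.covariate.shift_B])
        if cutoff_sd > 0.0:
            # per-study positivity cutoff: a lenient threshold raises both
            # sensitivity and the false-positive rate
            t = rng_cut.normal(0.0, cutoff_sd)
            ab = ab + np.array([t, -t])
        elif cutoff_sd == 0.0:
            pass
        n1 = int(_log_uniform(rng, *cfg.arm_range_diseased, 1)[0])
        n2 = int(_log_uniform(rng, *cfg.arm_range_nondiseased, 1)[0])
        tp = int(rng.binomial(n1, expit(ab[0])))
        tn = int(rng.binomial(n2, expit(ab[1])))
        if cfg.selection is not None:
            c = 0.5
            lndor = (
                math.log((tp + c) * (tn + c))
                - math.log((n2 - tn + c) * (n1 - tp + c))
            )
            keep = rng.uniform() < expit(
                cfg.selection.strength * (lndor - cfg.selection.center)
            )
            if not keep:
                continue
        rows.append(
            Study2x2(
                study_id=f"sim{k:04d}",
                author="sim",
                year=2020,
                b_value=2000,
                tp=tp, fp=n2 - tn, fn=n1 - tp, tn=tn,
                design="retrospective" if level else "prospective",
            )
        )
        latents[k] = ab
        k += 1
    panel = StudyPanel(rows, label=f"synthetic(seed={cfg.seed})")
    panel.latents = latents
    return panel


def generate(cfg: SyntheticConfig) -> StudyPanel:
    """Draw a synthetic panel from the bivariate binomial-normal model.

    Rows always satisfy the 2x2 invariants: arms are >= 1 by construction
    (counts may still be 0 or n, which the exact likelihood handles).
    The latent effects are exposed as ``panel.latents`` (K x 2).
    """
    return _generate(cfg)


def generate_threshold_panel(cfg: SyntheticConfig, threshold_strength: float) -> StudyPanel:
    """Panel with an induced threshold effect of the given strength.

    Each study receives a positivity-cutoff perturbation t ~ N(0,
    threshold_strength^2) added to its logit sensitivity and subtracted
    from its logit specificity, coupling sensitivity with the
    false-positive rate across studies.  Strength 0 reproduces
    :func:`generate` exactly under the same seed.
    """
    if threshold_strength < 0:
        raise ValueError("threshold_strength must be >= 0")
    return _generate(cfg, cutoff_sd=threshold_strength)
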