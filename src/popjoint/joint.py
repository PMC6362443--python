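"""Joint posterior combining the detection/non-detection and banding
likelihoods.

The two data types are assumed independent, so the joint posterior is the
product of the occupancy likelihood, the CJS likelihood and the priors,
with the shared apparent-survival block (b0..b4) entering both
likelihoods but its prior counted exactly once:

  [params, N, S, G, Z | Y_P, Y_B] ∝ [Y_P | N, p_P] [N_1 | lambda]
      [S | N, phi] [G | gamma] [Y_B | Z, p_B] [Z | phi] [priors]
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import expit

from .cjs import BandingData, alive_transition_loglik, band_obs_loglik
from .inference import PriorSpec
from .occupancy import (
    DetectionData,
    ModelParams,
    PopulationState,
    obs_loglik_total,
    state_loglik,
)

JointParams = ModelParams

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def _lnorm(x, mean, sd) -> float:
    z = (np.asarray(x, dtype=float) - mean) / sd
    return float(np.sum(-0.5 * z * z - math.log(sd) - _LOG_SQRT_2PI))


def shared_b_log_prior(params: ModelParams, priors: PriorSpec) -> float:
    """Log prior of the survival block both likelihood components share."""
    sd = priors.slope_sd()
    out = _lnorm(params.b0, 0.0, math.sqrt(priors.intercept_var_b0))
    for b in (params.b1, params.b2, params.b3, params.b4):
        out += _lnorm(b, 0.0, sd)
    return out


def log_prior(params: ModelParams, priors: PriorSpec, model: str) -> float:
    """Full log prior density for one model scope ('point', 'band',
    'joint'); the shared b block is counted once in every scope."""
    sd = priors.slope_sd()
    lo, hi = priors.sigma_bounds
    out = shared_b_log_prior(params, priors)
    if model in ("point", "joint"):
        for x in (params.a0, params.a1, params.a2, params.a3,
                  params.c0, params.c1, params.c2, params.c3, params.c4,
                  params.d1):
            out += _lnorm(x, 0.0, sd)
        out += _lnorm(params.d0, 0.0, math.sqrt(priors.intercept_var_d0))
        for scale, effs in ((params.sigma_a, params.a4),
                            (params.sigma_d, params.d2)):
            if not lo < scale < hi:
                return -np.inf
            out += -math.log(hi - lo)
            out += _lnorm(effs, 0.0, scale)
    if model in ("band", "joint"):
        if priors.e0_prior == "probability":
            p0 = expit(params.e0)
            out += math.log(p0) + math.log1p(-p0)   # logit Jacobian
        else:
            if not 0.0 <= params.e0 <= 1.0:
                return -np.inf
        out += _lnorm(params.e1, 0.0, sd)
    return out


def joint_log_posterior(occu_data: DetectionData | None,
                        band_data: BandingData | None,
                        design, covariates,
                        pop: PopulationState | None,
                        z: np.ndarray | None,
                        params: ModelParams,
                        priors: PriorSpec | None = None) -> float:
    """Unnormalized joint log posterior at one full state.

    Degenerates to the single-model log posterior when either data set is
    absent.  Any -inf component (invalid latent state, impossible
    observation) propagates.
    """
    priors = priors or PriorSpec()
    have_point = occu_data is not None
    have_band = band_data is not None and band_data.n_individuals > 0
    if have_point:
        model = "joint" if have_band else "point"
    else:
        model = "band"
    total = log_prior(params, priors, model)
    if have_point:
        if pop is None:
            raise ValueError("point-count component needs a PopulationState")
        total += state_loglik(pop, covariates, params)
        total += obs_loglik_total(occu_data, pop, design, covariates, params)
    if have_band:
        if z is None:
            raise ValueError("banding component needs an alive matrix z")
        total += alive_transition_loglik(z, band_data, covariates, params)
        total += band_obs_loglik(band_data.y, z, band_data, params)
    return float(total)
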