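"""State-space Cormack-Jolly-Seber model for annual banding data.

Conditional on each bird's first capture year f_i, the latent alive state
evolves as Z_{i,t} ~ Bernoulli(Z_{i,t-1} * phi_{jt}) with the same apparent
survival phi_jt that drives the occupancy state process (the shared block),
and resightings follow Y_{i,t} ~ Bernoulli(Z_{i,t} * p_{B,i}) with a
sex-specific logit-linear detection probability.  Individuals do not move
between sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .occupancy import ModelParams, phi_matrix

CjsParams = ModelParams  # same object: the b block exists exactly once


@dataclass
class BandingData:
    """Per-individual annual capture/resight histories.

    ``y``: (n_individuals, n_years) 0/1; entries before ``f`` are ignored.
    ``site``: home site index per individual; ``sex``: 0/1; ``f``: 0-based
    first-capture year with ``y[i, f[i]] == 1`` by definition.
    """

    y: np.ndarray
    site: np.ndarray
    sex: np.ndarray
    f: np.ndarray

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=np.int8)
        self.site = np.asarray(self.site, dtype=np.int64)
        self.sex = np.asarray(self.sex, dtype=np.int8)
        self.f = np.asarray(self.f, dtype=np.int64)

    def validate(self) -> None:
        n, T = self.y.shape
        for arr, name in ((self.site, "site"), (self.sex, "sex"), (self.f, "f")):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per individual")
        for i in range(n):
            if self.y[i, self.f[i]] != 1:
                raise ValueError(f"individual {i}: y at first capture must be 1")
            if self.y[i, : self.f[i]].any():
                raise ValueError(f"individual {i}: detection before first capture")

    @property
    def n_individuals(self) -> int:
        return self.y.shape[0]

    @property
    def n_years(self) -> int:
        return self.y.shape[1]


@dataclass
class LatentAlive:
    """Latent 0/1 alive matrix; 1 at first capture, non-increasing after."""

    z: np.ndarray

    def validate(self, data: BandingData) -> None:
        z = np.asarray(self.z)
        if z.shape != data.y.shape:
            raise ValueError("z must match the capture-history shape")
        for i in range(z.shape[0]):
            if z[i, data.f[i]] != 1:
                raise ValueError(f"individual {i}: z at first capture must be 1")
            zi = z[i, data.f[i]:]
            if (np.diff(zi.astype(int)) > 0).any():
                raise ValueError(f"individual {i}: dead birds cannot resurrect")


def band_detprob(data: BandingData, params: ModelParams) -> np.ndarray:
    """p_{B,i} = ilogit(e0 + e1 * sex_i) per individual."""
    return expit(params.e0 + params.e1 * data.sex.astype(float))


def alive_transition_loglik(z: np.ndarray, data: BandingData,
                            covariates, params: ModelParams) -> float:
    """Log mass of the alive-state transitions from f_i+1 onward.

    Resurrection (0 -> 1) yields -inf.
    """
    phi = phi_matrix(covariates, params)
    z = np.asarray(z)
    total = 0.0
    for i in range(data.n_individuals):
        j = data.site[i]
        for t in range(data.f[i] + 1, data.n_years):
            prob_alive = z[i, t - 1] * phi[j, t]
            if z[i, t] == 1:
                if prob_alive <= 0.0:
                    return -np.inf
                total += np.log(prob_alive)
            else:
                total += np.log1p(-prob_alive)
    return float(total)


def band_obs_loglik(y: np.ndarray, z: np.ndarray, data: BandingData,
                    params: ModelParams) -> float:
    """Log mass of resightings given alive states, for entries after f_i.

    A detection of a dead bird (y=1, z=0) yields -inf.
    """
    pB = band_detprob(data, params)
    y = np.asarray(y)
    z = np.asarray(z)
    total = 0.0
    for i in range(data.n_individuals):
        for t in range(data.f[i] + 1, data.n_years):
            pr = z[i, t] * pB[i]
            if y[i, t] == 1:
                if pr <= 0.0:
                    return -np.inf
                total += np.log(pr)
            else:
                total += np.log1p(-pr)
    return float(total)


def cjs_marginal_loglik(data: BandingData, covariates,
                        params: ModelParams) -> float:
    """Exact CJS log-likelihood with the alive matrix summed out.

    Standard two-state (alive/dead) forward recursion per individual,
    conditional on first capture.  Individuals first caught in the final
    year contribute probability one.
    """
    phi = phi_matrix(covariates, params)
    pB = band_detprob(data, params)
    total = 0.0
    for i in range(data.n_individuals):
        j = data.site[i]
        alive, dead = 1.0, 0.0
        for t in range(data.f[i] + 1, data.n_years):
            ph = phi[j, t]
            if data.y[i, t] == 1:
                alive, dead = alive * ph * pB[i], 0.0
            else:
                alive, dead = alive * ph * (1.0 - pB[i]), dead + alive * (1.0 - ph)
            if alive + dead <= 0.0:
                return -np.inf
        total += np.log(alive + dead) if data.f[i] < data.n_years - 1 else 0.0
    return float(total)
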