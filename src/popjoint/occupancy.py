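"""Dynamic N-occupancy model: latent-abundance state process and
detection/non-detection observation process.

The model is a state-space formulation for repeated binary detection
surveys.  Site abundance in the first year is Poisson; in later years it
decomposes into binomial survivors plus Poisson recruits,

    N_{j1} ~ Poisson(lambda_j)
    S_{jt} ~ Binomial(N_{j,t-1}, phi_{jt})
    G_{jt} ~ Poisson(gamma_{jt})
    N_{jt} = S_{jt} + G_{jt}          (t > 1)

and the observation layer follows the Royle–Nichols construction in which
the probability of detecting the species at all rises with local abundance,

    Y_{jkt} ~ Bernoulli(1 - (1 - p_{jkt})^{N_{jt}}).

All rates/probabilities are log- or logit-linear in site and site-year
covariates; transect and observer enter as normal random effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln, logit  # noqa: F401  (logit re-exported)
from scipy.stats import binom, poisson


class SimulationError(ValueError):
    """A linear predictor or state became non-finite / invalid."""


class InstanceTooLargeError(ValueError):
    """Brute-force marginalization refused: instance not tiny."""


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class ModelParams:
    """All regression coefficients and random-effect scales.

    Blocks: ``a`` (initial abundance), ``b`` (apparent survival, shared
    between the occupancy and the capture-recapture component), ``c``
    (recruitment), ``d`` (per-visit detection), ``e`` (band resighting).
    ``a4`` and ``d2`` are the transect and observer random-effect vectors
    with scales ``sigma_a`` and ``sigma_d``.  A single instance backs the
    point-count model, the banding model and the joint model, so the
    shared survival block exists exactly once.
    """

    a0: float = 0.0
    a1: float = 0.0
    a2: float = 0.0
    a3: float = 0.0
    a4: np.ndarray = field(default_factory=lambda: np.zeros(1))
    sigma_a: float = 0.5
    b0: float = 0.0
    b1: float = 0.0
    b2: float = 0.0
    b3: float = 0.0
    b4: float = 0.0
    c0: float = 0.0
    c1: float = 0.0
    c2: float = 0.0
    c3: float = 0.0
    c4: float = 0.0
    d0: float = 0.0
    d1: float = 0.0
    d2: np.ndarray = field(default_factory=lambda: np.zeros(1))
    sigma_d: float = 0.5
    e0: float = 0.0   # logit-scale baseline band-detection intercept
    e1: float = 0.0   # sex effect on band detection

    @classmethod
    def for_design(cls, design, **kw) -> "ModelParams":
        """Parameters sized to a study design (random effects default to 0)."""
        kw.setdefault("a4", np.zeros(design.n_transects))
        kw.setdefault("d2", np.zeros(design.n_observers))
        return cls(**kw)

    def copy(self) -> "ModelParams":
        import copy
        return copy.deepcopy(self)


# aliases matching the three model scopes; one class keeps a single copy of
# the shared survival (b) block by construction
OccuParams = ModelParams
JointParams = ModelParams


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class PopulationState:
    """Latent integer abundance trajectories per site and year.

    ``S`` and ``G`` are defined for year index >= 1 (column 0 unused, 0).
    Invariant: ``N[:, t] == S[:, t] + G[:, t]`` and ``S[:, t] <= N[:, t-1]``.
    """

    N: np.ndarray
    S: np.ndarray
    G: np.ndarray

    def validate(self) -> None:
        N, S, G = self.N, self.S, self.G
        if N.shape != S.shape or N.shape != G.shape:
            raise ValueError("N, S, G must share shape (n_sites, n_years)")
        if (N < 0).any() or (S[:, 1:] < 0).any() or (G[:, 1:] < 0).any():
            raise ValueError("abundance components must be nonnegative")
        if N.shape[1] > 1:
            if not np.array_equal(N[:, 1:], S[:, 1:] + G[:, 1:]):
                raise ValueError("N_jt must equal S_jt + G_jt for t > 1")


@dataclass
class DetectionData:
    """Binary site x session x year detection record.

    ``y`` holds 0/1 with -1 marking sessions that were never surveyed;
    the boolean ``sampled`` mask mirrors the -1 entries.
    """

    y: np.ndarray
    sampled: np.ndarray

    @classmethod
    def from_array(cls, y: np.ndarray) -> "DetectionData":
        y = np.asarray(y, dtype=np.int8)
        return cls(y=y, sampled=y >= 0)

    @property
    def n_sites(self) -> int:
        return self.y.shape[0]

    @property
    def n_sessions(self) -> int:
        return self.y.shape[1]

    @property
    def n_years(self) -> int:
        return self.y.shape[2]


# ---------------------------------------------------------------------------
# link-scale operations (scalar spec surface + vectorized internals)
# ---------------------------------------------------------------------------

def _check_finite(x: np.ndarray, label: str) -> np.ndarray:
    if not np.all(np.isfinite(x)):
        raise SimulationError(f"non-finite linear predictor in {label} block")
    return x


def lambda_vector(covariates, params: ModelParams) -> np.ndarray:
    """Expected initial abundance lambda_j for every site (year 1)."""
    c = covariates
    lp = (
        params.a0
        + params.a1 * c.dnbr
        + params.a2 * c.nbox
        + params.a3 * c.tfire[:, 0]
        + params.a4[c.transect]
    )
    return np.exp(_check_finite(lp, "a"))


def phi_matrix(covariates, params: ModelParams) -> np.ndarray:
    """Apparent survival phi_jt for the interval ending in year t (t >= 1).

    Column 0 is NaN: no interval precedes the first year.
    """
    c = covariates
    lp = (
        params.b0
        + params.b1 * c.nbox[:, None]
        + params.b2 * c.tfire
        + params.b3 * c.live
        + params.b4 * c.snag
    )
    out = expit(_check_finite(lp, "b"))
    out[:, 0] = np.nan
    return out


def gamma_matrix(covariates, params: ModelParams) -> np.ndarray:
    """Expected recruits gamma_jt gained between year t-1 and t (t >= 1)."""
    c = covariates
    lp = (
        params.c0
        + params.c1 * c.nbox[:, None]
        + params.c2 * c.tfire
        + params.c3 * c.live
        + params.c4 * c.snag
    )
    out = np.exp(_check_finite(lp, "c"))
    out[:, 0] = np.nan
    return out


def detprob_array(design, covariates, params: ModelParams) -> np.ndarray:
    """Per-visit detection probability p_jkt (site x session x year)."""
    c = covariates
    lp = (
        params.d0
        + params.d1 * c.nbox[:, None, None]
        + params.d2[design.observer_assignment]
    )
    return expit(_check_finite(lp, "d"))


def initial_intensity(covariates, params: ModelParams, site: int) -> float:
    """lambda_j = exp(a0 + a1 dnbr + a2 nbox + a3 tfire_1 + a4_{R_j})."""
    return float(lambda_vector(covariates, params)[site])


def survival_prob(covariates, params: ModelParams, site: int, year: int) -> float:
    """phi_jt for the interval from ``year``-1 to ``year`` (1-based, year >= 2)."""
    n_years = covariates.tfire.shape[1]
    if not 1 < year <= n_years:
        raise ValueError(f"year must be in (1, {n_years}], got {year}")
    return float(phi_matrix(covariates, params)[site, year - 1])


def recruitment_rate(covariates, params: ModelParams, site: int, year: int) -> float:
    """gamma_jt for the interval from ``year``-1 to ``year`` (1-based)."""
    n_years = covariates.tfire.shape[1]
    if not 1 < year <= n_years:
        raise ValueError(f"year must be in (1, {n_years}], got {year}")
    return float(gamma_matrix(covariates, params)[site, year - 1])


def det_prob(design, covariates, params: ModelParams,
             site: int, session: int, year: int) -> float:
    """Per-visit detection probability (1-based session and year)."""
    j, k, t = site, session - 1, year - 1
    if not design.sampled_mask[j, k, t]:
        raise ValueError(f"cell (site={site}, session={session}, year={year}) "
                         "was not surveyed")
    o = design.observer_assignment[j, k, t]
    return float(expit(params.d0 + params.d1 * covariates.nbox[j] + params.d2[o]))


# ---------------------------------------------------------------------------
# likelihood components
# ---------------------------------------------------------------------------

def obs_loglik(y_cell, N_jt: int, p: float) -> float:
    """Log Bernoulli mass of one survey cell under the Royle-Nichols layer.

    Success probability is 1-(1-p)^N (zero when N = 0).  Missing cells
    (``y_cell`` is None or negative) contribute 0.
    """
    if y_cell is None or y_cell < 0:
        return 0.0
    if N_jt < 0 or not 0.0 <= p <= 1.0:
        raise ValueError("require N >= 0 and p in [0, 1]")
    pi = -np.expm1(N_jt * np.log1p(-p)) if p < 1.0 else (1.0 if N_jt > 0 else 0.0)
    with np.errstate(divide="ignore"):
        return float(np.log(pi) if y_cell == 1 else np.log1p(-pi))


def obs_loglik_total(data: DetectionData, pop: PopulationState,
                     design, covariates, params: ModelParams) -> float:
    """Sum of ``obs_loglik`` over all surveyed cells."""
    p = detprob_array(design, covariates, params)
    N = pop.N[:, None, :]
    with np.errstate(divide="ignore"):
        log1mp = np.log1p(-p)
        pi = -np.expm1(N * log1mp)
        ll = np.where(data.y == 1, np.log(pi), np.log1p(-pi))
    ll = np.where(data.sampled, ll, 0.0)
    return float(ll.sum())


def state_loglik(pop: PopulationState, covariates, params: ModelParams) -> float:
    """Log mass of the latent trajectories: Poisson first-year abundance,
    binomial survivors, Poisson recruits.  Invalid states (S > previous N)
    yield -inf."""
    lam = lambda_vector(covariates, params)
    ll = poisson.logpmf(pop.N[:, 0], lam).sum()
    T = pop.N.shape[1]
    if T > 1:
        phi = phi_matrix(covariates, params)[:, 1:]
        gam = gamma_matrix(covariates, params)[:, 1:]
        ll += binom.logpmf(pop.S[:, 1:], pop.N[:, :-1], phi).sum()
        ll += poisson.logpmf(pop.G[:, 1:], gam).sum()
    return float(ll)


# ---------------------------------------------------------------------------
# exact marginal likelihood on tiny instances (test oracle)
# ---------------------------------------------------------------------------

def _site_obs_loglik_vec(y_jt: np.ndarray, p_jt: np.ndarray,
                         n_grid: np.ndarray) -> np.ndarray:
    """Observation log-lik of one site-year for every abundance in n_grid."""
    out = np.zeros_like(n_grid, dtype=float)
    for k in range(len(y_jt)):
        if y_jt[k] < 0:
            continue
        with np.errstate(divide="ignore"):
            pi = -np.expm1(n_grid * np.log1p(-p_jt[k]))
            out += np.where(y_jt[k] == 1, np.log(pi), np.log1p(-pi))
    return out


def marginal_loglik_bruteforce(data: DetectionData, design, covariates,
                               params: ModelParams, n_max: int = 8) -> float:
    """Exact detection/non-detection log-likelihood with (N, S, G) summed out.

    Per-site forward pass over the abundance grid 0..n_max with the exact
    transition kernel P(N_t | N_{t-1}) = sum_S Bin(S) * Pois(N_t - S).
    Only valid on tiny instances; guards refuse anything larger.
    """
    J, K, T = data.y.shape
    if J > 3 or T > 3:
        raise InstanceTooLargeError(
            f"brute-force marginal limited to <=3 sites and <=3 years "
            f"(got {J} sites, {T} years)")
    if n_max > 64:
        raise InstanceTooLargeError("n_max above 64 refused")

    grid = np.arange(n_max + 1)
    lam = lambda_vector(covariates, params)
    phi = phi_matrix(covariates, params)
    gam = gamma_matrix(covariates, params)
    p = detprob_array(design, covariates, params)

    total = 0.0
    for j in range(J):
        # forward weights over N in linear space, per site
        w = poisson.pmf(grid, lam[j]) * np.exp(
            _site_obs_loglik_vec(data.y[j, :, 0], p[j, :, 0], grid))
        for t in range(1, T):
            trans = np.zeros((n_max + 1, n_max + 1))
            for n_prev in grid:
                s = np.arange(n_prev + 1)
                ps = binom.pmf(s, n_prev, phi[j, t])
                for si, sp in zip(s, ps):
                    g = grid[si:] - si
                    trans[n_prev, si:] += sp * poisson.pmf(g, gam[j, t])
            w = w @ trans
            w = w * np.exp(_site_obs_loglik_vec(data.y[j, :, t], p[j, :, t], grid))
        if w.sum() <= 0.0:
            return -np.inf
        total += float(np.log(w.sum()))
    return total
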