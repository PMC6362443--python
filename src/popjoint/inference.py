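"""Bayesian inference engine: Metropolis-within-Gibbs sampling of the
point-count, banding and joint models, indicator-variable selection,
Brooks-Gelman convergence diagnostics, posterior summaries and a
squared-loss posterior-predictive (Bayesian p-value) check.

Priors follow the original analysis: slope coefficients get Normal(0,
sigma^2 = 0.1), the survival and per-visit detection intercepts
Normal(0, 1), random-effect scales Uniform(0, 5), the band-detection
intercept a prior flat on the probability scale, and every inclusion
indicator Bernoulli(0.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels as K
from .cjs import BandingData
from .occupancy import DetectionData, ModelParams

MODELS = ("point", "band", "joint")

#: indicator slots in kernel order, with the parameter each one gates
INDICATOR_NAMES = ("v_a1", "v_a2", "v_a3", "v_a4", "v_b1", "v_b2", "v_b3",
                   "v_b4", "v_c1", "v_c2", "v_c3", "v_c4", "v_d1", "v_d2",
                   "v_e1")


class InitializationError(RuntimeError):
    """The initial state has non-finite log posterior."""


class ConvergenceUnavailableError(ValueError):
    """R-hat needs at least two chains."""


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

@dataclass
class PriorSpec:
    """Normal/uniform prior settings for every coefficient block.

    The source analysis prints "normal (mu = 0, sigma^2 = 0.1)" but ran
    in JAGS, where the second argument of ``dnorm`` is a *precision*;
    read as a variance (SD 0.32) that prior cannot reach the abundance
    and detection levels the same analysis reports, so the default here
    is ``scale_reading='precision'`` (variance 10, SD 3.16) and
    ``'variance'`` gives the literal reading.  ``e0_prior='probability'``
    places the uniform(0, 1) prior on the band-detection probability
    itself (with the logit Jacobian); ``'literal'`` reads it as
    Uniform(0, 1) on the logit-scale intercept.
    """

    slope_var: float = 0.1
    intercept_var_b0: float = 1.0
    intercept_var_d0: float = 1.0
    sigma_bounds: tuple = (0.0, 5.0)
    indicator_prob: float = 0.5
    scale_reading: str = "precision"
    e0_prior: str = "probability"

    def slope_sd(self) -> float:
        if self.scale_reading == "variance":
            return math.sqrt(self.slope_var)
        if self.scale_reading == "precision":
            return math.sqrt(1.0 / self.slope_var)
        raise ValueError(f"unknown scale_reading {self.scale_reading!r}")


@dataclass
class McmcConfig:
    """Chain settings; desk-scale defaults (the original analysis ran
    3 chains of 4-8x10^5 iterations)."""

    n_chains: int = 3
    n_iter: int = 20_000
    burn_in: int = 10_000
    thin: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class IndicatorState:
    """Kuo-Mallick state: reported coefficient is beta_i = v_i * theta_i."""

    v: dict
    theta: dict

    def beta(self) -> dict:
        return {k: self.v[k] * self.theta[k] for k in self.v}


def indicator_full_conditional(loglik_on: float, loglik_off: float,
                               prior: float = 0.5) -> float:
    """P(v=1 | rest) for one indicator given the two likelihood branches."""
    a = loglik_on + math.log(prior)
    b = loglik_off + math.log1p(-prior)
    return 1.0 / (1.0 + math.exp(b - a))


def update_indicators(state: IndicatorState, loglik_fn, rng,
                      prior: float = 0.5) -> IndicatorState:
    """One Gibbs sweep over all indicators (jointly, one at a time).

    ``loglik_fn(beta_dict)`` evaluates the likelihood at the effective
    coefficients.  This python-level implementation mirrors the sweep the
    compiled sampler performs inline.
    """
    v = dict(state.v)
    for name in v:
        for trial in (1, 0):
            v[name] = trial
            beta = {k: v[k] * state.theta[k] for k in v}
            if trial == 1:
                ll_on = loglik_fn(beta)
            else:
                ll_off = loglik_fn(beta)
        p1 = indicator_full_conditional(ll_on, ll_off, prior)
        v[name] = 1 if rng.random() < p1 else 0
    return IndicatorState(v=v, theta=dict(state.theta))


# ---------------------------------------------------------------------------
# kernel plumbing
# ---------------------------------------------------------------------------

def _param_names(n_transects: int, n_observers: int) -> list:
    names = ["a0", "a1", "a2", "a3", "b0", "b1", "b2", "b3", "b4",
             "c0", "c1", "c2", "c3", "c4", "d0", "d1", "e0", "e1",
             "sigma_a", "sigma_d"]
    names += [f"a4[{r + 1}]" for r in range(n_transects)]
    names += [f"d2[{o + 1}]" for o in range(n_observers)]
    return names


def _build_priors(priors: PriorSpec, n_transects: int, n_observers: int):
    nt = K.NFIXED + n_transects + n_observers
    kind = np.zeros(nt, dtype=np.int64)
    mean = np.zeros(nt)
    sd = np.full(nt, priors.slope_sd())
    lo = np.zeros(nt)
    hi = np.zeros(nt)
    sd[K.IB0] = math.sqrt(priors.intercept_var_b0)
    sd[K.ID0] = math.sqrt(priors.intercept_var_d0)
    for i in (K.ISA, K.ISD):
        kind[i] = 1
        lo[i], hi[i] = priors.sigma_bounds
    if priors.e0_prior == "probability":
        kind[K.IE0] = 2
    elif priors.e0_prior == "literal":
        kind[K.IE0] = 1
        lo[K.IE0], hi[K.IE0] = 0.0, 1.0
    else:
        raise ValueError(f"unknown e0_prior {priors.e0_prior!r}")
    kind[K.NFIXED:K.NFIXED + n_transects] = 3
    kind[K.NFIXED + n_transects:] = 4
    return kind, mean, sd, lo, hi


def _masks(model: str, n_transects: int, n_observers: int, select: bool):
    nt = K.NFIXED + n_transects + n_observers
    active = np.zeros(nt, dtype=np.bool_)
    selectable = np.zeros(K.NV, dtype=np.bool_)
    v = np.ones(K.NV, dtype=np.int8)
    if model in ("point", "joint"):
        active[[K.IA0, K.IA1, K.IA2, K.IA3, K.IB0, K.IB1, K.IB2, K.IB3,
                K.IB4, K.IC0, K.IC1, K.IC2, K.IC3, K.IC4, K.ID0, K.ID1,
                K.ISA, K.ISD]] = True
        active[K.NFIXED:] = True
        selectable[[K.VA1, K.VA2, K.VA3, K.VA4, K.VB1, K.VB2, K.VB3, K.VB4,
                    K.VC1, K.VC2, K.VC3, K.VC4, K.VD1, K.VD2]] = True
    if model in ("band", "joint"):
        active[[K.IB0, K.IB2, K.IB3, K.IB4, K.IE0, K.IE1]] = True
        selectable[[K.VB2, K.VB3, K.VB4, K.VE1]] = True
    if model == "joint":
        active[K.IB1] = True
        selectable[K.VB1] = True
    if model == "band":
        # banding happens only at nest-box sites, so the nest-box survival
        # effect is confounded with the intercept and dropped
        v[K.VB1] = 0
    if not select:
        selectable[:] = False
    return active, selectable, v


def _init_latent(det: DetectionData):
    """Small upper envelope consistent with the detections."""
    seen = np.where(det.sampled, det.y, 0).max(axis=1)     # (J, T)
    N = (1 + seen).astype(np.int64)
    J, T = N.shape
    S = np.zeros_like(N)
    G = np.zeros_like(N)
    for t in range(1, T):
        S[:, t] = np.minimum(N[:, t], N[:, t - 1])
        G[:, t] = N[:, t] - S[:, t]
    return N, S, G


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Posterior draws from one model fit.

    ``theta``: (chains, draws, n_params) raw coefficient draws;
    ``v``: (chains, draws, 15) indicator draws (all ones when selection is
    off); ``phi``/``N``/``G``: per-site-per-year posterior draws;
    ``gof``: per-draw squared-loss discrepancies (obs, rep) x (point,
    band layer).  Reported coefficients are ``beta = v * theta``.
    """

    model: str
    names: list
    theta: np.ndarray
    v: np.ndarray
    phi: np.ndarray
    N: np.ndarray
    G: np.ndarray
    gof: np.ndarray
    config: McmcConfig
    n_transects: int
    n_observers: int

    # -- helpers -----------------------------------------------------------
    def _beta(self) -> np.ndarray:
        """Effective coefficients beta = v * theta, (chains, draws, nparam)."""
        beta = self.theta.copy()
        gate = {
            K.IA1: K.VA1, K.IA2: K.VA2, K.IA3: K.VA3,
            K.IB1: K.VB1, K.IB2: K.VB2, K.IB3: K.VB3, K.IB4: K.VB4,
            K.IC1: K.VC1, K.IC2: K.VC2, K.IC3: K.VC3, K.IC4: K.VC4,
            K.ID1: K.VD1, K.IE1: K.VE1,
        }
        for pi, vi in gate.items():
            beta[:, :, pi] *= self.v[:, :, vi]
        beta[:, :, K.NFIXED:K.NFIXED + self.n_transects] *= \
            self.v[:, :, [K.VA4]]
        beta[:, :, K.NFIXED + self.n_transects:] *= self.v[:, :, [K.VD2]]
        return beta

    def param_draws(self, name: str) -> np.ndarray:
        """Pooled effective-coefficient draws for one parameter name."""
        idx = self.names.index(name)
        return self._beta()[:, :, idx].reshape(-1)

    def indicator_means(self) -> pd.Series:
        return pd.Series(self.v.reshape(-1, K.NV).mean(axis=0),
                         index=list(INDICATOR_NAMES))

    def bayesian_pvalue(self) -> dict:
        """Squared-loss posterior-predictive p-values.

        Fraction of saved draws whose replicate discrepancy exceeds the
        observed one, per data layer and pooled across the layers the
        model fits.
        """
        g = self.gof.reshape(-1, 4)
        out = {}
        if self.model in ("point", "joint"):
            out["point"] = float((g[:, 1] > g[:, 0]).mean())
        if self.model in ("band", "joint"):
            out["band"] = float((g[:, 3] > g[:, 2]).mean())
        obs = g[:, 0] + g[:, 2]
        rep = g[:, 1] + g[:, 3]
        out["pooled"] = float((rep > obs).mean())
        return out

    def summarize(self) -> pd.DataFrame:
        return summarize(self)

    def site_year_bci(self, quantity: str) -> pd.DataFrame:
        """95% BCI length per site-year for 'phi', 'N' or 'G'."""
        arr = {"phi": self.phi, "N": self.N, "G": self.G}[quantity]
        flat = arr.reshape(-1, arr.shape[2], arr.shape[3]).astype(float)
        lo = np.quantile(flat, 0.025, axis=0)
        hi = np.quantile(flat, 0.975, axis=0)
        J, T = lo.shape
        t0 = 1 if quantity in ("phi", "G") else 0
        rows = [
            {"quantity": quantity, "site": j + 1, "year": t + 1,
             "lower": lo[j, t], "upper": hi[j, t],
             "length": hi[j, t] - lo[j, t]}
            for j in range(J) for t in range(t0, T)
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# diagnostics and summaries
# ---------------------------------------------------------------------------

def rhat(chains: np.ndarray) -> float:
    """Brooks-Gelman potential scale reduction factor.

    ``chains``: (n_chains, n_draws).  Requires at least two chains.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ConvergenceUnavailableError(
            "R-hat requires >= 2 chains of equal length")
    m, n = chains.shape
    means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W <= 0.0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def summarize(result: FitResult) -> pd.DataFrame:
    """Posterior medians, equal-tailed 95% BCIs and R-hat per parameter,
    plus posterior means for the inclusion indicators."""
    beta = result._beta()
    if beta.shape[0] * beta.shape[1] == 0:
        raise ValueError("no posterior draws to summarize")
    rows = []
    active = _active_names(result)
    for i, name in enumerate(result.names):
        if name not in active:
            continue
        draws = beta[:, :, i]
        pooled = draws.reshape(-1)
        rows.append({
            "parameter": name,
            "median": float(np.quantile(pooled, 0.5)),
            "lower": float(np.quantile(pooled, 0.025)),
            "upper": float(np.quantile(pooled, 0.975)),
            "rhat": rhat(draws) if draws.shape[0] >= 2 else np.nan,
        })
    df = pd.DataFrame(rows)
    means = result.indicator_means()
    df["indicator_mean"] = [
        means.get(_indicator_for(name), np.nan) for name in df["parameter"]
    ]
    return df


def _indicator_for(name: str) -> str:
    base = name.split("[")[0]
    return {"a1": "v_a1", "a2": "v_a2", "a3": "v_a3", "a4": "v_a4",
            "b1": "v_b1", "b2": "v_b2", "b3": "v_b3", "b4": "v_b4",
            "c1": "v_c1", "c2": "v_c2", "c3": "v_c3", "c4": "v_c4",
            "d1": "v_d1", "d2": "v_d2", "e1": "v_e1"}.get(base, "")


def _active_names(result: FitResult) -> set:
    active, _, _ = _masks(result.model, result.n_transects,
                          result.n_observers, select=False)
    return {n for i, n in enumerate(result.names) if active[i]}


def quantile_summary(draws: np.ndarray) -> dict:
    """Median and equal-tailed 95% interval of a 1-D draw vector."""
    draws = np.asarray(draws, dtype=float).reshape(-1)
    if draws.size == 0:
        raise ValueError("empty draws")
    return {
        "median": float(np.quantile(draws, 0.5)),
        "lower": float(np.quantile(draws, 0.025)),
        "upper": float(np.quantile(draws, 0.975)),
    }


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

def run_mcmc(model: str, design, covariates,
             detection: DetectionData | None = None,
             banding: BandingData | None = None,
             priors: PriorSpec | None = None,
             config: McmcConfig | None = None,
             select: bool = True,
             init_params: ModelParams | None = None,
             update_params: bool = True,
             update_latent: bool = True) -> FitResult:
    """Sample the posterior of one of the three models.

    ``model``: 'point' (detection/non-detection only), 'band' (CJS only)
    or 'joint' (both likelihoods sharing the survival block).  Latent
    abundance moves by integer proposals, continuous blocks by adaptive
    random-walk Metropolis, indicators by Gibbs; the CJS alive matrix is
    marginalized by the forward algorithm.  Chains are seeded and
    reproducible; ``update_params=False`` freezes the parameters at
    ``init_params`` (latent-state sampling only, used for validation).
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    priors = priors or PriorSpec()
    config = config or McmcConfig()
    have_point = model in ("point", "joint")
    have_band = model in ("band", "joint")
    if have_point and detection is None:
        raise ValueError(f"model {model!r} needs detection data")
    if have_band and (banding is None or banding.n_individuals == 0):
        raise ValueError(f"model {model!r} needs banding data")

    J, Ksess, T = design.n_sites, design.n_sessions, design.n_years
    R, O = design.n_transects, design.n_observers
    names = _param_names(R, O)
    nt = len(names)
    kind, mean, sd, lo, hi = _build_priors(priors, R, O)
    active, selectable, v0 = _masks(model, R, O, select)

    if detection is not None:
        yP = np.ascontiguousarray(detection.y, dtype=np.int8)
        sampled = np.ascontiguousarray(detection.sampled)
        N0, S0, G0 = _init_latent(detection)
    else:
        yP = np.zeros((J, Ksess, T), dtype=np.int8)
        sampled = np.zeros((J, Ksess, T), dtype=bool)
        N0 = np.zeros((J, T), dtype=np.int64)
        S0 = np.zeros((J, T), dtype=np.int64)
        G0 = np.zeros((J, T), dtype=np.int64)

    if banding is not None and banding.n_individuals > 0:
        yB = np.ascontiguousarray(banding.y, dtype=np.int8)
        f_i = banding.f.astype(np.int64)
        site_i = banding.site.astype(np.int64)
        sex_i = banding.sex.astype(np.float64)
    else:
        yB = np.zeros((0, T), dtype=np.int8)
        f_i = np.zeros(0, dtype=np.int64)
        site_i = np.zeros(0, dtype=np.int64)
        sex_i = np.zeros(0, dtype=np.float64)

    theta0 = np.zeros(nt)
    theta0[K.ISA] = 0.5
    theta0[K.ISD] = 0.5
    if init_params is not None:
        theta0 = _params_to_theta(init_params, R, O)

    cov = covariates
    # CSR-style index lists: sites per transect, surveyed cells per observer
    order = np.argsort(design.transect_of_site, kind="stable")
    trans_sites = order.astype(np.int64)
    trans_ptr = np.zeros(R + 1, dtype=np.int64)
    np.cumsum(np.bincount(design.transect_of_site, minlength=R),
              out=trans_ptr[1:])
    jj, kk, tt = np.nonzero(sampled)
    oo = design.observer_assignment[jj, kk, tt]
    cell_order = np.argsort(oo, kind="stable")
    obs_cj = jj[cell_order].astype(np.int64)
    obs_ck = kk[cell_order].astype(np.int64)
    obs_ct = tt[cell_order].astype(np.int64)
    obs_ptr = np.zeros(O + 1, dtype=np.int64)
    np.cumsum(np.bincount(oo, minlength=O), out=obs_ptr[1:])

    out_theta = []
    out_v = []
    out_phi = []
    out_N = []
    out_G = []
    out_gof = []
    for chain in range(config.n_chains):
        chain_seed = (config.seed * 100003 + 7919 * chain + 1) % (2**31 - 1)
        th = theta0.copy()
        if init_params is None:
            # overdispersed but safe starts
            jit = np.random.default_rng(chain_seed).normal(0.0, 0.1, size=nt)
            jit[[K.ISA, K.ISD]] = 0.0
            th = th + jit
        res = K.run_chain(
            yP, sampled, have_point,
            yB, f_i, site_i, sex_i, have_band and len(f_i) > 0,
            np.ascontiguousarray(cov.dnbr, dtype=np.float64),
            np.ascontiguousarray(cov.nbox, dtype=np.float64),
            np.ascontiguousarray(cov.tfire, dtype=np.float64),
            np.ascontiguousarray(cov.snag, dtype=np.float64),
            np.ascontiguousarray(cov.live, dtype=np.float64),
            np.ascontiguousarray(design.transect_of_site, dtype=np.int64),
            np.ascontiguousarray(design.observer_assignment, dtype=np.int64),
            R, O,
            kind, mean, sd, lo, hi,
            active, selectable, th, v0,
            N0, S0, G0,
            trans_ptr, trans_sites, obs_ptr, obs_cj, obs_ck, obs_ct,
            config.n_iter, config.burn_in, config.thin, chain_seed,
            update_params, bool(select), update_latent,
        )
        theta_c, v_c, phi_c, N_c, G_c, gof_c, _ = res
        if not np.all(np.isfinite(theta_c)):
            raise InitializationError(
                f"chain {chain}: non-finite parameter draws; check the "
                "initial state and data")
        out_theta.append(theta_c)
        out_v.append(v_c)
        out_phi.append(phi_c)
        out_N.append(N_c)
        out_G.append(G_c)
        out_gof.append(gof_c)

    phi = np.stack(out_phi)
    phi[:, :, :, 0] = np.nan      # no survival interval into year 1
    return FitResult(
        model=model, names=names,
        theta=np.stack(out_theta), v=np.stack(out_v).astype(np.int8),
        phi=phi, N=np.stack(out_N), G=np.stack(out_G),
        gof=np.stack(out_gof), config=config,
        n_transects=R, n_observers=O,
    )


def _params_to_theta(p: ModelParams, R: int, O: int) -> np.ndarray:
    th = np.zeros(K.NFIXED + R + O)
    for idx, name in ((K.IA0, "a0"), (K.IA1, "a1"), (K.IA2, "a2"),
                      (K.IA3, "a3"), (K.IB0, "b0"), (K.IB1, "b1"),
                      (K.IB2, "b2"), (K.IB3, "b3"), (K.IB4, "b4"),
                      (K.IC0, "c0"), (K.IC1, "c1"), (K.IC2, "c2"),
                      (K.IC3, "c3"), (K.IC4, "c4"), (K.ID0, "d0"),
                      (K.ID1, "d1"), (K.IE0, "e0"), (K.IE1, "e1"),
                      (K.ISA, "sigma_a"), (K.ISD, "sigma_d")):
        th[idx] = getattr(p, name)
    th[K.NFIXED:K.NFIXED + R] = p.a4
    th[K.NFIXED + R:] = p.d2
    return th


# ---------------------------------------------------------------------------
# generic adaptive random-walk Metropolis (used by validation tests)
# ---------------------------------------------------------------------------

def adaptive_rwm(logpdf, x0: float, n_iter: int, burn_in: int,
                 seed: int = 0) -> np.ndarray:
    """Scalar adaptive RWM targeting ``logpdf``; same adaptation policy as
    the compiled sampler (tune toward ~0.35 acceptance during burn-in,
    frozen after).  Returns post-burn-in draws."""
    rng = np.random.default_rng(seed)
    x = float(x0)
    lp = logpdf(x)
    step = 0.3
    out = np.empty(n_iter - burn_in)
    acc = 0
    for it in range(n_iter):
        prop = x + step * rng.normal()
        lp_new = logpdf(prop)
        if lp_new - lp > 0 or rng.random() < math.exp(lp_new - lp):
            x, lp = prop, lp_new
            acc += 1
        if it < burn_in and (it + 1) % 100 == 0:
            step = min(max(step * math.exp(acc / 100 - 0.35), 1e-3), 10.0)
            acc = 0
        if it >= burn_in:
            out[it - burn_in] = x
    return out
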