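"""Dynamic N-occupancy model: links, likelihood components, exact
marginalization oracle."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import binom, poisson

import popjoint as pj
from popjoint.occupancy import (
    DetectionData,
    InstanceTooLargeError,
    PopulationState,
    detprob_array,
    gamma_matrix,
    lambda_vector,
    marginal_loglik_bruteforce,
    obs_loglik,
    obs_loglik_total,
    phi_matrix,
    state_loglik,
)


def _zero_params(design):
    return pj.ModelParams.for_design(design)


class TestLinks:
    """The four link-scale predictors of the state and observation layers."""

    def test_initial_intensity(self, tiny_design, tiny_cov):
        p = _zero_params(tiny_design)
        assert pj.initial_intensity(tiny_cov, p, 0) == pytest.approx(1.0)
        p.a0 = 1.0
        assert pj.initial_intensity(tiny_cov, p, 0) == pytest.approx(np.e)
        # a1 slope acting on a known dnbr value
        p2 = _zero_params(tiny_design)
        p2.a1 = 0.5
        expected = np.exp(0.5 * tiny_cov.dnbr[1])
        assert pj.initial_intensity(tiny_cov, p2, 1) == pytest.approx(expected)

    def test_survival_prob(self, tiny_design, tiny_cov):
        p = _zero_params(tiny_design)
        assert pj.survival_prob(tiny_cov, p, 0, 2) == pytest.approx(0.5)
        p.b0 = float(np.log(0.9 / 0.1))
        assert pj.survival_prob(tiny_cov, p, 0, 2) == pytest.approx(0.9)
        p2 = _zero_params(tiny_design)
        p2.b4 = -1.0
        expected = 1.0 / (1.0 + np.exp(tiny_cov.snag[0, 1]))
        assert pj.survival_prob(tiny_cov, p2, 0, 2) == pytest.approx(expected)
        with pytest.raises(ValueError):
            pj.survival_prob(tiny_cov, p, 0, 1)   # no interval into year 1

    def test_recruitment_rate(self, tiny_design, tiny_cov):
        p = _zero_params(tiny_design)
        assert pj.recruitment_rate(tiny_cov, p, 0, 2) == pytest.approx(1.0)
        p.c0 = float(np.log(0.5))
        assert pj.recruitment_rate(tiny_cov, p, 0, 2) == pytest.approx(0.5)
        # tfire slope at the study's estimated effect size
        p2 = _zero_params(tiny_design)
        p2.c2 = 0.092
        expected = np.exp(0.092 * tiny_cov.tfire[0, 1])
        assert pj.recruitment_rate(tiny_cov, p2, 0, 2) == pytest.approx(expected)

    def test_det_prob(self, tiny_design, tiny_cov):
        p = _zero_params(tiny_design)
        assert pj.det_prob(tiny_design, tiny_cov, p, 0, 1, 1) == \
            pytest.approx(0.5)
        p.d1 = 1.0
        box_site = int(tiny_design.nbox_sites[0])
        assert pj.det_prob(tiny_design, tiny_cov, p, box_site, 1, 1) == \
            pytest.approx(1.0 / (1.0 + np.exp(-1.0)))
        p2 = _zero_params(tiny_design)
        p2.d0 = -2.0
        p2.d2[:] = -0.3
        plain = [j for j in range(2) if j not in tiny_design.nbox_sites][0]
        assert pj.det_prob(tiny_design, tiny_cov, p2, plain, 1, 1) == \
            pytest.approx(1.0 / (1.0 + np.exp(2.3)))

    def test_link_roundtrip(self, tiny_design, tiny_cov):
        """Link functions invert their stated transforms to 1e-12."""
        from scipy.special import expit, logit
        p = _zero_params(tiny_design)
        p.b0 = 0.734
        phi = phi_matrix(tiny_cov, p)[0, 1]
        assert logit(phi) == pytest.approx(0.734, abs=1e-12)
        p.a0 = -1.1
        lam = lambda_vector(tiny_cov, p)[0]
        assert np.log(lam) == pytest.approx(-1.1, abs=1e-12)
        assert expit(logit(0.37)) == pytest.approx(0.37, abs=1e-12)

    def test_nonfinite_predictor_names_block(self, tiny_design, tiny_cov):
        p = _zero_params(tiny_design)
        p.c2 = np.inf
        with pytest.raises(pj.occupancy.SimulationError, match="c"):
            gamma_matrix(tiny_cov, p)


class TestObsLoglik:
    @pytest.mark.parametrize("y,N,p,expected", [
        (1, 0, 0.5, -np.inf),                 # no animals, detection impossible
        (1, 2, 0.5, np.log(0.75)),
        (0, 3, 0.2, 3 * np.log(0.8)),
        (0, 0, 0.9, 0.0),                     # certain non-detection
        (None, 5, 0.5, 0.0),                  # missing cell skipped
    ])
    def test_values(self, y, N, p, expected):
        assert obs_loglik(y, N, p) == pytest.approx(expected, abs=1e-12)

    @given(st.integers(0, 30), st.integers(0, 30),
           st.floats(0.01, 0.99), st.floats(0.0, 0.3))
    def test_success_prob_monotone(self, n1, n2, p, dp):
        """P(detect) is nondecreasing in N and in p."""
        lo, hi = sorted((n1, n2))
        assert obs_loglik(1, hi, p) >= obs_loglik(1, lo, p) - 1e-12
        if p + dp <= 1.0 and lo > 0:
            assert obs_loglik(1, lo, min(p + dp, 1.0)) >= \
                obs_loglik(1, lo, p) - 1e-12


class TestStateLoglik:
    def test_single_poisson_mass(self, tiny_design, tiny_cov):
        p = _zero_params(tiny_design)
        p.a0 = float(np.log(2.0))
        lam = lambda_vector(tiny_cov, p)
        pop = PopulationState(N=np.array([[2, 1], [0, 0]]),
                              S=np.array([[0, 1], [0, 0]]),
                              G=np.array([[0, 0], [0, 0]]))
        expected = (poisson.logpmf(2, lam[0]) + poisson.logpmf(0, lam[1])
                    + binom.logpmf(1, 2, 0.5) + poisson.logpmf(0, 1.0)
                    + binom.logpmf(0, 0, 0.5) + poisson.logpmf(0, 1.0))
        assert state_loglik(pop, tiny_cov, p) == pytest.approx(expected)

    def test_hand_value(self, tiny_design, tiny_cov):
        # N1=1, S2=1, G2=0 at phi=0.5, gamma=1: log(0.5) - 1 plus N1 mass
        p = _zero_params(tiny_design)
        pop = PopulationState(N=np.array([[1, 1], [0, 0]]),
                              S=np.array([[0, 1], [0, 0]]),
                              G=np.array([[0, 0], [0, 0]]))
        expected = (poisson.logpmf(1, 1.0) + np.log(0.5) - 1.0
                    + poisson.logpmf(0, 1.0) + 0.0 - 1.0)
        assert state_loglik(pop, tiny_cov, p) == pytest.approx(expected)

    def test_invalid_state_is_impossible(self, tiny_design, tiny_cov):
        p = _zero_params(tiny_design)
        pop = PopulationState(N=np.array([[1, 3], [0, 0]]),
                              S=np.array([[0, 3], [0, 0]]),   # S > N_prev
                              G=np.array([[0, 0], [0, 0]]))
        assert state_loglik(pop, tiny_cov, p) == -np.inf


def enumerate_marginal(y, design, cov, params, n_max):
    """Independent oracle: per-site sum of exp(state + obs loglik) over all
    enumerated (N1, S, G) trajectories (2-year instances)."""
    lam = lambda_vector(cov, params)
    phi = phi_matrix(cov, params)
    gam = gamma_matrix(cov, params)
    p = detprob_array(design, cov, params)
    total = 0.0
    J, K, T = y.shape
    assert T == 2
    for j in range(J):
        acc = 0.0
        for n1 in range(n_max + 1):
            for s in range(n1 + 1):
                for g in range(n_max + 1):
                    n2 = s + g
                    pr = (poisson.pmf(n1, lam[j]) * binom.pmf(s, n1, phi[j, 1])
                          * poisson.pmf(g, gam[j, 1]))
                    for k in range(K):
                        for t, n in ((0, n1), (1, n2)):
                            if y[j, k, t] < 0:
                                continue
                            pi = 1 - (1 - p[j, k, t]) ** n
                            pr *= pi if y[j, k, t] == 1 else 1 - pi
                    acc += pr
        total += np.log(acc)
    return total


class TestBruteForceMarginal:
    def test_matches_trajectory_enumeration(self, tiny_design, tiny_cov,
                                            tiny_params):
        y = np.array([[[1, 0], [0, 1]], [[0, 0], [1, 0]]], dtype=np.int8)
        det = DetectionData.from_array(y)
        got = marginal_loglik_bruteforce(det, tiny_design, tiny_cov,
                                         tiny_params, n_max=25)
        want = enumerate_marginal(y, tiny_design, tiny_cov, tiny_params,
                                  n_max=25)
        assert got == pytest.approx(want, abs=1e-8)

    def test_missing_sessions_skipped(self, tiny_design, tiny_cov,
                                      tiny_params):
        y = np.array([[[1, -1], [0, 1]], [[0, 0], [-1, 0]]], dtype=np.int8)
        det = DetectionData.from_array(y)
        got = marginal_loglik_bruteforce(det, tiny_design, tiny_cov,
                                         tiny_params, n_max=25)
        want = enumerate_marginal(y, tiny_design, tiny_cov, tiny_params,
                                  n_max=25)
        assert got == pytest.approx(want, abs=1e-8)

    def test_uninformative_when_p_zero(self, tiny_design, tiny_cov):
        """With p -> 0 no detections are possible and the likelihood carries
        no abundance information (mass 1 for all-zero data)."""
        p = _zero_params(tiny_design)
        p.d0 = -40.0
        det = DetectionData.from_array(np.zeros((2, 2, 2), dtype=np.int8))
        got = marginal_loglik_bruteforce(det, tiny_design, tiny_cov, p,
                                         n_max=30)
        assert got == pytest.approx(0.0, abs=1e-6)

    def test_truncation_tail_stable(self, tiny_design, tiny_cov, tiny_params):
        y = np.array([[[1, 0], [0, 1]], [[0, 0], [1, 0]]], dtype=np.int8)
        det = DetectionData.from_array(y)
        lo = marginal_loglik_bruteforce(det, tiny_design, tiny_cov,
                                        tiny_params, n_max=20)
        hi = marginal_loglik_bruteforce(det, tiny_design, tiny_cov,
                                        tiny_params, n_max=40)
        assert abs(hi - lo) < 1e-10

    def test_combinatorial_guard(self, tiny_cov, tiny_params):
        design = pj.generate_design(n_sites=5, n_transects=1, n_sessions=2,
                                    n_years=2, nbox_fraction=0.5,
                                    n_observers=1, seed=1)
        cov = pj.generate_covariates(design, seed=2)
        params = pj.default_params(design, seed=3)
        det = DetectionData.from_array(np.zeros((5, 2, 2), dtype=np.int8))
        with pytest.raises(InstanceTooLargeError):
            marginal_loglik_bruteforce(det, design, cov, params)


def test_obs_total_matches_cellwise(tiny_design, tiny_cov, tiny_params,
                                    small_world):
    """Vectorized observation loglik equals the scalar-op sum."""
    ds = small_world
    p = detprob_array(ds.design, ds.covariates, ds.truth.params)
    total = 0.0
    for j in range(ds.design.n_sites):
        for k in range(ds.design.n_sessions):
            for t in range(ds.design.n_years):
                y = int(ds.detection.y[j, k, t])
                total += obs_loglik(y if y >= 0 else None,
                                    ds.truth.pop.N[j, t], p[j, k, t])
    got = obs_loglik_total(ds.detection, ds.truth.pop, ds.design,
                           ds.covariates, ds.truth.params)
    assert got == pytest.approx(total, rel=1e-10)
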