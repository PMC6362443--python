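"""Synthetic-data generator: design construction, covariate scaling and
the statistical structure of the simulated data."""

import numpy as np
import pytest

import popjoint as pj
from popjoint.synthetic import ConfigurationError, DesignError


class TestDesign:
    def test_study_scale_design(self):
        d = pj.generate_design(n_sites=149, n_transects=15, n_sessions=3,
                               n_years=8, nbox_fraction=0.48, n_observers=9,
                               seed=0)
        assert d.n_sites == 149 and d.n_transects == 15
        assert len(d.nbox_sites) == round(0.48 * 149) == 72
        assert len(np.unique(d.transect_of_site)) == 15
        assert d.sampled_mask.all()

    def test_minimal_design(self):
        d = pj.generate_design(1, 1, 1, 1, 1.0, 1, seed=0)
        assert d.n_sites == 1 and len(d.nbox_sites) == 1

    def test_determinism(self):
        d1 = pj.generate_design(seed=42)
        d2 = pj.generate_design(seed=42)
        assert np.array_equal(d1.transect_of_site, d2.transect_of_site)
        assert np.array_equal(d1.nbox_sites, d2.nbox_sites)
        assert np.array_equal(d1.observer_assignment, d2.observer_assignment)

    def test_too_many_transects_rejected(self):
        with pytest.raises(DesignError):
            pj.generate_design(n_sites=3, n_transects=5)

    def test_every_site_year_surveyed_invariant(self):
        d = pj.generate_design(n_sites=10, n_transects=2, seed=1)
        d.sampled_mask[3, :, 2] = False
        with pytest.raises(DesignError):
            d.validate()


class TestCovariates:
    def test_standardization(self):
        d = pj.generate_design(n_sites=149, n_transects=15, seed=3)
        cov = pj.generate_covariates(d, seed=4)
        for name in ("dnbr",):
            x = getattr(cov, name)
            assert abs(x.mean()) < 0.1 and abs(x.var() - 1) < 0.1
        for name in ("snag", "live"):
            x = getattr(cov, name)
            assert abs(x.mean()) < 0.1 and abs(x.var() - 1) < 0.1

    def test_tfire_codings(self):
        d = pj.generate_design(n_sites=20, n_transects=4, n_years=5, seed=5)
        site = pj.generate_covariates(d, tfire_mode="site", seed=6)
        yearly = pj.generate_covariates(d, tfire_mode="yearly", seed=6)
        # site coding: zero at unburned sites, 1..T at burned sites
        unburned = site.burned == 0
        assert (site.tfire[unburned] == 0).all()
        burned = ~unburned
        assert np.allclose(site.tfire[burned], np.arange(1, 6)[None, :])
        assert np.allclose(yearly.tfire, np.arange(1, 6)[None, :])


class TestPopulation:
    def test_identity_N_equals_S_plus_G(self, small_world):
        pop = small_world.truth.pop
        assert np.array_equal(pop.N[:, 1:], pop.S[:, 1:] + pop.G[:, 1:])
        assert (pop.S[:, 1:] <= pop.N[:, :-1]).all()

    def test_initial_abundance_mean(self):
        """Monte-Carlo mean of N_1 matches E[N] = e^{a0} with all slopes 0."""
        d = pj.generate_design(n_sites=10_000, n_transects=1, n_years=1,
                               seed=7)
        cov = pj.generate_covariates(d, seed=8)
        p = pj.ModelParams.for_design(d, a0=float(np.log(2.0)))
        pop = pj.simulate_population(d, cov, p, seed=9)
        se = np.sqrt(2.0 / 10_000)
        assert abs(pop.N[:, 0].mean() - 2.0) < 3 * se

    def test_closed_population_limit(self):
        """phi -> 1 and gamma -> 0 freezes N over time."""
        d = pj.generate_design(n_sites=50, n_transects=5, n_years=6, seed=10)
        cov = pj.generate_covariates(d, seed=11)
        p = pj.ModelParams.for_design(d, b0=40.0, c0=-40.0)
        pop = pj.simulate_population(d, cov, p, seed=12)
        assert (pop.N == pop.N[:, [0]]).all()

    def test_extinction_limit(self):
        d = pj.generate_design(n_sites=50, n_transects=5, n_years=4, seed=13)
        cov = pj.generate_covariates(d, seed=14)
        p = pj.ModelParams.for_design(d, b0=-40.0, c0=-40.0)
        pop = pj.simulate_population(d, cov, p, seed=15)
        assert (pop.N[:, 1:] == 0).all()

    def test_reproducible(self):
        d = pj.generate_design(n_sites=30, n_transects=3, seed=16)
        cov = pj.generate_covariates(d, seed=17)
        p = pj.default_params(d, seed=18)
        a = pj.simulate_population(d, cov, p, seed=19)
        b = pj.simulate_population(d, cov, p, seed=19)
        assert np.array_equal(a.N, b.N) and np.array_equal(a.G, b.G)


class TestDetectionSimulation:
    def test_no_animals_no_detections(self):
        d = pj.generate_design(n_sites=20, n_transects=2, n_years=3, seed=20)
        cov = pj.generate_covariates(d, seed=21)
        p = pj.ModelParams.for_design(d, a0=-40.0, b0=-40.0, c0=-40.0)
        pop = pj.simulate_population(d, cov, p, seed=22)
        det = pj.simulate_detection_data(d, pop, cov, p, seed=23)
        assert (det.y[det.sampled] == 0).all()

    @pytest.mark.parametrize("n,expected", [(1, 0.5), (2, 0.75)])
    def test_detection_frequency(self, n, expected):
        """Detection frequency approaches 1-(1-p)^N at p = 0.5."""
        d = pj.generate_design(n_sites=10_000, n_transects=1, n_sessions=1,
                               n_years=1, seed=24)
        cov = pj.generate_covariates(d, seed=25)
        p = pj.ModelParams.for_design(d)          # d-block zero: p = 0.5
        pop = pj.PopulationState(N=np.full((10_000, 1), n),
                                 S=np.zeros((10_000, 1), dtype=int),
                                 G=np.zeros((10_000, 1), dtype=int))
        det = pj.simulate_detection_data(d, pop, cov, p, seed=26)
        se = np.sqrt(expected * (1 - expected) / 10_000)
        assert abs(det.y.mean() - expected) < 3 * se

    def test_unsurveyed_marked_missing(self):
        d = pj.generate_design(n_sites=5, n_transects=1, n_years=2, seed=27)
        d.sampled_mask[:, 1, 0] = False
        cov = pj.generate_covariates(d, seed=28)
        p = pj.default_params(d, seed=29)
        pop = pj.simulate_population(d, cov, p, seed=30)
        det = pj.simulate_detection_data(d, pop, cov, p, seed=31)
        assert (det.y[:, 1, 0] == -1).all()

    def test_annual_occupancy_frequency(self):
        """Simulated annual occupancy matches 1 - E[(1-p)^N] over Poisson N
        within Monte-Carlo error (all covariate effects zero)."""
        lam, p_det, K = 1.5, 0.4, 3
        d = pj.generate_design(n_sites=20_000, n_transects=1, n_sessions=K,
                               n_years=1, seed=32)
        cov = pj.generate_covariates(d, seed=33)
        params = pj.ModelParams.for_design(
            d, a0=float(np.log(lam)),
            d0=float(np.log(p_det / (1 - p_det))))
        pop = pj.simulate_population(d, cov, params, seed=34)
        det = pj.simulate_detection_data(d, pop, cov, params, seed=35)
        occ = (det.y.reshape(20_000, K) == 1).any(axis=1).mean()
        # E over N~Pois(lam) of 1-(1-p)^(NK) = 1 - exp(-lam(1-(1-p)^K))
        expected = 1 - np.exp(-lam * (1 - (1 - p_det) ** K))
        se = np.sqrt(expected * (1 - expected) / 20_000)
        assert abs(occ - expected) < 3 * se


class TestBandingSimulation:
    def test_perfect_world(self):
        d = pj.generate_design(n_sites=30, n_transects=3, n_years=5,
                               nbox_fraction=1.0, seed=36)
        cov = pj.generate_covariates(d, seed=37)
        p = pj.ModelParams.for_design(d, a0=0.5, b0=40.0, e0=40.0)
        pop = pj.simulate_population(d, cov, p, seed=38)
        band, alive = pj.simulate_banding_data(d, pop, cov, p, 0.5, seed=39)
        assert band.n_individuals > 0
        for i in range(band.n_individuals):
            assert (band.y[i, band.f[i]:] == 1).all()

    def test_immediate_death_world(self):
        d = pj.generate_design(n_sites=30, n_transects=3, n_years=5,
                               nbox_fraction=1.0, seed=40)
        cov = pj.generate_covariates(d, seed=41)
        p = pj.ModelParams.for_design(d, a0=0.5, b0=-40.0)
        pop = pj.simulate_population(d, cov, p, seed=42)
        band, _ = pj.simulate_banding_data(d, pop, cov, p, 0.5, seed=43)
        for i in range(band.n_individuals):
            assert (band.y[i, band.f[i] + 1:] == 0).all()

    def test_entries_at_nbox_sites_only(self, small_world):
        band = small_world.banding
        assert set(band.site.tolist()) <= \
            set(small_world.design.nbox_sites.tolist())

    def test_marking_rule_at_non_nbox_site_rejected(self):
        d = pj.generate_design(n_sites=10, n_transects=2, nbox_fraction=0.3,
                               seed=44)
        cov = pj.generate_covariates(d, seed=45)
        p = pj.default_params(d, seed=46)
        pop = pj.simulate_population(d, cov, p, seed=47)
        non_box = [j for j in range(10) if j not in d.nbox_sites][0]
        with pytest.raises(ConfigurationError):
            pj.simulate_banding_data(d, pop, cov, p, {non_box: 0.5}, seed=48)

    def test_no_sex_effect_means_equal_rates(self):
        """With e1 = 0 male and female resighting frequencies agree within
        a two-proportion comparison at ~10^3 individuals."""
        d = pj.generate_design(n_sites=400, n_transects=4, n_years=6,
                               nbox_fraction=1.0, seed=49)
        cov = pj.generate_covariates(d, seed=50)
        p = pj.ModelParams.for_design(d, a0=1.0, b0=3.0, e0=0.0, e1=0.0)
        pop = pj.simulate_population(d, cov, p, seed=51)
        band, alive = pj.simulate_banding_data(d, pop, cov, p, 0.5, seed=52)
        assert band.n_individuals >= 1000
        rates, ns = [], []
        for sex in (0, 1):
            sel = band.sex == sex
            num = den = 0
            for i in np.flatnonzero(sel):
                zi = alive.z[i, band.f[i] + 1:]
                yi = band.y[i, band.f[i] + 1:]
                den += int(zi.sum())
                num += int(yi[zi == 1].sum())
            rates.append(num / den)
            ns.append(den)
        diff = abs(rates[0] - rates[1])
        pbar = (rates[0] * ns[0] + rates[1] * ns[1]) / sum(ns)
        se = np.sqrt(pbar * (1 - pbar) * (1 / ns[0] + 1 / ns[1]))
        assert diff < 3 * se

    def test_shared_survival_with_population_process(self):
        """Empirical per-transition survival of banded birds matches the
        site-level phi used by the population process (large n)."""
        d = pj.generate_design(n_sites=300, n_transects=3, n_years=6,
                               nbox_fraction=1.0, seed=53)
        cov = pj.generate_covariates(d, seed=54)
        p = pj.ModelParams.for_design(d, a0=1.0, b0=0.3, b4=0.5, e0=40.0)
        pop = pj.simulate_population(d, cov, p, seed=55)
        band, alive = pj.simulate_banding_data(d, pop, cov, p, 0.5, seed=56)
        from popjoint.occupancy import phi_matrix
        phi = phi_matrix(cov, p)
        surv, pred = [], []
        for i in range(band.n_individuals):
            j = band.site[i]
            for t in range(band.f[i] + 1, d.n_years):
                if alive.z[i, t - 1] == 1:
                    surv.append(alive.z[i, t])
                    pred.append(phi[j, t])
        surv = np.asarray(surv, dtype=float)
        pred = np.asarray(pred)
        assert len(surv) > 2000
        # grouped comparison: empirical survival tracks predicted phi
        lo_grp = pred < np.median(pred)
        for grp in (lo_grp, ~lo_grp):
            emp = surv[grp].mean()
            want = pred[grp].mean()
            se = np.sqrt(want * (1 - want) / grp.sum())
            assert abs(emp - want) < 4 * se


def test_dataset_bit_reproducible():
    d = pj.generate_design(n_sites=25, n_transects=5, seed=57)
    cov = pj.generate_covariates(d, seed=58)
    p = pj.default_params(d, seed=59)
    a = pj.simulate_dataset(d, cov, p, seed=60)
    b = pj.simulate_dataset(d, cov, p, seed=60)
    assert np.array_equal(a.detection.y, b.detection.y)
    assert np.array_equal(a.banding.y, b.banding.y)
    assert np.array_equal(a.truth.pop.N, b.truth.pop.N)
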