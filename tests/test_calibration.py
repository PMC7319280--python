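import numpy as np
import pytest

from p53pool.calibration import (CalibrationConfig, ModelPoolCalibration,
                                 pool_residuals, pool_targets, weighted_chi2)
from p53pool.clustering import PeakBasedMean
from p53pool.parameters import NOISE_SUSCEPTIBLE, REFERENCE_PARAMETERS
from p53pool.pool import ModelPool
from p53pool.synthetic import DEFAULT_MODIFIERS

CFG = CalibrationConfig()


class TestResiduals:
    def test_pool_is_its_own_perfect_target(self, two_pool, two_pool_targets):
        r = pool_residuals(two_pool, two_pool_targets, CFG)
        assert np.max(np.abs(r)) < 1e-6

    def test_sigma_normalisation_of_value_residuals(self, two_pool, two_pool_targets):
        shifted = []
        for t in two_pool_targets:
            sigma_y = CFG.sigma_y_frac * t.peak_values[0]
            vals = t.peak_values.copy()
            vals[1] += sigma_y  # not the first peak: it defines sigma_y itself
            shifted.append(PeakBasedMean(
                cluster=t.cluster, n_members=t.n_members,
                initial_value=t.initial_value, initial_time=t.initial_time,
                peak_times=t.peak_times, peak_values=vals,
                min_times=t.min_times, min_values=t.min_values))
        r = pool_residuals(two_pool, shifted, CFG, weighted=False)
        # exactly one unit residual per cluster block (the shifted value)
        assert sorted(np.abs(r[np.abs(r) > 1e-6]).round(6)) == [1.0, 1.0]

    def test_sigma_normalisation_of_timing_residuals(self, two_pool, two_pool_targets):
        shifted = []
        for t in two_pool_targets:
            times = t.peak_times.copy()
            times[1] += CFG.sigma_t
            shifted.append(PeakBasedMean(
                cluster=t.cluster, n_members=t.n_members,
                initial_value=t.initial_value, initial_time=t.initial_time,
                peak_times=times, peak_values=t.peak_values,
                min_times=t.min_times, min_values=t.min_values))
        r = pool_residuals(two_pool, shifted, CFG, weighted=False)
        assert sorted(np.abs(r[np.abs(r) > 1e-6]).round(6)) == [1.0, 1.0]

    def test_missing_simulated_peak_incurs_penalty(self, two_pool):
        from p53pool.calibration import simulated_extrema

        single = ModelPool(shared=two_pool.shared, modifiers=two_pool.modifiers[[0]],
                           weights=np.array([1.0]))
        _, seq = simulated_extrema(single.member_params(0), CFG)
        n_sim = seq.n_peaks
        # target demands one more pulse than the simulation produces
        times = [seq.maxima[i].time for i in range(n_sim)] + [90.0]
        vals = [seq.maxima[i].value for i in range(n_sim)] + [seq.maxima[0].value]
        target = PeakBasedMean(
            cluster=1, n_members=10, initial_value=vals[0], initial_time=0.5,
            peak_times=times, peak_values=vals,
            min_times=[np.nan] * (n_sim + 1), min_values=[np.nan] * (n_sim + 1))
        r = pool_residuals(single, [target], CFG, weighted=False)
        assert np.sum(r == CFG.missing_peak_penalty) == 2  # both slots of the pulse

    def test_weighting_matches_per_cluster_ssr(self, two_pool, two_pool_targets):
        w = np.array([0.75, 0.25])
        pool = ModelPool(shared=two_pool.shared, modifiers=two_pool.modifiers,
                         weights=w)
        # perturb the targets so residuals are nonzero
        bumped = []
        for t in two_pool_targets:
            vals = t.peak_values * 1.1
            bumped.append(PeakBasedMean(
                cluster=t.cluster, n_members=t.n_members,
                initial_value=t.initial_value, initial_time=t.initial_time,
                peak_times=t.peak_times, peak_values=vals,
                min_times=t.min_times, min_values=t.min_values))
        per_cluster = []
        for k in range(2):
            single = ModelPool(shared=pool.shared, modifiers=pool.modifiers[[k]],
                               weights=np.array([1.0]))
            rk = pool_residuals(single, [bumped[k]], CFG, weighted=False)
            per_cluster.append(float(np.sum(rk ** 2)))
        chi2, log10_chi2 = weighted_chi2(pool, bumped, CFG)
        assert chi2 == pytest.approx(w @ per_cluster, rel=1e-9)
        assert log10_chi2 == pytest.approx(np.log10(chi2))

    def test_perfect_fit_chi2_floored_log(self, two_pool, two_pool_targets):
        chi2, log10_chi2 = weighted_chi2(two_pool, two_pool_targets, CFG)
        assert chi2 < 1e-10
        assert log10_chi2 >= np.log10(CFG.log_chi2_floor)


class TestObjective:
    def test_candidate_modifier_count(self):
        from p53pool.synthetic import default_pool

        assert default_pool(10).n_candidate_modifiers == 60
        assert default_pool(2).n_candidate_modifiers == 12

    def test_zero_modifiers_zero_penalty(self, two_pool_targets):
        model = ModelPoolCalibration(two_pool_targets, config=CFG)
        pool = ModelPool(shared=REFERENCE_PARAMETERS,
                         modifiers=np.zeros((2, 6)), weights=np.full(2, 0.5))
        assert model.objective(pool, lam=100.0) == pytest.approx(
            model.objective(pool, lam=0.0))

    def test_objective_monotone_in_lambda(self, two_pool, two_pool_targets):
        model = ModelPoolCalibration(two_pool_targets, config=CFG)
        values = [model.objective(two_pool, lam) for lam in (0.0, 0.5, 2.0)]
        assert values[0] <= values[1] <= values[2]

    def test_penalty_arithmetic(self, two_pool, two_pool_targets):
        model = ModelPoolCalibration(two_pool_targets, config=CFG)
        j0 = model.objective(two_pool, 0.0)
        j1 = model.objective(two_pool, 1.0)
        assert j1 - j0 == pytest.approx(np.abs(two_pool.modifiers).sum(), rel=1e-9)

    def test_count_specific(self, two_pool):
        assert two_pool.count_specific() == 10  # the beta_wt column is zero
        z = ModelPool(shared=two_pool.shared, modifiers=np.zeros((2, 6)),
                      weights=np.full(2, 0.5))
        assert z.count_specific() == 0
        full = ModelPool(shared=two_pool.shared, modifiers=np.full((10, 6), 0.1),
                         weights=np.full(10, 0.1))
        assert full.count_specific() == 60


class TestFitting:
    def test_modifier_recovery_from_cold_start(self, two_pool, two_pool_targets):
        model = ModelPoolCalibration(
            two_pool_targets, config=CalibrationConfig(max_nfev=40),
            fit_shared=False)
        res = model.fit(n_starts=1)
        np.testing.assert_allclose(res.pool.modifiers, two_pool.modifiers,
                                   atol=0.05)

    def test_same_seed_identical_result(self, two_pool_targets):
        model = ModelPoolCalibration(
            two_pool_targets, config=CalibrationConfig(max_nfev=10),
            fit_shared=False)
        a = model.fit(n_starts=2, seed=5)
        b = model.fit(n_starts=2, seed=5)
        np.testing.assert_array_equal(a.x, b.x)

    def test_huge_penalty_drives_modifiers_to_zero(self, two_pool_targets):
        model = ModelPoolCalibration(
            two_pool_targets, config=CalibrationConfig(max_nfev=40),
            fit_shared=False)
        res = model.fit(lam=1e6, n_starts=1)
        assert np.max(np.abs(res.pool.modifiers)) < 0.02

    def test_single_cluster_degenerate_pool(self, two_pool):
        targets = pool_targets(
            ModelPool(shared=two_pool.shared, modifiers=two_pool.modifiers[[0]],
                      weights=np.array([1.0])), CFG)
        model = ModelPoolCalibration(targets, config=CalibrationConfig(max_nfev=30),
                                     fit_shared=False)
        res = model.fit(n_starts=1)
        assert res.pool.n_subpopulations == 1
        assert res.ssr_weighted < 1e-4

    def test_summary_mentions_key_quantities(self, two_pool, two_pool_targets):
        model = ModelPoolCalibration(two_pool_targets, config=CFG)
        from p53pool.calibration import PoolCalibrationResults
        import pandas as pd

        res = PoolCalibrationResults(model=model, pool=two_pool,
                                     x=np.zeros(34), lam=0.0,
                                     trace=pd.DataFrame(), seed=0)
        text = res.summary()
        assert "subpopulations: 2" in text
        assert "candidate modifiers: 12" in text
        for name in NOISE_SUSCEPTIBLE:
            assert name in text
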