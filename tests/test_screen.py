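import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp

from p53pool.calibration import CalibrationConfig, pool_targets
from p53pool.parameters import PARAM_NAMES
from p53pool.pool import ModelPool
from p53pool.screen import (CONSIDERED_PEAKS, CombinationFit, SignedCombination,
                            condense, condensed_report, enumerate_combinations,
                            feature_sensitivity, fit_combination,
                            group_mechanisms, match_expected_pattern,
                            qualitative_filters, rank_combinations,
                            validate_time_variant)
from p53pool.synthetic import inhibition_triplet

CFG = CalibrationConfig()


class TestEnumeration:
    def test_pair_count_for_22_parameters(self):
        combos = enumerate_combinations(PARAM_NAMES, size=2)
        assert len(combos) == 462
        assert len(set(combos)) == 462

    def test_single_count_with_directions(self):
        assert len(enumerate_combinations(PARAM_NAMES, size=1)) == 44

    def test_three_parameter_pairs(self):
        assert len(enumerate_combinations(["a_m" if False else "alpha_m",
                                           "beta_p", "beta_s"], size=2)) == 6

    def test_no_mirror_duplicates(self):
        combos = enumerate_combinations(("alpha_m", "beta_p"), size=2)
        labels = {c.label for c in combos}
        assert labels == {"alpha_m+ & beta_p+", "alpha_m+ & beta_p-"}

    def test_oversized_rejected(self):
        with pytest.raises(ValueError):
            enumerate_combinations(("alpha_m",), size=2)


class TestCondense:
    def test_below_low_threshold_is_no_effect(self):
        assert condense([5e-5, 8e-5, 2e-5]) == "no-effect"

    def test_consistent_positive_is_increase(self):
        assert condense([2e-3, 3e-3, 1.5e-3]) == "increase"

    def test_mixed_signs_inconsistent(self):
        assert condense([2e-3, -2e-3]) == "inconsistent"

    def test_consistent_negative_is_decrease(self):
        assert condense([-2e-3, -5e-4]) == "decrease"

    def test_all_nan_is_undefined(self):
        assert condense([np.nan, np.nan]) == "undefined"

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            condense([1e-3], theta_lo=1e-2, theta_hi=1e-3)


class TestSensitivity:
    def test_zero_perturbation_zero_coefficients(self, two_pool):
        table = feature_sensitivity(two_pool, SignedCombination(("alpha_s",), (1,)),
                                    delta=0.0, config=CFG)
        defined = table["s"].dropna()
        assert np.max(np.abs(defined)) == 0.0

    def test_matches_central_difference_oracle(self, two_pool):
        """Forward coefficients at +1% agree with a central finite
        difference computed with an independent integrator within 5%."""
        from tests.test_ode import independent_rhs
        from p53pool.trajectories import Trajectory, detect_extrema, extract_features
        from p53pool.ode import steady_state

        member = two_pool.member_params(0)

        def features_oracle(params):
            ss = steady_state(params)
            grid = np.arange(0.0, 24.0001, 0.01)
            sol = solve_ivp(independent_rhs(params), (0, 24), ss, method="LSODA",
                            t_eval=grid, rtol=1e-10, atol=1e-12)
            y = sol.y[1] + sol.y[2]
            traj = Trajectory("o", grid, y)
            seq = detect_extrema(traj, refine=True)
            return extract_features(seq, max_peaks=4,
                                    initial_value=float(y[0]), initial_time=0.0)

        delta = 0.01
        up = features_oracle(member.replace(alpha_m=member.alpha_m * (1 + delta)))
        down = features_oracle(member.replace(alpha_m=member.alpha_m * (1 - delta)))
        table = feature_sensitivity(two_pool, SignedCombination(("alpha_m",), (1,)),
                                    delta=delta, config=CFG)
        mine = table[table["subpopulation"] == 1].set_index(["feature", "peak_index"])["s"]
        checked = 0
        for feature in ("t_max", "t_min", "ipi", "df"):
            for idx in CONSIDERED_PEAKS[feature]:
                if idx in up[feature] and idx in down[feature]:
                    base = 0.5 * (up[feature][idx] + down[feature][idx])
                    central = (up[feature][idx] - down[feature][idx]) / (2 * base)
                    got = mine.get((feature, idx), np.nan)
                    if np.isfinite(got) and abs(got) > 1e-3:
                        # forward difference vs central difference: the
                        # half-step offset is within the 5% band
                        assert got * 2 == pytest.approx(2 * central, rel=0.05, abs=2e-4)
                        checked += 1
        assert checked >= 4

    def test_undefined_entries_when_pulsatility_lost(self, two_pool):
        # a -30% push on Wip1 translation can suppress late pulses
        table = feature_sensitivity(two_pool, SignedCombination(("beta_wtw",), (1,)),
                                    delta=-0.50, config=CFG)
        assert table["s"].isna().any() or (table["s"].abs() > 0).any()


class TestExpectedPattern:
    def make_report(self, calls):
        rows = []
        for (combo, sub), call in calls.items():
            for feature in ("t_max", "t_min", "ipi", "df"):
                rows.append({"combination": combo, "subpopulation": sub,
                             "feature": feature, "call": call})
        return pd.DataFrame(rows)

    def test_all_increase_everywhere_matches(self):
        combos = [SignedCombination(("alpha_m", "beta_p"), (1, 1))]
        report = self.make_report({(combos[0].label, s): "increase"
                                   for s in range(1, 11)})
        assert match_expected_pattern(report, combos, 10) == combos

    def test_boundary_six_of_ten_fails_at_seven(self):
        combos = [SignedCombination(("alpha_m", "beta_p"), (1, 1))]
        calls = {(combos[0].label, s): ("increase" if s <= 6 else "inconsistent")
                 for s in range(1, 11)}
        assert match_expected_pattern(self.make_report(calls), combos, 7) == []

    def test_all_decrease_matches_flipped_combination(self):
        combos = [SignedCombination(("alpha_m", "beta_p"), (1, -1))]
        report = self.make_report({(combos[0].label, s): "decrease"
                                   for s in range(1, 11)})
        matched = match_expected_pattern(report, combos, 10)
        assert matched == [combos[0].flipped()]
        assert matched[0].signs == (-1, 1)

    def test_relaxing_threshold_never_shrinks_selection(self, two_pool):
        combos = enumerate_combinations(
            ("alpha_mpi", "alpha_m", "beta_sp", "alpha_s"), size=2)
        report = condensed_report(two_pool, combos, delta=0.01, config=CFG)
        strict = set(c.label for c in match_expected_pattern(report, combos, 2))
        relaxed = set(c.label for c in match_expected_pattern(report, combos, 1))
        assert strict <= relaxed


class TestCombinationInference:
    def test_true_triplet_recovered_from_noiseless_targets(self, two_pool):
        targets = pool_targets(two_pool, CFG,
                               perturbations=inhibition_triplet(0.3, -1.0))
        fit = fit_combination(two_pool, ("alpha_mpi", "alpha_m", "beta_sp"),
                              targets, t_inh=-1.0, config=CFG)
        np.testing.assert_allclose(fit.pi, [0.3, 0.3, -0.3], atol=0.1)

    def test_null_perturbation_fits_to_zero(self, two_pool, two_pool_targets):
        fit = fit_combination(two_pool, ("alpha_mpi", "alpha_m"),
                              two_pool_targets, t_inh=-1.0, config=CFG)
        np.testing.assert_allclose(fit.pi, 0.0, atol=0.02)

    def test_irrelevant_pair_scores_worse_than_true_triplet(self, two_pool):
        targets = pool_targets(two_pool, CFG,
                               perturbations=inhibition_triplet(0.3, -1.0))
        true = fit_combination(two_pool, ("alpha_mpi", "alpha_m", "beta_sp"),
                               targets, config=CFG)
        decoy = fit_combination(two_pool, ("beta_wt", "alpha_wt"),
                                targets, config=CFG)
        assert decoy.chi2 > 10 * max(true.chi2, 1e-6)

    def test_unknown_parameter_rejected(self, two_pool, two_pool_targets):
        with pytest.raises(ValueError):
            fit_combination(two_pool, ("not_a_rate",), two_pool_targets)


class TestRankingAndValidation:
    def make_fit(self, label_params, chi2):
        return CombinationFit(params=label_params, pi=np.zeros(len(label_params)),
                              t_inh=-1.0, chi2=chi2,
                              log10_chi2=float(np.log10(max(chi2, 1e-12))))

    def test_ascending_rank_with_stable_ties(self):
        fits = [self.make_fit(("b",), 3.0), self.make_fit(("a",), 1.0),
                self.make_fit(("c",), 2.0), self.make_fit(("a", "b"), 2.0)]
        ranked = rank_combinations(fits, top_n=10)
        assert [f.chi2 for f in ranked] == [1.0, 2.0, 2.0, 3.0]
        assert ranked[1].label < ranked[2].label

    def test_top_n_larger_than_list(self):
        fits = [self.make_fit(("a",), 1.0)]
        assert len(rank_combinations(fits, top_n=30)) == 1

    def test_time_variant_scoring_prefers_true_combination(self, two_pool):
        onsets = (1.5, 5.0)
        datasets = {o: pool_targets(two_pool, CFG,
                                    perturbations=inhibition_triplet(0.3, o))
                    for o in onsets}
        true = CombinationFit(params=("alpha_mpi", "alpha_m", "beta_sp"),
                              pi=np.array([0.3, 0.3, -0.3]), t_inh=-1.0,
                              chi2=0.0, log10_chi2=-12.0)
        decoy = CombinationFit(params=("beta_p",), pi=np.array([0.4]),
                               t_inh=-1.0, chi2=0.0, log10_chi2=-12.0)
        true_v = validate_time_variant(two_pool, true, datasets,
                                       groups=[[1.5], [5.0]], config=CFG)
        decoy_v = validate_time_variant(two_pool, decoy, datasets,
                                        groups=[[1.5], [5.0]], config=CFG)
        assert true_v.summarized_log10_chi2 < decoy_v.summarized_log10_chi2
        assert set(true_v.validation) == {1.5, 5.0}
        # a perfectly matching perturbation floors at the guard
        assert true_v.validation[1.5] < 1e-6


class TestQualitativeFilters:
    def test_null_perturbation_passes_all(self, two_pool):
        verdicts = qualitative_filters(two_pool, (), config=CFG)
        assert verdicts["pass_all"]
        assert all(verdicts.values())

    def test_reduced_atm_activation_fails_kinase_check(self, two_pool):
        from p53pool.ode import Perturbation

        verdicts = qualitative_filters(
            two_pool, (Perturbation("beta_s", -0.5, -1.0),), config=CFG)
        assert not verdicts["kinase_activity_not_decreased"]
        assert not verdicts["pass_all"]

    def test_mdm2_mrna_overshoot_fails_ceiling(self, two_pool):
        from p53pool.ode import Perturbation

        verdicts = qualitative_filters(
            two_pool, (Perturbation("beta_mt", 2.0, -1.0),), config=CFG,
            mdm2_mrna_ceiling=5.0)
        assert not verdicts["mdm2_mrna_not_overshooting"]


class TestMechanismGrouping:
    def fit(self, params, pi):
        return CombinationFit(params=params, pi=np.asarray(pi, float),
                              t_inh=-1.0, chi2=1.0, log10_chi2=0.0)

    def test_activation_process_identity_merges_combinations(self):
        fits = [
            self.fit(("alpha_mpi", "alpha_m", "beta_sp"), [0.3, 0.3, -0.3]),
            self.fit(("alpha_mpi", "alpha_m", "T_s"), [0.3, 0.3, 0.3]),
            self.fit(("alpha_mpa", "alpha_sm", "beta_sp"), [-0.3, -0.3, -0.3]),
            self.fit(("alpha_mpa", "alpha_sm", "T_s"), [-0.3, -0.3, 0.3]),
        ]
        groups = group_mechanisms(fits)
        assert len(groups) == 2
        sizes = sorted(len(g.members) for g in groups)
        assert sizes == [2, 2]
        labels = {g.label for g in groups}
        assert any("p53 activation by ATM down" in l for l in labels)

    def test_disjoint_combinations_stay_separate(self):
        fits = [self.fit(("alpha_m",), [0.3]), self.fit(("beta_p",), [0.3])]
        assert len(group_mechanisms(fits)) == 2

    def test_opposite_directions_not_merged(self):
        fits = [self.fit(("beta_sp",), [0.3]), self.fit(("beta_sp",), [-0.3])]
        assert len(group_mechanisms(fits)) == 2
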