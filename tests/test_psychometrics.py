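import io

import numpy as np
import pytest

from rnlcolour.psychometrics import (LevelData, PsychometricFit,
                                     UnattainableCriterionError,
                                     binomial_criterion, compare_conditions,
                                     fit_psychometric, psi,
                                     read_trial_table, threshold_from_fit)
from rnlcolour.synth import SimulatedObserver, simulate_session

LADDER = (0.1, 0.6, 2.1, 3.7, 5.2, 6.9)


class TestPsi:
    def test_asymptotes(self):
        assert psi(-1e6, 0.5, 0.05, 3.0, 0.8) == pytest.approx(0.5)
        assert psi(1e6, 0.5, 0.05, 3.0, 0.8) == pytest.approx(0.95)

    def test_midpoint_at_position(self):
        val = psi(3.0, 0.5, 0.04, 3.0, 0.8)
        assert val == pytest.approx(0.5 + (1 - 0.5 - 0.04) / 2)

    def test_positive_steepness_required(self):
        with pytest.raises(ValueError):
            psi(1.0, 0.5, 0.0, 3.0, 0.0)


class TestFitting:
    def test_noise_free_data_reproduces_curve(self):
        # counts exactly on a logistic (gamma=0.5, lapse=0): the ML fit
        # must pass through the generating probabilities at every level
        a, b, n = 3.0, 0.8, 200
        probs = np.array([0.52, 0.60, 0.75, 0.90, 0.96])
        # place levels so psi(x)=p exactly, then counts p*n are integers
        levels = [a - b * np.log(0.5 / (p - 0.5) - 1.0) for p in probs]
        data = [LevelData(x, n, int(round(p * n)))
                for x, p in zip(levels, probs)]
        fit = fit_psychometric(data)
        assert fit.converged
        for x, p in zip(levels, probs):
            got = psi(x, fit.guess_rate, fit.lapse_rate, fit.position,
                      fit.steepness)
            assert got == pytest.approx(p, abs=1e-6)

    def test_chance_level_data_does_not_converge(self):
        data = [LevelData(x, 30, 15) for x in LADDER]
        fit = fit_psychometric(data)
        assert not fit.converged
        with pytest.raises(UnattainableCriterionError):
            threshold_from_fit(fit, 2 / 3)

    def test_threshold_recovery_median_within_ten_percent(self):
        # simulated observers at the experiment's design (6 levels, 30
        # trials each); generating params a=3, b=0.8, lapse=0.05
        obs = SimulatedObserver(position=3.0, steepness=0.8, lapse_rate=0.05)
        true_thr = 3.0 - 0.8 * np.log(0.45 / (2 / 3 - 0.5) - 1.0)
        rec = []
        for seed in range(60):
            data = simulate_session(obs, LADDER, 30, seed=seed)
            fit = fit_psychometric(data)
            if fit.converged:
                try:
                    rec.append(threshold_from_fit(fit, 2 / 3))
                except UnattainableCriterionError:
                    pass
        assert len(rec) >= 54  # >=90% usable fits
        assert abs(np.median(rec) - true_thr) <= 0.1 * true_thr

    def test_needs_three_distinct_levels(self):
        with pytest.raises(ValueError):
            fit_psychometric([LevelData(1, 30, 20), LevelData(2, 30, 25)])

    def test_wider_lapse_bound_never_lowers_likelihood(self):
        obs = SimulatedObserver(position=2.0, steepness=0.6, lapse_rate=0.2)
        data = simulate_session(obs, LADDER, 30, seed=11)
        narrow = fit_psychometric(data, lapse_bounds=(0.0, 0.05))
        wide = fit_psychometric(data, lapse_bounds=(0.0, 0.25))
        assert wide.log_likelihood >= narrow.log_likelihood - 1e-6


class TestThresholdInversion:
    fit = PsychometricFit(guess_rate=0.5, lapse_rate=0.0, position=3.0,
                          steepness=0.8, log_likelihood=0.0, converged=True,
                          n_levels=6)

    def test_threshold_at_midpoint_criterion(self):
        assert threshold_from_fit(self.fit, 0.75) == pytest.approx(3.0)

    def test_two_thirds_criterion_closed_form(self):
        # x* = a - b*ln((1-g-l)/(c-g) - 1) = 3 - 0.8*ln(2)
        assert threshold_from_fit(self.fit, 2 / 3) == pytest.approx(
            3.0 - 0.8 * np.log(2.0), abs=1e-10)

    def test_monotone_in_criterion(self):
        assert (threshold_from_fit(self.fit, 0.7)
                > threshold_from_fit(self.fit, 0.6))

    def test_psi_inverts_threshold(self):
        for c in (0.55, 2 / 3, 0.9):
            x = threshold_from_fit(self.fit, c)
            assert psi(x, 0.5, 0.0, 3.0, 0.8) == pytest.approx(c, abs=1e-10)

    def test_unattainable_criterion(self):
        lapsy = PsychometricFit(0.5, 0.25, 3.0, 0.8, 0.0, True, 6)
        with pytest.raises(UnattainableCriterionError):
            threshold_from_fit(lapsy, 0.8)


class TestBinomialCriterion:
    def test_thirty_trials_gives_two_thirds(self):
        k, prop = binomial_criterion(30, 0.5, 0.05)
        assert k == 20
        assert prop == pytest.approx(2 / 3, abs=1e-9)

    def test_ten_trials_gives_ninety_percent(self):
        # exact tails: P(X>=9)=11/1024 < 0.05 < P(X>=8)=56/1024
        k, prop = binomial_criterion(10, 0.5, 0.05)
        assert (k, prop) == (9, 0.9)

    def test_single_trial_unattainable(self):
        with pytest.raises(UnattainableCriterionError):
            binomial_criterion(1, 0.5, 0.05)


class TestRankSum:
    def test_identical_groups_p_one(self):
        w, p = compare_conditions([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_fully_separated_groups(self):
        # group ranks 1,2,3: minimal possible rank sum; exact two-sided p
        # over the 20 equally likely assignments is 2/20
        w, p = compare_conditions([1, 2, 3], [10, 20, 30])
        assert w == 6.0
        assert p == pytest.approx(0.1)

    def test_label_swap_symmetry(self):
        a, b = [1.1, 2.3, 0.4, 5.0], [2.0, 3.1, 4.2]
        _, p1 = compare_conditions(a, b)
        _, p2 = compare_conditions(b, a)
        assert p1 == pytest.approx(p2)

    def test_large_groups_use_normal_approximation(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(4, 1, 10)
        _, p = compare_conditions(a, b)
        assert p < 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_conditions([1.0], [1, 2, 3])


class TestTrialTable:
    def test_aggregated_layout(self):
        txt = "level,n_trials,n_correct\n0.1,30,16\n6.9,30,29\n"
        data = read_trial_table(io.StringIO(txt))
        assert data[1] == LevelData(6.9, 30, 29)

    def test_per_trial_layout_aggregates(self):
        txt = "level,choice_correct\n1.0,1\n1.0,0\n1.0,1\n2.0,1\n"
        data = read_trial_table(io.StringIO(txt))
        assert data[0] == LevelData(1.0, 3, 2)
        assert data[1] == LevelData(2.0, 1, 1)

    def test_bad_columns_rejected(self):
        with pytest.raises(ValueError):
            read_trial_table(io.StringIO("a,b\n1,2\n"))

    def test_count_invariant(self):
        with pytest.raises(ValueError):
            LevelData(1.0, 30, 31)
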