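"""Evidence pipeline and analytic race likelihood."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate
from scipy.special import expit

import goalglam as gg
from goalglam.core import (
    GlamParams,
    Trial,
    TrialDataset,
    average_absolute_evidence,
    dataset_nll,
    fpt_density,
    goal_relevant_evidence,
    race_choice_probability,
    relative_evidence_binary,
    relative_gaze,
    scaled_evidence,
    trial_likelihood,
)
from goalglam.fit import _simulate_recovery_dataset


class TestGoalRelevantEvidence:
    @pytest.mark.parametrize("r,frame,smax,smin,expected", [
        (3.0, "dislike", 3.0, 0.0, 0.0),      # max bid becomes worthless
        (133.0, "fewest", 133.0, 40.0, 40.0),  # fullest circle -> emptiest
        (1.5, "dislike", 3.0, 0.0, 1.5),       # fixed point of the involution
        (2.2, "like", 3.0, 0.0, 2.2),
        (87.0, "most", 133.0, 40.0, 87.0),
    ])
    def test_worked_values(self, r, frame, smax, smin, expected):
        assert goal_relevant_evidence(r, frame, smax, smin) == pytest.approx(expected)

    @given(r=st.floats(0.0, 3.0))
    @settings(max_examples=50, deadline=None)
    def test_dislike_involution(self, r):
        once = goal_relevant_evidence(r, "dislike", 3.0, 0.0)
        assert goal_relevant_evidence(once, "dislike", 3.0, 0.0) == pytest.approx(r)

    @given(r=st.floats(40.0, 133.0))
    @settings(max_examples=50, deadline=None)
    def test_fewest_involution(self, r):
        once = goal_relevant_evidence(r, "fewest", 133.0, 40.0)
        assert goal_relevant_evidence(once, "fewest", 133.0, 40.0) == pytest.approx(r)
        assert 40.0 <= once <= 133.0

    def test_out_of_scale_is_an_error(self):
        with pytest.raises(ValueError, match="outside scale"):
            goal_relevant_evidence(3.5, "dislike", 3.0, 0.0)
        with pytest.raises(ValueError, match="unknown frame"):
            goal_relevant_evidence(1.0, "maybe", 3.0, 0.0)


class TestEvidenceTerms:
    @pytest.mark.parametrize("dtl,dtr,gl", [
        (500.0, 500.0, 0.5), (0.0, 800.0, 0.0), (600.0, 400.0, 0.6),
    ])
    def test_relative_gaze(self, dtl, dtr, gl):
        g_left, g_right = relative_gaze(dtl, dtr)
        assert g_left == pytest.approx(gl)
        assert g_left + g_right == pytest.approx(1.0)

    def test_zero_dwell_is_an_error(self):
        with pytest.raises(ValueError, match="zero"):
            relative_gaze(0.0, 0.0)

    def test_gaze_discount(self):
        # gamma = 1: gaze makes no difference
        assert average_absolute_evidence(0.17, 2.4, 1.0) == pytest.approx(2.4)
        # the discussion's worked pair: gazed item keeps r, other keeps gamma*r
        a1 = average_absolute_evidence(1.0, 2.0, 0.3)
        a2 = average_absolute_evidence(0.0, 1.0, 0.3)
        assert (a1, a2) == (pytest.approx(2.0), pytest.approx(0.3))
        assert a1 - a2 == pytest.approx(1.7)
        assert average_absolute_evidence(0.5, 2.0, 0.0) == pytest.approx(1.0)

    @given(a=st.floats(-10, 10), b=st.floats(-10, 10))
    @settings(max_examples=50, deadline=None)
    def test_relative_evidence_antisymmetry(self, a, b):
        rl, rr = relative_evidence_binary(a, b)
        assert rl == pytest.approx(a - b)
        assert rr == -rl

    def test_scaled_evidence(self):
        assert scaled_evidence(0.0, 3.0) == pytest.approx(0.5)
        assert scaled_evidence(123.4, 0.0) == pytest.approx(0.5)
        assert scaled_evidence(1.7, 1.0) == pytest.approx(1 / (1 + np.exp(-1.7)))
        with pytest.raises(ValueError):
            scaled_evidence(1.0, -0.5)


class TestParams:
    @pytest.mark.parametrize("kwargs", [
        dict(nu=-1e-4, gamma=0.0, sigma=0.01, tau=1.0),
        dict(nu=5e-4, gamma=1.5, sigma=0.01, tau=1.0),
        dict(nu=5e-4, gamma=0.0, sigma=0.0, tau=1.0),
        dict(nu=5e-4, gamma=0.0, sigma=0.01, tau=-0.1),
        dict(nu=5e-4, gamma=0.0, sigma=0.01, tau=1.0, boundary=2.0),
        dict(nu=5e-4, gamma=0.0, sigma=0.01, tau=1.0, contaminant_rate=1.0),
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GlamParams(**kwargs)

    def test_trial_invariants(self):
        with pytest.raises(ValueError, match="exceed"):
            Trial(frame="like", r_left=1, r_right=2, dt_left=1500, dt_right=1000,
                  choice="left", rt=2.0)
        with pytest.raises(ValueError, match="rt"):
            Trial(frame="like", r_left=1, r_right=2, dt_left=100, dt_right=100,
                  choice="left", rt=0.0)


class TestFirstPassage:
    def test_wald_mean_and_normalisation(self):
        # mean of the distribution is boundary / drift
        mean, _ = integrate.quad(lambda t: t * fpt_density(t, 0.5, 0.3), 0, 200)
        assert mean == pytest.approx(2.0, rel=1e-4)
        total, _ = integrate.quad(lambda t: fpt_density(t, 0.5, 0.3), 0, 400)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_domain(self):
        assert fpt_density(-1.0, 0.5, 0.3) == 0.0
        assert fpt_density(0.0, 0.5, 0.3) == 0.0
        with pytest.raises(ValueError):
            fpt_density(1.0, -0.5, 0.3)


def _sym_trial(rt=2.0, dtl=500.0, dtr=500.0, rl=1.5, rr=1.5, choice="right"):
    return Trial(frame="like", r_left=rl, r_right=rr, dt_left=dtl, dt_right=dtr,
                 choice=choice, rt=rt, trial_index=1)


class TestTrialLikelihood:
    def test_symmetric_trial_is_fair(self, std_params):
        p = race_choice_probability(std_params.nu * 0.5, std_params.nu * 0.5,
                                    std_params.sigma)
        assert p == pytest.approx(0.5, abs=1e-6)

    def test_total_probability_is_one(self, std_params):
        # gaze split 0.7/0.3 held fixed while rt varies in the quadrature
        bounds = (0.1, 30.0)
        total = 0.0
        for choice in ("left", "right"):
            def f(rt, choice=choice):
                return trial_likelihood(
                    Trial(frame="like", r_left=2.0, r_right=1.0,
                          dt_left=0.7 * rt * 1000, dt_right=0.3 * rt * 1000,
                          choice=choice, rt=rt, trial_index=1),
                    std_params, bounds)
            val, _ = integrate.quad(f, 1e-3, 60.0, limit=200)
            total += val
        assert total == pytest.approx(1.0, abs=1e-4)

    def test_degenerate_bounds_rejected(self, std_params):
        with pytest.raises(ValueError, match="rt_bounds"):
            trial_likelihood(_sym_trial(), std_params, (2.0, 2.0))

    def test_choice_probability_matches_simulation(self, std_params):
        # likelihood-implied choice probability vs a large race simulation
        from goalglam.simulate import sample_wald_fpt
        d_r = std_params.nu * expit(std_params.tau * 0.9)
        d_l = std_params.nu * expit(-std_params.tau * 0.9)
        p_analytic = race_choice_probability(d_r, d_l, std_params.sigma)
        rng = np.random.default_rng(0)
        n = 100_000
        tr = sample_wald_fpt(np.full(n, d_r), std_params.sigma, 1.0, rng)
        tl = sample_wald_fpt(np.full(n, d_l), std_params.sigma, 1.0, rng)
        assert p_analytic == pytest.approx((tr < tl).mean(), abs=0.01)

    def test_monotone_in_gaze(self, std_params):
        # P(choose right) strictly increases with relative gaze on the right
        probs = []
        for g_right in (0.2, 0.4, 0.6, 0.8):
            t = _sym_trial(dtl=(1 - g_right) * 1000, dtr=g_right * 1000,
                           rl=1.5, rr=1.5)
            terms = gg.compute_evidence_terms(t, std_params)
            d_l = std_params.nu * terms.r_left_scaled
            d_r = std_params.nu * terms.r_right_scaled
            probs.append(race_choice_probability(d_r, d_l, std_params.sigma))
        assert np.all(np.diff(probs) > 0)

    def test_gamma_one_removes_gaze(self):
        params = GlamParams(nu=5e-4, gamma=1.0, sigma=0.01, tau=1.0)
        bounds = (0.1, 30.0)
        lik = [trial_likelihood(_sym_trial(dtl=dtl, dtr=1000 - dtl,
                                           rl=2.0, rr=1.0),
                                params, bounds)
               for dtl in (100.0, 500.0, 900.0)]
        assert np.ptp(lik) < 1e-12


class TestDatasetNLL:
    def test_empty_dataset(self, std_params):
        ds = TrialDataset("p", "value", [])
        assert dataset_nll(ds, std_params) == 0.0

    def test_single_trial_definition(self, std_params):
        t = _sym_trial(dtl=700.0, dtr=300.0, rl=2.0, rr=1.0)
        ds = TrialDataset("p", "value", [t])
        bounds = (0.5, 10.0)
        nll = dataset_nll(ds, std_params, rt_bounds=bounds)
        lik = trial_likelihood(t, std_params, bounds)
        assert nll == pytest.approx(-np.log(lik))

    def test_true_params_beat_perturbed(self, std_params):
        """NLL at generating parameters <= NLL at nu doubled, in >=95% of
        seeded replicates of 500 simulated trials."""
        perturbed = std_params.with_(nu=std_params.nu * 2)
        wins = 0
        n_rep = 40
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            ds = _simulate_recovery_dataset(std_params, 500, rng)
            if dataset_nll(ds, std_params) <= dataset_nll(ds, perturbed):
                wins += 1
        assert wins >= int(0.95 * n_rep)

    def test_zero_dwell_trials_excluded_with_warning(self, std_params):
        good = _sym_trial(dtl=700.0, dtr=300.0, rl=2.0, rr=1.0)
        bad = Trial(frame="like", r_left=1.0, r_right=2.0, dt_left=0.0,
                    dt_right=0.0, choice="left", rt=1.5, trial_index=2)
        ds = TrialDataset("p", "value", [good, bad])
        with pytest.warns(UserWarning, match="zero total dwell"):
            nll = dataset_nll(ds, std_params, rt_bounds=(0.5, 10.0))
        assert np.isfinite(nll)
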