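"""Behavioural analyses: regressions, gaze influence, time series, FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from statsmodels.stats.multitest import multipletests

import goalglam as gg
from goalglam.core import Fixation, Trial, TrialDataset
from goalglam.analysis import (
    choice_regression,
    confidence_regression,
    delta_e_regression,
    fixation_timeseries,
    gaze_influence,
    last_fixation_analysis,
    permutation_frame_test,
)


def _dataset(pid, trials):
    return TrialDataset(pid, "value", trials)


def _make_trials(rng, n, choice_rule, conf_rule=None, frame="like"):
    trials = []
    for i in range(n):
        rl, rr = rng.uniform(0, 3, 2)
        g_r = rng.beta(3, 3)
        rt = rng.uniform(1, 4)
        dv, ddt = rr - rl, (2 * g_r - 1) * 1000
        choice = choice_rule(dv, ddt, rng)
        conf = conf_rule(rl, rr, rt) if conf_rule else rng.integers(1, 11)
        trials.append(Trial(
            frame=frame, r_left=rl, r_right=rr, dt_left=(1 - g_r) * 1000,
            dt_right=g_r * 1000, choice=choice, rt=rt, confidence=float(conf),
            trial_index=i + 1))
    return trials


class TestChoiceRegression:
    def test_dwell_driven_chooser(self):
        rng = np.random.default_rng(0)
        rule = lambda dv, ddt, rng: "right" if ddt > 0 else "left"
        data = [_dataset(f"p{k}", _make_trials(rng, 100, rule))
                for k in range(6)]
        res = choice_regression(data, "like")
        c = res.coefficients.set_index("name")
        assert c.loc["ddt", "estimate"] > 2 * abs(c.loc["dv", "estimate"])
        assert c.loc["ddt", "estimate"] > 0

    def test_null_calibration_per_coefficient(self):
        """Random choices: each coefficient non-significant at alpha=0.05 in
        >=90% of seeded replicates."""
        counts = {p: 0 for p in ("dv", "rt", "sv", "ddt", "conf")}
        n_rep = 20
        for seed in range(n_rep):
            rng = np.random.default_rng(300 + seed)
            rule = lambda dv, ddt, rng: ("right" if rng.uniform() < 0.5
                                         else "left")
            data = [_dataset(f"p{k}", _make_trials(rng, 80, rule))
                    for k in range(6)]
            c = choice_regression(data, "like").coefficients.set_index("name")
            for p in counts:
                counts[p] += int(c.loc[p, "p"] > 0.05)
        for p, n_ns in counts.items():
            assert n_ns >= int(0.9 * n_rep), (p, n_ns)

    def test_needs_multiple_participants(self):
        rng = np.random.default_rng(1)
        rule = lambda dv, ddt, rng: "right"
        with pytest.raises(ValueError, match="two participants"):
            choice_regression([_dataset("p", _make_trials(rng, 40, rule))])


class TestConfidenceRegression:
    def test_exact_linear_recovery(self):
        rng = np.random.default_rng(2)
        data = []
        for k in range(4):
            trials = _make_trials(
                rng, 80,
                lambda dv, ddt, rng: "right" if dv > 0 else "left",
                conf_rule=lambda rl, rr, rt: 2.0 + 0.5 * abs(rr - rl))
            data.append(_dataset(f"p{k}", trials))
        res = confidence_regression(data, "like", predictors=("abs_dv", "rt", "sv"))
        c = res.coefficients.set_index("name")
        # confidence is an exact linear function of |dv|: per-participant
        # OLS recovers the z-scored coefficient exactly, others vanish
        assert abs(c.loc["rt", "estimate"]) < 1e-6
        assert abs(c.loc["sv", "estimate"]) < 1e-6
        per = res.per_participant
        for _, row in per.iterrows():
            assert row["abs_dv"] > 0

    def test_dispatch_to_delta_e_table(self, std_params):
        from goalglam.simulate import SimulationConfig, delta_e_table
        rng = np.random.default_rng(3)
        trials = _make_trials(rng, 60,
                              lambda dv, ddt, rng: "right" if dv > 0 else "left")
        tab = delta_e_table(_dataset("p0", trials), std_params,
                            SimulationConfig(), rng)
        res = confidence_regression(tab)
        assert res.model.startswith("delta_e")
        assert set(res.coefficients["name"]) == {"intercept", "abs_dv",
                                                 "sim_rt", "sv"}

    def test_contaminated_rows_excluded(self, std_params):
        from goalglam.simulate import SimulationConfig, delta_e_table
        rng = np.random.default_rng(4)
        trials = _make_trials(rng, 60,
                              lambda dv, ddt, rng: "right" if dv > 0 else "left")
        params = std_params.with_(contaminant_rate=0.5)
        tab = delta_e_table(_dataset("p0", trials), params,
                            SimulationConfig(), rng)
        res = delta_e_regression(tab)
        assert np.isfinite(res.coefficients["estimate"]).all()


class TestGazeInfluence:
    def _score(self, choice_rule, seed=5):
        rng = np.random.default_rng(seed)
        data = [_dataset(f"p{k}", _make_trials(rng, 120, choice_rule))
                for k in range(4)]
        return gaze_influence(data)["score"].mean()

    def test_value_driven_chooser_scores_zero(self):
        def rule(dv, ddt, rng):
            return "right" if rng.uniform() < expit(3 * dv) else "left"
        assert abs(self._score(rule)) < 0.05

    def test_gaze_driven_chooser_scores_high(self):
        rule = lambda dv, ddt, rng: "right" if ddt > 0 else "left"
        assert self._score(rule) > 0.2

    def test_anti_gaze_chooser_scores_negative(self):
        rule = lambda dv, ddt, rng: "left" if ddt > 0 else "right"
        assert self._score(rule) < -0.2


def _with_fixations(trials, rng, last_on_chosen_p=None):
    """Attach a two-fixation sequence; optionally force last-fixation side."""
    out = []
    for t in trials:
        if last_on_chosen_p is None:
            last = "right" if rng.uniform() < 0.5 else "left"
        else:
            on_chosen = rng.uniform() < last_on_chosen_p
            last = t.choice if on_chosen else ("left" if t.choice == "right"
                                               else "right")
        first = "left" if last == "right" else "right"
        fixs = (Fixation(first, 0.0, 500.0), Fixation(last, 500.0, 500.0))
        out.append(Trial(frame=t.frame, r_left=t.r_left, r_right=t.r_right,
                         dt_left=t.dt_left, dt_right=t.dt_right,
                         choice=t.choice, rt=t.rt, confidence=t.confidence,
                         trial_index=t.trial_index, fixations=fixs))
    return out


class TestLastFixation:
    def test_flip_on_synthetic_world(self, value_world):
        like = last_fixation_analysis(value_world["datasets"], "like")
        dislike = last_fixation_analysis(value_world["datasets"], "dislike")
        assert like.coef("slope") > 0
        assert dislike.coef("slope") < 0

    def test_degenerate_always_chosen_reported(self):
        rng = np.random.default_rng(6)
        rule = lambda dv, ddt, rng: "right" if dv > 0 else "left"
        data = []
        for k in range(3):
            trials = _with_fixations(_make_trials(rng, 60, rule), rng,
                                     last_on_chosen_p=1.0)
            data.append(_dataset(f"p{k}", trials))
        res = last_fixation_analysis(data, "like")
        assert set(res.flagged_participants) == {"p0", "p1", "p2"}
        assert res.per_participant.empty

    def test_sign_symmetry_under_evidence_negation(self):
        rng = np.random.default_rng(7)

        def rule(dv, ddt, rng):
            return "right" if rng.uniform() < expit(2 * dv) else "left"
        data = []
        for k in range(4):
            trials = _with_fixations(_make_trials(rng, 150, rule), rng,
                                     last_on_chosen_p=0.8)
            data.append(_dataset(f"p{k}", trials))
        res = last_fixation_analysis(data, "like")
        # negate evidence (mirror on the bid scale): slope flips exactly
        mirrored = []
        for ds in data:
            mt = [Trial(frame=t.frame, r_left=3 - t.r_left,
                        r_right=3 - t.r_right, dt_left=t.dt_left,
                        dt_right=t.dt_right, choice=t.choice, rt=t.rt,
                        trial_index=t.trial_index, fixations=t.fixations)
                  for t in ds.trials]
            mirrored.append(_dataset(ds.participant_id, mt))
        res_m = last_fixation_analysis(mirrored, "like")
        assert res.coef("slope") == pytest.approx(-res_m.coef("slope"),
                                                  rel=1e-6)


class TestFixationTimeseries:
    def test_null_gaze_uncorrelated(self):
        rng = np.random.default_rng(8)
        rule = lambda dv, ddt, rng: "right" if dv > 0 else "left"
        data = [_dataset(f"p{k}",
                         _with_fixations(_make_trials(rng, 150, rule), rng))
                for k in range(4)]
        ts = fixation_timeseries(data, "like", window_ms=1000.0)
        valid = ts.dropna(subset=["r"])
        bound = 3.0 / np.sqrt(valid["n_trials"])
        assert (np.abs(valid["r"]) < bound).mean() > 0.95

    def test_biased_window_structure(self, value_world):
        ts_like = fixation_timeseries(value_world["datasets"], "like")
        early = ts_like[ts_like["time_ms"] < 400]["r"].mean()
        late = ts_like[ts_like["time_ms"] > 1000]["r"].mean()
        assert abs(early) < 0.05
        assert late > 0.08
        ts_dis = fixation_timeseries(value_world["datasets"], "dislike")
        assert ts_dis[ts_dis["time_ms"] > 1000]["r"].mean() < -0.08

    def test_single_trial_bins_skipped(self):
        t = Trial(frame="like", r_left=1.0, r_right=2.0, dt_left=500,
                  dt_right=500, choice="right", rt=1.0, trial_index=1,
                  fixations=(Fixation("left", 0, 500), Fixation("right", 500, 500)))
        ts = fixation_timeseries([_dataset("p", [t])], "like")
        assert ts["r"].isna().all()


class TestPermutationTest:
    def _relabel_half(self, datasets, rng):
        """Random like/dislike relabelling of like-frame trials: a true null."""
        out = []
        for ds in datasets:
            trials = []
            for t in ds.trials:
                if t.frame != "like":
                    continue
                frame = "dislike" if rng.uniform() < 0.5 else "like"
                trials.append(Trial(
                    frame=frame, r_left=t.r_left, r_right=t.r_right,
                    dt_left=t.dt_left, dt_right=t.dt_right, choice=t.choice,
                    rt=t.rt, trial_index=t.trial_index, fixations=t.fixations))
            out.append(_dataset(ds.participant_id, trials))
        return out

    def test_null_has_no_flagged_bins(self, value_world):
        rng = np.random.default_rng(9)
        null_world = self._relabel_half(value_world["datasets"], rng)
        res = permutation_frame_test(null_world, "like", "dislike",
                                     n_perm=200, rng=rng)
        assert res.table["significant"].sum() == 0

    def test_detects_constructed_opposite_bias(self, value_world):
        res = permutation_frame_test(value_world["datasets"], "like",
                                     "dislike", n_perm=200,
                                     rng=np.random.default_rng(10))
        runs = res.significant_runs
        assert runs, "no significant region found"
        start, end = runs[0]
        assert end - start >= 60.0          # at least 6 contiguous bins
        assert start > 300.0                # not inside the unbiased window

    def test_pvalues_bounded_by_permutation_resolution(self, value_world):
        res = permutation_frame_test(value_world["datasets"], "like",
                                     "dislike", n_perm=200,
                                     rng=np.random.default_rng(11))
        p = res.table["p"].dropna()
        assert (p >= 1.0 / 201.0 - 1e-12).all()

    def test_low_permutation_count_warns(self, value_world):
        with pytest.warns(UserWarning, match="resolution"):
            permutation_frame_test(value_world["datasets"][:2], "like",
                                   "dislike", n_perm=50,
                                   rng=np.random.default_rng(12))


def _brute_force_bh(pvals, q):
    """Reject H_(i) for i <= max{k: p_(k) <= k q / m}, by direct enumeration."""
    m = len(pvals)
    order = np.argsort(pvals)
    k_max = 0
    for k in range(1, m + 1):
        if pvals[order[k - 1]] <= k * q / m:
            k_max = k
    reject = np.zeros(m, bool)
    reject[order[:k_max]] = True
    return reject


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_bh_fdr_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    for m in (7, 50, 200):
        p = rng.uniform(size=m) ** 2
        ours, *_ = multipletests(p, alpha=0.05, method="fdr_bh")[:1]
        np.testing.assert_array_equal(ours, _brute_force_bh(p, 0.05))
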