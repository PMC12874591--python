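"""auROC statistic, permutation test, selectivity classification, measures."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import odorgng as og
from odorgng.selectivity import AurocSeries, _runs
from conftest import go_correct, nogo_correct

samples = st.lists(st.integers(0, 8), min_size=1, max_size=12)


def brute_force_roc_area(pref, ref):
    wins = sum(1.0 if p > r else 0.5 if p == r else 0.0 for p in pref for r in ref)
    return wins / (len(pref) * len(ref))


class TestRocArea:
    def test_complete_separation(self):
        assert og.roc_area([4, 5, 6], [1, 2, 3]) == 1.0

    def test_identical_samples(self):
        assert og.roc_area([1, 2, 3], [1, 2, 3]) == 0.5

    def test_half_tie_credit(self):
        assert og.roc_area([1, 2], [0, 1]) == pytest.approx(3.5 / 4)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            og.roc_area([], [1.0])

    @settings(deadline=None, max_examples=200)
    @given(samples, samples)
    def test_matches_pairwise_oracle(self, pref, ref):
        assert og.roc_area(pref, ref) == pytest.approx(brute_force_roc_area(pref, ref))

    @settings(deadline=None, max_examples=100)
    @given(samples, samples)
    def test_auroc_antisymmetric_and_bounded(self, pref, ref):
        a = og.auroc(pref, ref)
        assert -1.0 <= a <= 1.0
        assert og.auroc(ref, pref) == pytest.approx(-a)


class TestPermutationTest:
    def test_extreme_rank_gives_minimal_pvalue(self, rng):
        pref = np.arange(10, 20)
        ref = np.arange(0, 10)
        p_exc, p_inh = og.permutation_test(pref, ref, 500, rng)
        assert p_exc == pytest.approx(1 / 501)
        assert p_inh == pytest.approx(1.0)

    def test_constant_samples_give_pvalue_one(self, rng):
        p_exc, p_inh = og.permutation_test([2.0] * 6, [2.0] * 6, 200, rng)
        assert p_exc == 1.0 and p_inh == 1.0

    def test_rejects_bad_n_permutations(self, rng):
        with pytest.raises(ValueError):
            og.permutation_test([1.0], [2.0], 0, rng)


def make_series(p_exc, auroc=None, step=0.02, neuron_id="n"):
    p_exc = np.asarray(p_exc, dtype=float)
    n = p_exc.size
    if auroc is None:
        auroc = np.where(p_exc < 0.01, 0.8, 0.0)
    return AurocSeries(
        neuron_id=neuron_id,
        bin_centers=step * np.arange(n),
        auroc=np.asarray(auroc, dtype=float),
        p_exc=p_exc,
        p_inh=np.ones(n),
        n_trials=np.full(n, 20),
        n_permutations=1000,
        contrast="vs_baseline",
        align_event="odor_on",
    )


class TestClassifyCueSelective:
    def null_series(self, n=20):
        return make_series(np.ones(n))

    def test_five_consecutive_bins_qualify(self):
        p = np.ones(20)
        p[6:11] = 0.001
        label = og.classify_cue_selective(make_series(p), self.null_series())
        assert label.label == "go_cue_selective"
        assert label.qualifying_run == (6, 10)

    def test_four_consecutive_bins_do_not_qualify(self):
        p = np.ones(20)
        p[6:10] = 0.001
        label = og.classify_cue_selective(make_series(p), self.null_series())
        assert label.label == "none"

    def test_longer_run_wins_between_conditions(self):
        p_go, p_nogo = np.ones(20), np.ones(20)
        p_go[2:8] = 0.001    # 6 bins
        p_nogo[2:12] = 0.001  # 10 bins
        label = og.classify_cue_selective(make_series(p_go), make_series(p_nogo))
        assert label.label == "nogo_cue_selective"

    def test_refused_series_cannot_qualify(self):
        label = og.classify_cue_selective(og.Refusal("x"), og.Refusal("x"))
        assert label.label == "none"


class TestResponseMeasures:
    def test_hand_computed_example(self):
        """Five equal-auROC significant bins centered 0.10-0.18 s: onset at
        0.10, center of mass 0.14, duration 5 x 20 ms + 80 ms = 0.18 s."""
        p = np.ones(20)
        p[5:10] = 0.001  # centers 0.10 .. 0.18
        m = og.response_measures(make_series(p, auroc=np.where(p < 0.01, 0.5, 0.0)))
        assert m.center_of_mass == pytest.approx(0.14)
        assert m.onset == pytest.approx(0.10)
        assert m.duration == pytest.approx(0.18)

    def test_symmetric_bump_center(self):
        p = np.ones(21)
        p[5:14] = 0.001
        auroc = np.zeros(21)
        auroc[5:14] = [0.1, 0.3, 0.5, 0.7, 0.9, 0.7, 0.5, 0.3, 0.1]
        m = og.response_measures(make_series(p, auroc=auroc))
        assert m.center_of_mass == pytest.approx(0.02 * 9)  # bump center

    def test_no_significant_bins_refused(self):
        assert isinstance(og.response_measures(make_series(np.ones(10))), og.Refusal)

    def test_short_run_returns_center_without_onset(self):
        p = np.ones(20)
        p[6:9] = 0.001  # only 3 consecutive bins
        m = og.response_measures(make_series(p))
        assert m.onset is None and m.duration is None
        assert np.isfinite(m.center_of_mass)


class TestClassifyRewardSelective:
    def test_center_in_waiting_epoch(self):
        m = og.ResponseMeasures(0.1, 0.0, 0.2)
        assert og.classify_reward_selective("n", m).label == "waiting_selective"

    def test_center_in_drinking_epoch(self):
        m = og.ResponseMeasures(0.5, 0.3, 0.4)  # valve opens at 0.3 after entry
        assert og.classify_reward_selective("n", m).label == "drinking_selective"

    def test_center_outside_both(self):
        m = og.ResponseMeasures(2.0, None, None)
        assert og.classify_reward_selective("n", m).label == "none"


def test_runs_helper():
    mask = np.array([0, 1, 1, 0, 1, 1, 1, 0], dtype=bool)
    assert _runs(mask) == [(1, 2), (4, 6)]


class TestSlidingAurocOnGroundTruth:
    def test_go_cue_late_neuron_detected(self, mixed_session, rng):
        session, truth = mixed_session
        nid = next(n for n, l in truth.labels.items() if l == "go_cue_late")
        train = next(s for s in session.spikes if s.neuron_id == nid)
        go = go_correct(session)
        series = og.sliding_auroc(train, go, rng, n_permutations=500)
        label = og.classify_cue_selective(series, og.Refusal("skip"))
        assert label.label == "go_cue_selective"
        # the qualifying run should lie in the late phase (>= 0.5 s post onset)
        sig = series.significant_exc()
        late = series.bin_centers[sig]
        assert late.max() > 0.5

    def test_go_vs_nogo_contrast_prefers_go_late_phase(self, mixed_session, rng):
        session, truth = mixed_session
        nid = next(n for n, l in truth.labels.items() if l == "go_cue_late")
        train = next(s for s in session.spikes if s.neuron_id == nid)
        series = og.sliding_auroc(
            train,
            go_correct(session),
            rng,
            contrast="go_vs_nogo",
            reference_trials=nogo_correct(session),
            n_permutations=500,
        )
        runs = [r for r in _runs(series.significant_exc()) if r[1] - r[0] + 1 >= 5]
        assert runs  # sustained go preference exists ...
        # ... and only in the late phase (isolated early bins can flicker
        # significant because overlapping windows correlate neighboring bins)
        assert all(series.bin_centers[r[0]] >= 0.4 for r in runs)

    def test_too_few_trials_refused(self, mixed_session, rng):
        session, _ = mixed_session
        train = session.spikes[0]
        out = og.sliding_auroc(train, go_correct(session)[:3], rng, n_permutations=100)
        assert isinstance(out, og.Refusal)

    def test_reward_aligned_measures_recover_archetypes(self, mixed_session, rng):
        session, truth = mixed_session
        go = go_correct(session)
        labels = {}
        drinking_onsets = []
        for train in session.spikes:
            series = og.sliding_auroc(
                train,
                go,
                rng,
                align_event="water_port_entry",
                centers=og.REWARD_CENTERS,
                exclude_after=None,
                n_permutations=500,
            )
            if isinstance(series, og.Refusal):
                labels[train.neuron_id] = "none"
                continue
            m = og.response_measures(series)
            labels[train.neuron_id] = og.classify_reward_selective(
                train.neuron_id, m
            ).label
            if truth.labels[train.neuron_id] == "drinking_ramp" and m.onset:
                drinking_onsets.append(m.onset)
        for nid, true_label in truth.labels.items():
            if true_label == "waiting_phasic":
                assert labels[nid] == "waiting_selective"
            elif true_label == "drinking_ramp":
                assert labels[nid] == "drinking_selective"
        # ramping starts before the valve opens (0.3 s after port entry)
        assert drinking_onsets and np.mean(drinking_onsets) < 0.3


def test_epoch_auroc_table_and_group_comparison(rng):
    session, truth = og.simulate_session(
        og.TaskConfig(n_trials=120),
        [
            (og.DEFAULT_ARCHETYPES["waiting_phasic"], 8),
            (og.DEFAULT_ARCHETYPES["drinking_ramp"], 8),
            (og.DEFAULT_ARCHETYPES["untuned"], 8),
        ],
        seed=77,
    )
    go = go_correct(session)
    table = og.epoch_auroc_table(
        session.spikes,
        truth.labels,
        {"go_correct": go},
        rng,
        n_permutations=300,
    )
    assert set(table["group"]) == {"waiting_phasic", "drinking_ramp", "untuned"}
    med = table.groupby("group")["auroc"].median()
    # waiting neurons fire through the late nose-poking epoch; drinking
    # neurons are suppressed below baseline during nose poking
    assert med["waiting_phasic"] > med["untuned"] > med["drinking_ramp"]
    result = og.compare_groups(table, "go_correct")
    assert result["anova_p"] < 0.05
    assert len(result["tukey"]) == 3  # three pairwise comparisons


def test_min_trial_rule_excludes_condition(mixed_session, rng):
    session, _ = mixed_session
    train = session.spikes[0]
    out = og.epoch_auroc(train, go_correct(session)[:4], rng)
    assert isinstance(out, og.Refusal)
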