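"""Encoding GLM: design-matrix layout, fitting, contributions."""

import numpy as np
import pytest

import odorgng as og
from odorgng.glm import DesignMatrix, _trial_folds


@pytest.fixture(scope="module")
def glm_session():
    session, truth = og.simulate_session(
        og.TaskConfig(n_trials=200),
        [
            (og.DEFAULT_ARCHETYPES["go_cue_late"], 1),
            (og.DEFAULT_ARCHETYPES["untuned"], 1),
        ],
        seed=4,
    )
    trials = [
        t
        for t in session.trials
        if t.outcome is og.Outcome.CORRECT and t.trial_type is not og.TrialType.CATCH
    ]
    return session, truth, trials


@pytest.fixture(scope="module")
def dm(glm_session):
    session, _, trials = glm_session
    return og.build_design_matrix(session.spikes[0], trials)


class TestDesignMatrix:
    def test_115_predictor_columns(self, dm):
        assert dm.X.shape[1] == 115
        counts = {v: len(dm.group_columns(v)) for v in og.VARIABLES}
        assert counts == og.GROUP_LAGS

    def test_go_columns_zero_on_nogo_rows(self, glm_session, dm):
        _, _, trials = glm_session
        nogo_ids = {t.trial_index for t in trials if t.trial_type is og.TrialType.NOGO}
        nogo_rows = np.isin(dm.trial_ids, list(nogo_ids))
        for var in ("go_early", "go_late", "pre_go_exit"):
            assert not dm.raw[np.ix_(nogo_rows, dm.group_columns(var))].any()

    def test_first_early_lag_marks_odor_onset_bin(self, glm_session):
        session, _, trials = glm_session
        go = [t for t in trials if t.trial_type is og.TrialType.GO][:1]
        dm1 = og.build_design_matrix(session.spikes[0], go)
        col = dm1.group_columns("go_early")[0]
        assert dm1.raw[0, col] == 1.0
        assert dm1.raw[1:, col].sum() == 0

    def test_pre_exit_window_of_100ms_gives_5_columns(self, glm_session):
        session, _, trials = glm_session
        dm1 = og.build_design_matrix(session.spikes[0], trials, pre_exit_lags=5)
        assert len(dm1.group_columns("pre_go_exit")) == 5
        assert dm1.X.shape[1] == 25 + 25 + 22 + 13 + 5 + 5


class TestFit:
    def test_noiseless_recovery_is_exact(self, dm, rng):
        beta_star = rng.normal(size=dm.X.shape[1])
        y = 1.7 + dm.X @ beta_star
        fit = og.fit_full(dm.X, y)
        assert np.max(np.abs(fit.beta - beta_star)) < 1e-8
        assert fit.beta0 == pytest.approx(1.7)

    def test_constant_response(self, dm):
        fit = og.fit_full(dm.X, np.full(dm.X.shape[0], 5.0))
        assert np.max(np.abs(fit.beta)) < 1e-8
        assert fit.beta0 == pytest.approx(5.0)

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ValueError, match="trials"):
            og.fit_full(rng.normal(size=(10, 115)), rng.normal(size=10))


class TestCrossValidation:
    def test_perfect_linear_response(self, dm, rng):
        y = dm.X @ rng.normal(size=dm.X.shape[1])
        r2 = og.cross_validated_r2(dm.X, y, dm.trial_ids, rng=np.random.default_rng(0))
        assert r2 == pytest.approx(1.0, abs=1e-6)

    def test_pure_noise_not_positive_on_average(self, dm):
        r = np.random.default_rng(5)
        r2s = [
            og.cross_validated_r2(
                dm.X, r.normal(size=dm.X.shape[0]), dm.trial_ids,
                rng=np.random.default_rng(i),
            )
            for i in range(5)
        ]
        assert np.mean(r2s) <= 0

    def test_folds_partition_trials_not_bins(self, dm):
        folds = _trial_folds(dm.trial_ids, 5, np.random.default_rng(3))
        seen = np.concatenate(folds)
        assert sorted(seen) == list(range(len(dm.y)))
        for fold in folds:
            fold_trials = set(dm.trial_ids[fold])
            other = np.setdiff1d(np.arange(len(dm.y)), fold)
            assert not fold_trials & set(dm.trial_ids[other])

    def test_invariant_to_bin_order_within_trials(self, dm, rng):
        y = dm.X @ rng.normal(size=dm.X.shape[1]) + rng.normal(
            scale=0.1, size=dm.X.shape[0]
        )
        perm = np.concatenate(
            [rng.permutation(np.flatnonzero(dm.trial_ids == t))
             for t in np.unique(dm.trial_ids)]
        )
        a = og.cross_validated_r2(dm.X, y, dm.trial_ids, rng=np.random.default_rng(0))
        b = og.cross_validated_r2(
            dm.X[perm], y[perm], dm.trial_ids[perm], rng=np.random.default_rng(0)
        )
        assert a == pytest.approx(b, rel=1e-9)


def synthetic_design(rng, n_trials=60, bins_per_trial=10, n_groups=6, lags=5):
    """Six symmetric groups with equal signal, for the symmetry check."""
    n = n_trials * bins_per_trial
    X = rng.normal(size=(n, n_groups * lags))
    col_group = [f"g{i}" for i in range(n_groups) for _ in range(lags)]
    trial_ids = np.repeat(np.arange(n_trials), bins_per_trial)
    y = X @ np.ones(X.shape[1]) + rng.normal(scale=0.5, size=n)
    dm = DesignMatrix(
        X=X, raw=X, y=y, col_group=col_group, trial_ids=trial_ids,
        bin_times=np.zeros(n),
    )
    return dm


class TestRelativeContributions:
    def test_symmetric_groups_share_equally(self, monkeypatch, rng):
        dm = synthetic_design(rng)
        monkeypatch.setattr(og.glm, "VARIABLES", [f"g{i}" for i in range(6)])
        res = og.glm.relative_contributions(dm, np.random.default_rng(1))
        values = list(res["contributions"].values())
        assert np.allclose(values, 1 / 6, atol=0.05)
        assert sum(values) == pytest.approx(1.0)

    def test_go_late_driven_neuron_dominated_by_go_late(self, dm):
        r = np.random.default_rng(8)
        cols = dm.group_columns("go_late")
        y = dm.raw[:, cols].sum(axis=1) * 10.0 + r.normal(scale=0.5, size=dm.X.shape[0])
        res = og.glm.relative_contributions(
            DesignMatrix(dm.X, dm.raw, y, dm.col_group, dm.trial_ids, dm.bin_times),
            np.random.default_rng(2),
        )
        assert res["contributions"]["go_late"] >= 0.8

    def test_contributions_clipped_nonnegative_and_normalized(self, glm_session):
        session, _, trials = glm_session
        dm = og.build_design_matrix(session.spikes[0], trials)
        res = og.relative_contributions(dm, np.random.default_rng(0))
        values = np.array(list(res["contributions"].values()))
        assert np.all(values >= 0)
        assert values.sum() == pytest.approx(1.0)

    def test_untuned_neuron_refused(self, glm_session):
        session, _, trials = glm_session
        dm = og.build_design_matrix(session.spikes[1], trials)  # untuned
        res = og.relative_contributions(dm, np.random.default_rng(0))
        assert isinstance(res, og.Refusal)

    def test_refit_agrees_with_no_refit_on_dominant_variable(self, dm):
        a = og.relative_contributions(dm, np.random.default_rng(0), mode="no_refit")
        b = og.relative_contributions(dm, np.random.default_rng(0), mode="refit")
        top = max(a["contributions"], key=a["contributions"].get)
        assert top == max(b["contributions"], key=b["contributions"].get)
        assert top == "go_late"  # ground-truth support of the archetype

    def test_scale_invariance_of_contributions(self, dm):
        a = og.relative_contributions(dm, np.random.default_rng(0))
        scaled = DesignMatrix(
            dm.X, dm.raw, 3.0 * dm.y, dm.col_group, dm.trial_ids, dm.bin_times
        )
        b = og.relative_contributions(scaled, np.random.default_rng(0))
        for v in og.VARIABLES:
            assert a["contributions"][v] == pytest.approx(
                b["contributions"][v], abs=1e-9
            )


class TestContributionSignificance:
    def test_dominant_variable_positive(self, dm):
        res = og.contribution_significance(dm, np.random.default_rng(1), n_controls=300)
        assert res["labels"]["go_late"] == "positive"

    def test_deterministic_under_fixed_seed(self, dm):
        a = og.contribution_significance(dm, np.random.default_rng(9), n_controls=100)
        b = og.contribution_significance(dm, np.random.default_rng(9), n_controls=100)
        assert a["labels"] == b["labels"]
        assert a["control_mean"] == b["control_mean"]


def test_window_robustness_stable_contributions(glm_session):
    session, _, trials = glm_session
    out = og.window_robustness(session.spikes[0], trials, np.random.default_rng(0))
    assert set(out) == {0.1, 0.2, 0.3}
    go_late = [res["contributions"]["go_late"] for res in out.values()]
    cv = np.std(go_late) / np.mean(go_late)
    assert cv < 0.2
    # the 0.3 s setting is the default pipeline
    default = og.relative_contributions(
        og.build_design_matrix(session.spikes[0], trials), np.random.default_rng(0)
    )
    assert out[0.3]["contributions"]["go_late"] == pytest.approx(
        default["contributions"]["go_late"]
    )
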