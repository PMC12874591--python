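"""Encoding model: lagged binary task-event predictors of smoothed firing.

Each neuron's smoothed firing rate (20 ms bins, 60 ms Gaussian kernel) over
the period from odor onset to 500 ms after odor-port exit is modeled as a
linear sum of temporal filters anchored to task events:

    y_t = b0 + sum_c sum_i b_i x_{t-i}

with six behavioral variables, each a group of binary lag columns active only
on trials of its condition (c in {go, no-go}):

    go_early / nogo_early    0..500 ms after odor-valve onset (25 lags)
    go_late / nogo_late      0..427 / 0..258 ms after valve offset (22 / 13
                             lags, the median valve-offset-to-exit durations)
    pre_go_exit / pre_nogo_exit   -300..0 ms before odor-port exit (15 lags)

115 predictor columns plus an intercept.  Predictors are z-scored over all
rows before fitting; the fit is ordinary least squares (the smoothed rate is
continuous, so a Gaussian identity-link model, not a Poisson count model).

A variable's *relative contribution* is the normalized drop in 5-fold
cross-validated explained variance (R^2 = 1 - SSE/SST, folds partition
trials) when that variable is excluded:

    (1 - R2_p,i / R2_f) / sum_j (1 - R2_p,j / R2_f)

with negative terms set to zero before normalization.  Exclusion is by
zeroing the variable's fitted coefficients without refitting (default), by
refitting without its columns, or by the no-refit rule on lasso-regularized
fits.  Significance of a contribution is judged against a control
distribution built by zeroing 10% of all predictor columns at random.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .session import Refusal, SpikeTrain, TrialEvents, TrialType
from .rates import BIN_WIDTH, SMOOTHING_SD, compute_peth

__all__ = [
    "VARIABLES",
    "GROUP_LAGS",
    "DesignMatrix",
    "GlmFit",
    "build_design_matrix",
    "fit_full",
    "cross_validated_r2",
    "relative_contributions",
    "contribution_significance",
    "window_robustness",
]

#: The six behavioral variables, in canonical order.
VARIABLES = [
    "go_early",
    "nogo_early",
    "go_late",
    "nogo_late",
    "pre_go_exit",
    "pre_nogo_exit",
]

#: Lag counts per variable: 25 + 25 + 22 + 13 + 15 + 15 = 115 columns.
GROUP_LAGS = {
    "go_early": 25,
    "nogo_early": 25,
    "go_late": 22,
    "nogo_late": 13,
    "pre_go_exit": 15,
    "pre_nogo_exit": 15,
}

#: Rows extend from odor onset to this long after odor-port exit (s).
POST_EXIT = 0.5
#: Offset (in bins) of the odor-valve closure from odor onset.
_OFFSET_BIN = int(round(0.5 / BIN_WIDTH))


@dataclass
class DesignMatrix:
    """Design matrix and response for one neuron.

    ``X`` is the z-scored predictor matrix (rows = 20 ms bins concatenated
    over trials); ``raw`` keeps the pre-normalization binary columns;
    ``col_group`` maps each column to its variable; ``trial_ids`` gives each
    row's trial index (fold assignment is by trial, never by bin).
    """

    X: np.ndarray
    raw: np.ndarray
    y: np.ndarray
    col_group: list[str]
    trial_ids: np.ndarray
    bin_times: np.ndarray  # bin centers relative to odor onset
    pre_exit_lags: int = 15

    def group_columns(self, variable: str) -> np.ndarray:
        return np.flatnonzero([g == variable for g in self.col_group])


def build_design_matrix(
    train: SpikeTrain,
    trials: Sequence[TrialEvents],
    pre_exit_lags: int = 15,
    bin_width: float = BIN_WIDTH,
    smoothing_sd: float = SMOOTHING_SD,
) -> DesignMatrix:
    """Assemble predictors and smoothed-rate response for one neuron.

    Catch trials carry no odor and are skipped.  Early-exit trials (exit
    before the end of the late window) are included; their late and pre-exit
    predictor support is truncated at the available rows.
    """
    lags = dict(GROUP_LAGS, pre_go_exit=pre_exit_lags, pre_nogo_exit=pre_exit_lags)
    order = [v for v in VARIABLES]
    col_group = [v for v in order for _ in range(lags[v])]
    col_start = {}
    pos = 0
    for v in order:
        col_start[v] = pos
        pos += lags[v]
    n_cols = pos

    rows_X: list[np.ndarray] = []
    rows_y: list[np.ndarray] = []
    rows_trial: list[np.ndarray] = []
    rows_time: list[np.ndarray] = []
    for trial in trials:
        if trial.trial_type is TrialType.CATCH:
            continue
        n_bins = int(round((trial.port_exit - trial.odor_on + POST_EXIT) / bin_width))
        if n_bins < 1:
            continue
        window = (0.0, n_bins * bin_width)
        from .session import align_spikes

        aligned = align_spikes(train, [trial.odor_on], window)
        peth = compute_peth(aligned, window, bin_width, smoothing_sd)
        y = peth.values[0]

        X = np.zeros((n_bins, n_cols))
        is_go = trial.trial_type is TrialType.GO
        early = "go_early" if is_go else "nogo_early"
        late = "go_late" if is_go else "nogo_late"
        pre = "pre_go_exit" if is_go else "pre_nogo_exit"
        for lag in range(lags[early]):
            if lag < n_bins:
                X[lag, col_start[early] + lag] = 1.0
        for lag in range(lags[late]):
            row = _OFFSET_BIN + lag
            if row < n_bins:
                X[row, col_start[late] + lag] = 1.0
        exit_bin = int(round((trial.port_exit - trial.odor_on) / bin_width))
        for lag in range(lags[pre]):
            row = exit_bin - lags[pre] + lag
            if 0 <= row < n_bins:
                X[row, col_start[pre] + lag] = 1.0

        rows_X.append(X)
        rows_y.append(y)
        rows_trial.append(np.full(n_bins, trial.trial_index))
        rows_time.append(bin_width * (np.arange(n_bins) + 0.5))

    if not rows_X:
        raise ValueError("no usable trials for the design matrix")
    raw = np.concatenate(rows_X)
    mu = raw.mean(axis=0)
    sd = raw.std(axis=0)
    sd[sd == 0] = 1.0  # never-active columns stay zero
    X = (raw - mu) / sd
    return DesignMatrix(
        X=X,
        raw=raw,
        y=np.concatenate(rows_y),
        col_group=col_group,
        trial_ids=np.concatenate(rows_trial),
        bin_times=np.concatenate(rows_time),
        pre_exit_lags=pre_exit_lags,
    )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


@dataclass
class GlmFit:
    beta0: float
    beta: np.ndarray
    rank_deficient: bool = False

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.beta0 + X @ self.beta


def _lstsq_fit(X: np.ndarray, y: np.ndarray) -> GlmFit:
    n, p = X.shape
    if n < p + 1:
        raise ValueError(
            f"{n} rows for {p + 1} coefficients; more trials are needed"
        )
    A = np.column_stack([np.ones(n), X])
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    deficient = rank < p + 1
    if deficient:
        # ridge fallback keeps the solution unique on collinear designs
        lam = 1e-8 * n
        G = A.T @ A + lam * np.eye(p + 1)
        G[0, 0] -= lam  # intercept never penalized
        coef = np.linalg.solve(G, A.T @ y)
    return GlmFit(float(coef[0]), coef[1:], deficient)


def _lasso_fit(X: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> GlmFit:
    from sklearn.linear_model import LassoCV

    model = LassoCV(
        n_alphas=20,
        cv=5,
        random_state=int(rng.integers(2**31 - 1)),
        max_iter=5000,
    ).fit(X, y)
    return GlmFit(float(model.intercept_), model.coef_.copy())


def fit_full(X: np.ndarray, y: np.ndarray) -> GlmFit:
    """Ordinary least-squares fit of the full model (with intercept)."""
    return _lstsq_fit(X, y)


def _trial_folds(
    trial_ids: np.ndarray, k: int, rng: np.random.Generator | None
) -> list[np.ndarray]:
    """Row-index folds that partition *trials*, not bins."""
    unique = np.unique(trial_ids)
    if unique.size < k:
        raise ValueError(f"{unique.size} trials cannot form {k} folds")
    order = unique.copy()
    if rng is not None:
        rng.shuffle(order)
    folds = np.array_split(order, k)
    return [np.flatnonzero(np.isin(trial_ids, f)) for f in folds]


def _pooled_r2(y: np.ndarray, residuals: np.ndarray) -> float:
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("response has zero variance")
    return 1.0 - float(np.sum(residuals**2)) / sst


def cross_validated_r2(
    X: np.ndarray,
    y: np.ndarray,
    trial_ids: np.ndarray,
    k: int = 5,
    rng: np.random.Generator | None = None,
) -> float:
    """Explained variance, 1 - SSE/SST pooled over held-out bins, with folds
    partitioning trials.  May be negative."""
    resid = np.empty_like(y)
    for test in _trial_folds(trial_ids, k, rng):
        train = np.setdiff1d(np.arange(len(y)), test)
        fit = _lstsq_fit(X[train], y[train])
        resid[test] = y[test] - fit.predict(X[test])
    return _pooled_r2(y, resid)


# ---------------------------------------------------------------------------
# Relative contributions
# ---------------------------------------------------------------------------


@dataclass
class _FoldCache:
    """Per-fold fitted full model and held-out data, reused across partial
    models and significance controls."""

    test_rows: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    fit: GlmFit
    pred_full: np.ndarray
    X_train: np.ndarray
    y_train: np.ndarray


def _fit_folds(
    dm: DesignMatrix,
    k: int,
    rng: np.random.Generator,
    mode: str,
) -> list[_FoldCache]:
    caches = []
    for test in _trial_folds(dm.trial_ids, k, rng):
        train = np.setdiff1d(np.arange(len(dm.y)), test)
        if mode == "no_refit_lasso":
            fit = _lasso_fit(dm.X[train], dm.y[train], rng)
        else:
            fit = _lstsq_fit(dm.X[train], dm.y[train])
        caches.append(
            _FoldCache(
                test_rows=test,
                X_test=dm.X[test],
                y_test=dm.y[test],
                fit=fit,
                pred_full=fit.predict(dm.X[test]),
                X_train=dm.X[train],
                y_train=dm.y[train],
            )
        )
    return caches


def _r2_zeroing(dm: DesignMatrix, caches: list[_FoldCache], cols: np.ndarray) -> float:
    """Held-out R^2 of the partial model that zeroes ``cols`` coefficients."""
    resid = np.empty_like(dm.y)
    for c in caches:
        pred = c.pred_full - c.X_test[:, cols] @ c.fit.beta[cols]
        resid[c.test_rows] = c.y_test - pred
    return _pooled_r2(dm.y, resid)


def relative_contributions(
    dm: DesignMatrix,
    rng: np.random.Generator,
    mode: str = "no_refit",
    k: int = 5,
) -> dict | Refusal:
    """Per-variable relative contributions to explained variance.

    ``mode`` is one of ``no_refit`` (zero the excluded variable's fitted
    coefficients; default), ``refit`` (re-estimate without its columns), or
    ``no_refit_lasso`` (no-refit rule on lasso fits).  Returns a dict with
    ``contributions`` (sums to 1 when any term is positive), ``r2_full``,
    and ``r2_partial``; a refusal when full-model R^2 is not positive.
    """
    if mode not in ("no_refit", "refit", "no_refit_lasso"):
        raise ValueError(f"unknown mode {mode!r}")
    caches = _fit_folds(dm, k, rng, mode)
    resid_full = np.empty_like(dm.y)
    for c in caches:
        resid_full[c.test_rows] = c.y_test - c.pred_full
    r2_full = _pooled_r2(dm.y, resid_full)
    if r2_full <= 0:
        return Refusal(f"full-model R^2 = {r2_full:.4f} <= 0")

    r2_partial = {}
    for var in VARIABLES:
        cols = dm.group_columns(var)
        if mode in ("no_refit", "no_refit_lasso"):
            r2_partial[var] = _r2_zeroing(dm, caches, cols)
        else:  # refit
            keep = np.setdiff1d(np.arange(dm.X.shape[1]), cols)
            resid = np.empty_like(dm.y)
            for c in caches:
                fit = _lstsq_fit(c.X_train[:, keep], c.y_train)
                resid[c.test_rows] = c.y_test - fit.predict(c.X_test[:, keep])
            r2_partial[var] = _pooled_r2(dm.y, resid)

    drops = np.array([1.0 - r2_partial[v] / r2_full for v in VARIABLES])
    drops = np.clip(drops, 0.0, None)  # negative contributions set to zero
    total = drops.sum()
    contributions = drops / total if total > 0 else drops
    return dict(
        contributions=dict(zip(VARIABLES, contributions)),
        r2_full=r2_full,
        r2_partial=r2_partial,
        mode=mode,
    )


def contribution_significance(
    dm: DesignMatrix,
    rng: np.random.Generator,
    n_controls: int = 1000,
    frac: float = 0.10,
    k: int = 5,
) -> dict | Refusal:
    """Significance labels for each variable's no-refit contribution.

    The control distribution is the performance drop from zeroing
    ``ceil(frac x n_columns)`` predictor columns chosen uniformly at random
    from all columns, repeated ``n_controls`` times.  A variable whose drop
    exceeds control mean + 2 SD is ``positive``; below mean - 2 SD,
    ``negative``; otherwise ``ns``.
    """
    caches = _fit_folds(dm, k, rng, "no_refit")
    resid_full = np.empty_like(dm.y)
    for c in caches:
        resid_full[c.test_rows] = c.y_test - c.pred_full
    r2_full = _pooled_r2(dm.y, resid_full)
    if r2_full <= 0:
        return Refusal(f"full-model R^2 = {r2_full:.4f} <= 0")

    n_cols = dm.X.shape[1]
    n_zero = int(np.ceil(frac * n_cols))
    control_drops = np.empty(n_controls)
    for i in range(n_controls):
        cols = rng.choice(n_cols, size=n_zero, replace=False)
        control_drops[i] = r2_full - _r2_zeroing(dm, caches, cols)
    lo = control_drops.mean() - 2 * control_drops.std()
    hi = control_drops.mean() + 2 * control_drops.std()

    labels = {}
    drops = {}
    for var in VARIABLES:
        d = r2_full - _r2_zeroing(dm, caches, dm.group_columns(var))
        drops[var] = d
        labels[var] = "positive" if d > hi else "negative" if d < lo else "ns"
    return dict(
        labels=labels,
        drops=drops,
        control_mean=float(control_drops.mean()),
        control_sd=float(control_drops.std()),
        r2_full=r2_full,
    )


def window_robustness(
    train: SpikeTrain,
    trials: Sequence[TrialEvents],
    rng: np.random.Generator,
    pre_windows: Sequence[float] = (0.1, 0.2, 0.3),
    mode: str = "no_refit",
    k: int = 5,
) -> dict[float, dict | Refusal]:
    """Relative contributions recomputed with shorter pre-exit predictor
    windows (0.1/0.2/0.3 s give 5/10/15 lag columns).

    Every window setting reuses the same generator state, so fold partitions
    are identical across settings and the comparison is paired.
    """
    out = {}
    state = rng.bit_generator.state
    for w in pre_windows:
        rng.bit_generator.state = state
        lags = int(round(w / BIN_WIDTH))
        dm = build_design_matrix(train, trials, pre_exit_lags=lags)
        out[w] = relative_contributions(dm, rng, mode=mode, k=k)
    return out
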