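"""Sliding-window auROC selectivity with permutation significance.

The central statistic quantifies how well an ideal observer could tell, from
a single-trial spike count, which of two conditions the count came from: the
area under the ROC curve, rescaled to ``auROC = 2 (ROCarea - 0.5)`` so that 0
means indistinguishable and +/-1 complete separation in either direction.
ROC area is computed as the Mann-Whitney U statistic with half credit for
ties, divided by the number of sample pairs.

Significance is a label-permutation test: firing rates are randomly
reassigned to the two groups (group sizes preserved), the auROC recomputed,
and one-sided p-values taken as the fraction of permuted values at or beyond
the observed one, with the add-one correction ``(1 + k) / (1 + n_perm)`` so a
p-value of exactly zero is impossible.  Excitation (``p_exc``) and inhibition
(``p_inh``) are tested separately, each at alpha = 0.01.

Sliding analyses use 100 ms windows stepped by 20 ms.  The nose-poking
analysis window spans bin centers 0 to 1.8 s after odor onset (91 bins).  A
neuron is go-cue selective when its go-correct versus-baseline series is
significantly excited for at least five consecutive bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .session import EPOCHS, Epoch, Refusal, SpikeTrain, TrialEvents
from .rates import SLIDING_STEP, SLIDING_WIDTH, make_centers, sliding_counts, epoch_rate

__all__ = [
    "ALPHA",
    "RUN_LENGTH",
    "NOSE_POKE_CENTERS",
    "AurocSeries",
    "SelectivityLabel",
    "ResponseMeasures",
    "RewardLabel",
    "roc_area",
    "auroc",
    "permutation_test",
    "sliding_auroc",
    "classify_cue_selective",
    "response_measures",
    "classify_reward_selective",
    "epoch_auroc",
    "epoch_auroc_table",
    "compare_groups",
]

#: Significance level of all permutation tests.
ALPHA = 0.01
#: Minimum number of consecutive significant bins (5 bins = 100 ms of step).
RUN_LENGTH = 5
#: Bin centers of the nose-poking analysis window: 0 to 1.8 s after odor
#: onset in 20 ms steps — 91 time bins.
NOSE_POKE_CENTERS = make_centers(0.0, 1.8)
#: Bin centers of the reward analysis window: water-port entry to 1.0 s after
#: the water valve opens (entry + 1.3 s).
REWARD_CENTERS = make_centers(0.0, 1.3)


# ---------------------------------------------------------------------------
# Core statistic
# ---------------------------------------------------------------------------


def roc_area(preferred: np.ndarray, reference: np.ndarray) -> float:
    """ROC area: P(preferred > reference) + 0.5 P(tie) over all pairs."""
    preferred = np.asarray(preferred, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if preferred.size == 0 or reference.size == 0:
        raise ValueError("both samples must be nonempty")
    n_p, n_r = preferred.size, reference.size
    ranks = stats.rankdata(np.concatenate([preferred, reference]))
    u = ranks[:n_p].sum() - n_p * (n_p + 1) / 2
    return float(u / (n_p * n_r))


def auroc(preferred: np.ndarray, reference: np.ndarray) -> float:
    """Rescaled ROC area in [-1, 1]; antisymmetric under swapping samples."""
    return 2.0 * (roc_area(preferred, reference) - 0.5)


def _perm_pvalues(
    ranks: np.ndarray,
    n_pref: int,
    n_permutations: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Permutation p-values for a batch of tests sharing group sizes.

    ``ranks``: (n_tests, m) pooled ranks with the preferred group first.
    Because midranks of the pooled sample are invariant under label
    permutation, each permuted auROC reduces to a rank-subset sum, computed
    for all tests at once as a ranks x selection-matrix product.  The block
    of permutations is shared across the tests in the batch (each test's
    marginal p-value is exact either way; batched tests are sliding bins of
    one neuron, which already share most of their data).  Returns
    (auroc, p_exc, p_inh).
    """
    ranks = np.atleast_2d(ranks)
    n_tests, m = ranks.shape
    n_ref = m - n_pref
    u_obs = ranks[:, :n_pref].sum(axis=1)
    scale = n_pref * n_ref
    auc = 2.0 * ((u_obs - n_pref * (n_pref + 1) / 2) / scale - 0.5)

    idx = np.broadcast_to(np.arange(m), (n_permutations, m)).copy()
    rng.permuted(idx, axis=1, out=idx)
    select = np.zeros((n_permutations, m))
    select[np.arange(n_permutations)[:, None], idx[:, :n_pref]] = 1.0
    u_perm = ranks @ select.T  # (n_tests, n_permutations)
    exceed = (u_perm >= u_obs[:, None] - 1e-9).sum(axis=1)
    below = (u_perm <= u_obs[:, None] + 1e-9).sum(axis=1)
    p_exc = (1.0 + exceed) / (1.0 + n_permutations)
    p_inh = (1.0 + below) / (1.0 + n_permutations)
    return auc, p_exc, p_inh


def permutation_test(
    preferred: np.ndarray,
    reference: np.ndarray,
    n_permutations: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """One-sided permutation p-values (excitation, inhibition) for the auROC
    of ``preferred`` versus ``reference``; group sizes are preserved."""
    if n_permutations < 1:
        raise ValueError("n_permutations must be at least 1")
    preferred = np.asarray(preferred, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if preferred.size == 0 or reference.size == 0:
        raise ValueError("both samples must be nonempty")
    ranks = stats.rankdata(np.concatenate([preferred, reference]))
    _, p_exc, p_inh = _perm_pvalues(ranks, preferred.size, n_permutations, rng)
    return float(p_exc[0]), float(p_inh[0])


# ---------------------------------------------------------------------------
# Sliding-window series
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AurocSeries:
    """Per-bin auROC values and permutation p-values for one neuron.

    Bins where fewer than the minimum number of trials remain (e.g., after a
    trial's odor-port exit) hold NaN and are never significant.
    """

    neuron_id: str
    bin_centers: np.ndarray
    auroc: np.ndarray
    p_exc: np.ndarray
    p_inh: np.ndarray
    n_trials: np.ndarray
    n_permutations: int
    contrast: str
    align_event: str

    def significant_exc(self, alpha: float = ALPHA) -> np.ndarray:
        return np.where(np.isnan(self.p_exc), False, self.p_exc < alpha)

    def significant_inh(self, alpha: float = ALPHA) -> np.ndarray:
        return np.where(np.isnan(self.p_inh), False, self.p_inh < alpha)


def _event_times(trials: Sequence[TrialEvents], align_event: str) -> np.ndarray:
    times = [getattr(t, align_event) for t in trials]
    if any(v is None for v in times):
        raise ValueError(f"some trials lack event {align_event!r}")
    return np.asarray(times, dtype=float)


def _baseline_counts(
    train: SpikeTrain,
    trials: Sequence[TrialEvents],
    baseline_epoch: Epoch,
    width: float,
) -> np.ndarray:
    """Per-trial baseline spike counts rescaled to ``width`` of exposure, so
    a 200 ms baseline count is halved before comparison with 100 ms bins."""
    counts = np.empty(len(trials))
    times = train.spike_times
    for i, trial in enumerate(trials):
        bounds = baseline_epoch.bounds(trial)
        if isinstance(bounds, Refusal):
            raise ValueError(f"baseline epoch unresolvable on trial {trial.trial_index}")
        start, end = bounds
        n = np.searchsorted(times, end, side="left") - np.searchsorted(
            times, start, side="left"
        )
        counts[i] = n * (width / (end - start))
    return counts


def _grouped_perm(
    values_pref: np.ndarray,
    values_ref: np.ndarray,
    valid_pref: np.ndarray,
    valid_ref: np.ndarray,
    min_trials: int,
    n_permutations: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-bin permutation test with per-bin trial-validity masks.

    ``values_pref``/``values_ref``: (n_trials, n_bins) samples; ``valid_*``:
    boolean masks of the same shape.  Bins sharing a validity pattern are
    batched through :func:`_perm_pvalues`.
    """
    n_bins = values_pref.shape[1]
    auc = np.full(n_bins, np.nan)
    p_exc = np.full(n_bins, np.nan)
    p_inh = np.full(n_bins, np.nan)
    n_used = np.zeros(n_bins, dtype=int)

    # group bins by (pref mask, ref mask) pattern
    pattern = {}
    for b in range(n_bins):
        key = (valid_pref[:, b].tobytes(), valid_ref[:, b].tobytes())
        pattern.setdefault(key, []).append(b)

    for (mp_b, mr_b), bins in pattern.items():
        mp = np.frombuffer(mp_b, dtype=bool)
        mr = np.frombuffer(mr_b, dtype=bool)
        n_p, n_r = int(mp.sum()), int(mr.sum())
        if n_p < min_trials or n_r < min_trials:
            continue
        bins = np.asarray(bins)
        pooled = np.concatenate(
            [values_pref[mp][:, bins], values_ref[mr][:, bins]], axis=0
        ).T  # (n_bins_in_group, n_p + n_r)
        ranks = stats.rankdata(pooled, axis=1)
        a, pe, pi = _perm_pvalues(ranks, n_p, n_permutations, rng)
        auc[bins], p_exc[bins], p_inh[bins] = a, pe, pi
        n_used[bins] = n_p + n_r
    return auc, p_exc, p_inh, n_used


def sliding_auroc(
    train: SpikeTrain,
    trials: Sequence[TrialEvents],
    rng: np.random.Generator,
    *,
    align_event: str = "odor_on",
    centers: np.ndarray = NOSE_POKE_CENTERS,
    width: float = SLIDING_WIDTH,
    contrast: str = "vs_baseline",
    reference_trials: Sequence[TrialEvents] | None = None,
    baseline_epoch: Epoch | str = "baseline_iti",
    n_permutations: int = 1000,
    exclude_after: str | None = "port_exit",
    min_trials: int = 5,
) -> AurocSeries | Refusal:
    """Sliding-bin auROC series for one neuron.

    ``vs_baseline`` contrasts each bin's per-trial spike counts against the
    same trials' baseline-epoch counts rescaled to equal exposure;
    ``go_vs_nogo`` contrasts the bin counts of ``trials`` (preferred) against
    those of ``reference_trials`` in the same bin.

    When ``exclude_after`` names an event (default: port exit), a trial
    contributes to a bin only while the bin center has not passed that
    trial's event, so late bins are not contaminated by post-exit activity;
    pass ``None`` to keep every trial in every bin.  Bins retaining fewer
    than ``min_trials`` trials in either group are NaN.  Returns a refusal if
    no bin is computable.
    """
    if isinstance(baseline_epoch, str):
        baseline_epoch = EPOCHS[baseline_epoch]
    trials = list(trials)
    if len(trials) < min_trials:
        return Refusal(f"{len(trials)} trials < minimum {min_trials}")
    centers = np.asarray(centers, dtype=float)

    def bin_counts(trs):
        events = _event_times(trs, align_event)
        from .session import align_spikes

        pad = width
        aligned = align_spikes(
            train, events, (centers[0] - pad, centers[-1] + pad)
        )
        return sliding_counts(aligned, centers, width=width).counts

    def validity(trs):
        if exclude_after is None:
            return np.ones((len(trs), len(centers)), dtype=bool)
        events = _event_times(trs, align_event)
        cut = _event_times(trs, exclude_after) - events
        return centers[None, :] <= cut[:, None]

    if contrast == "vs_baseline":
        counts = bin_counts(trials)
        base = _baseline_counts(train, trials, baseline_epoch, width)
        valid = validity(trials)
        auc, p_exc, p_inh, n_used = _grouped_perm(
            counts.astype(float),
            np.repeat(base[:, None], len(centers), axis=1),
            valid,
            valid,
            min_trials,
            n_permutations,
            rng,
        )
    elif contrast == "go_vs_nogo":
        if reference_trials is None:
            raise ValueError("go_vs_nogo contrast requires reference_trials")
        reference_trials = list(reference_trials)
        if len(reference_trials) < min_trials:
            return Refusal(
                f"{len(reference_trials)} reference trials < minimum {min_trials}"
            )
        auc, p_exc, p_inh, n_used = _grouped_perm(
            bin_counts(trials).astype(float),
            bin_counts(reference_trials).astype(float),
            validity(trials),
            validity(reference_trials),
            min_trials,
            n_permutations,
            rng,
        )
    else:
        raise ValueError(f"unknown contrast {contrast!r}")

    if np.all(np.isnan(auc)):
        return Refusal("no bin retained the minimum number of trials")
    return AurocSeries(
        neuron_id=train.neuron_id,
        bin_centers=centers,
        auroc=auc,
        p_exc=p_exc,
        p_inh=p_inh,
        n_trials=n_used,
        n_permutations=n_permutations,
        contrast=contrast,
        align_event=align_event,
    )


# ---------------------------------------------------------------------------
# Classification and response-shape measures
# ---------------------------------------------------------------------------


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end) inclusive bin indices."""
    runs = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(mask) - 1))
    return runs


@dataclass(frozen=True)
class SelectivityLabel:
    neuron_id: str
    label: str  # go_cue_selective | nogo_cue_selective | none
    qualifying_run: tuple[int, int] | None


def classify_cue_selective(
    series_go: AurocSeries | Refusal,
    series_nogo: AurocSeries | Refusal,
    alpha: float = ALPHA,
    run_length: int = RUN_LENGTH,
) -> SelectivityLabel:
    """Cue selectivity from the two versus-baseline series on go-correct and
    no-go-correct trials.

    A neuron is go-cue selective when its go series shows significant
    excitation for at least ``run_length`` consecutive bins; no-go analogous.
    If both qualify, the longer run wins, ties broken by peak auROC within
    the run.
    """

    def best_run(series):
        if isinstance(series, Refusal):
            return None
        sig = series.significant_exc(alpha)
        qualifying = [r for r in _runs(sig) if r[1] - r[0] + 1 >= run_length]
        if not qualifying:
            return None
        run = max(
            qualifying,
            key=lambda r: (r[1] - r[0], np.nanmax(series.auroc[r[0] : r[1] + 1])),
        )
        peak = float(np.nanmax(series.auroc[run[0] : run[1] + 1]))
        return run, run[1] - run[0] + 1, peak

    nid = next(
        (s.neuron_id for s in (series_go, series_nogo) if isinstance(s, AurocSeries)),
        "?",
    )
    go, nogo = best_run(series_go), best_run(series_nogo)
    if go is None and nogo is None:
        return SelectivityLabel(nid, "none", None)
    if nogo is None or (go is not None and (go[1], go[2]) >= (nogo[1], nogo[2])):
        return SelectivityLabel(nid, "go_cue_selective", go[0])
    return SelectivityLabel(nid, "nogo_cue_selective", nogo[0])


@dataclass(frozen=True)
class ResponseMeasures:
    """Shape summaries of a significant auROC time course (seconds).

    ``onset`` and ``duration`` are ``None`` when no qualifying run of five or
    more consecutive significant bins contains the center of mass.
    """

    center_of_mass: float
    onset: float | None
    duration: float | None


def response_measures(
    series: AurocSeries,
    alpha: float = ALPHA,
    weighted: bool = True,
) -> ResponseMeasures | Refusal:
    """Time of center of mass, onset, and duration of the excited response.

    The center of mass averages the significantly excited bin times, weighted
    by their auROC values (set ``weighted=False`` for an unweighted average).
    The qualifying run is the maximal block of at least five consecutive
    significant bins containing the significant bin nearest the center of
    mass; duration is run length x step plus the window-width overhang
    (width - step), and onset is the center of the run's first bin.
    """
    sig = series.significant_exc(alpha)
    if not sig.any():
        return Refusal("no significant bins")
    t = series.bin_centers[sig]
    w = series.auroc[sig] if weighted else np.ones(t.size)
    com = float(np.sum(t * w) / np.sum(w))

    step = float(np.diff(series.bin_centers).mean())
    nearest = int(np.flatnonzero(sig)[np.argmin(np.abs(t - com))])
    run = next(
        (
            r
            for r in _runs(sig)
            if r[0] <= nearest <= r[1] and r[1] - r[0] + 1 >= RUN_LENGTH
        ),
        None,
    )
    if run is None:
        return ResponseMeasures(com, None, None)
    n_bins = run[1] - run[0] + 1
    duration = n_bins * step + (SLIDING_WIDTH - step)
    return ResponseMeasures(com, float(series.bin_centers[run[0]]), duration)


@dataclass(frozen=True)
class RewardLabel:
    neuron_id: str
    label: str  # drinking_selective | waiting_selective | none


def classify_reward_selective(
    neuron_id: str,
    measures: ResponseMeasures | Refusal,
    waiting_window: tuple[float, float] = (0.0, EPOCHS["waiting"].end_offset),
    drinking_window: tuple[float, float] = (
        EPOCHS["waiting"].end_offset,
        EPOCHS["waiting"].end_offset + 1.0,
    ),
) -> RewardLabel:
    """Reward-epoch selectivity from the center of mass of the response
    aligned to water-port entry on go-correct trials: the waiting epoch is
    entry to valve opening (0.3 s), the drinking epoch valve opening to
    +1.0 s."""
    if isinstance(measures, Refusal):
        return RewardLabel(neuron_id, "none")
    com = measures.center_of_mass
    if waiting_window[0] <= com < waiting_window[1]:
        return RewardLabel(neuron_id, "waiting_selective")
    if drinking_window[0] <= com < drinking_window[1]:
        return RewardLabel(neuron_id, "drinking_selective")
    return RewardLabel(neuron_id, "none")


# ---------------------------------------------------------------------------
# Epoch-level auROC tables and group comparison
# ---------------------------------------------------------------------------


def epoch_auroc(
    train: SpikeTrain,
    trials: Sequence[TrialEvents],
    rng: np.random.Generator,
    epoch: Epoch | str = "nose_poking",
    baseline_epoch: Epoch | str = "baseline_iti",
    n_permutations: int = 1000,
    min_trials: int = 5,
) -> tuple[float, float, float] | Refusal:
    """Single auROC of epoch firing rate versus baseline rate across trials,
    with its permutation p-values (exc, inh).  Rates rather than counts are
    contrasted because the epoch's realized duration varies per trial."""
    if isinstance(epoch, str):
        epoch = EPOCHS[epoch]
    if isinstance(baseline_epoch, str):
        baseline_epoch = EPOCHS[baseline_epoch]
    trials = list(trials)
    r_epoch = epoch_rate(train, trials, epoch)
    r_base = epoch_rate(train, trials, baseline_epoch)
    ok = ~np.isnan(r_epoch) & ~np.isnan(r_base)
    if ok.sum() < min_trials:
        return Refusal(f"{int(ok.sum())} usable trials < minimum {min_trials}")
    a = auroc(r_epoch[ok], r_base[ok])
    p_exc, p_inh = permutation_test(r_epoch[ok], r_base[ok], n_permutations, rng)
    return a, p_exc, p_inh


def epoch_auroc_table(
    neurons: Sequence[SpikeTrain],
    groups: dict[str, str],
    conditions: dict[str, Sequence[TrialEvents]],
    rng: np.random.Generator,
    epoch: Epoch | str = "nose_poking",
    baseline_epoch: Epoch | str = "baseline_iti",
    n_permutations: int = 1000,
    min_trials: int = 5,
) -> pd.DataFrame:
    """Per-neuron, per-condition epoch auROC values with significance flags.

    ``groups`` maps neuron_id to a group label; ``conditions`` maps a
    condition name (e.g. go_correct, go_error, catch) to its trial subset.
    Neurons failing the minimum-trial rule in a condition appear with NaN
    and ``excluded=True`` for that condition.
    """
    rows = []
    for train in neurons:
        for cond, trials in conditions.items():
            res = epoch_auroc(
                train, trials, rng, epoch, baseline_epoch, n_permutations, min_trials
            )
            if isinstance(res, Refusal):
                rows.append(
                    dict(
                        neuron_id=train.neuron_id,
                        group=groups.get(train.neuron_id, "ungrouped"),
                        condition=cond,
                        auroc=np.nan,
                        p_exc=np.nan,
                        p_inh=np.nan,
                        excluded=True,
                    )
                )
            else:
                a, pe, pi = res
                rows.append(
                    dict(
                        neuron_id=train.neuron_id,
                        group=groups.get(train.neuron_id, "ungrouped"),
                        condition=cond,
                        auroc=a,
                        p_exc=pe,
                        p_inh=pi,
                        excluded=False,
                    )
                )
    return pd.DataFrame(rows)


def compare_groups(
    table: pd.DataFrame, condition: str
) -> dict | Refusal:
    """One-way ANOVA with Tukey's post hoc test across neuron groups for one
    condition's auROC values."""
    sub = table[(table["condition"] == condition) & ~table["excluded"]]
    by_group = {g: d["auroc"].to_numpy() for g, d in sub.groupby("group")}
    by_group = {g: v for g, v in by_group.items() if v.size >= 2}
    if len(by_group) < 2:
        return Refusal("need at least two groups with two or more neurons")
    f, p = stats.f_oneway(*by_group.values())
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate(list(by_group.values()))
    labels = np.concatenate([[g] * v.size for g, v in by_group.items()])
    tukey = pairwise_tukeyhsd(values, labels)
    return dict(
        anova_F=float(f),
        anova_p=float(p),
        tukey=pd.DataFrame(
            tukey.summary().data[1:], columns=tukey.summary().data[0]
        ),
    )
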