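"""Trial-progression stability and covariate-independence checks.

Within-session stability of a neuron's go-cue response is the Pearson
correlation between its baseline-subtracted nose-poking firing rate on each
go trial and that trial's order from the start of the session, judged
against the 0.5th/99.5th percentiles of the same correlation computed on
1,000 trial-shuffled rate sequences (a two-tailed 1% shuffle criterion).
The baseline subtracted is the neuron's session-wide mean inter-trial-
interval rate — a constant, kept so reported rates share the published axis
convention (it cannot change the correlation).

A second check correlates the late-phase firing rate with a per-trial
covariate such as odor-sampling duration, with the parametric p-value of the
Pearson coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .rates import epoch_rate
from .session import EPOCHS, Epoch, Refusal, SpikeTrain, TrialEvents

__all__ = ["StabilityResult", "trial_order_stability", "rate_covariate_correlation"]


@dataclass(frozen=True)
class StabilityResult:
    neuron_id: str
    r: float
    shuffle_bounds: tuple[float, float]  # (0.5th, 99.5th percentile)
    label: str  # negative | ns | positive


def trial_order_stability(
    train: SpikeTrain,
    go_trials: Sequence[TrialEvents],
    rng: np.random.Generator,
    all_trials: Sequence[TrialEvents] | None = None,
    n_shuffles: int = 1000,
    epoch: Epoch | str = "nose_poking",
    method: str = "pearson",
) -> StabilityResult | Refusal:
    """Correlation of go-cue epoch rate with trial order, shuffle-controlled.

    ``go_trials`` should be the go-correct trials in session order;
    ``all_trials`` (defaults to ``go_trials``) supplies the inter-trial-
    interval baseline mean that is subtracted from each rate.  Constant rate
    sequences have an undefined correlation and come back labeled ``ns``.
    """
    go_trials = list(go_trials)
    if len(go_trials) < 10:
        return Refusal(f"{len(go_trials)} go trials < minimum 10")
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr

    rates = epoch_rate(train, go_trials, epoch)
    iti = epoch_rate(train, list(all_trials or go_trials), EPOCHS["baseline_iti"])
    rates = rates - np.nanmean(iti)
    order = np.arange(len(go_trials), dtype=float)
    if np.all(rates == rates[0]):
        return StabilityResult(train.neuron_id, float("nan"), (np.nan, np.nan), "ns")
    r = float(corr(order, rates)[0])

    shuffled = np.empty(n_shuffles)
    for i in range(n_shuffles):
        shuffled[i] = corr(order, rng.permutation(rates))[0]
    lo, hi = np.percentile(shuffled, [0.5, 99.5])
    label = "negative" if r < lo else "positive" if r > hi else "ns"
    return StabilityResult(train.neuron_id, r, (float(lo), float(hi)), label)


def rate_covariate_correlation(
    train: SpikeTrain,
    trials: Sequence[TrialEvents],
    covariate: np.ndarray,
    epoch: Epoch | str = "late_nose_poking",
    method: str = "pearson",
) -> tuple[float, float]:
    """Pearson r (and parametric p) between epoch firing rate and a per-trial
    covariate, e.g. nose-poking duration, pooled across trials."""
    trials = list(trials)
    covariate = np.asarray(covariate, dtype=float)
    if covariate.size != len(trials):
        raise ValueError("covariate length must match trial count")
    if len(trials) < 10:
        raise ValueError(f"{len(trials)} trials < minimum 10")
    if np.ptp(covariate) == 0:
        raise ValueError("covariate has zero variance")
    rates = epoch_rate(train, trials, epoch)
    ok = ~np.isnan(rates)
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    r, p = corr(rates[ok], covariate[ok])
    return float(r), float(p)
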