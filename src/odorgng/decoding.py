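"""Pseudo-population go/no-go decoding with a linear SVM.

Neurons recorded in different sessions are combined into a pseudo-population:
pseudo-trial k of each type concatenates every neuron's k-th correct trial of
that type, counted from the start of its session, so trials are matched only
by type and within-type order.  Forty trials per type form the dataset.  The
classifier is a linear-kernel SVM; accuracy is the mean over 10-fold
cross-validation, reported in percent against a 50% chance level for the two
balanced classes and against the animals' behavioral accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .rates import SLIDING_STEP, SLIDING_WIDTH, sliding_counts
from .session import Outcome, Session, TrialType, align_spikes

__all__ = [
    "N_PER_TYPE",
    "PseudoPopulation",
    "DecodingResult",
    "build_pseudopopulation",
    "decode",
    "decode_time_course",
    "decode_vs_population_size",
]

#: Trials per type entering the decoder, taken from the start of the session.
N_PER_TYPE = 40
#: SVM regularization constant (conventional default; only the kernel is
#: dictated by the method).
SVM_C = 1.0


@dataclass(frozen=True)
class PseudoPopulation:
    """Per-window pseudo-trial x neuron spike-count tensor.

    ``counts`` has shape (2 * n_per_type, n_neurons, n_windows); ``labels``
    is 1 for go and 0 for no-go pseudo-trials.
    """

    counts: np.ndarray
    labels: np.ndarray
    neuron_ids: list[str]
    window_centers: np.ndarray
    dropped: list[str]

    def at(self, window_index: int) -> np.ndarray:
        return self.counts[:, :, window_index]


def _correct_trials(session: Session, trial_type: TrialType):
    return [
        t
        for t in session.trials
        if t.trial_type is trial_type and t.outcome is Outcome.CORRECT
    ]


def build_pseudopopulation(
    sessions: Sequence[Session],
    centers: np.ndarray | float,
    width: float = SLIDING_WIDTH,
    n_per_type: int = N_PER_TYPE,
    align_event: str = "odor_on",
) -> PseudoPopulation:
    """Assemble the pseudo-population count tensor over sliding windows.

    Neurons whose session lacks ``n_per_type`` correct trials of either type
    are dropped (listed in ``dropped``).  ``centers`` may be a scalar for a
    single window.
    """
    centers = np.atleast_1d(np.asarray(centers, dtype=float))
    columns = []
    ids: list[str] = []
    dropped: list[str] = []
    for session in sessions:
        go = _correct_trials(session, TrialType.GO)[:n_per_type]
        nogo = _correct_trials(session, TrialType.NOGO)[:n_per_type]
        enough = len(go) >= n_per_type and len(nogo) >= n_per_type
        events = (
            [getattr(t, align_event) for t in go + nogo] if enough else []
        )
        for train in session.spikes:
            if not enough:
                dropped.append(train.neuron_id)
                continue
            aligned = align_spikes(
                train, events, (centers[0] - width, centers[-1] + width)
            )
            counts = sliding_counts(aligned, centers, width=width).counts
            columns.append(counts)  # (2 * n_per_type, n_windows)
            ids.append(train.neuron_id)
    if not columns:
        raise ValueError("no neuron has enough correct trials of both types")
    counts = np.stack(columns, axis=1)  # (trials, neurons, windows)
    labels = np.concatenate([np.ones(n_per_type, int), np.zeros(n_per_type, int)])
    return PseudoPopulation(counts, labels, ids, centers, dropped)


def decode(
    X: np.ndarray,
    labels: np.ndarray,
    rng: np.random.Generator,
    k: int = 10,
    C: float = SVM_C,
) -> tuple[float, float]:
    """Mean and SD (over folds) of held-out linear-SVM accuracy, in percent."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("need both classes to decode")
    skf = StratifiedKFold(
        n_splits=k, shuffle=True, random_state=int(rng.integers(2**31 - 1))
    )
    accs = []
    for train_idx, test_idx in skf.split(X, labels):
        clf = SVC(kernel="linear", C=C)
        clf.fit(X[train_idx], labels[train_idx])
        accs.append(100.0 * clf.score(X[test_idx], labels[test_idx]))
    return float(np.mean(accs)), float(np.std(accs))


@dataclass(frozen=True)
class DecodingResult:
    window_centers: np.ndarray
    accuracy: np.ndarray  # percent, mean over folds
    accuracy_sd: np.ndarray  # percent, SD over folds
    behavioral_accuracy_reference: float | None
    crossing_time: float | None  # first window where accuracy >= reference
    chance: float = 50.0


def decode_time_course(
    pop: PseudoPopulation,
    rng: np.random.Generator,
    behavioral_accuracy: float | None = None,
    k: int = 10,
) -> DecodingResult:
    """Decoding accuracy per sliding window; the classifier is trained and
    tested independently at every time point.  ``behavioral_accuracy`` is a
    fraction in [0, 1]; the crossing time is the first window whose accuracy
    reaches that level (in percent)."""
    acc = np.empty(len(pop.window_centers))
    sd = np.empty(len(pop.window_centers))
    for i in range(len(pop.window_centers)):
        acc[i], sd[i] = decode(pop.at(i), pop.labels, rng, k=k)
    crossing = None
    ref = None
    if behavioral_accuracy is not None:
        ref = 100.0 * behavioral_accuracy
        hits = np.flatnonzero(acc >= ref)
        if hits.size:
            crossing = float(pop.window_centers[hits[0]])
    return DecodingResult(pop.window_centers, acc, sd, ref, crossing)


def decode_vs_population_size(
    pop: PseudoPopulation,
    window_index: int,
    sizes: Sequence[int],
    rng: np.random.Generator,
    n_resamples: int = 20,
    k: int = 10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean (and SD over neuron subsets) decoding accuracy versus population
    size at one window; each size averages ``n_resamples`` random subsets.
    A size equal to the full population uses all neurons once."""
    X = pop.at(window_index)
    n_neurons = X.shape[1]
    means = np.empty(len(sizes))
    sds = np.empty(len(sizes))
    for j, size in enumerate(sizes):
        if size > n_neurons:
            raise ValueError(f"size {size} exceeds population of {n_neurons}")
        if size == n_neurons:
            accs = [decode(X, pop.labels, rng, k=k)[0]]
        else:
            accs = [
                decode(
                    X[:, rng.choice(n_neurons, size=size, replace=False)],
                    pop.labels,
                    rng,
                    k=k,
                )[0]
                for _ in range(n_resamples)
            ]
        means[j], sds[j] = float(np.mean(accs)), float(np.std(accs))
    return np.asarray(sizes), means, sds
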