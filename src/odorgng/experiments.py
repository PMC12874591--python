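"""Canned calibration and recovery experiments on synthetic sessions.

These drive the full pipeline on generator-defined ground truth and are used
both by the test suite and by the reproduction script: chance-level decoding
of uninformative populations, the false-positive rate of the sliding-bin
permutation test on stationary neurons, and selectivity-label recovery on a
mixed population.
"""

from __future__ import annotations

import numpy as np

from .decoding import build_pseudopopulation, decode
from .selectivity import ALPHA, classify_cue_selective, sliding_auroc
from .session import Outcome, Refusal, Session, TrialType
from .simulate import DEFAULT_ARCHETYPES, TaskConfig, simulate_session

__all__ = [
    "null_decoding_accuracy",
    "permutation_false_positive_rate",
    "selectivity_recovery",
]


def _correct(session: Session, trial_type: TrialType):
    return [
        t
        for t in session.trials
        if t.trial_type is trial_type and t.outcome is Outcome.CORRECT
    ]


def null_decoding_accuracy(
    seed: int,
    n_repetitions: int = 20,
    n_neurons: int = 50,
    n_trials: int = 150,
    window_center: float = 0.7,
) -> dict:
    """Decoding accuracy on populations carrying no class information.

    Each repetition simulates a session of untuned neurons (homogeneous
    Poisson firing, identical for go and no-go trials), builds the
    40-trial-per-type pseudo-population in one 100 ms window, and runs the
    10-fold linear-SVM decoder.  Returns the mean accuracy (%) over
    repetitions, its standard error, and the per-repetition values; the mean
    should sit at the 50% chance level.
    """
    ss = np.random.SeedSequence([seed, 0xD0])
    accs = []
    for child in ss.spawn(n_repetitions):
        rep_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        session, _ = simulate_session(
            TaskConfig(n_trials=n_trials),
            [(DEFAULT_ARCHETYPES["untuned"], n_neurons)],
            seed=rep_seed,
        )
        pop = build_pseudopopulation([session], np.array([window_center]))
        rng = np.random.default_rng(child)
        acc, _ = decode(pop.at(0), pop.labels, rng)
        accs.append(acc)
    accs = np.asarray(accs)
    return dict(
        mean=float(accs.mean()),
        sem=float(accs.std(ddof=1) / np.sqrt(len(accs))),
        per_repetition=accs,
    )


def permutation_false_positive_rate(
    seed: int,
    n_neurons: int = 60,
    n_trials: int = 120,
    n_permutations: int = 1000,
    alpha: float = ALPHA,
) -> dict:
    """Per-bin excitation false-positive rate of the versus-baseline
    sliding-bin permutation test on stationary neurons.

    Simulates untuned (homogeneous Poisson) neurons through the full task
    timeline, runs the 91-bin versus-baseline series on go-correct trials for
    each, and reports the fraction of bins flagged significantly excited at
    the test's alpha.  Every trial contributes to every bin so all
    ``91 x n_neurons`` bins are scored.
    """
    session, _ = simulate_session(
        TaskConfig(n_trials=n_trials),
        [(DEFAULT_ARCHETYPES["untuned"], n_neurons)],
        seed=seed,
    )
    go = _correct(session, TrialType.GO)
    n_sig = 0
    n_bins = 0
    for i, train in enumerate(session.spikes):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xFA, i]))
        series = sliding_auroc(
            train,
            go,
            rng,
            n_permutations=n_permutations,
            exclude_after=None,
        )
        n_sig += int(series.significant_exc(alpha).sum())
        n_bins += len(series.bin_centers)
    return dict(fraction=n_sig / n_bins, n_significant=n_sig, n_bins=n_bins)


def selectivity_recovery(
    seed: int,
    n_selective: int = 30,
    n_untuned: int = 70,
    n_trials: int = 120,
    n_permutations: int = 1000,
) -> dict:
    """Recovery of go-cue-selective labels on a mixed simulated population.

    Simulates ``n_selective`` late-phase go-cue neurons among ``n_untuned``
    untuned neurons, runs the full classification pipeline (versus-baseline
    series on go-correct and no-go-correct trials, five-consecutive-bin
    criterion), and tabulates hits against ground truth.
    """
    session, truth = simulate_session(
        TaskConfig(n_trials=n_trials),
        [
            (DEFAULT_ARCHETYPES["go_cue_late"], n_selective),
            (DEFAULT_ARCHETYPES["untuned"], n_untuned),
        ],
        seed=seed,
    )
    go = _correct(session, TrialType.GO)
    nogo = _correct(session, TrialType.NOGO)
    true_positive = false_positive = 0
    for i, train in enumerate(session.spikes):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5E, i]))
        series_go = sliding_auroc(train, go, rng, n_permutations=n_permutations)
        series_nogo = sliding_auroc(train, nogo, rng, n_permutations=n_permutations)
        label = classify_cue_selective(series_go, series_nogo)
        is_selective = label.label == "go_cue_selective"
        if truth.labels[train.neuron_id] == "go_cue_late":
            true_positive += is_selective
        else:
            false_positive += label.label != "none"
    return dict(
        true_positive=true_positive,
        n_selective=n_selective,
        false_positive=false_positive,
        n_untuned=n_untuned,
        recovery=true_positive / n_selective,
        false_positive_rate=false_positive / n_untuned,
    )
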