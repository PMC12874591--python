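"""Synthetic odor-guided go/no-go sessions with ground-truth neuron tuning.

The generator reproduces the task's timeline — 3 s inter-trial interval, 500 ms
odor presentation at the odor port, a variable nose-poking epoch, a 2 s
response window, a 300 ms pre-reward wait at the water port, and one odorless
catch trial in ten — and draws spikes from inhomogeneous Poisson processes
whose rate profiles follow four archetypes seen in cortical-amygdala
recordings during this task:

``go_cue_late``
    baseline firing except a plateau from odor-valve closure to odor-port
    exit on go trials (late-phase go-cue preference).
``waiting_phasic``
    the same go-cue late plateau plus a phasic burst just after water-port
    entry that decays before the water valve opens.
``drinking_ramp``
    firing ramps up starting ~200 ms before the water valve opens, is
    sustained ~400 ms into drinking, and is suppressed below baseline during
    the rest of the trial.
``untuned``
    constant baseline.

Rate profiles are piecewise linear, so they integrate in closed form and give
exact thinning ceilings.  Nose-poke durations are log-normal, parameterized by
the published median and interquartile range (927 ms, IQR 745-1,123 ms on go
trials; 758 ms, IQR 660-910 ms on no-go trials) and clipped below at the odor
duration, which leaves the median untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .session import (
    ODOR_DURATION,
    PRE_REWARD_WAIT,
    Outcome,
    Session,
    SpikeTrain,
    TrialEvents,
    TrialType,
)

__all__ = [
    "TaskConfig",
    "NeuronArchetype",
    "GroundTruth",
    "DEFAULT_ARCHETYPES",
    "simulate_session",
    "archetype_rate",
    "poisson_spikes",
    "lognormal_from_median_iqr",
]

#: z-score of the 75th percentile of a standard normal.
_Z75 = stats.norm.ppf(0.75)


def lognormal_from_median_iqr(
    median: float, iqr: tuple[float, float]
) -> tuple[float, float]:
    """(mu, sigma) of the log-normal with the given median and IQR width.

    ``mu = ln(median)`` matches the median exactly; ``sigma`` is fitted to the
    interquartile ratio, ``ln(q75/q25) / (2 z_0.75)``.
    """
    q25, q75 = iqr
    if not 0 < q25 < median < q75:
        raise ValueError("require 0 < q25 < median < q75")
    return float(np.log(median)), float(np.log(q75 / q25) / (2 * _Z75))


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the behavioral task and of the simulated animal."""

    n_trials: int = 200
    p_go: float = 0.5
    catch_every: int = 10
    odor_duration: float = ODOR_DURATION
    iti: float = 3.0
    response_window: float = 2.0
    pre_reward_wait: float = PRE_REWARD_WAIT
    go_poke_median: float = 0.927
    go_poke_iqr: tuple[float, float] = (0.745, 1.123)
    nogo_poke_median: float = 0.758
    nogo_poke_iqr: tuple[float, float] = (0.660, 0.910)
    accuracy: float = 0.85
    move_time_mean: float = 0.4
    drink_duration: float = 1.0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be at least 1")
        if not 0 < self.accuracy <= 1:
            raise ValueError("accuracy must be in (0, 1]")
        if not 0 <= self.p_go <= 1:
            raise ValueError("p_go must be in [0, 1]")


@dataclass(frozen=True)
class NeuronArchetype:
    """A parameterized firing archetype.

    ``profile`` holds shape parameters shared across archetypes: rise/fall
    time of plateaus (``edge``), the waiting bump's peak latency and end
    (``bump_peak``, ``bump_end``), the drinking ramp's lead before the valve,
    plateau hold, and fall (``ramp_lead``, ``ramp_hold``, ``ramp_fall``), and
    the below-baseline suppression factor of drinking neurons elsewhere in
    the trial (``suppression``).  Times in seconds, rates in Hz.
    """

    label: str
    baseline_rate: float
    peak_rate: float
    profile: dict[str, float] = field(
        default_factory=lambda: dict(
            edge=0.05,
            bump_peak=0.05,
            bump_end=0.25,
            ramp_lead=0.2,
            ramp_hold=0.25,
            ramp_fall=0.2,
            suppression=0.5,
        )
    )

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or self.peak_rate < 0:
            raise ValueError("rates must be nonnegative")
        if self.label not in _KNOT_BUILDERS:
            raise ValueError(f"unknown archetype label {self.label!r}")


# ---------------------------------------------------------------------------
# Rate profiles (piecewise linear knot lists per trial)
# ---------------------------------------------------------------------------


def _late_plateau_knots(
    trial: TrialEvents, b: float, p: float, edge: float
) -> list[tuple[float, float]]:
    s0 = trial.odor_on + ODOR_DURATION
    return [(s0 - edge, b), (s0, p), (trial.port_exit, p), (trial.port_exit + edge, b)]


def _knots_go_cue_late(a: NeuronArchetype, trial: TrialEvents):
    if trial.trial_type is not TrialType.GO:
        return []
    return _late_plateau_knots(trial, a.baseline_rate, a.peak_rate, a.profile["edge"])


def _knots_waiting_phasic(a: NeuronArchetype, trial: TrialEvents):
    knots = []
    if trial.trial_type is TrialType.GO:
        knots += _late_plateau_knots(
            trial, a.baseline_rate, a.peak_rate, a.profile["edge"]
        )
    if trial.water_port_entry is not None:
        e = trial.water_port_entry
        knots += [
            (e, a.baseline_rate),
            (e + a.profile["bump_peak"], a.peak_rate),
            (e + a.profile["bump_end"], a.baseline_rate),
        ]
    return knots


def _knots_drinking_ramp(a: NeuronArchetype, trial: TrialEvents):
    b = a.baseline_rate
    s = a.profile["suppression"] * b
    edge = a.profile["edge"]
    if trial.water_valve_open is None:
        # engaged but unrewarded: suppressed during nose poking
        return [
            (trial.odor_on - edge, b),
            (trial.odor_on, s),
            (trial.port_exit, s),
            (trial.port_exit + edge, b),
        ]
    v = trial.water_valve_open
    return [
        (trial.odor_on - edge, b),
        (trial.odor_on, s),
        (v - a.profile["ramp_lead"], s),
        (v, a.peak_rate),
        (v + a.profile["ramp_hold"], a.peak_rate),
        (v + a.profile["ramp_hold"] + a.profile["ramp_fall"], b),
    ]


def _knots_untuned(a: NeuronArchetype, trial: TrialEvents):
    return []


_KNOT_BUILDERS = {
    "go_cue_late": _knots_go_cue_late,
    "waiting_phasic": _knots_waiting_phasic,
    "drinking_ramp": _knots_drinking_ramp,
    "untuned": _knots_untuned,
}

#: Baselines of 3-5 Hz and peaks of ~20 Hz are conventional for this cell
#: class; they are configurable, not measured values.
DEFAULT_ARCHETYPES: dict[str, NeuronArchetype] = {
    "go_cue_late": NeuronArchetype("go_cue_late", 3.0, 20.0),
    "waiting_phasic": NeuronArchetype("waiting_phasic", 3.0, 18.0),
    "drinking_ramp": NeuronArchetype("drinking_ramp", 3.0, 20.0),
    "untuned": NeuronArchetype("untuned", 4.0, 4.0),
}


def archetype_rate(
    archetype: NeuronArchetype, trial: TrialEvents, t: float | np.ndarray
) -> np.ndarray:
    """Instantaneous firing rate (Hz) of an archetype at time(s) ``t`` on one
    trial; baseline outside the archetype's tuned windows."""
    knots = _KNOT_BUILDERS[archetype.label](archetype, trial)
    t = np.asarray(t, dtype=float)
    if not knots:
        return np.full(t.shape, archetype.baseline_rate)
    kt, kr = map(np.asarray, zip(*knots))
    return np.interp(t, kt, kr, left=archetype.baseline_rate, right=archetype.baseline_rate)


def _session_knots(
    archetype: NeuronArchetype, trials: Sequence[TrialEvents], session_end: float
) -> tuple[np.ndarray, np.ndarray]:
    """Concatenated piecewise-linear rate knots spanning the whole session."""
    b = archetype.baseline_rate
    knots: list[tuple[float, float]] = [(0.0, b)]
    for trial in trials:
        knots.extend(_KNOT_BUILDERS[archetype.label](archetype, trial))
    knots.append((session_end, b))
    kt, kr = map(np.array, zip(*knots))
    keep = np.concatenate([[True], np.diff(kt) > 0])
    return kt[keep], kr[keep]


# ---------------------------------------------------------------------------
# Spike generation
# ---------------------------------------------------------------------------


def poisson_spikes(
    rate_fn: Callable[[np.ndarray], np.ndarray],
    interval: tuple[float, float],
    rng: np.random.Generator,
    ceiling: float,
) -> np.ndarray:
    """Inhomogeneous Poisson spike times on ``interval`` by thinning.

    ``rate_fn`` must be bounded by ``ceiling`` (Hz) on the interval; candidate
    events are drawn homogeneously at the ceiling rate and kept with
    probability ``rate(t) / ceiling``.
    """
    t0, t1 = interval
    if t1 <= t0:
        raise ValueError("empty interval")
    if ceiling < 0:
        raise ValueError("negative rate ceiling")
    if ceiling == 0:
        return np.empty(0)
    n = rng.poisson(ceiling * (t1 - t0))
    candidates = np.sort(rng.uniform(t0, t1, size=n))
    rates = np.asarray(rate_fn(candidates), dtype=float)
    if np.any(rates < 0):
        raise ValueError("rate function returned a negative rate")
    if np.any(rates > ceiling * (1 + 1e-9)):
        raise ValueError("rate function exceeds the stated ceiling")
    keep = rng.uniform(0, ceiling, size=n) < rates
    return candidates[keep]


@dataclass
class GroundTruth:
    """What the generator knows: each neuron's archetype and its latent rate.

    ``rate_knots`` maps neuron_id to the (times, rates) breakpoints of the
    session-long piecewise-linear rate function, so tests can evaluate the
    exact latent rate at any time via :meth:`rate`.
    """

    labels: dict[str, str]
    archetypes: dict[str, NeuronArchetype]
    rate_knots: dict[str, tuple[np.ndarray, np.ndarray]]

    def rate(self, neuron_id: str, t: float | np.ndarray) -> np.ndarray:
        kt, kr = self.rate_knots[neuron_id]
        return np.interp(np.asarray(t, dtype=float), kt, kr)


# ---------------------------------------------------------------------------
# Session assembly
# ---------------------------------------------------------------------------


def _draw_poke(rng, median, iqr, floor):
    mu, sigma = lognormal_from_median_iqr(median, iqr)
    return max(float(rng.lognormal(mu, sigma)), floor)


def simulate_session(
    task: TaskConfig,
    archetype_counts: Sequence[tuple[NeuronArchetype, int]],
    seed: int,
    session_id: str = "sim",
    animal_id: str = "simulated",
) -> tuple[Session, GroundTruth]:
    """Simulate one full session.

    Trials are laid out sequentially with the configured inter-trial
    interval; every ``catch_every``-th trial is an odorless catch trial, the
    rest are go/no-go with probability ``p_go``, and outcomes are drawn so
    realized accuracy converges to ``task.accuracy``.  Spikes for each neuron
    are drawn from its archetype's session-long rate function.  The same seed
    reproduces the session bit-exactly.
    """
    n_neurons = sum(max(c, 0) for _, c in archetype_counts)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(1 + n_neurons)
    rng = np.random.default_rng(children[0])

    poke_floor = task.odor_duration + 0.02
    trials: list[TrialEvents] = []
    cursor = 0.0
    for i in range(task.n_trials):
        odor_on = cursor + task.iti
        is_catch = task.catch_every > 0 and (i + 1) % task.catch_every == 0
        if is_catch:
            trial_type = TrialType.CATCH
            outcome = Outcome.CORRECT  # catch trials are unscored
            moved = bool(rng.random() < 0.5)
        else:
            trial_type = TrialType.GO if rng.random() < task.p_go else TrialType.NOGO
            outcome = (
                Outcome.CORRECT if rng.random() < task.accuracy else Outcome.ERROR
            )
            moved = (trial_type is TrialType.GO) == (outcome is Outcome.CORRECT)
        go_like = moved  # movement decision sets which poke distribution applies
        if go_like:
            poke = _draw_poke(rng, task.go_poke_median, task.go_poke_iqr, poke_floor)
        else:
            poke = _draw_poke(
                rng, task.nogo_poke_median, task.nogo_poke_iqr, poke_floor
            )
        port_exit = odor_on + poke
        water_port_entry = water_valve_open = None
        trial_end = port_exit + 0.3
        if moved:
            move = float(
                np.clip(
                    rng.gamma(4.0, task.move_time_mean / 4.0),
                    0.15,
                    task.response_window - 0.1,
                )
            )
            water_port_entry = port_exit + move
            rewarded = trial_type is TrialType.GO and outcome is Outcome.CORRECT
            if rewarded:
                water_valve_open = water_port_entry + task.pre_reward_wait
                trial_end = water_valve_open + task.drink_duration
            else:
                trial_end = water_port_entry + 0.5
        trials.append(
            TrialEvents(
                trial_index=i,
                trial_type=trial_type,
                outcome=outcome,
                odor_on=odor_on,
                odor_off=odor_on + task.odor_duration,
                port_exit=port_exit,
                water_port_entry=water_port_entry,
                water_valve_open=water_valve_open,
            )
        )
        cursor = trial_end
    session_end = cursor + task.iti

    spikes: list[SpikeTrain] = []
    labels: dict[str, str] = {}
    archetypes: dict[str, NeuronArchetype] = {}
    rate_knots: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    neuron_idx = 0
    for archetype, count in archetype_counts:
        for _ in range(max(count, 0)):
            nid = f"n{neuron_idx:03d}"
            kt, kr = _session_knots(archetype, trials, session_end)
            nrng = np.random.default_rng(children[1 + neuron_idx])
            times = poisson_spikes(
                lambda t, kt=kt, kr=kr: np.interp(t, kt, kr),
                (0.0, session_end),
                nrng,
                ceiling=float(kr.max()),
            )
            spikes.append(SpikeTrain(nid, times))
            labels[nid] = archetype.label
            archetypes[nid] = archetype
            rate_knots[nid] = (kt, kr)
            neuron_idx += 1

    session = Session(session_id, animal_id, trials, spikes)
    session.validate()
    return session, GroundTruth(labels, archetypes, rate_knots)
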