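"""Domain model for odor-guided go/no-go recording sessions.

A session holds the per-trial behavioral event times of the task — odor valve
opening/closing at the odor port, odor-port exit, water-port entry, and water
valve opening — together with the spike times of every simultaneously recorded
neuron, all on a single per-session clock in seconds.

The task timeline: after a 3 s inter-trial interval the animal pokes the odor
port, an odor is presented for 500 ms, the animal keeps its nose in the port
for the nose-poking epoch and then exits.  On go trials it moves to the water
port, waits 300 ms, and the water valve opens; on no-go trials it withholds.
One in ten trials is an odorless catch trial, unrewarded regardless of choice.

Epoch definitions (baseline, nose-poking, waiting, drinking, ...) are
centralized here so every downstream analysis resolves window bounds through
the same table rather than re-deriving offsets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrialType",
    "Outcome",
    "TrialEvents",
    "SpikeTrain",
    "Session",
    "Epoch",
    "EPOCHS",
    "Refusal",
    "ValidationError",
    "SessionParseError",
    "read_session",
    "write_session",
    "align_spikes",
    "trial_filter",
]

#: Time the odor valve stays open (s).
ODOR_DURATION = 0.5
#: Required nose-poke hold at the water port before the valve opens (s).
PRE_REWARD_WAIT = 0.3
#: Tolerance used when checking timing invariants (s).
TIME_TOL = 1e-6


class TrialType(str, Enum):
    GO = "go"
    NOGO = "nogo"
    CATCH = "catch"


class Outcome(str, Enum):
    CORRECT = "correct"
    ERROR = "error"


class ValidationError(ValueError):
    """A session or trial violates a structural invariant."""


class SessionParseError(ValueError):
    """A session container on disk is malformed."""


@dataclass(frozen=True)
class Refusal:
    """Typed refusal returned when an analysis precondition is not met.

    Downstream stages treat a refusal as "neuron (or condition) excluded"
    rather than an error, mirroring the minimum-trial inclusion rule.
    """

    reason: str

    def __bool__(self) -> bool:  # refusals are falsy so `if result:` reads well
        return False


@dataclass(frozen=True)
class TrialEvents:
    """Event times for one trial, session clock, seconds.

    ``iti_end`` coincides with ``odor_on`` (odor-port entry opens the valve);
    it is kept as an explicit field because the baseline epoch is anchored to
    the end of the inter-trial interval.  Water-port fields are ``None`` on
    trials without a water-port visit (no-go correct, go error).
    """

    trial_index: int
    trial_type: TrialType
    outcome: Outcome
    odor_on: float
    odor_off: float
    port_exit: float
    water_port_entry: float | None = None
    water_valve_open: float | None = None

    @property
    def iti_end(self) -> float:
        return self.odor_on

    def validate(self) -> None:
        if self.trial_index < 0:
            raise ValidationError(f"trial {self.trial_index}: negative index")
        if not self.odor_on < self.odor_off:
            raise ValidationError(
                f"trial {self.trial_index}: odor_off ({self.odor_off}) must be "
                f"after odor_on ({self.odor_on})"
            )
        if self.odor_off > self.port_exit + TIME_TOL:
            raise ValidationError(
                f"trial {self.trial_index}: port_exit ({self.port_exit}) "
                f"precedes odor_off ({self.odor_off})"
            )
        if self.water_valve_open is not None:
            if self.water_port_entry is None:
                raise ValidationError(
                    f"trial {self.trial_index}: water_valve_open without "
                    "water_port_entry"
                )
            wait = self.water_valve_open - self.water_port_entry
            if abs(wait - PRE_REWARD_WAIT) > 1e-3:
                raise ValidationError(
                    f"trial {self.trial_index}: water valve opened {wait:.4f} s "
                    f"after port entry, expected {PRE_REWARD_WAIT} s"
                )
        if self.water_port_entry is not None and (
            self.water_port_entry < self.port_exit - TIME_TOL
        ):
            raise ValidationError(
                f"trial {self.trial_index}: water_port_entry precedes port_exit"
            )


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times of one neuron on the session clock (sorted, seconds)."""

    neuron_id: str
    spike_times: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.spike_times, dtype=float)
        object.__setattr__(self, "spike_times", times)

    def validate(self) -> None:
        if np.any(np.diff(self.spike_times) < 0):
            raise ValidationError(f"neuron {self.neuron_id}: spike times not sorted")


@dataclass
class Session:
    """One recording: trials, spike trains, and identifying metadata."""

    session_id: str
    animal_id: str
    trials: list[TrialEvents]
    spikes: list[SpikeTrain]

    @property
    def behavioral_accuracy(self) -> float:
        """Fraction of correct go/no-go trials; catch trials are excluded
        because they are unrewarded regardless of the animal's choice."""
        scored = [t for t in self.trials if t.trial_type is not TrialType.CATCH]
        if not scored:
            return float("nan")
        return sum(t.outcome is Outcome.CORRECT for t in scored) / len(scored)

    def validate(self) -> None:
        indices = [t.trial_index for t in self.trials]
        if len(set(indices)) != len(indices):
            raise ValidationError("duplicate trial indices")
        for t in self.trials:
            t.validate()
        for s in self.spikes:
            s.validate()

    def select_trials(
        self, condition: Callable[[TrialEvents], bool]
    ) -> list[TrialEvents]:
        return [t for t in self.trials if condition(t)]


# ---------------------------------------------------------------------------
# Epochs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Epoch:
    """A behavioral epoch: a window anchored to a trial event.

    Fixed-length epochs give ``start_offset``/``end_offset`` relative to
    ``align_event``.  Epochs whose end depends on the animal's behavior
    (e.g., nose-poking, which ends at odor-port exit) give ``end_event``
    instead, and the window for a trial runs from
    ``event(align_event) + start_offset`` to ``event(end_event) + end_offset``.
    """

    name: str
    align_event: str
    start_offset: float
    end_offset: float = 0.0
    end_event: str | None = None

    def bounds(self, trial: TrialEvents) -> tuple[float, float] | Refusal:
        """Absolute (start, end) for one trial, or a refusal if an anchoring
        event is absent on this trial."""
        t0 = getattr(trial, self.align_event)
        if t0 is None:
            return Refusal(f"trial {trial.trial_index}: no {self.align_event}")
        start = t0 + self.start_offset
        if self.end_event is None:
            end = t0 + self.end_offset
        else:
            t1 = getattr(trial, self.end_event)
            if t1 is None:
                return Refusal(f"trial {trial.trial_index}: no {self.end_event}")
            end = t1 + self.end_offset
        if not start < end:
            raise ValidationError(
                f"epoch {self.name}: empty window [{start}, {end}) on trial "
                f"{trial.trial_index}"
            )
        return start, end


#: Canonical epoch table.  All paper windows (given in ms) are converted to
#: seconds exactly once, here.
EPOCHS: dict[str, Epoch] = {
    # 200-0 ms before the end of the inter-trial interval (== odor-port entry)
    "baseline_iti": Epoch("baseline_iti", "odor_on", -0.2, 0.0),
    # 1200-1000 ms before odor-port entry; baseline for population distances
    "pre_odor_baseline": Epoch("pre_odor_baseline", "odor_on", -1.2, -1.0),
    "odor_presentation": Epoch("odor_presentation", "odor_on", 0.0, ODOR_DURATION),
    "nose_poking": Epoch("nose_poking", "odor_on", 0.0, end_event="port_exit"),
    # late phase: valve closure (odor_on + 0.5) to odor-port exit
    "late_nose_poking": Epoch(
        "late_nose_poking", "odor_on", ODOR_DURATION, end_event="port_exit"
    ),
    "pre_exit": Epoch("pre_exit", "port_exit", -0.3, 0.0),
    "moving": Epoch("moving", "port_exit", 0.0, end_event="water_port_entry"),
    # 300 ms hold between water-port entry and valve opening
    "waiting": Epoch("waiting", "water_port_entry", 0.0, PRE_REWARD_WAIT),
    # reward consumption, analyzed to +1000 ms after the valve opens
    "drinking": Epoch("drinking", "water_valve_open", 0.0, 1.0),
}


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def align_spikes(
    train: SpikeTrain,
    event_times: Sequence[float],
    window: tuple[float, float],
) -> list[np.ndarray]:
    """Spike times relative to each event, restricted to ``window``.

    Windows are half-open ``[start, end)`` so a spike on a shared boundary of
    adjacent windows is counted exactly once.  Returns one array per event, in
    event order; an empty event list yields an empty list.
    """
    start, end = window
    if not start < end:
        raise ValueError(f"window start {start} must precede end {end}")
    times = train.spike_times
    out: list[np.ndarray] = []
    for ev in event_times:
        lo = np.searchsorted(times, ev + start, side="left")
        hi = np.searchsorted(times, ev + end, side="left")
        out.append(times[lo:hi] - ev)
    return out


def trial_filter(
    trials: Iterable[TrialEvents],
    condition: Callable[[TrialEvents], bool],
    min_trials: int = 5,
) -> list[TrialEvents] | Refusal:
    """Trials matching ``condition`` if at least ``min_trials`` match.

    Implements the minimum-trial inclusion rule: conditions with fewer than
    five trials are excluded from analysis, signaled by a :class:`Refusal`.
    """
    subset = [t for t in trials if condition(t)]
    if len(subset) < min_trials:
        return Refusal(
            f"{len(subset)} matching trials, fewer than required {min_trials}"
        )
    return subset


# ---------------------------------------------------------------------------
# Container I/O
# ---------------------------------------------------------------------------

_TRIAL_COLUMNS = [
    "trial_index",
    "trial_type",
    "outcome",
    "odor_on",
    "odor_off",
    "port_exit",
    "water_port_entry",
    "water_valve_open",
]


def write_session(session: Session, path: str | Path) -> Path:
    """Write the session container: trials.csv, spikes.csv, metadata.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for t in session.trials:
        rows.append(
            {
                "trial_index": t.trial_index,
                "trial_type": t.trial_type.value,
                "outcome": t.outcome.value,
                "odor_on": t.odor_on,
                "odor_off": t.odor_off,
                "port_exit": t.port_exit,
                "water_port_entry": t.water_port_entry,
                "water_valve_open": t.water_valve_open,
            }
        )
    pd.DataFrame(rows, columns=_TRIAL_COLUMNS).to_csv(
        path / "trials.csv", index=False, float_format="%.17g"
    )
    spike_rows = {
        "neuron_id": np.concatenate(
            [[s.neuron_id] * len(s.spike_times) for s in session.spikes]
        )
        if session.spikes
        else [],
        "spike_time": np.concatenate([s.spike_times for s in session.spikes])
        if session.spikes
        else [],
    }
    pd.DataFrame(spike_rows).to_csv(
        path / "spikes.csv", index=False, float_format="%.17g"
    )
    meta = {
        "session_id": session.session_id,
        "animal_id": session.animal_id,
        "neuron_order": [s.neuron_id for s in session.spikes],
    }
    (path / "metadata.json").write_text(json.dumps(meta, indent=1))
    return path


def read_session(path: str | Path) -> Session:
    """Read a session container and validate its invariants.

    Round-trips with :func:`write_session` bit-exactly on event and spike
    values (times are serialized with 17 significant digits).
    """
    path = Path(path)
    try:
        trials_df = pd.read_csv(path / "trials.csv", float_precision="round_trip")
        spikes_df = pd.read_csv(path / "spikes.csv", float_precision="round_trip")
        meta = json.loads((path / "metadata.json").read_text())
    except FileNotFoundError as exc:
        raise SessionParseError(f"missing session file: {exc.filename}") from exc

    missing = set(_TRIAL_COLUMNS) - set(trials_df.columns)
    if missing:
        raise SessionParseError(f"trials.csv missing columns: {sorted(missing)}")

    trials: list[TrialEvents] = []
    for _, row in trials_df.iterrows():
        try:
            trials.append(
                TrialEvents(
                    trial_index=int(row["trial_index"]),
                    trial_type=TrialType(row["trial_type"]),
                    outcome=Outcome(row["outcome"]),
                    odor_on=float(row["odor_on"]),
                    odor_off=float(row["odor_off"]),
                    port_exit=float(row["port_exit"]),
                    water_port_entry=None
                    if pd.isna(row["water_port_entry"])
                    else float(row["water_port_entry"]),
                    water_valve_open=None
                    if pd.isna(row["water_valve_open"])
                    else float(row["water_valve_open"]),
                )
            )
        except (ValueError, KeyError) as exc:
            raise SessionParseError(
                f"trials.csv row {row.get('trial_index', '?')}: {exc}"
            ) from exc

    spikes: list[SpikeTrain] = []
    if len(spikes_df):
        spikes_df["neuron_id"] = spikes_df["neuron_id"].astype(str)
        order = meta.get("neuron_order")
        grouped = {
            nid: np.sort(g["spike_time"].to_numpy(float))
            for nid, g in spikes_df.groupby("neuron_id", sort=False)
        }
        ids = [str(n) for n in order] if order else list(grouped)
        spikes = [SpikeTrain(nid, grouped.get(nid, np.empty(0))) for nid in ids]

    session = Session(
        session_id=str(meta["session_id"]),
        animal_id=str(meta["animal_id"]),
        trials=trials,
        spikes=spikes,
    )
    session.validate()
    return session
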