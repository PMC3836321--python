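"""Event-log data model for patch-crossing trials.

A trial watches a small shoal of damselfish in a two-patch arena.  Every
time a fish crosses the centre line we record when it happened, which fish
moved and in which direction.  This module defines the containers for those
records (:class:`CrossingEvent`, :class:`Trial`, :class:`Dataset`), CSV
input/output, replay and validation of the implied side occupancies, and
the conversion of an event stream into the per-event decision states
(:class:`DecisionPoint`) consumed by the likelihood machinery.

Conventions
-----------
* Times are seconds since the central divider was removed.  Input files may
  give a ``frame`` column instead, which is divided by the trial's frame
  rate.
* Events within a trial are ordered by ``(time_s, input record order)``;
  simultaneous-frame crossings keep their input order.
* In the asymmetric (single refuge) configuration the left side denotes the
  refuge and the right side open water.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "L2R",
    "R2L",
    "LEFT",
    "RIGHT",
    "CrossingEvent",
    "FishRecord",
    "TrialMetadata",
    "Trial",
    "Dataset",
    "DecisionPoint",
    "Violation",
    "ValidationReport",
    "EventLogError",
    "EventLogFormatError",
    "EventLogConsistencyError",
    "origin_side",
    "destination_side",
    "flip_direction",
    "flip_lr",
    "build_decision_points",
    "read_event_log",
    "write_event_log",
    "validate_dataset",
]

L2R = "L2R"
R2L = "R2L"
DIRECTIONS = (L2R, R2L)
LEFT = "L"
RIGHT = "R"
ENVIRONMENT_MODES = ("symmetric", "asymmetric")


class EventLogError(ValueError):
    """Base class for event-log problems."""


class EventLogFormatError(EventLogError):
    """A file or record does not match the expected layout."""


class EventLogConsistencyError(EventLogError):
    """An event stream contradicts the occupancy it implies."""


def origin_side(direction: str) -> str:
    """Side a crossing started from (``'L'`` for ``L2R``)."""
    return LEFT if direction == L2R else RIGHT


def destination_side(direction: str) -> str:
    """Side a crossing ended on."""
    return RIGHT if direction == L2R else LEFT


def flip_direction(direction: str) -> str:
    return R2L if direction == L2R else L2R


@dataclass(frozen=True)
class CrossingEvent:
    """One fish crossing the centre line at one instant."""

    trial_id: str
    time_s: float
    fish_id: str
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise EventLogFormatError(
                f"direction must be one of {DIRECTIONS}, got {self.direction!r}"
            )
        if not np.isfinite(self.time_s) or self.time_s < 0:
            raise EventLogFormatError(
                f"time_s must be a non-negative finite number, got {self.time_s!r}"
            )


@dataclass(frozen=True)
class FishRecord:
    """Identity and (optionally) body length of one fish."""

    fish_id: str
    length_mm: float | None = None

    def __post_init__(self) -> None:
        if self.length_mm is not None and not self.length_mm > 0:
            raise EventLogFormatError(
                f"length_mm must be positive when present, got {self.length_mm!r}"
            )


@dataclass(frozen=True)
class TrialMetadata:
    """Per-trial design facts: group size, timing and initial split."""

    trial_id: str
    group_size: int
    initial_left_ids: frozenset[str]
    duration_s: float = 600.0
    fps: float = 15.0
    environment_mode: str = "symmetric"

    def __post_init__(self) -> None:
        object.__setattr__(self, "initial_left_ids", frozenset(self.initial_left_ids))
        if not 2 <= self.group_size <= 12:
            raise EventLogFormatError(
                f"group_size must be in [2, 12], got {self.group_size}"
            )
        if not 1 <= len(self.initial_left_ids) <= self.group_size - 1:
            raise EventLogFormatError(
                f"trial {self.trial_id!r}: need at least one fish per side "
                f"({len(self.initial_left_ids)} of {self.group_size} initially left)"
            )
        if self.duration_s < 0:
            raise EventLogFormatError("duration_s must be non-negative")
        if not self.fps > 0:
            raise EventLogFormatError("fps must be positive")
        if self.environment_mode not in ENVIRONMENT_MODES:
            raise EventLogFormatError(
                f"environment_mode must be one of {ENVIRONMENT_MODES}"
            )


@dataclass(frozen=True)
class Trial:
    """Metadata plus the ordered crossing events of one trial."""

    metadata: TrialMetadata
    events: tuple[CrossingEvent, ...] = ()
    roster: tuple[FishRecord, ...] = ()

    def __post_init__(self) -> None:
        events = tuple(
            sorted(self.events, key=lambda ev: ev.time_s)  # stable: ties keep order
        )
        object.__setattr__(self, "events", events)
        object.__setattr__(self, "roster", tuple(self.roster))
        for ev in events:
            if ev.trial_id != self.metadata.trial_id:
                raise EventLogFormatError(
                    f"event for trial {ev.trial_id!r} attached to trial "
                    f"{self.metadata.trial_id!r}"
                )

    @property
    def trial_id(self) -> str:
        return self.metadata.trial_id

    @property
    def group_size(self) -> int:
        return self.metadata.group_size

    @property
    def n_left_initial(self) -> int:
        return len(self.metadata.initial_left_ids)

    def initial_side(self, fish_id: str) -> str:
        return LEFT if fish_id in self.metadata.initial_left_ids else RIGHT

    def replay(self) -> Iterator[tuple[int, CrossingEvent]]:
        """Yield ``(n_left_before_event, event)`` pairs in order."""
        n_left = self.n_left_initial
        for ev in self.events:
            yield n_left, ev
            n_left += 1 if ev.direction == R2L else -1

    def final_occupancy(self) -> int:
        """Number of fish on the left after the last event."""
        n_left = self.n_left_initial
        for ev in self.events:
            n_left += 1 if ev.direction == R2L else -1
        return n_left


@dataclass(frozen=True)
class Dataset:
    """A collection of trials; the unit the likelihood multiplies over."""

    trials: tuple[Trial, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "trials", tuple(self.trials))
        ids = [t.trial_id for t in self.trials]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise EventLogFormatError(f"duplicate trial ids: {dupes}")

    def __iter__(self) -> Iterator[Trial]:
        return iter(self.trials)

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def n_events(self) -> int:
        return sum(len(t.events) for t in self.trials)

    def trial(self, trial_id: str) -> Trial:
        for t in self.trials:
            if t.trial_id == trial_id:
                return t
        raise KeyError(trial_id)

    def filter_group_size(self, group_size: int) -> "Dataset":
        return Dataset(tuple(t for t in self.trials if t.group_size == group_size))

    def events_frame(self) -> pd.DataFrame:
        rows = [
            (ev.trial_id, ev.time_s, ev.fish_id, ev.direction)
            for t in self.trials
            for ev in t.events
        ]
        return pd.DataFrame(rows, columns=["trial_id", "time_s", "fish_id", "direction"])

    def metadata_frame(self) -> pd.DataFrame:
        rows = [
            (
                t.trial_id,
                t.group_size,
                t.metadata.duration_s,
                t.metadata.fps,
                ";".join(sorted(t.metadata.initial_left_ids)),
                t.metadata.environment_mode,
            )
            for t in self.trials
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "trial_id",
                "group_size",
                "duration_s",
                "fps",
                "initial_left_ids",
                "environment_mode",
            ],
        )

    def roster_frame(self) -> pd.DataFrame:
        rows = [
            (t.trial_id, f.fish_id, f.length_mm)
            for t in self.trials
            for f in t.roster
        ]
        return pd.DataFrame(rows, columns=["trial_id", "fish_id", "length_mm"])


def flip_lr(data: Trial | Dataset) -> Trial | Dataset:
    """Mirror a trial or dataset left<->right.

    Requires a complete roster (one record per fish), because the mirrored
    initial-left set is the roster complement of the original one.
    """
    if isinstance(data, Dataset):
        return Dataset(tuple(flip_lr(t) for t in data.trials))
    trial = data
    roster_ids = {f.fish_id for f in trial.roster}
    if len(roster_ids) != trial.group_size:
        raise EventLogError(
            "flip_lr needs a complete roster to invert the initial split"
        )
    new_left = frozenset(roster_ids - trial.metadata.initial_left_ids)
    meta = replace(trial.metadata, initial_left_ids=new_left)
    events = tuple(
        replace(ev, direction=flip_direction(ev.direction)) for ev in trial.events
    )
    return Trial(meta, events, trial.roster)


@dataclass(frozen=True)
class DecisionPoint:
    """Pre-event state plus the observed outcome of one crossing.

    ``informative`` is true exactly when both sides were occupied before
    the event; only informative points contribute to model selection (a
    crossing from the only occupied side carries no information about
    side choice).
    """

    trial_id: str
    time_s: float
    n_left: int
    n_right: int
    last_direction: str | None
    run_length: int
    time_since_last_s: float | None
    recent_moves: tuple[tuple[str, float], ...]
    outcome_side: str
    informative: bool

    @property
    def group_size(self) -> int:
        return self.n_left + self.n_right


def build_decision_points(
    trial: Trial, memory_window_s: float = 3.5
) -> list[DecisionPoint]:
    """Convert a trial's event stream into ordered decision points.

    Each event yields one point describing the occupancy immediately
    *before* the event, the direction/run-length/recency of preceding
    moves (recent moves are those no older than ``memory_window_s``), and
    the side the observed crossing originated from.
    """
    points: list[DecisionPoint] = []
    n_left = trial.n_left_initial
    g = trial.group_size
    history: list[tuple[float, str]] = []
    head = 0  # index of the oldest move still inside the memory window
    last_dir: str | None = None
    last_t: float | None = None
    run = 0
    for ev in trial.events:
        while head < len(history) and ev.time_s - history[head][0] > memory_window_s:
            head += 1
        recent = tuple(
            (d, ev.time_s - t) for t, d in history[head:]
        )
        n_right = g - n_left
        points.append(
            DecisionPoint(
                trial_id=trial.trial_id,
                time_s=ev.time_s,
                n_left=n_left,
                n_right=n_right,
                last_direction=last_dir,
                run_length=run,
                time_since_last_s=None if last_t is None else ev.time_s - last_t,
                recent_moves=recent,
                outcome_side=origin_side(ev.direction),
                informative=min(n_left, n_right) >= 1,
            )
        )
        n_left += 1 if ev.direction == R2L else -1
        run = run + 1 if ev.direction == last_dir else 1
        last_dir = ev.direction
        last_t = ev.time_s
        history.append((ev.time_s, ev.direction))
    return points


@dataclass(frozen=True)
class Violation:
    trial_id: str
    event_index: int | None
    kind: str
    message: str


@dataclass(frozen=True)
class ValidationReport:
    event_counts: Mapping[str, int]
    violations: tuple[Violation, ...]

    @property
    def ok(self) -> bool:
        return not self.violations

    def summary_frame(self) -> pd.DataFrame:
        counts = pd.DataFrame(
            sorted(self.event_counts.items()), columns=["trial_id", "n_events"]
        )
        nviol = {tid: 0 for tid in self.event_counts}
        for v in self.violations:
            nviol[v.trial_id] = nviol.get(v.trial_id, 0) + 1
        counts["n_violations"] = counts["trial_id"].map(nviol).fillna(0).astype(int)
        return counts


def _trial_violations(trial: Trial) -> list[Violation]:
    out: list[Violation] = []
    tid = trial.trial_id
    roster_ids = {f.fish_id for f in trial.roster}
    side: dict[str, str] = {f: LEFT for f in trial.metadata.initial_left_ids}
    prev_t = -np.inf
    for i, ev in enumerate(trial.events):
        if ev.time_s < prev_t:
            out.append(
                Violation(tid, i, "non-monotone time",
                          f"event {i} at t={ev.time_s} precedes t={prev_t}")
            )
        prev_t = ev.time_s
        if roster_ids and ev.fish_id not in roster_ids:
            out.append(
                Violation(tid, i, "unknown fish",
                          f"event {i}: fish {ev.fish_id!r} not in roster")
            )
        cur = side.get(ev.fish_id, RIGHT)
        if cur != origin_side(ev.direction):
            out.append(
                Violation(
                    tid, i, "side mismatch",
                    f"event {i}: fish {ev.fish_id!r} crossed {ev.direction} "
                    f"while on side {cur}",
                )
            )
        side[ev.fish_id] = destination_side(ev.direction)
    return out


def validate_dataset(dataset: Dataset) -> ValidationReport:
    """Report-only consistency check: ordering, rosters and side replay."""
    counts = {t.trial_id: len(t.events) for t in dataset.trials}
    violations: list[Violation] = []
    for trial in dataset.trials:
        violations.extend(_trial_violations(trial))
    return ValidationReport(event_counts=counts, violations=tuple(violations))


def _read_csv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(
            path,
            dtype={"trial_id": str, "fish_id": str},
            float_precision="round_trip",
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: str | Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise EventLogFormatError(f"{path}: missing column(s) {missing}")


def read_event_log(
    events_path: str | Path,
    metadata_path: str | Path,
    roster_path: str | Path | None = None,
) -> Dataset:
    """Read a dataset from delimited-text files.

    ``events_path`` needs columns ``trial_id, fish_id, direction`` and one
    of ``time_s`` or ``frame`` (frames are divided by the trial's fps).
    ``metadata_path`` needs ``trial_id, group_size, initial_left_ids``
    (';'-separated) and may give ``duration_s, fps, environment_mode``.
    The optional roster file has ``trial_id, fish_id, length_mm``.

    Raises :class:`EventLogFormatError` for missing columns and
    :class:`EventLogConsistencyError` if a fish crosses from a side it is
    not on.
    """
    meta_df = _read_csv(metadata_path)
    _require_columns(meta_df, ["trial_id", "group_size", "initial_left_ids"], metadata_path)

    events_df = _read_csv(events_path)
    if not events_df.empty:
        _require_columns(events_df, ["trial_id", "fish_id", "direction"], events_path)
        if "time_s" not in events_df.columns and "frame" not in events_df.columns:
            raise EventLogFormatError(
                f"{events_path}: missing column(s) ['time_s' or 'frame']"
            )

    roster_df = pd.DataFrame()
    if roster_path is not None:
        roster_df = _read_csv(roster_path)
        if not roster_df.empty:
            _require_columns(roster_df, ["trial_id", "fish_id"], roster_path)

    trials: list[Trial] = []
    for _, row in meta_df.iterrows():
        tid = str(row["trial_id"])
        fps = float(row["fps"]) if "fps" in meta_df.columns and pd.notna(row.get("fps")) else 15.0
        duration = (
            float(row["duration_s"])
            if "duration_s" in meta_df.columns and pd.notna(row.get("duration_s"))
            else 600.0
        )
        mode = (
            str(row["environment_mode"])
            if "environment_mode" in meta_df.columns and pd.notna(row.get("environment_mode"))
            else "symmetric"
        )
        left_ids = frozenset(
            s for s in str(row["initial_left_ids"]).split(";") if s
        )
        meta = TrialMetadata(
            trial_id=tid,
            group_size=int(row["group_size"]),
            initial_left_ids=left_ids,
            duration_s=duration,
            fps=fps,
            environment_mode=mode,
        )

        events: list[CrossingEvent] = []
        if not events_df.empty:
            sub = events_df[events_df["trial_id"] == tid]
            for _, erow in sub.iterrows():
                if "time_s" in events_df.columns and pd.notna(erow.get("time_s")):
                    t = float(erow["time_s"])
                else:
                    t = float(erow["frame"]) / fps
                events.append(
                    CrossingEvent(tid, t, str(erow["fish_id"]), str(erow["direction"]))
                )

        roster: list[FishRecord] = []
        if not roster_df.empty:
            rsub = roster_df[roster_df["trial_id"] == tid]
            for _, rrow in rsub.iterrows():
                length = rrow.get("length_mm")
                roster.append(
                    FishRecord(
                        str(rrow["fish_id"]),
                        None if pd.isna(length) else float(length),
                    )
                )
        trials.append(Trial(meta, tuple(events), tuple(roster)))

    dataset = Dataset(tuple(trials))
    report = validate_dataset(dataset)
    hard = [v for v in report.violations if v.kind in ("side mismatch", "unknown fish")]
    if hard:
        v = hard[0]
        raise EventLogConsistencyError(
            f"trial {v.trial_id!r}, event {v.event_index}: {v.message}"
            + (f" (+{len(hard) - 1} more)" if len(hard) > 1 else "")
        )
    return dataset


def write_event_log(
    dataset: Dataset,
    events_path: str | Path,
    metadata_path: str | Path,
    roster_path: str | Path | None = None,
) -> None:
    """Write a dataset back to the CSV layout accepted by `read_event_log`."""
    dataset.events_frame().to_csv(events_path, index=False)
    dataset.metadata_frame().to_csv(metadata_path, index=False)
    if roster_path is not None:
        dataset.roster_frame().to_csv(roster_path, index=False)
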