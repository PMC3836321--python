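"""Event-driven simulation of crossing sequences.

Crossings are generated as a race of competing exponential hazards: each
fish carries hazard ``base_rate * weight(side, state)``, the next event
time is exponential with the summed hazard, and the origin side is chosen
with probability proportional to its total hazard.  That side probability
is exactly the one the likelihood assigns, so the simulator and the
likelihood share a single definition of the decision rule.

Within the chosen side the crossing fish is picked uniformly at random by
default (the side-level likelihood carries no identity information); a
round-robin option and per-fish rate multipliers are available for
leadership experiments.

Waiting times are drawn from the hazard prevailing just after the previous
event; for the recent-movers model (D2), whose weights also depend on how
much of the memory window has elapsed, the origin side is then re-drawn
from the weights evaluated at the realized event time, so simulated side
outcomes match the likelihood exactly even though waiting times are
approximated piecewise-constantly.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .eventlog import (
    L2R,
    LEFT,
    R2L,
    RIGHT,
    CrossingEvent,
    Dataset,
    FishRecord,
    Trial,
    TrialMetadata,
)
from .models import DecisionState, per_fish_weight, side_probability, validate_params

__all__ = ["SimulationDesign", "SimulationError", "simulate_trial", "simulate_experiment"]


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimulationDesign:
    """One simulated trial's configuration.

    ``base_rate`` is the per-fish crossing hazard (per second) before model
    weighting; its default of 0.08 gives inter-crossing intervals on the
    few-second scale typical of small shoals in a two-patch arena.
    Termination is by ``duration_s``, ``n_events`` or whichever comes
    first if both are set.
    """

    group_size: int
    initial_left: int
    model: str = "M0"
    params: Mapping[str, float] = field(default_factory=dict)
    duration_s: float | None = 600.0
    n_events: int | None = None
    base_rate: float = 0.08
    seed: int = 0
    trial_id: str = "sim"
    environment_mode: str = "symmetric"
    memory_window_s: float = 3.5
    include_focal: bool = False
    fish_selection: str = "uniform"  # "uniform" | "round_robin"
    fish_rate_multipliers: tuple[float, ...] | None = None
    max_events: int = 500_000

    def __post_init__(self) -> None:
        object.__setattr__(self, "params", dict(self.params))
        if not 1 <= self.initial_left <= self.group_size - 1:
            raise ValueError(
                f"initial_left must be in [1, {self.group_size - 1}], "
                f"got {self.initial_left}"
            )
        if not self.base_rate > 0:
            raise ValueError("base_rate must be positive")
        if self.duration_s is None and self.n_events is None:
            raise ValueError("set duration_s and/or n_events")
        if self.fish_selection not in ("uniform", "round_robin"):
            raise ValueError(f"unknown fish_selection {self.fish_selection!r}")
        if (
            self.fish_rate_multipliers is not None
            and len(self.fish_rate_multipliers) != self.group_size
        ):
            raise ValueError("fish_rate_multipliers must have one entry per fish")
        validate_params(self.model, self.params)


def _pick_fish(
    side_fish: deque,
    multipliers: Sequence[float],
    selection: str,
    rng: np.random.Generator,
) -> int:
    if selection == "round_robin":
        return side_fish[0]
    weights = np.array([multipliers[i] for i in side_fish], dtype=float)
    probs = weights / weights.sum()
    return side_fish[int(rng.choice(len(side_fish), p=probs))]


def simulate_trial(
    design: SimulationDesign, rng: np.random.Generator | None = None
) -> Trial:
    """Simulate one trial; identical design and seed give identical events."""
    if rng is None:
        rng = np.random.default_rng(design.seed)
    g = design.group_size
    tid = design.trial_id
    fish_ids = [f"{tid}-f{i + 1:02d}" for i in range(g)]
    multipliers = design.fish_rate_multipliers or (1.0,) * g
    left: deque[int] = deque(range(design.initial_left))
    right: deque[int] = deque(range(design.initial_left, g))

    cfg = dict(
        include_focal=design.include_focal,
        memory_window_s=design.memory_window_s,
        environment_mode=design.environment_mode,
    )

    def total_hazard(t_now: float, recent: deque, last_dir: str | None) -> float:
        state = DecisionState(
            n_left=len(left),
            n_right=len(right),
            last_direction=last_dir,
            recent_moves=tuple((d, t_now - tt) for tt, d in recent),
        )
        lam = 0.0
        if left:
            lam += len(left) * design.base_rate * per_fish_weight(
                design.model, design.params, LEFT, state, **cfg
            )
        if right:
            lam += len(right) * design.base_rate * per_fish_weight(
                design.model, design.params, RIGHT, state, **cfg
            )
        return lam

    events: list[CrossingEvent] = []
    recent: deque[tuple[float, str]] = deque()  # memory window for D2 only
    last_dir: str | None = None  # the last mover has no age limit (D1)
    t = 0.0
    target = design.n_events if design.n_events is not None else design.max_events
    target = min(target, design.max_events)
    while len(events) < target:
        while recent and t - recent[0][0] > design.memory_window_s:
            recent.popleft()
        lam = total_hazard(t, recent, last_dir)
        if lam <= 0:
            raise SimulationError(
                f"total hazard vanished at t={t:.3f} (model {design.model})"
            )
        t_new = t + rng.exponential(1.0 / lam)
        if design.duration_s is not None and t_new > design.duration_s:
            break
        # side choice uses the state at the realized event time
        while recent and t_new - recent[0][0] > design.memory_window_s:
            recent.popleft()
        state = DecisionState(
            n_left=len(left),
            n_right=len(right),
            last_direction=last_dir,
            recent_moves=tuple((d, t_new - tt) for tt, d in recent),
        )
        p_left = side_probability(design.model, design.params, state, **cfg)
        if rng.random() < p_left:
            fish = _pick_fish(left, multipliers, design.fish_selection, rng)
            left.remove(fish)
            right.append(fish)
            direction = L2R
        else:
            fish = _pick_fish(right, multipliers, design.fish_selection, rng)
            right.remove(fish)
            left.append(fish)
            direction = R2L
        events.append(CrossingEvent(tid, t_new, fish_ids[fish], direction))
        recent.append((t_new, direction))
        last_dir = direction
        t = t_new

    duration = design.duration_s if design.duration_s is not None else t
    metadata = TrialMetadata(
        trial_id=tid,
        group_size=g,
        initial_left_ids=frozenset(fish_ids[: design.initial_left]),
        duration_s=duration,
        fps=15.0,
        environment_mode=design.environment_mode,
    )
    roster = tuple(FishRecord(fid) for fid in fish_ids)
    return Trial(metadata, tuple(events), roster)


def simulate_experiment(
    designs: Sequence[SimulationDesign], master_seed: int | None = None
) -> Dataset:
    """Simulate independent trials.

    With ``master_seed`` given, trial ``i`` uses seed ``master_seed + i``;
    otherwise each design's own seed applies.  Trial ids are suffixed with
    their index whenever the designs' ids are not already unique.
    """
    if not designs:
        raise ValueError("need at least one design")
    ids = [d.trial_id for d in designs]
    unique = len(set(ids)) == len(ids)
    trials = []
    for i, design in enumerate(designs):
        seed = master_seed + i if master_seed is not None else design.seed
        tid = design.trial_id if unique else f"{design.trial_id}-{i + 1:03d}"
        trials.append(replace(design, seed=seed, trial_id=tid) if (seed != design.seed or tid != design.trial_id) else design)
    return Dataset(tuple(simulate_trial(d) for d in trials))
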