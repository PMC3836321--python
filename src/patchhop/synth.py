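"""Synthetic experiments with known ground truth.

Emulates the study design of the two-patch crossing experiments: 10-minute
trials recorded at 15 frames per second, group sizes 3 (16 trials),
4 (16), 5 (11) and 6 (14), at least one fish initially on each side, and
event times quantized to the frame grid after simulation (the recording
pipeline sees frames, not continuous time).  Body lengths are drawn from a
truncated normal; an optional leadership effect makes longer fish more
likely to be the one that crosses, without changing the side-level
dynamics the likelihood sees.

The generating decision model defaults to the asocial null (M0); analyses
that need social structure pass the model of interest explicitly, e.g.
``generate_dataset(default_design(model="D1", params={"alpha": 4.0}))``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .eventlog import CrossingEvent, Dataset, FishRecord, Trial
from .models import validate_params
from .simulate import SimulationDesign, simulate_trial

__all__ = ["SynthConfig", "GroundTruth", "default_design", "generate_dataset"]

#: the study's trial counts per group size
DESIGN_TRIALS = {3: 16, 4: 16, 5: 11, 6: 14}


@dataclass(frozen=True)
class SynthConfig:
    """Ground-truth configuration of a synthetic experiment."""

    model: str = "M0"
    params: Mapping[str, float] = field(default_factory=dict)
    trials_per_group: Mapping[int, int] = field(
        default_factory=lambda: dict(DESIGN_TRIALS)
    )
    duration_s: float = 600.0
    fps: float = 15.0
    base_rate: float = 0.08
    length_mean_mm: float = 35.0
    length_sd_mm: float = 5.0
    leadership_effect: float = 0.0  # per-mm multiplier on the crossing fish's pick
    environment_mode: str = "symmetric"
    memory_window_s: float = 3.5
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "params", dict(self.params))
        object.__setattr__(self, "trials_per_group", dict(self.trials_per_group))
        validate_params(self.model, self.params)
        if any(n < 0 for n in self.trials_per_group.values()):
            raise ValueError("trial counts must be non-negative")
        if any(g < 2 for g in self.trials_per_group):
            raise ValueError("group sizes must be at least 2")
        if self.length_sd_mm < 0:
            raise ValueError("length_sd_mm must be non-negative")

    @property
    def n_trials(self) -> int:
        return sum(self.trials_per_group.values())


def default_design(**overrides) -> SynthConfig:
    """The study-mirroring defaults: 57 trials, 10 min at 15 fps."""
    return SynthConfig(**overrides)


@dataclass(frozen=True)
class GroundTruth:
    """Everything needed to regenerate a synthetic dataset bit-for-bit."""

    model: str
    params: dict[str, float]
    master_seed: int
    trial_seeds: dict[str, int]
    config: dict

    def to_json(self, **kwargs) -> str:
        return json.dumps(dataclasses.asdict(self), **kwargs)


def _draw_lengths(rng: np.random.Generator, n: int, mean: float, sd: float) -> np.ndarray:
    if sd == 0:
        return np.full(n, mean)
    lengths = rng.normal(mean, sd, size=n)
    while np.any(lengths <= 0):
        bad = lengths <= 0
        lengths[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return lengths


def generate_dataset(config: SynthConfig) -> tuple[Dataset, GroundTruth]:
    """Simulate a full synthetic experiment.

    Per trial: body lengths from a positive-truncated normal, an initial
    left-side count uniform over 1..G-1, event-driven simulation from the
    configured decision model, and frame quantization of event times
    (``round(t * fps) / fps``) applied afterwards.  A positive
    ``leadership_effect`` multiplies each fish's chance of being the one
    that crosses by ``1 + effect * (length - mean)``.
    """
    trials: list[Trial] = []
    trial_seeds: dict[str, int] = {}
    i = 0
    for g in sorted(config.trials_per_group):
        for j in range(config.trials_per_group[g]):
            trial_id = f"synth-g{g}-t{j + 1:02d}"
            seed = (config.seed + i) % 2**31
            trial_seeds[trial_id] = seed
            rng = np.random.default_rng(seed)
            lengths = _draw_lengths(
                rng, g, config.length_mean_mm, config.length_sd_mm
            )
            multipliers = np.maximum(
                0.05, 1.0 + config.leadership_effect * (lengths - config.length_mean_mm)
            )
            initial_left = int(rng.integers(1, g))
            design = SimulationDesign(
                group_size=g,
                initial_left=initial_left,
                model=config.model,
                params=config.params,
                duration_s=config.duration_s,
                base_rate=config.base_rate,
                seed=seed,
                trial_id=trial_id,
                environment_mode=config.environment_mode,
                memory_window_s=config.memory_window_s,
                fish_rate_multipliers=tuple(multipliers),
            )
            sim = simulate_trial(design, rng=rng)
            events = tuple(
                CrossingEvent(
                    ev.trial_id,
                    round(ev.time_s * config.fps) / config.fps,
                    ev.fish_id,
                    ev.direction,
                )
                for ev in sim.events
            )
            roster = tuple(
                FishRecord(f.fish_id, float(length))
                for f, length in zip(sim.roster, lengths)
            )
            meta = dataclasses.replace(sim.metadata, fps=config.fps)
            trials.append(Trial(meta, events, roster))
            i += 1
    dataset = Dataset(tuple(trials))
    cfg_dict = dataclasses.asdict(config)
    cfg_dict["trials_per_group"] = {
        str(k): v for k, v in config.trials_per_group.items()
    }
    truth = GroundTruth(
        model=config.model,
        params=dict(config.params),
        master_seed=config.seed,
        trial_seeds=trial_seeds,
        config=cfg_dict,
    )
    return dataset, truth
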