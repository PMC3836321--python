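import numpy as np
import pytest

import patchhop as ph
from patchhop.eventlog import CrossingEvent, Dataset, Trial, TrialMetadata
from patchhop.simulate import SimulationDesign, simulate_experiment


@pytest.fixture
def hand_trial() -> Trial:
    """3 fish, 2 initially left, one crossing each way."""
    meta = TrialMetadata("t1", 3, frozenset({"f1", "f2"}), duration_s=10.0)
    events = (
        CrossingEvent("t1", 4.0, "f1", "L2R"),
        CrossingEvent("t1", 5.0, "f3", "R2L"),
    )
    roster = tuple(ph.FishRecord(f) for f in ("f1", "f2", "f3"))
    return Trial(meta, events, roster)


def _design_mix(model: str, params: dict, duration: float, seed: int):
    designs = []
    for i, g in enumerate((3, 4, 5, 6)):
        designs.append(
            SimulationDesign(
                group_size=g,
                initial_left=1 + i % (g - 1),
                model=model,
                params=params,
                duration_s=duration,
                seed=seed + i,
                trial_id=f"{model.lower()}-g{g}",
            )
        )
    return designs


@pytest.fixture(scope="session")
def d1_dataset() -> Dataset:
    """A moderate follow-the-last-mover dataset (alpha=4), 4 trials."""
    return simulate_experiment(_design_mix("D1", {"alpha": 4.0}, 300.0, 11))


@pytest.fixture(scope="session")
def m0_dataset() -> Dataset:
    """A moderate null-model dataset, 4 trials."""
    return simulate_experiment(_design_mix("M0", {}, 300.0, 7))


def random_valid_trial(seed: int, max_events: int = 40) -> Trial:
    """A random but replay-consistent trial built by moving random fish."""
    rng = np.random.default_rng(seed)
    g = int(rng.integers(2, 7))
    n_left = int(rng.integers(1, g))
    fish = [f"f{i}" for i in range(g)]
    sides = {f: ("L" if i < n_left else "R") for i, f in enumerate(fish)}
    t = 0.0
    events = []
    for _ in range(int(rng.integers(0, max_events))):
        t += float(rng.exponential(2.0))
        fid = fish[int(rng.integers(g))]
        direction = "L2R" if sides[fid] == "L" else "R2L"
        sides[fid] = "R" if sides[fid] == "L" else "L"
        events.append(CrossingEvent("rt", round(t, 3), fid, direction))
    meta = TrialMetadata(
        "rt", g, frozenset(fish[:n_left]), duration_s=max(t + 1.0, 10.0)
    )
    roster = tuple(ph.FishRecord(f, 30.0 + i) for i, f in enumerate(fish))
    return Trial(meta, tuple(events), roster)
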