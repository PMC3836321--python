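"""Candidate decision rules for which side crosses next.

Each model assigns every fish a non-negative crossing propensity (weight)
given the current state of the arena; the probability that the next
crossing originates from the left is the total left-side weight over the
total weight.  *Static* models respond to the current split of fish
between the sides, *dynamic* models to the direction of recent crossings.

For a fish on side ``s`` let ``delta = n_opposite - (n_same - 1)``: the
number of conspecifics it sees on the other side minus those beside it
(the focal fish is excluded from its own side by default; set
``include_focal=True`` to compare raw side counts instead).

========  ==========================================================
model     per-fish weight
========  ==========================================================
M0        1 (asocial null)
S1        gamma if delta > 0, 1 if delta == 0, 1/gamma if delta < 0
S2        max(w_floor, 1 + beta * delta)
S3        g ** delta  (geometric stand-in family)
S4        1 / (1 + a * s ** -delta)  (probabilistic quorum rule)
D1        alpha if the last move originated from s, else 1
D2        alpha ** m, m = net recent moves (window tau) matching a
          cross from s
C1        S1 weight times D1 weight (combined static + dynamic)
========  ==========================================================

In the asymmetric (refuge/open-water) configuration every refuge-side
(left) weight is additionally multiplied by a side-bias factor ``b``.

All weights are evaluated in log2 space internally so that extreme
parameters (large ``alpha``, long same-direction runs for D2) stay finite.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .eventlog import (
    LEFT,
    RIGHT,
    Dataset,
    DecisionPoint,
    Trial,
    build_decision_points,
    origin_side,
)

__all__ = [
    "ModelSpec",
    "DecisionState",
    "PARAM_BOUNDS",
    "W_FLOOR",
    "list_models",
    "get_model",
    "validate_params",
    "per_fish_weight",
    "side_probability",
    "log_likelihood",
    "sufficient_stats",
]

#: positivity floor for the linear (S2) response, keeping likelihoods finite
W_FLOOR = 1e-9

#: default parameter support, shared with the evidence integrals
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "gamma": (2.0**-6, 2.0**6),
    "beta": (-5.0, 5.0),
    "g": (2.0**-6, 2.0**6),
    "a": (2.0**-6, 2.0**6),
    "s": (1.0 + 2.0**-6, 2.0**6),
    "alpha": (2.0**-6, 2.0**6),
    "b": (2.0**-6, 2.0**6),
}

_MULTIPLICATIVE = frozenset({"gamma", "g", "a", "s", "alpha", "b"})


@dataclass(frozen=True)
class ModelSpec:
    """Name, free parameters and class of one candidate model."""

    name: str
    param_names: tuple[str, ...]
    model_class: str  # null | static | dynamic | combined
    core: bool
    description: str

    @property
    def n_params(self) -> int:
        return len(self.param_names)


_REGISTRY: dict[str, ModelSpec] = {
    "M0": ModelSpec("M0", (), "null", True,
                    "asocial null: all fish equally likely to cross"),
    "S1": ModelSpec("S1", ("gamma",), "static", True,
                    "binary response: attraction to the larger group"),
    "S2": ModelSpec("S2", ("beta",), "static", True,
                    "linear response to the difference in side counts"),
    "S3": ModelSpec("S3", ("g",), "static", True,
                    "geometric response to the difference in side counts "
                    "(stand-in family)"),
    "S4": ModelSpec("S4", ("a", "s"), "static", True,
                    "probabilistic quorum rule (logistic in the count difference)"),
    "D1": ModelSpec("D1", ("alpha",), "dynamic", True,
                    "follow the last mover"),
    "D2": ModelSpec("D2", ("alpha",), "dynamic", True,
                    "respond to the net direction of recent movers "
                    "within the memory window"),
    "C1": ModelSpec("C1", ("gamma", "alpha"), "combined", False,
                    "binary static response combined with follow-the-last-mover"),
}


def list_models(include_extensions: bool = False) -> tuple[ModelSpec, ...]:
    """The registered models; the seven core ones by default."""
    return tuple(
        spec for spec in _REGISTRY.values() if spec.core or include_extensions
    )


def get_model(name: str) -> ModelSpec:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; known: {sorted(_REGISTRY)}"
        ) from None


def validate_params(
    model: str,
    params: Mapping[str, float],
    check_bounds: bool = False,
) -> None:
    """Check that ``params`` are admissible for ``model``.

    Domain validity (positivity of multiplicative factors, ``s > 1``) is
    always enforced; ``check_bounds=True`` additionally requires the
    default prior support used by the evidence integrals.
    """
    spec = get_model(model)
    missing = [p for p in spec.param_names if p not in params]
    if missing:
        raise ValueError(f"model {model}: missing parameter(s) {missing}")
    for name, value in params.items():
        if name not in PARAM_BOUNDS:
            raise ValueError(f"unknown parameter {name!r}")
        if name in _MULTIPLICATIVE and not value > 0:
            raise ValueError(f"parameter {name} must be positive, got {value}")
        if name == "s" and not value > 1:
            raise ValueError(f"parameter s must exceed 1, got {value}")
        if check_bounds:
            lo, hi = PARAM_BOUNDS[name]
            if not lo <= value <= hi:
                raise ValueError(
                    f"parameter {name}={value} outside bounds [{lo}, {hi}]"
                )


@dataclass(frozen=True)
class DecisionState:
    """Minimal arena state for weight evaluation (simulator-side twin of
    :class:`~patchhop.eventlog.DecisionPoint`)."""

    n_left: int
    n_right: int
    last_direction: str | None = None
    recent_moves: tuple[tuple[str, float], ...] = ()


def _log2p(params: Mapping[str, float | np.ndarray], name: str) -> np.ndarray:
    return np.log2(np.asarray(params[name], dtype=float))


def _log2_weight(
    model: str,
    params: Mapping[str, float | np.ndarray],
    delta: np.ndarray,
    follow: np.ndarray,
    m: np.ndarray,
) -> np.ndarray:
    """log2 of the per-fish weight; inputs broadcast against each other."""
    if model == "M0":
        return np.zeros(np.broadcast_shapes(np.shape(delta), np.shape(follow)))
    if model == "S1":
        return np.sign(delta) * _log2p(params, "gamma")
    if model == "S2":
        beta = np.asarray(params["beta"], dtype=float)
        return np.log2(np.maximum(W_FLOOR, 1.0 + beta * delta))
    if model == "S3":
        return np.asarray(delta, dtype=float) * _log2p(params, "g")
    if model == "S4":
        return -np.logaddexp2(
            0.0, _log2p(params, "a") - np.asarray(delta, dtype=float) * _log2p(params, "s")
        )
    if model == "D1":
        return np.asarray(follow, dtype=float) * _log2p(params, "alpha")
    if model == "D2":
        return np.asarray(m, dtype=float) * _log2p(params, "alpha")
    if model == "C1":
        return np.sign(delta) * _log2p(params, "gamma") + np.asarray(
            follow, dtype=float
        ) * _log2p(params, "alpha")
    raise KeyError(f"unknown model {model!r}")


def _state_features(
    state: DecisionPoint | DecisionState,
    side: str,
    memory_window_s: float,
    include_focal: bool,
) -> tuple[int, float, int]:
    """(delta, follow, m) seen by a fish on ``side``."""
    n_same = state.n_left if side == LEFT else state.n_right
    n_opp = state.n_right if side == LEFT else state.n_left
    delta = n_opp - n_same if include_focal else n_opp - (n_same - 1)
    last = getattr(state, "last_direction", None)
    follow = 1.0 if (last is not None and origin_side(last) == side) else 0.0
    m = 0
    for direction, age in getattr(state, "recent_moves", ()):
        if age <= memory_window_s:
            m += 1 if origin_side(direction) == side else -1
    return delta, follow, m


def per_fish_weight(
    model: str,
    params: Mapping[str, float],
    side: str,
    state: DecisionPoint | DecisionState,
    *,
    include_focal: bool = False,
    memory_window_s: float = 3.5,
    environment_mode: str = "symmetric",
) -> float:
    """Crossing propensity of one fish on ``side`` in the given state."""
    validate_params(model, params)
    if side not in (LEFT, RIGHT):
        raise ValueError(f"side must be 'L' or 'R', got {side!r}")
    delta, follow, m = _state_features(state, side, memory_window_s, include_focal)
    lw = float(_log2_weight(model, params, delta, follow, m))
    if environment_mode == "asymmetric" and side == LEFT:
        lw += math.log2(float(params.get("b", 1.0)))
    return 2.0**lw


def side_probability(
    model: str,
    params: Mapping[str, float],
    state: DecisionPoint | DecisionState,
    *,
    include_focal: bool = False,
    memory_window_s: float = 3.5,
    environment_mode: str = "symmetric",
) -> float:
    """Probability that the next crossing originates from the left side."""
    validate_params(model, params)
    nl, nr = state.n_left, state.n_right
    if nl + nr < 1:
        raise ValueError("at least one fish required")
    if nl == 0:
        return 0.0
    if nr == 0:
        return 1.0
    dl, fl, ml = _state_features(state, LEFT, memory_window_s, include_focal)
    dr, fr, mr = _state_features(state, RIGHT, memory_window_s, include_focal)
    lw_l = float(_log2_weight(model, params, dl, fl, ml))
    lw_r = float(_log2_weight(model, params, dr, fr, mr))
    if environment_mode == "asymmetric":
        lw_l += math.log2(float(params.get("b", 1.0)))
    # P(L) = 2^x_L / (2^x_L + 2^x_R) with x = log2(n) + log2(w)
    r = (math.log2(nr) + lw_r) - (math.log2(nl) + lw_l)
    return float(2.0 ** (-np.logaddexp2(0.0, r)))


def _iter_decision_points(
    data: Dataset | Trial | Iterable[DecisionPoint],
    memory_window_s: float,
) -> Iterable[DecisionPoint]:
    if isinstance(data, Dataset):
        for trial in data:
            yield from build_decision_points(trial, memory_window_s)
    elif isinstance(data, Trial):
        yield from build_decision_points(data, memory_window_s)
    else:
        yield from data


def sufficient_stats(
    data: Dataset | Trial | Iterable[DecisionPoint],
    memory_window_s: float = 3.5,
) -> pd.DataFrame:
    """Compress the informative decision points of ``data``.

    The likelihood of every registered model depends on a decision point
    only through ``(n_left, n_right, origin side of the last move, net
    recent movement m, outcome side)``, so points sharing those values are
    pooled into counts.  This makes dense parameter grids cheap: the cost
    of a likelihood surface scales with the number of distinct states, not
    the number of events.
    """
    counter: Counter[tuple[int, int, str, int, str]] = Counter()
    for dp in _iter_decision_points(data, memory_window_s):
        if not dp.informative:
            continue
        last = "N" if dp.last_direction is None else origin_side(dp.last_direction)
        m = 0
        for direction, age in dp.recent_moves:
            if age <= memory_window_s:
                m += 1 if origin_side(direction) == LEFT else -1
        counter[(dp.n_left, dp.n_right, last, m, dp.outcome_side)] += 1
    rows = [
        (nl, nr, last, m, outcome, count)
        for (nl, nr, last, m, outcome), count in sorted(counter.items())
    ]
    return pd.DataFrame(
        rows, columns=["n_left", "n_right", "last", "m", "outcome", "count"]
    )


# columns of the sufficient-statistics table each model's weight reads;
# rows identical in these are pooled before evaluating a parameter grid
_RELEVANT_COLS: dict[str, tuple[str, ...]] = {
    "M0": ("n_left", "n_right", "outcome"),
    "S1": ("n_left", "n_right", "outcome"),
    "S2": ("n_left", "n_right", "outcome"),
    "S3": ("n_left", "n_right", "outcome"),
    "S4": ("n_left", "n_right", "outcome"),
    "D1": ("n_left", "n_right", "last", "outcome"),
    "D2": ("n_left", "n_right", "m", "outcome"),
    "C1": ("n_left", "n_right", "last", "outcome"),
}


def _aggregate_stats(model: str, stats: pd.DataFrame) -> pd.DataFrame:
    cols = list(_RELEVANT_COLS[model])
    agg = stats.groupby(cols, as_index=False)["count"].sum()
    for col in ("last", "m"):
        if col not in agg.columns:
            agg[col] = "N" if col == "last" else 0
    return agg


def _loglik2_from_stats(
    model: str,
    params: Mapping[str, float | np.ndarray],
    stats: pd.DataFrame,
    *,
    include_focal: bool = False,
    environment_mode: str = "symmetric",
) -> np.ndarray:
    """log2-likelihood for a batch of parameter points.

    ``params`` values may be scalars or 1-D arrays of a common length P;
    returns shape ``(P,)`` (``(1,)`` for all-scalar input).

    Model-specific state pooling is applied only for parameter batches
    (grids): single-point evaluations keep the shared state table so that
    parameter choices reducing a model to the null reproduce the null's
    log-likelihood bit for bit.
    """
    batch = max((np.size(v) for v in params.values()), default=1)
    if not stats.empty and batch > 1:
        stats = _aggregate_stats(model, stats)
    if stats.empty:
        p = max(
            [np.size(v) for v in params.values()] or [1]
        )
        return np.zeros(p)
    nl = stats["n_left"].to_numpy(dtype=float)[None, :]
    nr = stats["n_right"].to_numpy(dtype=float)[None, :]
    last = stats["last"].to_numpy()
    m = stats["m"].to_numpy(dtype=float)[None, :]
    counts = stats["count"].to_numpy(dtype=float)
    out_left = (stats["outcome"].to_numpy() == LEFT)

    if include_focal:
        delta_l, delta_r = nr - nl, nl - nr
    else:
        delta_l, delta_r = nr - (nl - 1.0), nl - (nr - 1.0)
    follow_l = (last == LEFT).astype(float)[None, :]
    follow_r = (last == RIGHT).astype(float)[None, :]

    p2 = {k: np.asarray(v, dtype=float).reshape(-1, 1) for k, v in params.items()}
    lw_l = _log2_weight(model, p2, delta_l, follow_l, m)
    lw_r = _log2_weight(model, p2, delta_r, follow_r, -m)
    if environment_mode == "asymmetric":
        b = p2.get("b", np.ones((1, 1)))
        lw_l = lw_l + np.log2(b)
    x_l = np.log2(nl) + lw_l
    x_r = np.log2(nr) + lw_r
    r = x_r - x_l
    lp_l = -np.logaddexp2(0.0, r)
    lp_r = -np.logaddexp2(0.0, -r)
    lp = np.where(out_left[None, :], lp_l, lp_r)
    return lp @ counts


def log_likelihood(
    model: str,
    params: Mapping[str, float],
    data: Dataset | Trial | Iterable[DecisionPoint],
    base: float = 2.0,
    *,
    include_focal: bool = False,
    memory_window_s: float = 3.5,
    environment_mode: str = "symmetric",
) -> float:
    """Sequence log-likelihood of the observed outcome sides.

    Sums ``log P(outcome side)`` over informative decision points;
    non-informative points (one side empty) contribute zero.  Reported in
    log base 2 by default, matching the evidence scale.
    """
    validate_params(model, params)
    stats = sufficient_stats(data, memory_window_s)
    ll2 = float(
        _loglik2_from_stats(
            model,
            params,
            stats,
            include_focal=include_focal,
            environment_mode=environment_mode,
        )[0]
    )
    if base == 2.0:
        return ll2
    return ll2 * math.log(2.0) / math.log(base)
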