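"""Large-scale descriptive statistics and leadership analyses.

Covers the occupancy distribution (share of trial time with k fish on the
left), crossing groups (maximal runs of same-direction crossings, with the
crossing pool available when the run started), the group-size-given-pool
frequency matrix, the same-direction probability as a function of the
interval between successive crossings, the exact one-sided sign test for
coral association, per-fish leadership scores, and a dominance-hierarchy
test (Kendall's linearity from circular triads, Monte Carlo calibrated,
combined across trials with Fisher's omnibus statistic).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .eventlog import (
    L2R,
    LEFT,
    R2L,
    RIGHT,
    Dataset,
    Trial,
    origin_side,
)

__all__ = [
    "CrossingGroup",
    "OccupancyDistribution",
    "DirectionIntervalResult",
    "LeadershipSummary",
    "LinearityTest",
    "HierarchyResult",
    "occupancy_distribution",
    "crossing_groups",
    "pool_group_matrix",
    "direction_interval_analysis",
    "coral_association_test",
    "leadership_scores",
    "follow_matrix",
    "kendall_linearity",
    "circular_triads_score_form",
    "linearity_mc_test",
    "fisher_omnibus",
    "hierarchy_test",
]


@dataclass(frozen=True)
class CrossingGroup:
    """A maximal run of same-direction crossings and its crossing pool."""

    trial_id: str
    direction: str
    members: tuple[str, ...]
    pool: int
    start_s: float
    end_s: float

    @property
    def size(self) -> int:
        return len(self.members)

    def __post_init__(self) -> None:
        if not 1 <= self.size <= self.pool:
            raise ValueError(
                f"group size {self.size} exceeds pool {self.pool} "
                f"(trial {self.trial_id})"
            )


@dataclass(frozen=True)
class OccupancyDistribution:
    """Time-weighted distribution of the number of fish on the left."""

    trial_id: str
    proportions: np.ndarray  # index k = 0..G

    @property
    def group_size(self) -> int:
        return len(self.proportions) - 1


def occupancy_distribution(trial: Trial) -> OccupancyDistribution:
    """Share of trial time spent with each possible left-side count."""
    duration = trial.metadata.duration_s
    if duration <= 0:
        raise ValueError("occupancy needs a positive trial duration")
    g = trial.group_size
    time_at = np.zeros(g + 1)
    t_prev = 0.0
    n_left = trial.n_left_initial
    for ev in trial.events:
        t = min(ev.time_s, duration)
        if t > t_prev:
            time_at[n_left] += t - t_prev
            t_prev = t
        n_left += 1 if ev.direction == R2L else -1
    if duration > t_prev:
        time_at[n_left] += duration - t_prev
    return OccupancyDistribution(trial.trial_id, time_at / duration)


def crossing_groups(trial: Trial) -> list[CrossingGroup]:
    """Maximal same-direction runs; a direction change closes a group.

    The crossing pool is the occupancy of the origin side immediately
    before the group's first event.  No maximum time gap applies: fish
    crossing any time apart in the same direction share a group.
    """
    groups: list[CrossingGroup] = []
    cur_dir: str | None = None
    members: list[str] = []
    pool = 0
    start = end = 0.0
    n_left = trial.n_left_initial
    g = trial.group_size
    for ev in trial.events:
        origin_occ = n_left if origin_side(ev.direction) == LEFT else g - n_left
        if ev.direction != cur_dir:
            if cur_dir is not None:
                groups.append(
                    CrossingGroup(trial.trial_id, cur_dir, tuple(members), pool,
                                  start, end)
                )
            cur_dir = ev.direction
            members = []
            pool = origin_occ
            start = ev.time_s
        members.append(ev.fish_id)
        end = ev.time_s
        n_left += 1 if ev.direction == R2L else -1
    if cur_dir is not None:
        groups.append(
            CrossingGroup(trial.trial_id, cur_dir, tuple(members), pool, start, end)
        )
    return groups


def pool_group_matrix(data: Dataset | Trial) -> pd.DataFrame:
    """Frequency table P(group size n | pool m).

    Rows are observed pool sizes, columns group sizes 1..max pool; each
    row is normalized to sum to one.
    """
    trials = data.trials if isinstance(data, Dataset) else (data,)
    groups = [grp for t in trials for grp in crossing_groups(t)]
    if not groups:
        raise ValueError("no crossing groups in the data")
    max_pool = max(grp.pool for grp in groups)
    pools = sorted({grp.pool for grp in groups})
    counts = pd.DataFrame(
        0.0, index=pd.Index(pools, name="pool"),
        columns=pd.Index(range(1, max_pool + 1), name="group_size"),
    )
    for grp in groups:
        counts.loc[grp.pool, grp.size] += 1
    return counts.div(counts.sum(axis=1), axis=0)


@dataclass(frozen=True)
class DirectionIntervalResult:
    """Same-direction probability by inter-crossing interval."""

    table: pd.DataFrame  # columns: interval, n_pairs, p_same
    overall_p_same: float
    n_pairs: int

    @property
    def overall_p_opposite(self) -> float:
        return 1.0 - self.overall_p_same


def direction_interval_analysis(
    data: Dataset | Trial,
    threshold_s: float = 3.5,
    bin_edges: Sequence[float] | None = None,
) -> DirectionIntervalResult:
    """Classify consecutive crossing pairs as same/opposite direction.

    Pairs never span trials.  Intervals are binned with right-closed bins;
    the default bins split at ``threshold_s`` so the table contrasts quick
    successions (<= threshold) with delayed ones (> threshold).
    """
    if bin_edges is None:
        bin_edges = (0.0, threshold_s, np.inf)
    trials = data.trials if isinstance(data, Dataset) else (data,)
    dts: list[float] = []
    same: list[bool] = []
    for t in trials:
        for prev, cur in itertools.pairwise(t.events):
            dts.append(cur.time_s - prev.time_s)
            same.append(cur.direction == prev.direction)
    if not dts:
        table = pd.DataFrame(columns=["interval", "n_pairs", "p_same"])
        return DirectionIntervalResult(table, float("nan"), 0)
    frame = pd.DataFrame({"dt": dts, "same": same})
    frame["interval"] = pd.cut(
        frame["dt"], bins=list(bin_edges), include_lowest=True, right=True
    )
    grouped = frame.groupby("interval", observed=False)["same"]
    table = pd.DataFrame(
        {
            "interval": grouped.size().index.astype(str),
            "n_pairs": grouped.size().to_numpy(),
            "p_same": grouped.mean().to_numpy(),
        }
    )
    return DirectionIntervalResult(
        table, float(frame["same"].mean()), len(frame)
    )


def coral_association_test(n_trials: int, n_success: int) -> float:
    """Exact one-sided sign test against chance one half.

    Probability that at least ``n_success`` of ``n_trials`` trials show
    more fish on than off the coral under a fair-coin null.
    """
    if n_trials < 0 or n_success < 0 or n_success > n_trials:
        raise ValueError(
            f"need 0 <= n_success <= n_trials, got {n_success}/{n_trials}"
        )
    return float(
        sps.binomtest(n_success, n_trials, 0.5, alternative="greater").pvalue
    )


@dataclass(frozen=True)
class LeadershipSummary:
    """Per-fish solo/initiation/follow counts and pooled correlations."""

    per_fish: pd.DataFrame
    solo_initiation_r: float
    solo_initiation_p: float
    length_initiation_r: float
    length_initiation_p: float
    flags: tuple[str, ...] = ()


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float, str | None]:
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 3:
        return float("nan"), float("nan"), "undefined: fewer than 3 observations"
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan"), "undefined: zero variance"
    r, p = sps.pearsonr(x, y)  # two-sided p via the t transform, n-2 df
    return float(r), float(p), None


def leadership_scores(data: Dataset | Trial) -> LeadershipSummary:
    """Solo-crossing, initiation and follow counts per fish.

    A solo crossing is a crossing group of size one; the initiator of a
    larger group is its first mover, the rest are followers.  Pearson
    correlations (solo vs initiations, body length vs initiations) pool
    fish across trials; fish without a recorded length are skipped by the
    length correlation.
    """
    trials = data.trials if isinstance(data, Dataset) else (data,)
    rows: dict[tuple[str, str], dict] = {}
    for t in trials:
        lengths = {f.fish_id: f.length_mm for f in t.roster}
        fish_ids = set(lengths)
        for grp in crossing_groups(t):
            fish_ids.update(grp.members)
        for fid in fish_ids:
            rows[(t.trial_id, fid)] = {
                "trial_id": t.trial_id,
                "fish_id": fid,
                "solo": 0,
                "initiations": 0,
                "follows": 0,
                "length_mm": lengths.get(fid, np.nan),
            }
        for grp in crossing_groups(t):
            if grp.size == 1:
                rows[(t.trial_id, grp.members[0])]["solo"] += 1
            else:
                rows[(t.trial_id, grp.members[0])]["initiations"] += 1
                for fid in grp.members[1:]:
                    rows[(t.trial_id, fid)]["follows"] += 1
    per_fish = pd.DataFrame(rows.values()).reset_index(drop=True)
    flags = []
    if per_fish.empty:
        return LeadershipSummary(per_fish, *(float("nan"),) * 4,
                                 ("undefined: no fish",))
    solo = per_fish["solo"].to_numpy(dtype=float)
    init = per_fish["initiations"].to_numpy(dtype=float)
    length = per_fish["length_mm"].to_numpy(dtype=float)
    r1, p1, f1 = _pearson(solo, init)
    r2, p2, f2 = _pearson(length, init)
    if f1:
        flags.append(f"solo~initiations {f1}")
    if f2:
        flags.append(f"length~initiations {f2}")
    return LeadershipSummary(per_fish, r1, p1, r2, p2, tuple(flags))


# --------------------------------------------------------------------------
# dominance hierarchy: Kendall's linearity from circular triads
# --------------------------------------------------------------------------


def follow_matrix(trial: Trial) -> tuple[list[str], np.ndarray]:
    """F[i, j] = number of times fish j crossed immediately after fish i
    within a crossing group."""
    fish = sorted({f.fish_id for f in trial.roster})
    if not fish:
        fish = sorted({ev.fish_id for ev in trial.events})
    index = {fid: i for i, fid in enumerate(fish)}
    f_mat = np.zeros((len(fish), len(fish)), dtype=int)
    for grp in crossing_groups(trial):
        for a, b in itertools.pairwise(grp.members):
            f_mat[index[a], index[b]] += 1
    return fish, f_mat


def _triad_dyads(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Dyad index pairs and, per triad, the indices of its three dyads
    ordered (i,j), (j,k), (i,k) for i<j<k."""
    dyads = list(itertools.combinations(range(n), 2))
    dyad_index = {d: i for i, d in enumerate(dyads)}
    triads = [
        (dyad_index[(i, j)], dyad_index[(j, k)], dyad_index[(i, k)])
        for i, j, k in itertools.combinations(range(n), 3)
    ]
    return np.array(dyads, dtype=int), np.array(triads, dtype=int)


def _max_triads(n: int) -> float:
    # maximum possible number of circular triads in a complete tournament
    return (n**3 - n) / 24.0 if n % 2 else (n**3 - 4 * n) / 24.0


def _linearity_from_dyads(
    wins_ij: np.ndarray, totals: np.ndarray, triads: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized circular-triad count for batches of dyad outcomes.

    ``wins_ij`` has shape (batch, n_dyads): events won by the
    lower-indexed fish of each dyad.  Returns (K, d, decided_triads); K is
    NaN where no triad is decided.  Tied dyads (including 0-0) are
    excluded and the maximum triad count is scaled by the decided share.
    """
    direction = wins_ij * 2 > totals  # lower-indexed fish dominates
    decided = wins_ij * 2 != totals
    d_ij = direction[:, triads[:, 0]]
    d_jk = direction[:, triads[:, 1]]
    d_ik = direction[:, triads[:, 2]]
    triad_decided = (
        decided[:, triads[:, 0]] & decided[:, triads[:, 1]] & decided[:, triads[:, 2]]
    )
    circular = (d_ij == d_jk) & (d_ik != d_ij)
    d = (circular & triad_decided).sum(axis=1).astype(float)
    n_dec = triad_decided.sum(axis=1).astype(float)
    n_triads = triads.shape[0]
    d_max = _max_triads(n) * n_dec / n_triads
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(d_max > 0, 1.0 - d / d_max, np.nan)
    return k, d, n_dec


def kendall_linearity(f_mat: np.ndarray) -> tuple[float, int, float]:
    """Kendall's linearity K of a follow matrix.

    Builds the binary dominance relation (i dominates j if it led j more
    often than the reverse), counts circular triads d among triads whose
    three dyads are all decided, and returns ``K = 1 - d / d_max`` with
    the usual maximum scaled by the decided-triad share.  Returns
    ``(K, d, d_max)``; K is NaN when no triad is decided.
    """
    n = f_mat.shape[0]
    if n < 3:
        raise ValueError("linearity needs at least 3 individuals")
    dyads, triads = _triad_dyads(n)
    wins = f_mat[dyads[:, 0], dyads[:, 1]][None, :].astype(float)
    totals = wins + f_mat[dyads[:, 1], dyads[:, 0]][None, :]
    k, d, _ = _linearity_from_dyads(wins, totals, triads, n)
    n_dec = np.sum(
        (wins * 2 != totals)[
            :, triads
        ].all(axis=2)
    )
    d_max = _max_triads(n) * n_dec / triads.shape[0]
    return float(k[0]), int(d[0]), float(d_max)


def circular_triads_score_form(f_mat: np.ndarray) -> int:
    """Circular triads via the score-variance identity.

    Valid only for complete tournaments (every dyad decided):
    ``d = C(n,3) - sum_i C(s_i, 2)`` with ``s_i`` the number of fish that
    fish i dominates.
    """
    n = f_mat.shape[0]
    wins = f_mat > f_mat.T
    if np.any((f_mat == f_mat.T) & ~np.eye(n, dtype=bool)):
        raise ValueError("score form requires every dyad to be decided")
    s = wins.sum(axis=1)
    return int(math.comb(n, 3) - sum(math.comb(int(si), 2) for si in s))


@dataclass(frozen=True)
class LinearityTest:
    k: float
    d: int
    p: float
    n_mc: int


def linearity_mc_test(
    f_mat: np.ndarray,
    n_mc: int = 10000,
    rng: np.random.Generator | int | None = None,
) -> LinearityTest:
    """Monte Carlo p-value for linearity of a follow matrix.

    The null redirects each dyad's observed events with a fair coin and
    recomputes K.  The p-value uses the randomized tie-broken form

        p = (#{K' > K} + U * (#{K' = K} + 1)) / (n_mc + 1),

    which is exactly uniform on (0, 1) under the null despite the discrete
    support of K, so downstream Fisher combination is exact.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = f_mat.shape[0]
    k_obs, d_obs, _ = kendall_linearity(f_mat)
    if not np.isfinite(k_obs):
        raise ValueError("observed linearity undefined (no decided triads)")
    dyads, triads = _triad_dyads(n)
    totals = (
        f_mat[dyads[:, 0], dyads[:, 1]] + f_mat[dyads[:, 1], dyads[:, 0]]
    ).astype(float)
    wins_null = rng.binomial(
        totals.astype(int)[None, :].repeat(n_mc, axis=0), 0.5
    ).astype(float)
    k_null, _, _ = _linearity_from_dyads(wins_null, totals[None, :], triads, n)
    greater = int(np.sum(k_null > k_obs + 1e-12))
    equal = int(np.sum(np.abs(k_null - k_obs) <= 1e-12))
    p = (greater + rng.uniform() * (equal + 1)) / (n_mc + 1)
    return LinearityTest(k_obs, d_obs, float(p), n_mc)


def fisher_omnibus(pvalues: Sequence[float]) -> tuple[float, int, float]:
    """Fisher's combined-probability statistic.

    Returns ``(chi2, df, p)`` with ``chi2 = -2 * sum(ln p_i)`` on
    ``2 * len(pvalues)`` degrees of freedom.
    """
    ps = np.asarray(pvalues, dtype=float)
    if len(ps) == 0 or np.any((ps <= 0) | (ps > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = float(-2.0 * np.sum(np.log(ps)))
    df = 2 * len(ps)
    return chi2, df, float(sps.chi2.sf(chi2, df))


@dataclass(frozen=True)
class HierarchyResult:
    """Per-trial linearity tests and their Fisher combination."""

    trials: pd.DataFrame  # trial_id, n_fish, d, d_max, K, p
    fisher_chi2: float
    df: int
    fisher_p: float
    excluded: tuple[tuple[str, str], ...] = ()


def hierarchy_test(
    data: Dataset | Trial, n_mc: int = 10000, seed: int | None = None
) -> HierarchyResult:
    """Test for hierarchical leader-follower relations across trials.

    Each trial with at least three fish and a defined linearity gets a
    Monte Carlo p-value for Kendall's K; the p-values are combined with
    Fisher's omnibus statistic on ``2 x (number of combined trials)``
    degrees of freedom.  Trials with fewer than three fish or with no
    decided dominance relations are excluded (and reported as such).
    """
    trials = data.trials if isinstance(data, Dataset) else (data,)
    rng = np.random.default_rng(seed)
    rows = []
    excluded: list[tuple[str, str]] = []
    for t in trials:
        fish, f_mat = follow_matrix(t)
        if len(fish) < 3:
            excluded.append((t.trial_id, "fewer than 3 fish"))
            continue
        k, d, d_max = kendall_linearity(f_mat)
        if not np.isfinite(k):
            excluded.append((t.trial_id, "no decided dominance relations"))
            continue
        test = linearity_mc_test(f_mat, n_mc=n_mc, rng=rng)
        rows.append(
            {
                "trial_id": t.trial_id,
                "n_fish": len(fish),
                "d": d,
                "d_max": d_max,
                "K": k,
                "p": test.p,
            }
        )
    frame = pd.DataFrame(rows)
    if frame.empty:
        return HierarchyResult(frame, float("nan"), 0, float("nan"),
                               tuple(excluded))
    chi2, df, p = fisher_omnibus(frame["p"].to_numpy())
    return HierarchyResult(frame, chi2, df, p, tuple(excluded))
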