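"""Wayfinding performance scoring from raw 2 Hz trajectories.

The score for a player is built in four steps:

1. path length per attempt: sum of Euclidean distances between consecutive
   sampled positions;
2. first attempts only on the test levels; a per-player tutorial baseline
   equal to the sum over the two practice levels of the mean path length
   across up to the first three attempts (controls for device/motor skill);
3. corrected distance = first-attempt path length / tutorial baseline,
   then per-level z-standardisation (sample sd, n-1) so levels with
   different spatial layouts are comparable;
4. performance score = minus the mean of a player's available standardised
   values (sign reversed so that larger = better navigation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_TEST_LEVELS",
    "DEFAULT_TUTORIAL_LEVELS",
    "trajectory_length",
    "distances_from_trajectories",
    "first_attempts",
    "tutorial_baseline",
    "corrected_distances",
    "standardize_levels",
    "performance_score",
    "score_cohort",
    "ScoringResult",
]

DEFAULT_TEST_LEVELS = (3, 6, 7, 8, 11, 12)
DEFAULT_TUTORIAL_LEVELS = (1, 2)


def trajectory_length(points) -> float:
    """Total path length of a point sequence: sum of consecutive Euclidean
    segment lengths.  ``points`` is an (n, 2) array of x, y positions in
    sampling order.  Order-dependent, and never below the straight-line
    start-to-end distance.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"points must be an (n, 2) array, got shape {pts.shape}")
    if pts.shape[0] < 2:
        raise ValueError(f"need at least 2 points, got {pts.shape[0]}")
    bad = ~np.isfinite(pts)
    if bad.any():
        row = int(np.argwhere(bad.any(axis=1))[0, 0])
        raise ValueError(f"non-finite coordinate at point index {row}: {pts[row]}")
    return float(np.hypot(np.diff(pts[:, 0]), np.diff(pts[:, 1])).sum())


_TRAJ_KEY = ["player_id", "level", "attempt"]


def distances_from_trajectories(trajectories: pd.DataFrame) -> pd.DataFrame:
    """Per-attempt path lengths from a long-format trajectory table.

    Expects columns ``player_id, level, attempt, t, x, y``; points within an
    attempt are ordered by ``t``.  Returns one row per (player, level,
    attempt) with column ``distance``.
    """
    required = set(_TRAJ_KEY + ["t", "x", "y"])
    missing = required - set(trajectories.columns)
    if missing:
        raise ValueError(f"trajectory table missing columns {sorted(missing)}")
    if len(trajectories) == 0:
        return pd.DataFrame(columns=_TRAJ_KEY + ["distance"])
    xy = trajectories[["x", "y"]].to_numpy(dtype=float)
    bad = ~np.isfinite(xy)
    if bad.any():
        row = trajectories.index[np.argwhere(bad.any(axis=1))[0, 0]]
        raise ValueError(f"non-finite coordinate in trajectory row {row}")

    df = trajectories.sort_values(_TRAJ_KEY + ["t"], kind="mergesort")
    x = df["x"].to_numpy(dtype=float)
    y = df["y"].to_numpy(dtype=float)
    seg = np.hypot(np.diff(x, prepend=x[:1]), np.diff(y, prepend=y[:1]))
    new_attempt = np.zeros(len(df), dtype=bool)
    new_attempt[0] = True
    for col in _TRAJ_KEY:
        v = df[col].to_numpy()
        new_attempt[1:] |= v[1:] != v[:-1]
    seg[new_attempt] = 0.0

    grp = new_attempt.cumsum() - 1
    dist = np.bincount(grp, weights=seg)
    counts = np.bincount(grp)
    if (counts < 2).any():
        first_bad = int(np.argwhere(counts < 2)[0, 0])
        key = df.loc[new_attempt, _TRAJ_KEY].iloc[first_bad]
        raise ValueError(
            f"attempt with fewer than 2 points: player={key.player_id} "
            f"level={key.level} attempt={key.attempt}"
        )
    out = df.loc[new_attempt, _TRAJ_KEY].copy()
    out["distance"] = dist
    return out.reset_index(drop=True)


def first_attempts(distances: pd.DataFrame, levels) -> pd.DataFrame:
    """Keep one row per (player, level): the minimum recorded attempt number.

    Analysis is limited to first attempts because players could repeat
    levels freely.  "First" means the minimum attempt present, not literally
    attempt 1, so the step is robust to upstream log loss.
    """
    levels = set(levels)
    sub = distances[distances["level"].isin(levels)]
    if len(sub) == 0:
        return sub.reset_index(drop=True)
    idx = sub.groupby(["player_id", "level"], sort=False)["attempt"].idxmin()
    return sub.loc[idx].reset_index(drop=True)


def tutorial_baseline(
    distances: pd.DataFrame,
    tutorial_levels=DEFAULT_TUTORIAL_LEVELS,
    max_attempts: int = 3,
) -> tuple[pd.Series, list]:
    """Per-player baseline: sum over tutorial levels of the mean path length
    across up to the first ``max_attempts`` attempts.

    Returns ``(baselines, flagged)`` where ``flagged`` lists players missing
    at least one tutorial level (to be excluded by the caller).  A zero
    baseline is an error: corrected distances would be undefined.
    """
    tutorial_levels = list(tutorial_levels)
    sub = distances[distances["level"].isin(tutorial_levels)].copy()
    sub = sub.sort_values(["player_id", "level", "attempt"], kind="mergesort")
    kept = sub.groupby(["player_id", "level"], sort=False).head(max_attempts)
    per_level = kept.groupby(["player_id", "level"], sort=False)["distance"].mean()
    n_levels = per_level.groupby(level="player_id").size()
    baseline = per_level.groupby(level="player_id").sum()

    flagged = sorted(n_levels.index[n_levels < len(tutorial_levels)])
    baseline = baseline.drop(index=flagged)
    zero = baseline.index[baseline <= 0.0]
    if len(zero):
        raise ValueError(f"zero tutorial baseline for players {list(zero[:5])}")
    baseline.name = "baseline"
    return baseline, flagged


def corrected_distances(
    first_attempt_distances: pd.DataFrame, baselines: pd.Series
) -> tuple[pd.DataFrame, list]:
    """Divide first-attempt distances by each player's tutorial baseline.

    Returns a players x levels wide table of dimensionless corrected
    distances plus the list of players dropped for lack of a baseline.
    """
    have = first_attempt_distances["player_id"].isin(baselines.index)
    dropped = sorted(first_attempt_distances.loc[~have, "player_id"].unique())
    sub = first_attempt_distances[have]
    wide = sub.pivot(index="player_id", columns="level", values="distance")
    wide = wide.div(baselines.reindex(wide.index), axis=0)
    return wide, dropped


@dataclass
class LevelStandardization:
    """Per-level mean/sd used for z-scoring (sample sd, ddof=1)."""

    mean: pd.Series
    sd: pd.Series


def standardize_levels(
    corrected: pd.DataFrame,
    params: LevelStandardization | None = None,
) -> tuple[pd.DataFrame, LevelStandardization]:
    """z-score each level column over its non-missing entries.

    Pass ``params`` to re-apply a previously computed standardisation (e.g.
    score a stratum on the whole-population scale).  A constant column makes
    the z-score undefined and raises.
    """
    if params is None:
        counts = corrected.count()
        if (counts < 2).any():
            bad = list(counts.index[counts < 2])
            raise ValueError(f"levels with <2 observed values: {bad}")
        mean = corrected.mean()
        sd = corrected.std(ddof=1)
        if (sd <= 0).any():
            bad = list(sd.index[sd <= 0])
            raise ValueError(f"constant level columns, cannot standardise: {bad}")
        params = LevelStandardization(mean=mean, sd=sd)
    z = corrected.sub(params.mean, axis=1).div(params.sd, axis=1)
    return z, params


def performance_score(z_matrix: pd.DataFrame) -> pd.DataFrame:
    """Sign-reversed mean of each player's available standardised distances.

    Larger = better performance (shorter relative paths).  Players keep a
    score over whichever levels they completed; ``n_levels_used`` records
    how many entered the mean.
    """
    n_used = z_matrix.count(axis=1)
    if (n_used == 0).any():
        raise ValueError("player with no standardised level values")
    score = -z_matrix.mean(axis=1)
    out = pd.DataFrame({"score": score, "n_levels_used": n_used})
    out.index.name = "player_id"
    return out.reset_index()


@dataclass
class ScoringResult:
    scores: pd.DataFrame  # player_id, score, n_levels_used
    z_matrix: pd.DataFrame  # players x levels
    standardization: LevelStandardization
    baselines: pd.Series
    missing_tutorial: list
    missing_baseline: list


def score_cohort(
    trajectories: pd.DataFrame,
    test_levels=DEFAULT_TEST_LEVELS,
    tutorial_levels=DEFAULT_TUTORIAL_LEVELS,
    max_tutorial_attempts: int = 3,
) -> ScoringResult:
    """Full scoring pipeline: path lengths -> first attempts -> baseline
    correction -> per-level z-scores -> per-player performance score."""
    dist = distances_from_trajectories(trajectories)
    firsts = first_attempts(dist, test_levels)
    baselines, flagged = tutorial_baseline(dist, tutorial_levels, max_tutorial_attempts)
    corrected, dropped = corrected_distances(firsts, baselines)
    z, params = standardize_levels(corrected)
    scores = performance_score(z)
    return ScoringResult(
        scores=scores,
        z_matrix=z,
        standardization=params,
        baselines=baselines,
        missing_tutorial=flagged,
        missing_baseline=dropped,
    )
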