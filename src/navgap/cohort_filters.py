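"""Inclusion cascade with a per-step audit trail.

Steps, applied in a fixed order:

1. complete demographics (age, binary gender, country, valid 4-level
   self-estimate label);
2. age between 19 and 70 inclusive;
3. completion of all six test levels and both tutorial levels;
4. outlier removal on the performance score (|score - mean| >= k sd, one
   pass, mean/sd from the current sample);
5. countries with at least 500 players;
6. membership in one of the 11 cultural clusters.

Every step records (n_before, n_excluded, n_after); the audit chains and
conserves counts, mirroring how large volunteer samples shrink from raw
downloads to the analysis set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cultural_atlas import ClusterMap
from .synthetic_cohort import SELF_ESTIMATE_LABELS
from . import trajectory_scoring

__all__ = [
    "FilterConfig",
    "AuditStep",
    "FilterAudit",
    "CascadeResult",
    "filter_complete_demographics",
    "filter_age",
    "filter_completed_levels",
    "remove_outliers",
    "filter_country_size",
    "filter_cluster_membership",
    "run_cascade",
]

_VALID_LABELS = {s.casefold() for s in SELF_ESTIMATE_LABELS}


@dataclass
class FilterConfig:
    age_min: int = 19
    age_max: int = 70
    required_levels: tuple[int, ...] = (3, 6, 7, 8, 11, 12)
    required_tutorials: tuple[int, ...] = (1, 2)
    outlier_sd: float = 2.0
    country_min_players: int = 500
    drop_unmapped_countries: bool = True

    def validate(self) -> None:
        if not self.age_min < self.age_max:
            raise ValueError(f"age_min {self.age_min} >= age_max {self.age_max}")
        if self.outlier_sd <= 0:
            raise ValueError(f"outlier_sd {self.outlier_sd} <= 0")
        if self.country_min_players < 1:
            raise ValueError(f"country_min_players {self.country_min_players} < 1")


@dataclass(frozen=True)
class AuditStep:
    step: str
    n_before: int
    n_excluded: int
    n_after: int

    def __post_init__(self) -> None:
        if self.n_after != self.n_before - self.n_excluded:
            raise ValueError(f"audit step {self.step}: counts do not balance")


@dataclass
class FilterAudit:
    steps: list[AuditStep] = field(default_factory=list)

    def add(self, step: AuditStep) -> None:
        if self.steps and step.n_before != self.steps[-1].n_after:
            raise ValueError(
                f"audit does not chain: {self.steps[-1].step} ended with "
                f"{self.steps[-1].n_after}, {step.step} starts with {step.n_before}"
            )
        self.steps.append(step)

    @property
    def n_initial(self) -> int:
        return self.steps[0].n_before if self.steps else 0

    @property
    def n_final(self) -> int:
        return self.steps[-1].n_after if self.steps else 0

    @property
    def total_excluded(self) -> int:
        return sum(s.n_excluded for s in self.steps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(s) for s in self.steps])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps([asdict(s) for s in self.steps], indent=1))


def _step(name: str, before: pd.DataFrame, keep: pd.Series) -> tuple[pd.DataFrame, AuditStep]:
    keep = keep.fillna(False).astype(bool)
    after = before[keep]
    return after, AuditStep(name, len(before), int((~keep).sum()), len(after))


def filter_complete_demographics(players: pd.DataFrame) -> tuple[pd.DataFrame, AuditStep]:
    """Keep players with numeric age, binary gender, a country, and one of
    the four self-estimate labels.  Gender values outside {female, male} are
    treated as missing because the downstream models use binary gender."""
    age_ok = pd.to_numeric(players["age"], errors="coerce").notna()
    gender_ok = players["gender"].astype(str).str.strip().str.casefold().isin(
        {"female", "male"}
    )
    country_ok = players["country"].notna() & (
        players["country"].astype(str).str.strip() != ""
    )
    se_ok = players["self_estimate"].astype(str).str.strip().str.casefold().isin(
        _VALID_LABELS
    )
    return _step("complete_demographics", players, age_ok & gender_ok & country_ok & se_ok)


def filter_age(players: pd.DataFrame, config: FilterConfig) -> tuple[pd.DataFrame, AuditStep]:
    """Keep players aged between age_min and age_max, both inclusive."""
    age = pd.to_numeric(players["age"], errors="coerce")
    return _step("age_range", players, (age >= config.age_min) & (age <= config.age_max))


def filter_completed_levels(
    players: pd.DataFrame, trajectories: pd.DataFrame, config: FilterConfig
) -> tuple[pd.DataFrame, AuditStep]:
    """Keep players with >= 1 recorded attempt at every required test level
    and every tutorial level."""
    required = set(config.required_levels) | set(config.required_tutorials)
    sub = trajectories.loc[
        trajectories["level"].isin(required), ["player_id", "level"]
    ].drop_duplicates()
    n_levels = sub.groupby("player_id")["level"].nunique()
    complete = set(n_levels.index[n_levels == len(required)])
    return _step("completed_levels", players, players["player_id"].isin(complete))


def remove_outliers(
    scores: pd.DataFrame, config: FilterConfig
) -> tuple[pd.DataFrame, AuditStep]:
    """Drop score outliers: |score - mean| >= outlier_sd * sd.

    Mean and sd are computed once on the input scores (single pass, no
    re-iteration).  With sd = 0 every score equals the mean and nothing is
    excluded.
    """
    if len(scores) < 2:
        raise ValueError("need >= 2 scores for outlier removal")
    s = scores["score"].to_numpy(dtype=float)
    mean, sd = s.mean(), s.std(ddof=1)
    if sd == 0:
        keep = pd.Series(True, index=scores.index)
    else:
        keep = pd.Series(np.abs(s - mean) < config.outlier_sd * sd, index=scores.index)
    return _step("score_outliers", scores, keep)


def filter_country_size(
    players: pd.DataFrame, config: FilterConfig
) -> tuple[pd.DataFrame, AuditStep]:
    """Keep players whose country has >= country_min_players players in the
    current (post-previous-steps) sample.  Evaluated once, not re-iterated."""
    sizes = players["country"].value_counts()
    big = set(sizes.index[sizes >= config.country_min_players])
    return _step("country_size", players, players["country"].isin(big))


def filter_cluster_membership(
    players: pd.DataFrame, cluster_map: ClusterMap
) -> tuple[pd.DataFrame, AuditStep]:
    """Keep players from countries mapped to one of the 11 clusters."""
    countries = players["country"].astype(str)
    mapped = {c for c in countries.unique() if cluster_map.get(c) is not None}
    return _step("cluster_membership", players, countries.isin(mapped))


@dataclass
class CascadeResult:
    players: pd.DataFrame  # analysis set with score column attached
    audit: FilterAudit
    scoring: trajectory_scoring.ScoringResult | None


def run_cascade(
    players: pd.DataFrame,
    trajectories: pd.DataFrame,
    config: FilterConfig | None = None,
    cluster_map: ClusterMap | None = None,
    scores: pd.DataFrame | None = None,
) -> CascadeResult:
    """Apply the whole inclusion cascade in order and return the analysis
    set with its audit trail.

    When ``scores`` is not given, performance scores are computed on the
    demographically complete, age-valid, level-complete population, so the
    z-standardisation parameters reflect that population (outliers are then
    removed without re-standardising).
    """
    config = config or FilterConfig()
    config.validate()
    audit = FilterAudit()

    step1, a = filter_complete_demographics(players)
    audit.add(a)
    step2, a = filter_age(step1, config)
    audit.add(a)
    step3, a = filter_completed_levels(step2, trajectories, config)
    audit.add(a)

    scoring = None
    if scores is None:
        kept_traj = trajectories[trajectories["player_id"].isin(set(step3["player_id"]))]
        scoring = trajectory_scoring.score_cohort(
            kept_traj, config.required_levels, config.required_tutorials
        )
        scores = scoring.scores
    merged = step3.merge(scores, on="player_id", how="inner", validate="one_to_one")
    if len(merged) < len(step3):
        # players that could not be scored (e.g. zero-length logs) drop here
        audit.add(AuditStep("unscoreable", len(step3), len(step3) - len(merged), len(merged)))

    step4, a = remove_outliers(merged, config)
    audit.add(a)
    step5, a = filter_country_size(step4, config)
    audit.add(a)
    if config.drop_unmapped_countries:
        if cluster_map is None:
            raise ValueError("cluster_map required when drop_unmapped_countries is set")
        step6, a = filter_cluster_membership(step5, cluster_map)
        audit.add(a)
    else:
        step6 = step5

    if len(step6) == 0:
        raise ValueError("inclusion cascade excluded every player")
    return CascadeResult(players=step6.reset_index(drop=True), audit=audit, scoring=scoring)
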