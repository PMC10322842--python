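"""Synthetic cohort generator with planted country effects.

Emulates the statistical structure the analysis pipeline assumes, so that
planted over/under-confidence is recoverable end-to-end:

* per-player navigation skill
  ``skill = a_c + beta_age_perf * (age - 19) + beta_male_perf * [male]``
  with a planted country intercept ``a_c``;
* per-attempt travelled distance on level L
  ``optimal_length(L) * (1 + detour) * device``, with
  ``detour = softplus(-skill + eps)`` on test levels and
  ``softplus(eps)`` on the two tutorial levels,
  ``eps ~ N(0, sigma_resid)`` per attempt — softplus keeps every path at
  least as long as the optimal route.  ``device = exp(N(0, sigma_device))``
  is a per-player device/motor-familiarity factor that multiplies every
  level alike; the tutorial-baseline correction exists to cancel exactly
  this kind of nuisance, so tutorials carry the device factor but not
  navigation skill;
* a 4-level ordinal self-estimate (very bad / bad / good / very good, no
  neutral option) from a latent
  ``b_c + beta_age_se * (age - 19) + beta_male_se * [male] + noise`` cut at
  three ascending thresholds (probit-style normal latent by default,
  logistic optional);
* 2 Hz trajectories realised as jittered constant-speed walks whose summed
  segment lengths equal the planted travelled distance.

The planted country-level overconfidence is ``b_c - a_c``; ``plant_world``
can couple a synthetic masculinity score to it with a chosen rank
correlation for recovery experiments.

All randomness flows from one ``numpy`` generator seeded by the config, in
a fixed stream order (ages, genders, covariates, self-estimate noise,
attempt counts, detour noise, trajectory headings), so identical
``(config, seed)`` give bit-identical output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cultural_atlas import load_cluster_map

__all__ = [
    "CountrySpec",
    "CohortConfig",
    "GroundTruth",
    "ConfigError",
    "SELF_ESTIMATE_LABELS",
    "generate_cohort",
    "generate_trajectory",
    "write_cohort",
    "read_cohort",
    "plant_world",
]

SELF_ESTIMATE_LABELS = ("very bad", "bad", "good", "very good")

#: Optimal route length per level, arbitrary planar units.  Levels 1-2 are
#: tutorials; 3, 6, 7, 8, 11, 12 are the wayfinding test levels.
DEFAULT_OPTIMAL_LENGTHS = {
    1: 50.0,
    2: 60.0,
    3: 80.0,
    6: 100.0,
    7: 120.0,
    8: 140.0,
    11: 160.0,
    12: 180.0,
}

EDUCATION_LEVELS = ("secondary", "high_school", "college", "university")
HOME_ENVIRONMENTS = ("city", "suburbs", "rural")
COMMUTE_TIMES = ("<30min", "30-60min", ">60min")


class ConfigError(ValueError):
    """Raised when a cohort configuration violates an invariant."""


@dataclass
class CountrySpec:
    """One country's planted parameters.

    ``perf_intercept`` (a_c) shifts skill, ``selfest_intercept`` (b_c)
    shifts the self-estimate latent; ``b_c - a_c`` is the planted
    overconfidence.  ``masculinity`` is a synthetic Hofstede-style score.
    """

    name: str
    n_players: int
    perf_intercept: float = 0.0
    selfest_intercept: float = 0.0
    masculinity: float = 50.0


@dataclass
class CohortConfig:
    countries: list[CountrySpec] = field(default_factory=list)
    age_range: tuple[int, int] = (19, 70)
    gender_mix: float = 0.55  # proportion male
    beta_age_perf: float = -0.02  # skill change per year of age
    beta_male_perf: float = 0.25
    beta_age_se: float = 0.01  # latent self-estimate change per year
    beta_male_se: float = 0.5
    sigma_country_perf: float = 0.5  # sd of drawn a_c (plant_world)
    sigma_country_se: float = 0.5  # sd of drawn b_c (plant_world)
    sigma_resid: float = 1.0  # per-attempt detour noise sd
    sigma_device: float = 0.2  # sd of log per-player device factor
    sigma_se_resid: float = 1.0  # self-estimate latent noise sd
    # P(very bad, bad, good, very good) ~ (3%, 12%, 60%, 25%) on a standard
    # normal latent: most players rate themselves good, as in field samples.
    ordinal_thresholds: tuple[float, float, float] = (-1.881, -1.036, 0.674)
    latent_link: str = "probit"  # or "logit"
    test_levels: tuple[int, ...] = (3, 6, 7, 8, 11, 12)
    tutorial_levels: tuple[int, ...] = (1, 2)
    optimal_lengths: dict = field(default_factory=lambda: dict(DEFAULT_OPTIMAL_LENGTHS))
    sampling_rate: float = 2.0  # Hz
    trajectory_duration: float = 5.0  # seconds per attempt
    repeat_test_prob: float = 0.1  # chance of a 2nd attempt on a test level
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if not self.countries:
            problems.append("countries list is empty")
        for c in self.countries:
            if c.n_players < 1:
                problems.append(f"{c.name}: n_players {c.n_players} < 1")
        if not self.age_range[0] < self.age_range[1]:
            problems.append(f"age_range {self.age_range} not increasing")
        if not 0.0 <= self.gender_mix <= 1.0:
            problems.append(f"gender_mix {self.gender_mix} outside [0, 1]")
        th = self.ordinal_thresholds
        if not (len(th) == 3 and th[0] < th[1] < th[2]):
            problems.append(f"ordinal_thresholds {th} not 3 strictly ascending values")
        if self.sampling_rate <= 0:
            problems.append(f"sampling_rate {self.sampling_rate} <= 0")
        for name in (
            "sigma_country_perf",
            "sigma_country_se",
            "sigma_resid",
            "sigma_device",
            "sigma_se_resid",
        ):
            if getattr(self, name) < 0:
                problems.append(f"{name} {getattr(self, name)} < 0")
        if self.latent_link not in ("probit", "logit"):
            problems.append(f"latent_link {self.latent_link!r} not 'probit' or 'logit'")
        missing = [
            lv
            for lv in (*self.tutorial_levels, *self.test_levels)
            if lv not in self.optimal_lengths
        ]
        if missing:
            problems.append(f"levels without optimal_lengths entry: {missing}")
        if self.trajectory_duration * self.sampling_rate < 1:
            problems.append("trajectory_duration * sampling_rate < 1 (need >= 2 points)")
        if problems:
            raise ConfigError("; ".join(problems))


@dataclass
class GroundTruth:
    """Planted parameters: per-country intercepts and per-player latents."""

    countries: pd.DataFrame  # index country; perf_intercept, selfest_intercept, masculinity
    players: pd.DataFrame  # index player_id; skill, latent_self_estimate

    def to_json(self, path: str | Path) -> None:
        payload = {
            "countries": self.countries.to_dict(orient="index"),
            "players": self.players.to_dict(orient="index"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        countries = pd.DataFrame.from_dict(payload["countries"], orient="index")
        countries.index.name = "country"
        players = pd.DataFrame.from_dict(payload["players"], orient="index")
        players.index.name = "player_id"
        return cls(countries=countries, players=players)


def _softplus(x: np.ndarray) -> np.ndarray:
    # overflow-safe log(1 + exp(x))
    return np.logaddexp(0.0, x)


def generate_trajectory(
    target_length: float, duration: float, rate: float, rng
) -> pd.DataFrame:
    """One jittered constant-speed trajectory of exact total path length.

    Returns a frame with columns ``t, x, y``: ``round(duration * rate)``
    equal-length segments whose Euclidean lengths sum to ``target_length``
    (up to float rounding, well within 1e-9 relative).
    """
    if target_length <= 0:
        raise ValueError(f"target_length must be > 0, got {target_length}")
    n_seg = int(round(duration * rate))
    if n_seg < 1:
        raise ValueError("duration * rate must be >= 1 (need >= 2 points)")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    t, x, y = _walks(np.asarray([target_length], dtype=float), n_seg, rate, rng)
    return pd.DataFrame({"t": t[0], "x": x[0], "y": y[0]})


def _walks(lengths: np.ndarray, n_seg: int, rate: float, rng) -> tuple:
    """Vectorised jittered walks: one row per trajectory, n_seg+1 points."""
    m = len(lengths)
    theta0 = rng.uniform(0.0, 2.0 * math.pi, size=(m, 1))
    turns = rng.normal(0.0, 0.3, size=(m, n_seg))
    theta = theta0 + np.cumsum(turns, axis=1)
    step = (lengths / n_seg)[:, None]
    x = np.concatenate([np.zeros((m, 1)), np.cumsum(step * np.cos(theta), axis=1)], axis=1)
    y = np.concatenate([np.zeros((m, 1)), np.cumsum(step * np.sin(theta), axis=1)], axis=1)
    t = np.broadcast_to(np.arange(n_seg + 1) / rate, (m, n_seg + 1))
    return t, x, y


def generate_cohort(config: CohortConfig):
    """Generate ``(players, trajectories, ground_truth)`` for a config.

    ``players``: one row per player with demographics and self-estimate
    label.  ``trajectories``: long-format 2 Hz point table covering 1-3
    attempts per tutorial level and >= 1 attempt per test level.
    Deterministic given ``(config, config.seed)``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_total = sum(c.n_players for c in config.countries)
    country = np.repeat([c.name for c in config.countries], [c.n_players for c in config.countries])
    a_c = np.repeat([c.perf_intercept for c in config.countries], [c.n_players for c in config.countries])
    b_c = np.repeat([c.selfest_intercept for c in config.countries], [c.n_players for c in config.countries])
    player_id = np.array([f"P{i:06d}" for i in range(n_total)])

    # stream order: ages, genders, covariates, self-estimate noise,
    # device factors, attempt counts, detour noise, trajectory headings
    lo, hi = config.age_range
    age = rng.integers(lo, hi + 1, size=n_total)
    male = rng.random(n_total) < config.gender_mix
    education = rng.choice(EDUCATION_LEVELS, size=n_total)
    home_env = rng.choice(HOME_ENVIRONMENTS, size=n_total)
    commute = rng.choice(COMMUTE_TIMES, size=n_total)

    if config.latent_link == "probit":
        se_noise = rng.normal(0.0, config.sigma_se_resid, size=n_total)
    else:
        se_noise = rng.logistic(0.0, config.sigma_se_resid, size=n_total)
    latent = b_c + config.beta_age_se * (age - lo) + config.beta_male_se * male + se_noise
    cat = np.searchsorted(np.asarray(config.ordinal_thresholds), latent, side="left")
    self_estimate = np.asarray(SELF_ESTIMATE_LABELS)[cat]

    skill = a_c + config.beta_age_perf * (age - lo) + config.beta_male_perf * male
    device = np.exp(rng.normal(0.0, config.sigma_device, size=n_total))

    players = pd.DataFrame(
        {
            "player_id": player_id,
            "age": age,
            "gender": np.where(male, "male", "female"),
            "country": country,
            "self_estimate": self_estimate,
            "education": education,
            "home_environment": home_env,
            "commute_time": commute,
        }
    )

    # attempt plan: tutorials 1-3 attempts each; test levels 1, sometimes 2
    n_tut = len(config.tutorial_levels)
    n_test = len(config.test_levels)
    tut_counts = rng.integers(1, 4, size=(n_total, n_tut))
    test_counts = 1 + (rng.random((n_total, n_test)) < config.repeat_test_prob)

    levels_order = list(config.tutorial_levels) + list(config.test_levels)
    counts = np.concatenate([tut_counts, test_counts], axis=1)  # players x levels
    total_attempts = int(counts.sum())

    flat_counts = counts.ravel()  # player-major, level within player
    att_player = np.repeat(np.arange(n_total), counts.sum(axis=1))
    att_level = np.repeat(np.tile(levels_order, n_total), flat_counts)
    starts = np.repeat(np.cumsum(flat_counts) - flat_counts, flat_counts)
    att_number = np.arange(total_attempts) - starts + 1

    eps = rng.normal(0.0, config.sigma_resid, size=total_attempts)
    is_test = np.isin(att_level, list(config.test_levels))
    detour = _softplus(np.where(is_test, -skill[att_player], 0.0) + eps)
    opt = np.asarray([config.optimal_lengths[lv] for lv in att_level])
    distance = opt * (1.0 + detour) * device[att_player]

    n_seg = int(round(config.trajectory_duration * config.sampling_rate))
    t, x, y = _walks(distance, n_seg, config.sampling_rate, rng)
    n_pts = n_seg + 1
    trajectories = pd.DataFrame(
        {
            "player_id": np.repeat(player_id[att_player], n_pts),
            "level": np.repeat(att_level, n_pts),
            "attempt": np.repeat(att_number, n_pts),
            "t": t.ravel(),
            "x": x.ravel(),
            "y": y.ravel(),
        }
    )

    truth = GroundTruth(
        countries=pd.DataFrame(
            {
                "perf_intercept": [c.perf_intercept for c in config.countries],
                "selfest_intercept": [c.selfest_intercept for c in config.countries],
                "masculinity": [c.masculinity for c in config.countries],
            },
            index=pd.Index([c.name for c in config.countries], name="country"),
        ),
        players=pd.DataFrame(
            {"skill": skill, "latent_self_estimate": latent, "device_factor": device},
            index=pd.Index(player_id, name="player_id"),
        ),
    )
    return players, trajectories, truth


def write_cohort(
    players: pd.DataFrame,
    trajectories: pd.DataFrame,
    outdir: str | Path,
    ground_truth: GroundTruth | None = None,
) -> dict:
    """Write ``players.csv``, ``trajectories.csv`` and, when given, the
    ``ground_truth.json`` sidecar, in the pipeline's input dialect."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "players": outdir / "players.csv",
        "trajectories": outdir / "trajectories.csv",
    }
    cols_p = [
        "player_id", "age", "gender", "country", "self_estimate",
        "education", "home_environment", "commute_time",
    ]
    players.reindex(columns=cols_p).to_csv(paths["players"], index=False)
    cols_t = ["player_id", "level", "attempt", "t", "x", "y"]
    trajectories.reindex(columns=cols_t).to_csv(paths["trajectories"], index=False)
    if ground_truth is not None:
        paths["ground_truth"] = outdir / "ground_truth.json"
        ground_truth.to_json(paths["ground_truth"])
    return paths


def read_cohort(indir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read ``players.csv`` and ``trajectories.csv`` back."""
    indir = Path(indir)
    players = pd.read_csv(indir / "players.csv")
    trajectories = pd.read_csv(indir / "trajectories.csv")
    return players, trajectories


def plant_world(
    n_countries: int,
    n_players: int,
    seed: int,
    gap_masculinity_spearman: float = 0.6,
    **overrides,
) -> CohortConfig:
    """Config for a synthetic world with drawn country effects.

    Country intercepts ``a_c ~ N(0, sigma_country_perf)`` and
    ``b_c ~ N(0, sigma_country_se)``; a synthetic masculinity score is
    coupled to the planted overconfidence ``b_c - a_c`` through a Gaussian
    copula whose coefficient is chosen so the population Spearman
    correlation equals ``gap_masculinity_spearman``.  Countries take real
    names from the bundled cluster table so cluster aggregation works
    downstream (``n_countries`` <= 46).
    """
    names = sorted(load_cluster_map().countries)
    if not 1 <= n_countries <= len(names):
        raise ConfigError(f"n_countries must be in [1, {len(names)}], got {n_countries}")
    base = CohortConfig(**{k: v for k, v in overrides.items() if k != "countries"})
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, base.sigma_country_perf, size=n_countries)
    b = rng.normal(0.0, base.sigma_country_se, size=n_countries)
    over = b - a
    z = (over - over.mean()) / over.std(ddof=0) if over.std(ddof=0) > 0 else over * 0.0
    # bivariate-normal Spearman rho_s corresponds to Pearson r = 2 sin(pi rho_s / 6)
    r = 2.0 * math.sin(math.pi * gap_masculinity_spearman / 6.0)
    w = rng.normal(size=n_countries)
    masc = 50.0 + 20.0 * (r * z + math.sqrt(max(0.0, 1.0 - r * r)) * w)
    base.countries = [
        CountrySpec(
            name=names[i],
            n_players=n_players,
            perf_intercept=float(a[i]),
            selfest_intercept=float(b[i]),
            masculinity=float(masc[i]),
        )
        for i in range(n_countries)
    ]
    base.seed = int(rng.integers(2**31))
    base.validate()
    return base
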