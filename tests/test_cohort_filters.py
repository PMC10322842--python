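import numpy as np
import pandas as pd
import pytest

from navgap.cohort_filters import (
    FilterConfig,
    filter_age,
    filter_cluster_membership,
    filter_complete_demographics,
    filter_completed_levels,
    filter_country_size,
    remove_outliers,
    run_cascade,
)
from navgap.cultural_atlas import assign_cluster
from navgap.synthetic_cohort import generate_cohort, plant_world


def make_players(rows):
    cols = ["player_id", "age", "gender", "country", "self_estimate"]
    return pd.DataFrame(rows, columns=cols)


def brute_force_demographics(players):
    """Independently coded predicate scan for the demographics step."""
    keep = []
    for r in players.itertuples(index=False):
        ok = (
            pd.notna(r.age)
            and str(r.gender).strip().lower() in ("female", "male")
            and pd.notna(r.country)
            and str(r.country).strip() != ""
            and str(r.self_estimate).strip().lower()
            in ("very bad", "bad", "good", "very good")
        )
        keep.append(ok)
    return players[keep]


class TestDemographics:
    def test_planted_gaps_counted(self):
        players = make_players(
            [
                ("p1", 30, "female", "Germany", "good"),
                ("p2", None, "male", "Germany", "good"),  # missing age
                ("p3", 25, "other", "Germany", "bad"),  # non-binary gender label
                ("p4", 40, "male", "Germany", None),  # missing self-estimate
                ("p5", 50, "male", "France", "very good"),
                ("p6", 22, "female", "France", "average"),  # not a scale label
                ("p7", 33, "male", "", "good"),  # blank country
            ]
        )
        kept, step = filter_complete_demographics(players)
        assert step.n_excluded == 5
        assert list(kept.player_id) == ["p1", "p5"]

    def test_matches_brute_force(self, rng):
        genders = ["female", "male", "other", None]
        labels = ["good", "bad", "average", None, "very good"]
        players = make_players(
            [
                (
                    f"p{i}",
                    rng.choice([25, None]),
                    rng.choice(genders),
                    rng.choice(["Germany", "", None]),
                    rng.choice(labels),
                )
                for i in range(100)
            ]
        )
        kept, _ = filter_complete_demographics(players)
        expected = brute_force_demographics(players)
        assert list(kept.player_id) == list(expected.player_id)


class TestAge:
    def test_inclusive_boundaries(self):
        players = make_players(
            [(f"p{a}", a, "male", "Germany", "good") for a in (18, 19, 70, 71)]
        )
        kept, step = filter_age(players, FilterConfig())
        assert list(kept.age) == [19, 70]
        assert step.n_excluded == 2

    def test_uniform_sweep_matches_brute_force(self):
        ages = np.arange(15, 76)
        players = make_players(
            [(f"p{a}", a, "male", "Germany", "good") for a in ages]
        )
        kept, _ = filter_age(players, FilterConfig())
        assert len(kept) == int(((ages >= 19) & (ages <= 70)).sum())


class TestCompletedLevels:
    def test_staged_missingness(self):
        config = FilterConfig()
        all_levels = [*config.required_tutorials, *config.required_levels]
        traj_rows = []
        for pid, drop in [("full", None), ("no11", 11), ("no1", 1)]:
            for lv in all_levels:
                if lv == drop:
                    continue
                traj_rows.append((pid, lv, 1, 0.0, 0.0, 0.0))
                traj_rows.append((pid, lv, 1, 0.5, 1.0, 1.0))
        trajectories = pd.DataFrame(
            traj_rows, columns=["player_id", "level", "attempt", "t", "x", "y"]
        )
        players = make_players(
            [(pid, 30, "male", "Germany", "good") for pid in ("full", "no11", "no1")]
        )
        kept, step = filter_completed_levels(players, trajectories, config)
        assert list(kept.player_id) == ["full"]
        assert step.n_excluded == 2


class TestOutliers:
    def test_constructed_set(self):
        scores = pd.DataFrame({"player_id": range(10), "score": [0.0] * 9 + [10.0]})
        kept, step = remove_outliers(scores, FilterConfig())
        # mean 1, sd ~3.16: the 10 is 2.85 sd away -> excluded; others kept
        assert step.n_excluded == 1
        assert 10.0 not in kept.score.values

    def test_all_equal_scores_all_retained(self):
        scores = pd.DataFrame({"player_id": range(5), "score": [1.0] * 5})
        kept, step = remove_outliers(scores, FilterConfig())
        assert step.n_excluded == 0

    def test_normal_tail_fraction(self, rng):
        """On N(0,1) the two-sided 2 sd rule excludes ~4.55%."""
        scores = pd.DataFrame({"player_id": range(100_000), "score": rng.normal(size=100_000)})
        _, step = remove_outliers(scores, FilterConfig())
        frac = step.n_excluded / step.n_before
        assert frac == pytest.approx(0.0455, abs=0.003)

    def test_boundary_is_exclusive_at_least_two_sd(self):
        # "at least 2 sd" excludes a score exactly 2 sd from the mean
        s = np.array([-1.0, 1.0] * 8)  # mean 0, sd ~1.03 — construct directly:
        scores = pd.DataFrame({"score": s})
        mean, sd = s.mean(), s.std(ddof=1)
        exactly = pd.DataFrame({"score": np.append(s, mean + 2 * sd)})
        kept, step = remove_outliers(exactly, FilterConfig())
        # recomputed mean/sd shift, so just assert the rule on a clean case:
        keep_mask = np.abs(exactly.score - exactly.score.mean()) < 2 * exactly.score.std(ddof=1)
        assert step.n_excluded == int((~keep_mask).sum())


class TestCountrySizeAndCluster:
    def test_country_size_boundary(self):
        rows = [(f"a{i}", 30, "male", "Germany", "good") for i in range(500)]
        rows += [(f"b{i}", 30, "male", "France", "good") for i in range(499)]
        players = make_players(rows)
        kept, step = filter_country_size(players, FilterConfig())
        assert set(kept.country) == {"Germany"}
        assert step.n_excluded == 499

    def test_cluster_membership(self, cluster_map):
        players = make_players(
            [
                ("p1", 30, "male", "Croatia", "good"),
                ("p2", 30, "male", "France", "good"),
            ]
        )
        kept, step = filter_cluster_membership(players, cluster_map)
        assert list(kept.country) == ["France"]
        assert step.n_excluded == 1


@pytest.fixture(scope="module")
def clean_world():
    config = plant_world(3, 120, seed=21)
    players, trajectories, _ = generate_cohort(config)
    return players, trajectories


class TestCascade:

    def test_audit_conservation_and_chaining(self, clean_world, cluster_map):
        players, trajectories = clean_world
        res = run_cascade(
            players, trajectories, FilterConfig(country_min_players=50), cluster_map
        )
        audit = res.audit
        assert audit.total_excluded + audit.n_final == audit.n_initial
        for prev, nxt in zip(audit.steps, audit.steps[1:]):
            assert prev.n_after == nxt.n_before

    def test_one_violation_of_each_kind(self, clean_world, cluster_map):
        players, trajectories = clean_world
        players = players.copy()
        # plant exactly one violation per rule in otherwise-clean players
        players.loc[0, "self_estimate"] = None  # demographics
        players.loc[1, "age"] = 75  # age range
        victim = players.loc[2, "player_id"]  # completed levels
        trajectories = trajectories[
            ~((trajectories.player_id == victim) & (trajectories.level == 11))
        ]
        croat = players.loc[3].copy()  # cluster membership
        croat["player_id"], croat["country"] = "croat1", "Croatia"
        players = pd.concat([players, croat.to_frame().T], ignore_index=True)
        croat_traj = trajectories[trajectories.player_id == players.loc[3, "player_id"]].copy()
        croat_traj["player_id"] = "croat1"
        trajectories = pd.concat([trajectories, croat_traj], ignore_index=True)

        # country_min_players=1 so the lone Croatia player reaches the
        # cluster-membership step instead of dying at country_size
        res = run_cascade(
            players, trajectories, FilterConfig(country_min_players=1), cluster_map
        )
        by_step = {s.step: s.n_excluded for s in res.audit.steps}
        assert by_step["complete_demographics"] == 1
        assert by_step["age_range"] == 1
        assert by_step["completed_levels"] == 1
        assert by_step["cluster_membership"] == 1

    def test_row_order_invariance(self, clean_world, cluster_map):
        players, trajectories = clean_world
        res1 = run_cascade(players, trajectories, FilterConfig(country_min_players=50), cluster_map)
        shuffled_p = players.sample(frac=1.0, random_state=9).reset_index(drop=True)
        shuffled_t = trajectories.sample(frac=1.0, random_state=9).reset_index(drop=True)
        res2 = run_cascade(shuffled_p, shuffled_t, FilterConfig(country_min_players=50), cluster_map)
        assert [(s.step, s.n_excluded) for s in res1.audit.steps] == [
            (s.step, s.n_excluded) for s in res2.audit.steps
        ]

    def test_idempotence_except_outliers(self, clean_world, cluster_map):
        players, trajectories = clean_world
        config = FilterConfig(country_min_players=50)
        res1 = run_cascade(players, trajectories, config, cluster_map)
        res2 = run_cascade(
            res1.players.drop(columns=["score", "n_levels_used"]),
            trajectories,
            config,
            cluster_map,
            scores=res1.players[["player_id", "score", "n_levels_used"]],
        )
        for s in res2.audit.steps:
            if s.step == "score_outliers":
                # mean/sd recomputed on the trimmed sample: a small second-pass
                # tail may go, but no more than the first pass removed
                first_pass = next(
                    t.n_excluded for t in res1.audit.steps if t.step == "score_outliers"
                )
                assert s.n_excluded <= max(first_pass, 1)
            else:
                assert s.n_excluded == 0

    def test_empty_final_set_errors(self, cluster_map):
        players = make_players([("p1", 30, "male", "Croatia", "good")])
        trajectories = pd.DataFrame(
            [("p1", lv, 1, t, float(t), 0.0) for lv in (1, 2, 3, 6, 7, 8, 11, 12) for t in (0, 1)],
            columns=["player_id", "level", "attempt", "t", "x", "y"],
        )
        with pytest.raises(ValueError):
            run_cascade(players, trajectories, FilterConfig(country_min_players=1), cluster_map)
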