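"""Score raw 2 Hz trajectories into per-player wayfinding performance.

Generates a tiny synthetic cohort, then runs the scoring chain: per-attempt
path lengths -> first attempts on the six test levels -> tutorial baseline
(mean of up to the first three attempts on levels 1-2) -> corrected,
per-level z-scored distances -> sign-reversed mean score.  Higher score =
shorter relative paths = better navigation.
"""

from navgap import generate_cohort, plant_world, score_cohort

config = plant_world(n_countries=3, n_players=50, seed=42)
players, trajectories, truth = generate_cohort(config)
print(f"{len(players)} players, {len(trajectories)} trajectory points")

result = score_cohort(trajectories)
scored = players.merge(result.scores, on="player_id")

print("\nFirst players (score in per-level z units; ~0 is an average navigator):")
print(scored[["player_id", "age", "gender", "country", "score"]].head(6).to_string(index=False))

by_country = scored.groupby("country")["score"].mean().sort_values()
print("\nMean score by country (ordering follows the planted country intercepts):")
print(by_country.to_string())
print("\nPlanted performance intercepts for comparison:")
print(truth.countries["perf_intercept"].sort_values().to_string())
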