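"""The over/under-confidence gap and its correlation with masculinity.

Runs the whole analysis on a planted world where countries' masculinity
scores rank-correlate 0.6 with their planted overconfidence (self-estimate
intercept minus performance intercept).  The gap is the difference of
min-max normalised conditional modes, in [-1, 1]: positive = the country
rates itself better than it navigates.
"""

from navgap.recovery import recover_planted_world

out = recover_planted_world(seed=1, n_countries=20, n_players=500)

gaps = out.pop("gaps")
print("Most overconfident countries (gap close to +1):")
print(gaps.sort_values("gap", ascending=False).head(3).round(3).to_string())
print("\nMost underconfident countries (gap close to -1):")
print(gaps.sort_values("gap").head(3).round(3).to_string())

print(
    f"\nPlanted-intercept recovery (Spearman): performance "
    f"{out['rho_perf_recovery']:.3f}, self-estimate {out['rho_selfest_recovery']:.3f}"
)
print(
    f"gap vs masculinity: rho = {out['masculinity_rho']:.3f}, "
    f"Bonferroni p = {out['masculinity_p_bonferroni']:.4f} "
    f"(planted rank correlation was 0.6)"
)
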