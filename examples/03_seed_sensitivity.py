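"""Seed-productivity sensitivity: the cut ladder.

Re-estimates a simulated sample after removing unproductive seeds, chains
of <= 1 wave, and chains of <= 2 waves, and checks whether the crude
proportion stays inside every weighted estimator's 95% CI — the robustness
signature that seed selection is not driving the estimates.
"""

from rdskit import (
    PopulationConfig,
    RecruitmentConfig,
    cut_report_frame,
    generate_population,
    run_cut_analysis,
    simulate_rds,
)

cfg = PopulationConfig(
    N=10_000,
    outcomes={"status": {"pos": 0.3, "neg": 0.7}},
    degree_mean=12.0,
)
pop, truth = generate_population(cfg, rng_seed=4)
sim = simulate_rds(
    pop,
    RecruitmentConfig(n_seeds=25, target_n=600, coupon_return_prob=0.16),
    rng_seed=4,
)

report = run_cut_analysis(
    sim.forest,
    ["status"],
    estimators=["rds_i", "rds_ii", "rds_ss"],
    N=truth.N,
    B=300,
    rng_seed=4,
)

print("Cut bookkeeping (counts, % removed, chain-depth stats):")
print(cut_report_frame(report.cut_summaries).to_string(index=False))

print("\nEstimates by cut (positive category):")
df = report.frame()
print(
    df[df["category"] == "pos"][
        ["cut", "estimator", "point", "ci_low", "ci_high", "n",
         "crude_within_ci"]
    ].to_string(index=False)
)

ok = sum(report.containment.values())
print(
    f"\ncrude-within-CI holds in {ok}/{len(report.containment)} cells: when "
    "homophily is low,\npruning unproductive seeds should barely move the "
    "estimates, so every cut's\ncrude share stays inside the weighted CIs."
)
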