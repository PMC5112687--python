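"""Convergence, bottleneck, homophily and equilibrium diagnostics.

Contrasts a low-homophily sample (one bottleneck: every seed tree's running
estimate settles on the overall value) with a strongly homophilous sample
seeded in both groups (two bottlenecks: seed trees plateau apart).
"""

from rdskit import (
    PopulationConfig,
    RecruitmentConfig,
    bottleneck_series,
    build_transition_model,
    convergence_series,
    equilibrium_waves,
    generate_population,
    homophily_index,
    simulate_rds,
)


def diagnose(label, mixing, seed_rule):
    cfg = PopulationConfig(
        N=10_000,
        outcomes={"status": {"pos": 0.5, "neg": 0.5}},
        degree_mean=12.0,
        mixing=mixing,
    )
    pop, truth = generate_population(cfg, rng_seed=8)
    sim = simulate_rds(
        pop,
        RecruitmentConfig(
            n_seeds=4, seed_rule=seed_rule, target_n=600,
            coupon_return_prob=0.5,
        ),
        rng_seed=88,
    )
    forest = sim.forest
    overall = convergence_series(forest, "status", category="pos")
    per_seed = bottleneck_series(forest, "status", category="pos")
    model = build_transition_model(forest, "status")
    waves = equilibrium_waves(model, epsilon=0.01)

    print(f"--- {label} ---")
    print(f"realized homophily (truth): {truth.homophily}")
    print(f"recruitment homophily index: {homophily_index(model)}")
    print(f"overall estimate: {overall.final_value:.1f}%")
    print(
        "per-seed plateaus: "
        + ", ".join(f"{s.seed_id}={s.final_value:.1f}%" for s in per_seed)
    )
    print(f"waves to equilibrium (eps=0.01): {waves.waves}\n")


diagnose("low homophily (proportionate mixing)", None, "uniform")
diagnose(
    "strong homophily, segregated seeds",
    {"status": [[0.95, 0.05], [0.05, 0.95]]},
    "group-biased",
)

print(
    "With proportionate mixing the per-seed plateaus agree (one bottleneck)\n"
    "and equilibrium arrives in a couple of waves; with 0.95-diagonal mixing\n"
    "the chains stay inside their seed's group, the plateaus split (two\n"
    "bottlenecks) and equilibrium needs many more waves."
)
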