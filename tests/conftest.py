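"""Shared fixtures: toy forests and small synthetic study samples.

All fixtures are generated programmatically; stochastic ones are seeded so
the suite is deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

from rdskit import (
    ParticipantRecord,
    PopulationConfig,
    RecruitmentConfig,
    RecruitmentForest,
    generate_population,
    simulate_rds,
)


def record(pid, degree=2, recruiter=None, order=None, **outcomes):
    return ParticipantRecord(
        id=pid,
        degree=degree,
        recruiter_id=recruiter,
        enroll_order=order,
        outcomes=outcomes or {},
    )


@pytest.fixture
def toy_forest():
    """Two chains: A->B->C (depth 2) and the unproductive seed D."""
    return RecruitmentForest(
        [
            record("A", 3, None, hiv="pos"),
            record("B", 2, "A", hiv="neg"),
            record("C", 4, "B", hiv="neg"),
            record("D", 1, None, hiv="pos"),
        ]
    )


def chain_records(seed_id, outcomes_by_member, degree=2, outcome="status"):
    """Linear chain seed -> m1 -> m2 ... with given outcome labels."""
    recs = []
    prev = None
    for i, cat in enumerate(outcomes_by_member):
        pid = f"{seed_id}{i}"
        recs.append(
            ParticipantRecord(
                id=pid,
                degree=degree,
                recruiter_id=prev,
                outcomes={outcome: cat},
            )
        )
        prev = pid
    return recs


def random_forest(rng, n_chains=5, max_children=3, max_depth=4, outcome="y"):
    """Random forest with random degrees/outcomes for property tests."""
    recs = []
    counter = 0
    for c in range(n_chains):
        seed_id = f"s{c}"
        frontier = [(seed_id, 0)]
        recs.append(
            ParticipantRecord(
                id=seed_id,
                degree=int(rng.integers(1, 10)),
                recruiter_id=None,
                outcomes={outcome: str(rng.choice(["a", "b"]))},
            )
        )
        while frontier:
            parent, depth = frontier.pop()
            if depth >= max_depth:
                continue
            for _ in range(rng.integers(0, max_children + 1)):
                counter += 1
                pid = f"r{counter}"
                recs.append(
                    ParticipantRecord(
                        id=pid,
                        degree=int(rng.integers(1, 10)),
                        recruiter_id=parent,
                        outcomes={outcome: str(rng.choice(["a", "b"]))},
                    )
                )
                frontier.append((pid, depth + 1))
    return RecruitmentForest(recs)


@pytest.fixture(scope="session")
def small_study():
    """A small but realistic synthetic RDS sample with known truth.

    N=4000, 30% prevalence with mild homophily, n=400 drawn by coupon
    recruitment; session-scoped because several test modules reuse it.
    """
    cfg = PopulationConfig(
        N=4000,
        outcomes={"status": {"pos": 0.3, "neg": 0.7}},
        degree_mean=12.0,
        mixing={"status": [[0.75, 0.25], [0.45, 0.55]]},
        # rows ordered (neg, pos): sorted categories
    )
    pop, truth = generate_population(cfg, rng_seed=11)
    sim = simulate_rds(
        pop,
        RecruitmentConfig(n_seeds=8, target_n=400, coupon_return_prob=0.35),
        rng_seed=11,
    )
    return sim


@pytest.fixture(scope="session")
def flat_population():
    """Zero-homophily population used by recovery/coverage style tests."""
    cfg = PopulationConfig(
        N=10_000,
        outcomes={"status": {"pos": 0.3, "neg": 0.7}},
        degree_mean=12.0,
        mixing=None,  # proportionate wiring: no homophily
    )
    pop, truth = generate_population(cfg, rng_seed=7)
    return pop, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
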