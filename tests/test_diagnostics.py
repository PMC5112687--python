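"""Convergence/bottleneck series, homophily index and equilibrium waves."""

from __future__ import annotations

import math

import numpy as np
import pytest

from rdskit import (
    RecruitmentForest,
    bottleneck_series,
    build_transition_model,
    convergence_series,
    equilibrium_waves,
    homophily_index,
)
from rdskit.diagnostics import series_frame
from rdskit.estimators import TransitionModel

from conftest import chain_records, record


def model_from_matrix(t, e, groups=("a", "b"), seed_dist=None):
    """Build a TransitionModel directly from a transition matrix (the
    diagnostics only consume probs/equilibrium/seed_distribution)."""
    t = np.asarray(t, dtype=float)
    k = len(groups)
    return TransitionModel(
        outcome="y",
        groups=tuple(groups),
        counts=t * 100,
        probs=t,
        equilibrium=np.asarray(e, dtype=float),
        harmonic_degrees=np.ones(k),
        group_sizes=np.full(k, 10),
        seed_distribution=(
            np.asarray(seed_dist, float) if seed_dist is not None
            else np.full(k, 1.0 / k)
        ),
    )


class TestConvergenceSeries:
    def test_constant_outcome_is_flat_at_100(self):
        f = RecruitmentForest(chain_records("c", ["pos"] * 15, outcome="y"))
        s = convergence_series(f, "y", estimator="crude", k_min=5)
        assert s.values == pytest.approx((100.0,) * len(s.values))

    def test_final_point_equals_full_sample_estimate(self, small_study):
        f = small_study.forest
        s = convergence_series(f, "status", estimator="rds_ii", k_min=10)
        from rdskit import rds_ii

        full = rds_ii(f, "status").estimates[s.category]
        assert s.final_value == pytest.approx(full)
        assert s.k[-1] == f.n

    def test_prefix_counts_match_hand_enumeration(self):
        # 6-record chain pos,pos,neg,pos,neg,neg; crude prefix shares of pos:
        # k=3: 2/3, k=4: 3/4, k=5: 3/5, k=6: 3/6
        f = RecruitmentForest(
            chain_records("c", ["pos", "pos", "neg", "pos", "neg", "neg"], outcome="y")
        )
        s = convergence_series(f, "y", estimator="crude", category="pos", k_min=3)
        assert s.k == (3, 4, 5, 6)
        assert s.values == pytest.approx((200 / 3, 75.0, 60.0, 50.0))

    def test_k_strictly_increasing(self, small_study):
        s = convergence_series(small_study.forest, "status", k_min=10)
        assert all(b > a for a, b in zip(s.k, s.k[1:]))

    def test_enroll_order_used_when_present(self):
        recs = [
            record("a", 2, None, order=2, y="pos"),
            record("b", 2, "a", order=0, y="neg"),
            record("c", 2, "a", order=1, y="neg"),
        ]
        f = RecruitmentForest(recs)
        s = convergence_series(f, "y", estimator="crude", category="pos", k_min=2)
        assert s.ordering == "enroll_order"
        # first two by enroll_order are b, c (both neg)
        assert s.values[0] == pytest.approx(0.0)


class TestBottleneckSeries:
    def test_single_chain_matches_overall_series(self):
        f = RecruitmentForest(
            chain_records("c", ["pos", "neg"] * 6, outcome="y")
        )
        overall = convergence_series(f, "y", estimator="crude", category="pos")
        (per_seed,) = bottleneck_series(f, "y", estimator="crude", category="pos")
        assert per_seed.k == overall.k
        assert per_seed.values == overall.values
        assert per_seed.seed_id == "c0"

    def test_opposite_constant_chains_show_two_bottlenecks(self):
        recs = chain_records("a", ["pos"] * 12, outcome="y")
        recs += chain_records("b", ["neg"] * 12, outcome="y")
        series = bottleneck_series(
            RecruitmentForest(recs), "y", estimator="crude", category="pos"
        )
        finals = sorted(s.final_value for s in series)
        assert finals == [pytest.approx(0.0), pytest.approx(100.0)]

    def test_short_chains_skipped(self):
        recs = chain_records("a", ["pos"] * 12, outcome="y")
        recs += [record("tiny", 2, None, y="neg")]
        series = bottleneck_series(RecruitmentForest(recs), "y", estimator="crude")
        assert [s.seed_id for s in series] == ["a0"]

    def test_chain_series_depends_only_on_its_records(self):
        base = chain_records("a", ["pos", "neg"] * 7, outcome="y")
        other1 = chain_records("b", ["pos"] * 11, outcome="y")
        other2 = chain_records("z", ["neg"] * 13, outcome="y")
        s1 = [
            s
            for s in bottleneck_series(
                RecruitmentForest(base + other1), "y", estimator="crude",
                category="pos",
            )
            if s.seed_id == "a0"
        ][0]
        s2 = [
            s
            for s in bottleneck_series(
                RecruitmentForest(base + other2), "y", estimator="crude",
                category="pos",
            )
            if s.seed_id == "a0"
        ][0]
        assert s1.values == s2.values

    def test_series_frame_tidy_export(self, small_study):
        series = bottleneck_series(small_study.forest, "status", k_min=10)
        df = series_frame(series)
        assert list(df.columns) == [
            "outcome", "category", "estimator", "seed_id", "k", "value",
        ]
        assert df["seed_id"].notna().all()


class TestHomophilyIndex:
    def test_zero_when_within_group_rate_matches_equilibrium(self):
        m = model_from_matrix([[0.3, 0.7], [0.3, 0.7]], [0.3, 0.7])
        h = homophily_index(m)
        assert h["a"] == pytest.approx(0.0)
        assert h["b"] == pytest.approx(0.0)

    def test_strong_symmetric_homophily(self):
        m = model_from_matrix([[0.9, 0.1], [0.1, 0.9]], [0.5, 0.5])
        h = homophily_index(m)
        assert h["a"] == pytest.approx(0.8)
        assert h["b"] == pytest.approx(0.8)

    def test_perfect_self_recruitment_gives_one(self):
        m = model_from_matrix([[1.0, 0.0], [0.5, 0.5]], [0.4, 0.6])
        assert homophily_index(m)["a"] == pytest.approx(1.0)

    def test_avoidance_negative_branch(self):
        # within-group rate below equilibrium share: H = (T_gg - e_g)/e_g
        m = model_from_matrix([[0.1, 0.9], [0.9, 0.1]], [0.5, 0.5])
        assert homophily_index(m)["a"] == pytest.approx((0.1 - 0.5) / 0.5)

    def test_degenerate_equilibrium_flagged_nan(self):
        m = model_from_matrix([[1.0, 0.0], [1.0, 0.0]], [1.0, 0.0])
        h = homophily_index(m)
        assert math.isnan(h["a"]) and math.isnan(h["b"])

    def test_realized_forest_homophily_in_range(self, small_study):
        model = build_transition_model(small_study.forest, "status")
        for v in homophily_index(model).values():
            assert -1.0 <= v <= 1.0


class TestEquilibriumWaves:
    def test_one_step_mixing_when_rows_equal(self):
        m = model_from_matrix([[0.3, 0.7], [0.3, 0.7]], [0.3, 0.7])
        rep = equilibrium_waves(m, epsilon=0.01)
        assert rep.waves == {"a": 1.0, "b": 1.0}

    def test_closed_form_geometric_decay(self):
        """For T=[[.9,.1],[.1,.9]] a one-hot start is 0.5*0.8^w from
        equilibrium, so w=18 is the first wave below 0.01."""
        m = model_from_matrix([[0.9, 0.1], [0.1, 0.9]], [0.5, 0.5])
        rep = equilibrium_waves(m, epsilon=0.01)
        assert rep.waves["a"] == 18.0
        assert rep.waves["b"] == 18.0

    def test_monotone_in_epsilon(self):
        m = model_from_matrix([[0.9, 0.1], [0.1, 0.9]], [0.5, 0.5])
        loose = equilibrium_waves(m, epsilon=0.5).max_waves
        tight = equilibrium_waves(m, epsilon=0.01).max_waves
        assert loose <= tight

    def test_observed_seed_start(self):
        m = model_from_matrix(
            [[0.9, 0.1], [0.1, 0.9]], [0.5, 0.5], seed_dist=[0.5, 0.5]
        )
        rep = equilibrium_waves(m, epsilon=0.01, start_mode="observed-seeds")
        assert rep.waves["observed-seeds"] == 0.0  # already at equilibrium

    def test_agrees_with_matrix_power_bruteforce(self, rng):
        """Waves found by stepping equal the first w with
        max|start·T^w − e| < ε computed via explicit matrix powers."""
        for _ in range(10):
            k = int(rng.integers(2, 6))
            t = rng.random((k, k)) + 0.05
            t /= t.sum(axis=1, keepdims=True)
            vals, vecs = np.linalg.eig(t.T)
            v = np.abs(np.real(vecs[:, np.argmin(np.abs(vals - 1))]))
            e = v / v.sum()
            groups = tuple(f"g{j}" for j in range(k))
            m = model_from_matrix(t, e, groups=groups)
            eps = 0.02
            rep = equilibrium_waves(m, epsilon=eps)
            for j, g in enumerate(groups):
                start = np.eye(k)[j]
                w = 0
                while np.max(np.abs(start @ np.linalg.matrix_power(t, w) - e)) >= eps:
                    w += 1
                assert rep.waves[g] == w

    def test_non_ergodic_reports_infinite_waves(self):
        recs = chain_records("c", ["pos"] * 4, outcome="y")
        recs += [record("x", 2, None, y="neg")]
        model = build_transition_model(RecruitmentForest(recs), "y")
        rep = equilibrium_waves(model, epsilon=0.01)
        assert not rep.ergodic
        assert math.isinf(rep.waves["neg"])
        assert rep.waves["pos"] == 0.0
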