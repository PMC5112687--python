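"""Estimator correctness against hand-derived and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from rdskit import (
    EstimatorUndefinedError,
    RecruitmentForest,
    bootstrap_ci,
    build_transition_model,
    crude_proportion,
    rds_i,
    rds_ii,
    rds_ss,
    ss_inclusion_probs,
)

from conftest import chain_records, random_forest, record


def chain_of(cats, degree=2):
    """Linear chain with the given category sequence; its recruiter→recruit
    pairs are exactly the consecutive category pairs."""
    return RecruitmentForest(chain_records("c", cats, degree=degree, outcome="y"))


class TestCrude:
    def test_printed_count_arithmetic(self):
        recs = [record(f"p{i}", 2, None, y="pos") for i in range(199)]
        recs += [record(f"n{i}", 2, None, y="neg") for i in range(719 - 199)]
        res = crude_proportion(RecruitmentForest(recs), "y")
        assert res.estimates["pos"] == pytest.approx(100 * 199 / 719)

    def test_zero_positive_gives_zero_percent(self):
        f = RecruitmentForest([record(f"n{i}", 2, None, y="neg") for i in range(5)])
        assert crude_proportion(f, "y").estimates == {"neg": 100.0}

    def test_denominator_modes_differ_only_under_missingness(self):
        recs = [
            record("a", 2, None, y="pos"),
            record("b", 2, None, y="neg"),
            record("c", 2, None, y=None),
        ]
        f = RecruitmentForest(recs)
        allrec = crude_proportion(f, "y", "all_records")
        nonmiss = crude_proportion(f, "y", "non_missing")
        assert allrec.estimates["pos"] == pytest.approx(100 / 3)
        assert nonmiss.estimates["pos"] == 50.0
        assert sum(nonmiss.estimates.values()) == pytest.approx(100.0)

    def test_empty_forest_rejected(self):
        with pytest.raises(EstimatorUndefinedError):
            crude_proportion(RecruitmentForest([]), "y")


class TestRdsII:
    def test_hand_harmonic_weighting(self):
        f = RecruitmentForest(
            [
                record("a", 1, None, y="pos"),
                record("b", 2, None, y="pos"),
                record("c", 2, None, y="neg"),
                record("d", 4, None, y="neg"),
            ]
        )
        res = rds_ii(f, "y")
        assert res.estimates["pos"] == pytest.approx(100 * 1.5 / 2.25)

    def test_equal_degrees_reduce_to_crude(self, rng):
        f = random_forest(rng)
        equalized = RecruitmentForest(
            type(r)(
                id=r.id,
                degree=5,
                recruiter_id=r.recruiter_id,
                outcomes=r.outcomes,
            )
            for r in f.records
        )
        crude = crude_proportion(equalized, "y", "non_missing").estimates
        weighted = rds_ii(equalized, "y").estimates
        assert weighted == pytest.approx(crude)

    def test_single_record_is_certain(self):
        f = RecruitmentForest([record("a", 7, None, y="pos")])
        assert rds_ii(f, "y").estimates == {"pos": pytest.approx(100.0)}

    def test_matches_bruteforce_weighted_mean(self, rng):
        """Inverse-degree weighting equals an explicit record-by-record loop."""
        for _ in range(20):
            f = random_forest(rng, n_chains=3)
            res = rds_ii(f, "y").estimates
            num: dict[str, float] = {}
            den = 0.0
            for r in f.records:
                cat = r.outcomes["y"]
                num[cat] = num.get(cat, 0.0) + 1.0 / r.degree
                den += 1.0 / r.degree
            for cat, share in num.items():
                assert res[cat] == pytest.approx(100 * share / den, abs=1e-12)

    def test_estimates_sum_to_100(self, rng):
        f = random_forest(rng)
        assert sum(rds_ii(f, "y").estimates.values()) == pytest.approx(100.0)


class TestTransitionModel:
    def test_hand_solved_equilibrium(self):
        # chain pos->neg->pos->neg->neg: pairs pos->neg x2, neg->pos, neg->neg
        f = chain_of(["pos", "neg", "pos", "neg", "neg"])
        m = build_transition_model(f, "y")
        assert m.groups == ("neg", "pos")
        np.testing.assert_allclose(m.probs, [[0.5, 0.5], [1.0, 0.0]])
        np.testing.assert_allclose(m.equilibrium, [2 / 3, 1 / 3], atol=1e-10)

    def test_single_group_equilibrium_degenerate_and_flagged(self):
        recs = chain_records("c", ["pos", "pos", "pos"], outcome="y")
        recs += [record("x", 2, None, y="neg")]
        m = build_transition_model(RecruitmentForest(recs), "y")
        assert m.reducible
        assert m.equilibrium[list(m.groups).index("pos")] == pytest.approx(1.0)

    def test_symmetric_counts_equal_rowsums_give_uniform_equilibrium(self):
        # chain pos->pos->neg->neg->pos realizes the symmetric count matrix
        # [[1,1],[1,1]] (one pair in each direction plus both self-pairs)
        m = build_transition_model(chain_of(["pos", "pos", "neg", "neg", "pos"]), "y")
        np.testing.assert_allclose(m.equilibrium, [0.5, 0.5], atol=1e-10)

    def test_smoothing_is_noop_for_symmetric_transitions(self):
        f = chain_of(["pos", "pos", "neg", "neg", "pos"])
        raw = build_transition_model(f, "y", smoothing=False)
        smooth = build_transition_model(f, "y", smoothing=True)
        np.testing.assert_allclose(raw.probs, smooth.probs, atol=1e-10)
        np.testing.assert_allclose(raw.equilibrium, smooth.equilibrium, atol=1e-10)

    def test_harmonic_degrees(self):
        f = RecruitmentForest(
            [
                record("a", 2, None, y="pos"),
                record("b", 6, "a", y="pos"),
                record("c", 3, "b", y="neg"),
            ]
        )
        m = build_transition_model(f, "y")
        dhat = dict(zip(m.groups, m.harmonic_degrees))
        assert dhat["pos"] == pytest.approx(2 / (1 / 2 + 1 / 6))
        assert dhat["neg"] == pytest.approx(3.0)


class TestRdsI:
    def test_hand_example_equal_scores(self):
        """e=(1/3,2/3) against harmonic degrees (2,4) balances to 50/50."""
        # pairs pos->neg x2, neg->pos, neg->neg give e=(neg 2/3, pos 1/3);
        # every pos member degree 2 and neg member degree 4, so the
        # group scores e_g/D_g are both 1/6.
        recs = [
            record("s", 2, None, y="pos"),
            record("r1", 4, "s", y="neg"),
            record("r2", 2, "r1", y="pos"),
            record("r3", 4, "r2", y="neg"),
            record("r4", 4, "r3", y="neg"),
        ]
        f = RecruitmentForest(recs)
        m = build_transition_model(f, "y")
        np.testing.assert_allclose(m.equilibrium, [2 / 3, 1 / 3], atol=1e-10)
        res = rds_i(f, "y", smoothing=False)
        assert res.estimates["pos"] == pytest.approx(50.0, abs=1e-8)

    def test_equal_harmonic_degrees_return_equilibrium(self):
        f = chain_of(["pos", "neg", "pos", "neg", "neg"], degree=3)
        m = build_transition_model(f, "y")
        res = rds_i(f, "y", smoothing=False)
        for g, e in zip(m.groups, m.equilibrium):
            assert res.estimates[g] == pytest.approx(100 * e)

    def test_two_group_closed_form_identity(self, rng):
        """P_A = C_BA D_B / (C_AB D_A + C_BA D_B) on any two-group forest."""
        for _ in range(10):
            f = random_forest(rng, n_chains=3)
            try:
                res = rds_i(f, "y", smoothing=False)
            except EstimatorUndefinedError:
                continue
            m = build_transition_model(f, "y", smoothing=False)
            if len(m.groups) != 2:
                continue
            (a, b) = m.groups
            c_ab, c_ba = m.probs[0, 1], m.probs[1, 0]
            d_a, d_b = m.harmonic_degrees
            expected = 100 * c_ba * d_b / (c_ab * d_a + c_ba * d_b)
            assert res.estimates[a] == pytest.approx(expected, abs=1e-8)

    def test_category_absent_from_pairs_raises_with_guidance(self):
        recs = chain_records("c", ["pos", "pos"], outcome="y")
        recs += [record("iso", 2, None, y="neg")]  # never in any pair
        with pytest.raises(EstimatorUndefinedError, match="neg"):
            rds_i(RecruitmentForest(recs), "y")


class TestSuccessiveSampling:
    def test_equal_degrees_give_uniform_inclusion(self):
        table = ss_inclusion_probs([3, 3], [50, 50], 20)
        np.testing.assert_allclose(table.pi, 0.2, atol=1e-9)

    def test_large_population_limit_proportional_to_degree(self):
        table = ss_inclusion_probs([1, 2, 5], [1e9, 1e9, 1e9], 30)
        ratios = table.pi / table.pi[0]
        np.testing.assert_allclose(ratios, [1, 2, 5], rtol=1e-6)

    def test_monotone_in_degree_and_mass_balance(self):
        table = ss_inclusion_probs([1, 2, 5, 9], [40, 30, 20, 10], 35)
        assert np.all(np.diff(table.pi) >= 0)
        assert abs(float(table.pop_counts @ table.pi) - 35) <= 0.5
        assert table.converged

    def test_overdraw_rejected(self):
        with pytest.raises(ValueError):
            ss_inclusion_probs([1, 2], [3, 3], 10)


class TestRdsSS:
    def test_huge_population_equals_inverse_degree(self, rng):
        f = random_forest(rng)
        ss = rds_ss(f, "y", N=1e9)
        ii = rds_ii(f, "y")
        for cat in ss.estimates:
            assert ss.estimates[cat] == pytest.approx(ii.estimates[cat], abs=1e-6)

    def test_census_equals_crude(self, rng):
        f = random_forest(rng)
        ss = rds_ss(f, "y", N=f.n)
        crude = crude_proportion(f, "y", "non_missing")
        for cat in ss.estimates:
            assert ss.estimates[cat] == pytest.approx(crude.estimates[cat], abs=1e-9)

    def test_reports_convergence(self, rng):
        f = random_forest(rng)
        assert rds_ss(f, "y", N=10 * f.n).info["converged"]


class TestBootstrap:
    def test_constant_outcome_zero_width_ci(self):
        recs = chain_records("c", ["pos"] * 12, outcome="y")
        res = bootstrap_ci(RecruitmentForest(recs), "y", "rds_ii", B=50, rng_seed=1)
        lo, hi = res.ci["pos"]
        assert lo == hi == pytest.approx(100.0)

    def test_same_seed_reproduces_ci_exactly(self, small_study):
        a = bootstrap_ci(small_study.forest, "status", "rds_ii", B=60, rng_seed=42)
        b = bootstrap_ci(small_study.forest, "status", "rds_ii", B=60, rng_seed=42)
        assert a.ci == b.ci

    def test_different_seeds_differ(self, small_study):
        a = bootstrap_ci(small_study.forest, "status", "rds_ii", B=60, rng_seed=1)
        b = bootstrap_ci(small_study.forest, "status", "rds_ii", B=60, rng_seed=2)
        assert a.ci != b.ci

    def test_ci_brackets_point(self, small_study):
        res = bootstrap_ci(small_study.forest, "status", "rds_ii", B=100, rng_seed=3)
        for cat, (lo, hi) in res.ci.items():
            assert lo <= res.estimates[cat] <= hi

    def test_reachable_group_with_empty_pool_is_an_error(self):
        # a 'neg' seed exists but nobody was ever recruited by a 'neg' member
        recs = [
            record("s1", 2, None, y="neg"),
            *chain_records("c", ["pos"] * 11, outcome="y"),
        ]
        with pytest.raises(EstimatorUndefinedError, match="neg"):
            bootstrap_ci(RecruitmentForest(recs), "y", "rds_ii", B=10, rng_seed=0)

    def test_percentile_method(self, small_study):
        res = bootstrap_ci(
            small_study.forest, "status", "rds_ii", B=100, rng_seed=5,
            method="percentile",
        )
        for lo, hi in res.ci.values():
            assert 0.0 <= lo <= hi <= 100.0
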