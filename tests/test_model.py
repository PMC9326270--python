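import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from destchoice import (
    ModelParams,
    ParticipantTrajectory,
    Schedule,
    choice_probabilities,
    desirability_vector,
    log_likelihood,
    normalize_predictors,
    utility,
)
from destchoice.model import DecisionArrays

from .conftest import make_context, make_trajectory

DESTS = tuple("ABCDEF")


class TestDesirability:
    def test_worked_example_fresh_schedule(self):
        q = desirability_vector(Schedule("ABCDE"), (), DESTS, variant="worked_example")
        expected = {d: math.exp(-(p + 1)) for p, d in enumerate(DESTS)}
        assert q == pytest.approx(expected)

    def test_worked_example_after_visiting_first_entry(self):
        q = desirability_vector(Schedule("ABCDE"), ("A",), DESTS, variant="worked_example")
        expected = {"A": 0.0}
        expected.update({d: math.exp(-(p + 1)) for p, d in enumerate("BCDEF")})
        assert q == pytest.approx(expected)

    def test_rule_variant_zeroes_off_schedule_destinations(self):
        q = desirability_vector(Schedule("ABCDE"), (), DESTS, variant="rule")
        assert q["F"] == 0.0
        assert q["A"] == pytest.approx(math.exp(-1))
        assert q["E"] == pytest.approx(math.exp(-5))

    def test_empty_schedule_all_zero(self):
        q = desirability_vector(Schedule(""), ("A",), DESTS, variant="rule")
        assert set(q.values()) == {0.0}

    def test_visit_reindexes_remaining_schedule(self):
        q = desirability_vector(Schedule("ABCDE"), ("B", "A"), DESTS, variant="rule")
        # remaining schedule (C, D, E): positions 1..3
        assert q["C"] == pytest.approx(math.exp(-1))
        assert q["E"] == pytest.approx(math.exp(-3))
        assert q["A"] == q["B"] == q["F"] == 0.0

    def test_unknown_visited_label_rejected(self):
        with pytest.raises(ValueError):
            desirability_vector(Schedule("AB"), ("Z",), DESTS)

    @settings(max_examples=50, derandomize=True)
    @given(st.permutations(list(DESTS)))
    def test_variants_agree_when_schedule_covers_all(self, order):
        s = Schedule(order)
        for visited in ((), (order[0],), tuple(order[:3])):
            assert desirability_vector(s, visited, DESTS, "rule") == \
                desirability_vector(s, visited, DESTS, "worked_example")


class TestNormalize:
    def test_divide_by_max(self):
        assert normalize_predictors([2, 4, 8]) == pytest.approx([0.25, 0.5, 1.0])

    def test_zero_max_convention(self):
        assert normalize_predictors([0, 0, 0]) == pytest.approx([0, 0, 0])

    def test_singleton(self):
        assert normalize_predictors([7]) == pytest.approx([1.0])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            normalize_predictors([1, -1])


class TestUtility:
    def test_zero_params(self):
        assert utility(ModelParams(0, 0), 0.3, 0.9) == 0.0

    def test_two_param_arithmetic(self):
        assert utility(ModelParams(-1, -2), 1.0, 0.5) == pytest.approx(-2.0)

    def test_base_condition_point_estimates(self):
        # direct arithmetic with the aggregate open-environment estimates
        assert utility(ModelParams(-3.95, -0.40), 0.5, 1.0) == pytest.approx(-2.375)

    def test_arity_mismatch_rejected(self):
        with pytest.raises(ValueError):
            utility(ModelParams(-1, -1), 0.5, 0.5, q_hat=0.5)
        with pytest.raises(ValueError):
            utility(ModelParams(-1, -1, 1.0), 0.5, 0.5)

    def test_beta_des_must_be_nonnegative(self):
        with pytest.raises(ValueError):
            ModelParams(-1, -1, -0.5)


class TestChoiceProbabilities:
    def test_equal_utilities_uniform(self):
        ctx = make_context(occupancies=[3, 3, 3, 3], distances=[2, 2, 2, 2])
        probs = choice_probabilities(ModelParams(-4, -0.5), ctx)
        assert list(probs.values()) == pytest.approx([0.25] * 4)

    def test_log_two_utility_gap(self):
        # n-hat = (1, 0), d-hat = (0, 0) -> utilities (ln 2, 0) -> (2/3, 1/3)
        ctx = make_context(occupancies=[5, 0], distances=[0, 0])
        probs = choice_probabilities(ModelParams(math.log(2), -1.0), ctx)
        assert probs["A"] == pytest.approx(2 / 3)
        assert probs["B"] == pytest.approx(1 / 3)

    def test_matches_brute_force_softmax(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            m = int(rng.integers(2, 7))
            occ = rng.uniform(0, 10, m)
            dist = rng.uniform(0, 10, m)
            des = rng.uniform(0, 1, m)
            params = ModelParams(*rng.normal(0, 3, 2), float(rng.uniform(0, 3)))
            ctx = make_context(occ, dist, des)
            got = choice_probabilities(params, ctx)
            # independent per-alternative recomputation
            n, d, q = (v / v.max() if v.max() > 0 else v for v in (occ, dist, des))
            u = [params.beta_occ * n[i] + params.beta_dist * d[i]
                 + params.beta_des * q[i] for i in range(m)]
            denom = sum(math.exp(ui) for ui in u)
            for i, label in enumerate("ABCDEF"[:m]):
                assert got[label] == pytest.approx(math.exp(u[i]) / denom, abs=1e-12)

    def test_extreme_parameters_do_not_overflow(self):
        ctx = make_context(occupancies=[1, 9], distances=[9, 1])
        probs = choice_probabilities(ModelParams(-500.0, -500.0), ctx)
        assert sum(probs.values()) == pytest.approx(1.0)
        assert all(np.isfinite(list(probs.values())))

    def test_busiest_alternative_loses_as_beta_occ_falls(self):
        ctx = make_context(occupancies=[9, 2, 4], distances=[3, 3, 3])
        p = [choice_probabilities(ModelParams(b, -0.5), ctx)["A"]
             for b in (0.0, -1.0, -3.0, -8.0)]
        assert all(a >= b for a, b in zip(p, p[1:]))


class TestLogLikelihood:
    def test_null_params_single_decision(self):
        traj = make_trajectory([make_context([1] * 6, [1] * 6)])
        assert log_likelihood(ModelParams(0, 0), [traj]) == pytest.approx(math.log(1 / 6))

    def test_additivity(self, base_cohort):
        trajectories, _ = base_cohort
        params = ModelParams(-3.0, -1.0)
        a, b = trajectories[:40], trajectories[40:90]
        assert log_likelihood(params, a + b) == pytest.approx(
            log_likelihood(params, a) + log_likelihood(params, b)
        )

    def test_matches_per_record_oracle(self, base_cohort):
        trajectories, _ = base_cohort
        subset = trajectories[:10]  # 50 decisions
        params = ModelParams(-4.0, -0.5)
        oracle = sum(
            math.log(choice_probabilities(params, ctx)[ctx.chosen])
            for t in subset
            for ctx in t.decisions
        )
        assert log_likelihood(params, subset) == pytest.approx(oracle, abs=1e-10)

    @settings(max_examples=30, derandomize=True)
    @given(st.floats(-10, 10), st.floats(-10, 10))
    def test_never_positive(self, b_occ, b_dist):
        traj = make_trajectory(
            [make_context([2, 5, 1], [4, 1, 3], chosen_idx=1)]
        )
        assert log_likelihood(ModelParams(b_occ, b_dist), [traj]) <= 0.0

    def test_zero_only_for_single_alternative(self):
        traj = make_trajectory([make_context([4], [2])])
        assert log_likelihood(ModelParams(-2, -2), [traj]) == pytest.approx(0.0)

    def test_gradient_matches_finite_differences(self, schedule_cohort):
        trajectories, _ = schedule_cohort
        arrays = DecisionArrays.from_trajectories(trajectories[:30], k=3)
        beta = np.array([-2.0, -0.7, 1.1])
        ll, grad = arrays.log_likelihood_grad(beta)
        assert ll == pytest.approx(arrays.log_likelihood(beta))
        eps = 1e-6
        for i in range(3):
            step = np.zeros(3)
            step[i] = eps
            fd = (arrays.log_likelihood(beta + step)
                  - arrays.log_likelihood(beta - step)) / (2 * eps)
            assert grad[i] == pytest.approx(fd, rel=1e-4)


class TestTrajectoryInvariants:
    def test_revisit_rejected(self):
        ctxs = [
            make_context([1, 2], [1, 2], chosen_idx=0, decision_index=1),
            make_context([1, 2], [1, 2], chosen_idx=0, decision_index=2),
        ]
        with pytest.raises(ValueError, match="revisit"):
            make_trajectory(ctxs)

    def test_schedule_presence_tied_to_condition(self):
        ctx = make_context([1, 2], [1, 2])
        with pytest.raises(ValueError, match="schedule"):
            make_trajectory([ctx], condition="base", schedule=Schedule("AB"))
        with pytest.raises(ValueError, match="schedule"):
            make_trajectory([ctx], condition="schedule_given", schedule=None)

    def test_schedule_duplicates_rejected(self):
        with pytest.raises(ValueError):
            Schedule("AAB")

    def test_chosen_must_be_among_alternatives(self):
        from destchoice import DecisionContext

        alts = make_context([1, 2], [1, 2]).alternatives
        with pytest.raises(ValueError, match="chosen"):
            DecisionContext(decision_index=1, position="O",
                            alternatives=alts, chosen="Z")
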