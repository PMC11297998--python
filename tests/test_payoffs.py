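"""Sharing rules, the pooled collective decision, and mutant perturbations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from grouphawk import (
    ConfigError,
    DegenerateDivisionError,
    InvalidPerturbationError,
    ModelConfig,
    StrategyPair,
    UndefinedDecisionError,
    class_payoffs,
    collective_hawk_probability,
    mutant_group_hawk_probability,
)

@st.composite
def configs(draw, d_c_min=0.01, d_c_max=0.99):
    v = draw(st.floats(0.1, 10.0))
    return ModelConfig(
        omega=draw(st.floats(0.0, 1.0)),
        epsilon=draw(st.floats(0.02, 0.98)),
        n_group=draw(st.integers(2, 500)),
        v_total=v,
        c_total=v * draw(st.floats(1.01, 10.0)),
        d_v=draw(st.floats(0.0, 1.0)),
        d_c=draw(st.floats(d_c_min, d_c_max)),
    )


class TestModelConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(omega=-0.1, epsilon=0.3, n_group=10),
            dict(omega=1.1, epsilon=0.3, n_group=10),
            dict(omega=0.5, epsilon=0.0, n_group=10),
            dict(omega=0.5, epsilon=1.0, n_group=10),  # all-leader limit is omega=0 instead
            dict(omega=0.5, epsilon=0.3, n_group=1),
            dict(omega=0.5, epsilon=0.3, n_group=10, v_total=0.0),
            dict(omega=0.5, epsilon=0.3, n_group=10, v_total=2.0, c_total=1.0),  # needs C > V
            dict(omega=0.5, epsilon=0.3, n_group=10, d_v=1.2),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            ModelConfig(**kwargs)

    def test_integer_leader_count_enforced_only_on_request(self):
        cfg = ModelConfig(omega=0.5, epsilon=0.31, n_group=10)  # fine analytically
        with pytest.raises(ConfigError):
            cfg.require_integer_leaders()
        assert ModelConfig(omega=0.5, epsilon=0.3, n_group=10).require_integer_leaders() == 3


class TestClassPayoffs:
    def test_symmetric_division_collapses_to_equal_shares(self):
        cfg = ModelConfig(omega=0.2, epsilon=0.3, n_group=100, v_total=1.0, c_total=2.0)
        pay = class_payoffs(cfg)
        assert pay.c_leader == pytest.approx(0.02)
        assert pay.c_follower == pytest.approx(0.02)
        assert pay.v_leader == pytest.approx(0.01)
        assert pay.v_follower == pytest.approx(0.01)
        assert pay.vtilde_leader == pytest.approx(0.5)
        assert pay.vtilde_follower == pytest.approx(0.5)

    def test_mild_leader_advantage_hand_values(self, baseline_config):
        # hand-substitution into the four sharing-rule formulas
        pay = class_payoffs(baseline_config)
        assert pay.c_leader == pytest.approx(0.9 / 52, rel=1e-12)
        assert pay.c_follower == pytest.approx(1.1 / 52, rel=1e-12)
        assert pay.v_leader == pytest.approx(0.55 / 48, rel=1e-12)
        assert pay.v_follower == pytest.approx(0.45 / 48, rel=1e-12)
        assert pay.vtilde_leader == pytest.approx(0.6620370370370, rel=1e-10)
        assert pay.vtilde_follower == pytest.approx(0.4431818181818, rel=1e-10)

    def test_degenerate_cost_division_raises(self):
        for d_c in (0.0, 1.0):
            cfg = ModelConfig(omega=0.5, epsilon=0.3, n_group=10, d_c=d_c)
            with pytest.raises(DegenerateDivisionError):
                class_payoffs(cfg)

    @settings(max_examples=200, derandomize=True)
    @given(configs())
    def test_group_totals_reconstruct_collective_cost_and_benefit(self, cfg):
        pay = class_payoffs(cfg)
        n, eps = cfg.n_group, cfg.epsilon
        total_c = n * eps * pay.c_leader + n * (1 - eps) * pay.c_follower
        total_v = n * eps * pay.v_leader + n * (1 - eps) * pay.v_follower
        assert total_c == pytest.approx(cfg.c_total, rel=1e-12)
        assert total_v == pytest.approx(cfg.v_total, rel=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(configs())
    def test_division_bias_direction(self, cfg):
        pay = class_payoffs(cfg)
        if cfg.d_c > 0.5:
            assert pay.c_leader < pay.c_follower
        elif cfg.d_c < 0.5:
            assert pay.c_leader > pay.c_follower
        if cfg.d_v > 0.5:
            assert pay.v_leader > pay.v_follower
        elif cfg.d_v < 0.5:
            assert pay.v_leader < pay.v_follower


class TestCollectiveDecision:
    @pytest.mark.parametrize(
        "p_l, p_f, omega, eps, expected",
        [
            (0.7, 0.2, 0.0, 0.3, 0.7),  # unshared: pure leader control
            (0.7, 0.2, 1.0, 0.3, 0.35),  # fully shared: population mean vote
            (1.0, 0.0, 0.3, 0.3, 0.3 / 0.51),  # hand evaluation of the pooling rule
        ],
    )
    def test_pooling_examples(self, p_l, p_f, omega, eps, expected):
        assert collective_hawk_probability(p_l, p_f, omega, eps) == pytest.approx(expected)

    def test_zero_total_influence_rejected(self):
        with pytest.raises(UndefinedDecisionError):
            collective_hawk_probability(0.5, 0.5, omega=0.0, epsilon=0.0)

    @settings(max_examples=100, derandomize=True)
    @given(
        st.floats(0, 1), st.floats(0, 1), st.floats(0, 1), st.floats(0, 1),
        st.floats(0.001, 1), st.floats(0.02, 0.98),
    )
    def test_monotone_in_each_class_vote(self, pl1, pl2, pf1, pf2, om, eps):
        lo_l, hi_l = sorted((pl1, pl2))
        lo_f, hi_f = sorted((pf1, pf2))
        assert collective_hawk_probability(lo_l, lo_f, om, eps) <= (
            collective_hawk_probability(hi_l, lo_f, om, eps) + 1e-12
        )
        assert collective_hawk_probability(lo_l, lo_f, om, eps) <= (
            collective_hawk_probability(lo_l, hi_f, om, eps) + 1e-12
        )

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0.02, 0.98))
    def test_sharing_moves_outcome_from_leader_vote_to_population_mean(self, pl, pf, eps):
        # |P - population mean| shrinks monotonically as omega -> 1
        mean = eps * pl + (1 - eps) * pf
        omegas = np.linspace(0.0, 1.0, 11)
        values = [collective_hawk_probability(pl, pf, om, eps) for om in omegas]
        gaps = np.abs(np.asarray(values) - mean)
        assert values[0] == pytest.approx(pl)
        assert values[-1] == pytest.approx(mean)
        assert np.all(np.diff(gaps) <= 1e-12)


class TestMutantGroupProbability:
    def test_no_deviation_leaves_group_unchanged(self, baseline_config):
        res = StrategyPair.from_class_strategies(0.4, 0.7, baseline_config)
        for role, p in (("leader", 0.4), ("follower", 0.7)):
            assert mutant_group_hawk_probability(res, p, role, baseline_config) == res.p_group

    def test_single_leader_deviation_hand_value(self):
        cfg = ModelConfig(omega=1.0, epsilon=0.3, n_group=100, v_total=1.0, c_total=2.0)
        res = StrategyPair.from_class_strategies(0.5, 0.5, cfg)
        q = mutant_group_hawk_probability(res, 1.0, "leader", cfg)
        assert q == pytest.approx(0.505)

    def test_follower_deviation_ignored_without_sharing(self):
        cfg = ModelConfig(omega=0.0, epsilon=0.3, n_group=100, v_total=1.0, c_total=2.0)
        res = StrategyPair.from_class_strategies(0.5, 0.5, cfg)
        assert mutant_group_hawk_probability(res, 1.0, "follower", cfg) == 0.5

    @settings(max_examples=100, derandomize=True)
    @given(configs(), st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
    def test_matches_recomputed_group_mean(self, cfg, pl, pf, mutant_p):
        """Replacing one leader's vote and re-pooling the group mean must
        reproduce the perturbation formula exactly (requires integer
        leader/follower counts, so snap epsilon to a grid of N)."""
        n_lead = max(1, min(cfg.n_group - 1, round(cfg.epsilon * cfg.n_group)))
        cfg = cfg.with_(epsilon=n_lead / cfg.n_group)
        res = StrategyPair.from_class_strategies(pl, pf, cfg)
        mean_l = pl + (mutant_p - pl) / n_lead
        expected = collective_hawk_probability(mean_l, pf, cfg.omega, cfg.epsilon)
        q = mutant_group_hawk_probability(res, mutant_p, "leader", cfg)
        assert q == pytest.approx(expected, abs=1e-12)

    def test_large_excursion_is_an_error_not_a_clamp(self, baseline_config):
        # a mis-wired call (resident strategies inconsistent with p_group)
        # pushes the perturbation formula past 1 by far more than round-off
        tiny = baseline_config.with_(n_group=2, epsilon=0.5)
        with pytest.raises(InvalidPerturbationError):
            mutant_group_hawk_probability(
                StrategyPair(p_leader=0.0, p_follower=1.0, p_group=1.0),
                1.0,
                "leader",
                tiny,
            )
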