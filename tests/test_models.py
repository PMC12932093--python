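"""The six choice models: states, probabilities, updates, likelihoods."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metamoral.models import (
    BetaState,
    ModelId,
    ModelParams,
    QState,
    choice_prob,
    init_state,
    loglik_vectorized,
    param_names,
    sequence_loglik,
    update_state,
)
from metamoral.paradigm import (
    Choice,
    Condition,
    Framing,
    ParticipantData,
    build_default_paradigm,
    make_trial,
)
from metamoral.priors import sample_params

DILEMMAS = build_default_paradigm()


def _trial(t=1, dilemma_idx=0, choice=Choice.YES, condition=Condition.CBR_SUCCESS, rating=80.0):
    return make_trial(t, DILEMMAS[dilemma_idx], choice, condition, rating)


class TestInitState:
    def test_mf_starts_neutral(self):
        st_ = init_state(ModelId.MF_M, ModelParams(alpha=0.3, tau=2.0))
        assert isinstance(st_, QState)
        assert np.array_equal(st_.q, [0.0, 0.0])

    def test_mb_starts_at_symmetric_prior(self):
        st_ = init_state(ModelId.MB_M, ModelParams(a0=2.5, tau=1.0))
        assert isinstance(st_, BetaState)
        assert np.array_equal(st_.counts, [[2.5, 2.5], [2.5, 2.5]])
        assert np.allclose(st_.posterior_means(), 0.5)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            init_state(ModelId.MF_M, ModelParams(alpha=1.5, tau=1.0))
        with pytest.raises(ValueError):
            init_state(ModelId.MB_B, ModelParams(a0=-1.0, tau=1.0))
        with pytest.raises(ValueError):
            init_state(ModelId.C_M, ModelParams(theta=2.0))


class TestChoiceProb:
    def test_softmax_symmetry_gives_half(self):
        params = ModelParams(alpha=0.5, tau=7.3)
        state = QState(q=np.array([0.42, 0.42]))
        for framing in Framing:
            assert choice_prob(ModelId.MF_M, state, params, framing) == pytest.approx(0.5)

    def test_mf_softmax_value(self):
        # Q_CBR = 1, Q_rule = 0, tau = 1, CBR-framed: p(yes) = e/(e+1)
        params = ModelParams(alpha=0.5, tau=1.0)
        state = QState(q=np.array([1.0, 0.0]))
        p = choice_prob(ModelId.MF_M, state, params, Framing.CBR_ACTION)
        assert p == pytest.approx(math.e / (math.e + 1.0), rel=1e-12)
        # rule-framed flips to the complement
        q = choice_prob(ModelId.MF_M, state, params, Framing.RULE_ACTION)
        assert p + q == pytest.approx(1.0)

    def test_mb_initialization_gives_half(self):
        params = ModelParams(a0=3.0, tau=11.0)
        state = init_state(ModelId.MB_M, params)
        for framing in Framing:
            assert choice_prob(ModelId.MB_M, state, params, framing) == pytest.approx(0.5)

    def test_constant_model_framing_mapping(self):
        params = ModelParams(theta=0.7)
        state = init_state(ModelId.C_M, params)
        assert choice_prob(ModelId.C_M, state, params, Framing.CBR_ACTION) == pytest.approx(0.7)
        assert choice_prob(ModelId.C_M, state, params, Framing.RULE_ACTION) == pytest.approx(0.3)
        # behaviour-space constant ignores framing
        params_b = ModelParams(theta=0.7)
        state_b = init_state(ModelId.C_B, params_b)
        for framing in Framing:
            assert choice_prob(ModelId.C_B, state_b, params_b, framing) == pytest.approx(0.7)


class TestUpdateState:
    def test_mf_one_step(self):
        params = ModelParams(alpha=0.5, tau=1.0)
        state = init_state(ModelId.MF_M, params)
        trial = _trial(choice=Choice.YES, rating=80.0)  # chosen strategy CBR, mj 0.8
        new = update_state(ModelId.MF_M, state, params, trial)
        assert new.q[0] == pytest.approx(0.4)
        assert new.q[1] == 0.0

    def test_mf_full_learning_rate_jumps_to_mj(self):
        params = ModelParams(alpha=1.0, tau=1.0)
        state = QState(q=np.array([-0.6, 0.2]))
        trial = _trial(choice=Choice.YES, rating=55.0)
        new = update_state(ModelId.MF_M, state, params, trial)
        assert new.q[0] == pytest.approx(0.55)
        assert new.q[1] == pytest.approx(0.2)

    def test_mb_counting(self):
        params = ModelParams(a0=2.0, tau=1.0)
        state = init_state(ModelId.MB_M, params)
        # chosen = CBR with mj > 0 twice, then mj < 0 once
        good = _trial(choice=Choice.YES, rating=50.0)
        for _ in range(2):
            state = update_state(ModelId.MB_M, state, params, good)
        bad = make_trial(1, DILEMMAS[0], Choice.YES, Condition.RULE_SUCCESS, -40.0)
        state = update_state(ModelId.MB_M, state, params, bad)
        assert np.array_equal(state.counts[0], [4.0, 3.0])
        assert state.posterior_means()[0] == pytest.approx(4.0 / 7.0)
        assert np.array_equal(state.counts[1], [2.0, 2.0])

    def test_zero_rating_updates_nothing_mb(self):
        params = ModelParams(a0=2.0, tau=1.0)
        state = init_state(ModelId.MB_M, params)
        trial = _trial(rating=0.0)
        new = update_state(ModelId.MB_M, state, params, trial)
        assert np.array_equal(new.counts, state.counts)

    def test_constant_model_is_stateless(self):
        params = ModelParams(theta=0.3)
        state = init_state(ModelId.C_B, params)
        assert update_state(ModelId.C_B, state, params, _trial()) is not None

    @given(
        q0=st.floats(-1, 1),
        mj=st.floats(-1, 1),
        alpha=st.floats(0, 1),
    )
    @settings(deadline=None, max_examples=200)
    def test_mf_contraction(self, q0, mj, alpha):
        """Q moves toward mj and never overshoots past it."""
        params = ModelParams(alpha=alpha, tau=1.0)
        state = QState(q=np.array([q0, 0.0]))
        trial = make_trial(
            1, DILEMMAS[0], Choice.YES,
            Condition.CBR_SUCCESS if mj >= 0 else Condition.RULE_SUCCESS,
            rating=mj * 100,
        )
        new = update_state(ModelId.MF_M, state, params, trial)
        lo, hi = min(q0, mj), max(q0, mj)
        assert lo - 1e-12 <= new.q[0] <= hi + 1e-12

    def test_mb_pseudocount_conservation(self, mixed_participants):
        """Total pseudo-count is 4*a0 + number of nonzero-mj trials."""
        params = ModelParams(a0=1.7, tau=2.0)
        for p in mixed_participants:
            state = init_state(ModelId.MB_B, params)
            nonzero = 0
            for tr in p.trials:
                state = update_state(ModelId.MB_B, state, params, tr)
                nonzero += tr.mj != 0
            assert state.counts.sum() == pytest.approx(4 * 1.7 + nonzero)

    def test_mj_out_of_range_rejected(self):
        params = ModelParams(alpha=0.5, tau=1.0)
        state = init_state(ModelId.MF_M, params)
        trial = _trial(rating=90.0)
        object.__setattr__(trial, "rating", 150.0)
        with pytest.raises(ValueError, match="mj"):
            update_state(ModelId.MF_M, state, params, trial)


class TestSequenceLoglik:
    def test_fair_coin_equivalences(self, mixed_participants):
        """MF with alpha=0, MB with tau=0 and C with theta=0.5 all reduce
        to a fair coin over any data."""
        p = mixed_participants[0]
        n = len(p.trials)
        expected = n * math.log(0.5)
        assert sequence_loglik(ModelId.C_M, ModelParams(theta=0.5), p) == pytest.approx(expected)
        assert sequence_loglik(ModelId.C_B, ModelParams(theta=0.5), p) == pytest.approx(expected)
        assert sequence_loglik(ModelId.MF_M, ModelParams(alpha=0.0, tau=3.7), p) == pytest.approx(expected)
        assert sequence_loglik(ModelId.MB_B, ModelParams(a0=2.0, tau=0.0), p) == pytest.approx(expected)
        assert expected == pytest.approx(-9.0109, abs=1e-3)  # 13 trials

    def test_empty_trials_warns_and_returns_zero(self):
        p = ParticipantData("empty", Condition.CBR_SUCCESS, [])
        with pytest.warns(UserWarning):
            assert sequence_loglik(ModelId.C_M, ModelParams(theta=0.3), p) == 0.0

    def test_vectorized_matches_scalar(self, mixed_participants):
        """loglik_vectorized agrees with the scalar recursion everywhere."""
        rng = np.random.default_rng(7)
        for p in mixed_participants[:6]:
            for model in ModelId:
                params = sample_params(model, rng)
                scalar = sequence_loglik(model, params, p)
                kwargs = {
                    name: np.array([getattr(params, name)])
                    for name in param_names(model)
                }
                vec = loglik_vectorized(model, p, **kwargs)
                assert vec.shape == (1,)
                assert vec[0] == pytest.approx(scalar, rel=1e-10)

    def test_choice_probabilities_sum_to_one(self, mixed_participants):
        rng = np.random.default_rng(11)
        p = mixed_participants[1]
        for model in ModelId:
            params = sample_params(model, rng)
            state = init_state(model, params)
            for tr in p.trials:
                p_yes = choice_prob(model, state, params, tr.framing)
                assert 0.0 <= p_yes <= 1.0
                state = update_state(model, state, params, tr)

    def test_framing_covariance(self):
        """Flipping framing and choice together preserves the strategy-space
        likelihood but changes the behaviour-space one (the deconfound)."""
        cond = Condition.CBR_SUCCESS
        cbr_dilemma = DILEMMAS[0]     # cbr_action framing
        rule_dilemma = DILEMMAS[-1]   # rule_action framing
        # same strategy sequence (CBR, CBR) expressed through opposite framings
        p1 = ParticipantData("a", cond, [
            make_trial(1, cbr_dilemma, Choice.YES, cond, 60.0),
            make_trial(2, cbr_dilemma, Choice.YES, cond, 60.0),
        ])
        p2 = ParticipantData("b", cond, [
            make_trial(1, cbr_dilemma, Choice.YES, cond, 60.0),
            make_trial(2, rule_dilemma, Choice.NO, cond, 60.0),
        ])
        strat_params = ModelParams(alpha=0.6, tau=4.0)
        assert sequence_loglik(ModelId.MF_M, strat_params, p1) == pytest.approx(
            sequence_loglik(ModelId.MF_M, strat_params, p2)
        )
        assert sequence_loglik(ModelId.MF_B, strat_params, p1) != pytest.approx(
            sequence_loglik(ModelId.MF_B, strat_params, p2)
        )
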