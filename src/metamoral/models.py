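"""Six models of trial-by-trial choice in the moral-learning paradigm.

Two axes define the model space. The *learning space* is either the
decision strategy (rely on cost-benefit reasoning vs. on moral rules;
"metacognitive" models, suffix ``-M``) or the behaviour itself (perform
the action under consideration vs. omit it; "behavioural" models, suffix
``-B``). The *learning rule* is model-free Q-learning (``MF-``),
model-based beta-Bernoulli updating of outcome probabilities (``MB-``),
or no learning at all (constant choice rate, ``C-``).

Model-free learners hold one Q-value per unit (strategy or behaviour),
initialized at 0, and after each trial move the chosen unit's value toward
the participant's moral evaluation ``mj`` in [-1, 1]:

    MPE_t = Q_t(chosen) - mj_t
    Q_{t+1}(chosen) = Q_t(chosen) - alpha * MPE_t

Choices follow a softmax over the two Q-values with inverse temperature
``tau``. Model-based learners keep a symmetric Beta(a0, a0) prior per unit
over the probability that the unit produces a good outcome and increment
the good (bad) pseudo-count of the chosen unit when mj > 0 (mj < 0);
choices follow a softmax over the two Beta posterior means. An evaluation
of exactly 0 updates neither count. Constant models choose the first unit
(CBR / action) with a fixed rate ``theta``.

Strategy-space choice probabilities are mapped to the observed yes/no
response through the dilemma's framing; behaviour-space probabilities are
the probability of "yes" (action) directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Union
import warnings

import numpy as np

from .paradigm import (
    Behaviour,
    Framing,
    ParticipantData,
    Strategy,
    Trial,
)

__all__ = [
    "ModelId",
    "ModelParams",
    "QState",
    "BetaState",
    "ConstState",
    "LatentState",
    "MODEL_FAMILIES",
    "init_state",
    "choice_prob",
    "update_state",
    "sequence_loglik",
    "loglik_vectorized",
    "param_names",
]


class ModelId(str, Enum):
    MF_M = "MF-M"
    MB_M = "MB-M"
    C_M = "C-M"
    MF_B = "MF-B"
    MB_B = "MB-B"
    C_B = "C-B"

    @property
    def space(self) -> str:
        """'strategy' for metacognitive models, 'behaviour' for behavioural."""
        return "strategy" if self.value.endswith("-M") else "behaviour"

    @property
    def kind(self) -> str:
        """'mf' (Q-learning), 'mb' (beta-Bernoulli) or 'c' (constant)."""
        return {"MF": "mf", "MB": "mb", "C": "c"}[self.value.split("-")[0]]

    @property
    def family(self) -> str:
        if self.kind == "c":
            return "no_learning"
        return "metacognitive" if self.space == "strategy" else "behavioural"


#: Default partition used for family-level inference.
MODEL_FAMILIES: dict[str, tuple[ModelId, ...]] = {
    "metacognitive": (ModelId.MB_M, ModelId.MF_M),
    "behavioural": (ModelId.MB_B, ModelId.MF_B),
    "no_learning": (ModelId.C_M, ModelId.C_B),
}


@dataclass(frozen=True)
class ModelParams:
    """Free parameters; only the fields a model uses may be set.

    alpha: MF learning rate in [0, 1].
    tau:   softmax inverse temperature, > 0 (MF and MB models).
    a0:    MB symmetric Beta prior pseudo-count, > 0.
    theta: constant choice rate in [0, 1] (C models).
    """

    alpha: float | None = None
    tau: float | None = None
    a0: float | None = None
    theta: float | None = None

    def validate(self, model_id: ModelId) -> None:
        kind = ModelId(model_id).kind
        if kind == "mf":
            if self.alpha is None or not 0.0 <= self.alpha <= 1.0:
                raise ValueError(f"MF model needs alpha in [0, 1], got {self.alpha}")
            if self.tau is None or self.tau < 0:
                raise ValueError(f"MF model needs tau >= 0, got {self.tau}")
        elif kind == "mb":
            if self.a0 is None or self.a0 <= 0:
                raise ValueError(f"MB model needs a0 > 0, got {self.a0}")
            if self.tau is None or self.tau < 0:
                raise ValueError(f"MB model needs tau >= 0, got {self.tau}")
        else:
            if self.theta is None or not 0.0 <= self.theta <= 1.0:
                raise ValueError(f"C model needs theta in [0, 1], got {self.theta}")


def param_names(model_id: ModelId) -> tuple[str, ...]:
    """Names of the free parameters of a model, in canonical order."""
    return {
        "mf": ("alpha", "tau"),
        "mb": ("a0", "tau"),
        "c": ("theta",),
    }[ModelId(model_id).kind]


# --- latent state ---------------------------------------------------------
# Unit 0 is CBR (strategy space) or action (behaviour space); unit 1 is
# rules or omission.


@dataclass
class QState:
    q: np.ndarray  # shape (2,), values in [-1, 1]


@dataclass
class BetaState:
    counts: np.ndarray  # shape (2, 2): [[good0, bad0], [good1, bad1]]

    def posterior_means(self) -> np.ndarray:
        return self.counts[:, 0] / self.counts.sum(axis=1)


@dataclass
class ConstState:
    pass


LatentState = Union[QState, BetaState, ConstState]


def init_state(model_id: ModelId, params: ModelParams) -> LatentState:
    model_id = ModelId(model_id)
    params.validate(model_id)
    kind = model_id.kind
    if kind == "mf":
        return QState(q=np.zeros(2))
    if kind == "mb":
        return BetaState(counts=np.full((2, 2), float(params.a0)))
    return ConstState()


def _chosen_unit(model_id: ModelId, trial: Trial) -> int:
    if model_id.space == "strategy":
        return 0 if trial.strategy is Strategy.CBR else 1
    return 0 if trial.behaviour is Behaviour.ACTION else 1


def _p_unit0(model_id: ModelId, state: LatentState, params: ModelParams) -> float:
    """Probability of choosing unit 0 (CBR or action)."""
    kind = model_id.kind
    if kind == "mf":
        assert isinstance(state, QState), "MF model requires QState"
        delta = state.q[0] - state.q[1]
    elif kind == "mb":
        assert isinstance(state, BetaState), "MB model requires BetaState"
        means = state.posterior_means()
        delta = means[0] - means[1]
    else:
        return float(params.theta)
    # softmax over two units == logistic of the scaled value difference
    return float(1.0 / (1.0 + np.exp(-params.tau * delta)))


def choice_prob(
    model_id: ModelId,
    state: LatentState,
    params: ModelParams,
    framing: Framing,
) -> float:
    """Probability that the participant answers 'yes' on this trial."""
    model_id = ModelId(model_id)
    p0 = _p_unit0(model_id, state, params)
    if model_id.space == "behaviour":
        return p0  # unit 0 is the action; 'yes' == perform it
    framing = Framing(framing)
    return p0 if framing is Framing.CBR_ACTION else 1.0 - p0


def update_state(
    model_id: ModelId,
    state: LatentState,
    params: ModelParams,
    trial: Trial,
) -> LatentState:
    """Return the post-trial state; the input state is not mutated."""
    model_id = ModelId(model_id)
    mj = trial.mj
    if not -1.0 <= mj <= 1.0:
        raise ValueError(f"moral evaluation mj={mj} outside [-1, 1]")
    unit = _chosen_unit(model_id, trial)
    kind = model_id.kind
    if kind == "mf":
        assert isinstance(state, QState)
        q = state.q.copy()
        mpe = q[unit] - mj
        q[unit] = q[unit] - params.alpha * mpe
        return QState(q=q)
    if kind == "mb":
        assert isinstance(state, BetaState)
        counts = state.counts.copy()
        if mj > 0:
            counts[unit, 0] += 1.0
        elif mj < 0:
            counts[unit, 1] += 1.0
        # mj == 0: neither indicator fires, no update
        return BetaState(counts=counts)
    return ConstState()


def sequence_loglik(
    model_id: ModelId,
    params: ModelParams,
    participant: ParticipantData,
) -> float:
    """Log-likelihood of a participant's ordered choice sequence.

    Interleaves prediction and learning: each trial contributes
    log p(observed choice | state before the trial), then the state is
    updated with that trial's chosen unit and moral evaluation.
    """
    model_id = ModelId(model_id)
    if not participant.trials:
        warnings.warn("empty trial list: log-likelihood is 0 by convention")
        return 0.0
    state = init_state(model_id, params)
    total = 0.0
    for trial in participant.trials:
        p_yes = choice_prob(model_id, state, params, trial.framing)
        p_obs = p_yes if trial.choice.value == "yes" else 1.0 - p_yes
        with np.errstate(divide="ignore"):
            total += float(np.log(p_obs))
        state = update_state(model_id, state, params, trial)
    return total


# --- vectorized likelihood (used by quadrature and Monte-Carlo fitting) ---


def _trial_arrays(model_id: ModelId, participant: ParticipantData):
    """Per-trial chosen-unit indices, observed-unit signs and evaluations.

    sign_t is +1 when the observed choice corresponds to unit 0 (CBR or
    action), -1 otherwise, so that p(observed) = logistic(sign * logit0).
    """
    trials = participant.trials
    chosen = np.array([_chosen_unit(model_id, tr) for tr in trials], dtype=np.int64)
    sign = np.where(chosen == 0, 1.0, -1.0)
    mj = np.array([tr.mj for tr in trials])
    return chosen, sign, mj


def loglik_vectorized(
    model_id: ModelId,
    participant: ParticipantData,
    **params_arrays: np.ndarray,
) -> np.ndarray:
    """Sequence log-likelihood evaluated at arrays of parameter values.

    Keyword arguments name the model's free parameters (see
    :func:`param_names`); arrays must broadcast against each other and the
    result has the broadcast shape. Exact same recursion as
    :func:`sequence_loglik`, vectorized across parameter values.
    """
    model_id = ModelId(model_id)
    expected = set(param_names(model_id))
    if set(params_arrays) != expected:
        raise ValueError(
            f"{model_id.value} expects parameters {sorted(expected)}, "
            f"got {sorted(params_arrays)}"
        )
    if not participant.trials:
        warnings.warn("empty trial list: log-likelihood is 0 by convention")
        shape = np.broadcast_shapes(*(np.shape(v) for v in params_arrays.values()))
        return np.zeros(shape)

    chosen, sign, mj = _trial_arrays(model_id, participant)
    n = len(chosen)
    kind = model_id.kind

    if kind == "c":
        theta = np.asarray(params_arrays["theta"], dtype=float)
        k = int((sign > 0).sum())  # choices of unit 0
        with np.errstate(divide="ignore", invalid="ignore"):
            out = k * np.log(theta) + (n - k) * np.log1p(-theta)
        # 0 * log(0) = 0 by continuity at the support edges
        if k == 0:
            out = np.where(theta == 0.0, (n - k) * np.log1p(-theta), out)
        if k == n:
            out = np.where(theta == 1.0, k * np.log(theta), out)
        return out

    tau = np.asarray(params_arrays["tau"], dtype=float)
    if kind == "mf":
        alpha = np.asarray(params_arrays["alpha"], dtype=float)
        alpha_b, tau_b = np.broadcast_arrays(alpha, tau)
        shape = alpha_b.shape
        q = np.zeros(shape + (2,))
        total = np.zeros(shape)
        for t in range(n):
            delta = q[..., 0] - q[..., 1]
            total += -np.logaddexp(0.0, -sign[t] * tau_b * delta)
            u = chosen[t]
            q[..., u] = (1.0 - alpha_b) * q[..., u] + alpha_b * mj[t]
        return total

    # model-based: Beta posterior means depend on a0 and the running counts,
    # which are parameter-independent and can be accumulated once
    a0 = np.asarray(params_arrays["a0"], dtype=float)
    a0_b, tau_b = np.broadcast_arrays(a0, tau)
    good = np.zeros(2)
    bad = np.zeros(2)
    total = np.zeros(a0_b.shape)
    for t in range(n):
        mean0 = (a0_b + good[0]) / (2.0 * a0_b + good[0] + bad[0])
        mean1 = (a0_b + good[1]) / (2.0 * a0_b + good[1] + bad[1])
        total += -np.logaddexp(0.0, -sign[t] * tau_b * (mean0 - mean1))
        u = chosen[t]
        if mj[t] > 0:
            good[u] += 1.0
        elif mj[t] < 0:
            bad[u] += 1.0
    return total
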