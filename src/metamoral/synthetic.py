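"""Simulated cohorts for the moral-learning paradigm.

Stands in for the real trial-level study data: simulates participants from
any of the six choice models under either condition, with outcomes that
follow the paradigm's deterministic valence logic and moral-evaluation
ratings whose sign matches the outcome valence (pilot calibration of the
real materials found all good outcomes rated > 0 and all bad ones < 0).

Rating magnitudes are drawn uniformly from ``magnitude_range`` (default
(0.3, 1.0) on the mj scale): only the sign of the evaluation is constrained
by the study materials, and keeping |mj| away from zero keeps the
model-free learning signal informative. ``evaluation_noise`` is the
probability that a rating's sign is flipped relative to the outcome
valence (default 0: fully congruent, as in the deterministic paradigm).
Ratings are never exactly 0 so the beta-Bernoulli sign indicators always
fire on simulated data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import ModelId, ModelParams, choice_prob, init_state, param_names, update_state
from .paradigm import (
    Choice,
    Condition,
    DilemmaSpec,
    ParticipantData,
    Valence,
    build_default_paradigm,
    make_trial,
)
from .priors import sample_params

__all__ = [
    "SimulationSpec",
    "generate_moral_evaluation",
    "simulate_participant",
    "simulate_cohort",
]

DEFAULT_MAGNITUDE_RANGE = (0.3, 1.0)


@dataclass
class SimulationSpec:
    """Configuration for one simulated cohort.

    ``params=None`` samples each participant's parameters independently
    from the fitting priors (as in model-recovery studies).
    """

    model_id: ModelId
    condition: Condition
    n_participants: int
    params: ModelParams | None = None
    n_trials: int = 13
    evaluation_noise: float = 0.0
    magnitude_range: tuple[float, float] = DEFAULT_MAGNITUDE_RANGE
    seed: int = 0

    def __post_init__(self) -> None:
        self.model_id = ModelId(self.model_id)
        self.condition = Condition(self.condition)
        if self.n_participants < 0:
            raise ValueError("n_participants must be >= 0")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not 0.0 <= self.evaluation_noise <= 1.0:
            raise ValueError("evaluation_noise must lie in [0, 1]")
        lo, hi = self.magnitude_range
        if not 0.0 < lo <= hi <= 1.0:
            raise ValueError("magnitude_range must satisfy 0 < lo <= hi <= 1")


def generate_moral_evaluation(
    valence: Valence,
    evaluation_noise: float,
    magnitude_range: tuple[float, float],
    rng: np.random.Generator,
) -> float:
    """Draw a -100..100 rating whose sign is congruent with valence.

    With probability ``evaluation_noise`` the sign is flipped. The
    magnitude is 100 x Uniform(magnitude_range), rounded to the integer
    rating scale the task uses; never exactly 0.
    """
    if not 0.0 <= evaluation_noise <= 1.0:
        raise ValueError("evaluation_noise must lie in [0, 1]")
    lo, hi = magnitude_range
    if not 0.0 < lo <= hi <= 1.0:
        raise ValueError("magnitude_range must satisfy 0 < lo <= hi <= 1")
    magnitude = max(1.0, float(np.rint(100.0 * rng.uniform(lo, hi))))
    sign = 1.0 if Valence(valence) is Valence.GOOD else -1.0
    if rng.random() < evaluation_noise:
        sign = -sign
    return sign * magnitude


def _extend_paradigm(paradigm: list[DilemmaSpec], n_trials: int) -> list[DilemmaSpec]:
    """Cycle the dilemma list to cover longer simulated sequences."""
    if n_trials <= len(paradigm):
        return paradigm[:n_trials]
    reps = -(-n_trials // len(paradigm))
    return (paradigm * reps)[:n_trials]


def simulate_participant(
    model_id: ModelId,
    params: ModelParams,
    condition: Condition,
    rng: np.random.Generator,
    paradigm: list[DilemmaSpec] | None = None,
    n_trials: int = 13,
    evaluation_noise: float = 0.0,
    magnitude_range: tuple[float, float] = DEFAULT_MAGNITUDE_RANGE,
    participant_id: str = "sim",
) -> ParticipantData:
    """Simulate one participant's full trial sequence from a model.

    Each trial: the model's current state gives p(yes) through the
    dilemma's framing; the choice is drawn; strategy, behaviour and the
    deterministic outcome valence are derived; a rating is drawn; and the
    model state is updated with the chosen unit and the evaluation.
    """
    model_id = ModelId(model_id)
    params.validate(model_id)
    if paradigm is None:
        paradigm = build_default_paradigm()
    dilemmas = _extend_paradigm(paradigm, n_trials)
    state = init_state(model_id, params)
    out = ParticipantData(participant_id=participant_id, condition=Condition(condition))
    for t, dilemma in enumerate(dilemmas, start=1):
        p_yes = choice_prob(model_id, state, params, dilemma.framing)
        choice = Choice.YES if rng.random() < p_yes else Choice.NO
        trial = make_trial(
            t=t,
            dilemma=dilemma,
            choice=choice,
            condition=out.condition,
            rating=0.0,
        )
        rating = generate_moral_evaluation(
            trial.valence, evaluation_noise, magnitude_range, rng
        )
        trial = make_trial(t=t, dilemma=dilemma, choice=choice,
                           condition=out.condition, rating=rating)
        state = update_state(model_id, state, params, trial)
        out.trials.append(trial)
    return out


def simulate_cohort(spec: SimulationSpec) -> tuple[list[ParticipantData], pd.DataFrame]:
    """Simulate a cohort and return (participants, ground-truth table).

    The truth table has one row per participant with the generating model
    and its parameter values, for parameter- and model-recovery studies.
    Fully reproducible given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    participants: list[ParticipantData] = []
    rows: list[dict] = []
    names = param_names(spec.model_id)
    for i in range(spec.n_participants):
        params = spec.params if spec.params is not None else sample_params(spec.model_id, rng)
        pid = f"{spec.model_id.value}_{spec.condition.value}_{i:04d}"
        participants.append(
            simulate_participant(
                spec.model_id,
                params,
                spec.condition,
                rng,
                n_trials=spec.n_trials,
                evaluation_noise=spec.evaluation_noise,
                magnitude_range=spec.magnitude_range,
                participant_id=pid,
            )
        )
        row = {"participant_id": pid, "model_id": spec.model_id.value,
               "condition": spec.condition.value}
        for name in names:
            row[name] = getattr(params, name)
        rows.append(row)
    truth = pd.DataFrame(rows, columns=["participant_id", "model_id", "condition", *names])
    return participants, truth
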