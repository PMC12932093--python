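"""Structure of the moral-learning paradigm.

Participants face a fixed series of 13 moral dilemmas. In each dilemma a
yes/no question asks whether they would perform a particular action. In
eight dilemmas the action under consideration is the option favoured by
cost-benefit reasoning (CBR), e.g. "Do you push the man?"; in the other
five it is the option prescribed by a moral rule, e.g. "Do you quit your
job?". This framing deconfounds the action/omission distinction from the
rule/CBR distinction: saying "yes" is always an *action*, but which
*strategy* it expresses depends on the framing.

Each participant is assigned to one of two conditions that deterministically
fix outcome valence: in CBR Success the CBR option always produces an
overall good outcome and the rule option an overall bad one; in Rule
Success the mapping is reversed. After seeing the outcome, participants
rate how good or bad it was on a -100..100 scale; dividing by 100 yields
the moral evaluation ``mj`` in [-1, 1] that drives learning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
__all__ = [
    "Framing",
    "Condition",
    "Choice",
    "Strategy",
    "Behaviour",
    "Valence",
    "DilemmaSpec",
    "Trial",
    "ParticipantData",
    "build_default_paradigm",
    "strategy_of_choice",
    "behaviour_of_choice",
    "choice_of_strategy",
    "outcome_valence",
    "validate_participant",
    "N_DILEMMAS",
    "N_CBR_FRAMED",
    "N_RULE_FRAMED",
]

N_DILEMMAS = 13
N_CBR_FRAMED = 8
N_RULE_FRAMED = 5


class Framing(str, Enum):
    """Which option the 'yes' action corresponds to."""

    CBR_ACTION = "cbr_action"
    RULE_ACTION = "rule_action"


class Condition(str, Enum):
    """Which strategy's option deterministically yields good outcomes."""

    CBR_SUCCESS = "cbr_success"
    RULE_SUCCESS = "rule_success"


class Choice(str, Enum):
    YES = "yes"
    NO = "no"


class Strategy(str, Enum):
    CBR = "CBR"
    RULE = "rule"


class Behaviour(str, Enum):
    ACTION = "action"
    OMISSION = "omission"


class Valence(str, Enum):
    GOOD = "good"
    BAD = "bad"


@dataclass(frozen=True)
class DilemmaSpec:
    """Framing metadata for one dilemma."""

    dilemma_id: int
    framing: Framing
    label: str = ""


@dataclass(frozen=True)
class Trial:
    """One decision with its outcome and the participant's evaluation.

    ``strategy`` and ``behaviour`` are derived from (framing, choice);
    ``valence`` from (condition, strategy); ``mj = rating / 100``.
    """

    t: int
    dilemma_id: int
    framing: Framing
    choice: Choice
    strategy: Strategy
    behaviour: Behaviour
    valence: Valence
    rating: float

    @property
    def mj(self) -> float:
        return self.rating / 100.0


@dataclass
class ParticipantData:
    participant_id: str
    condition: Condition
    trials: list[Trial] = field(default_factory=list)


def build_default_paradigm() -> list[DilemmaSpec]:
    """Return the 13-dilemma paradigm: 8 CBR-framed then 5 rule-framed.

    Order is fixed and deterministic; callers wanting a randomized order
    should shuffle with their own seeded RNG.
    """
    specs = [
        DilemmaSpec(i, Framing.CBR_ACTION, f"cbr_framed_{i}")
        for i in range(1, N_CBR_FRAMED + 1)
    ]
    specs += [
        DilemmaSpec(i, Framing.RULE_ACTION, f"rule_framed_{i}")
        for i in range(N_CBR_FRAMED + 1, N_DILEMMAS + 1)
    ]
    return specs


def strategy_of_choice(framing: Framing, choice: Choice) -> Strategy:
    """Map a yes/no choice to the decision strategy it expresses."""
    framing = Framing(framing)
    choice = Choice(choice)
    if framing is Framing.CBR_ACTION:
        return Strategy.CBR if choice is Choice.YES else Strategy.RULE
    return Strategy.RULE if choice is Choice.YES else Strategy.CBR


def choice_of_strategy(framing: Framing, strategy: Strategy) -> Choice:
    """Inverse of :func:`strategy_of_choice` for a given framing."""
    framing = Framing(framing)
    strategy = Strategy(strategy)
    if framing is Framing.CBR_ACTION:
        return Choice.YES if strategy is Strategy.CBR else Choice.NO
    return Choice.YES if strategy is Strategy.RULE else Choice.NO


def behaviour_of_choice(choice: Choice) -> Behaviour:
    """Saying yes is performing the action under consideration."""
    choice = Choice(choice)
    return Behaviour.ACTION if choice is Choice.YES else Behaviour.OMISSION


def outcome_valence(condition: Condition, strategy: Strategy) -> Valence:
    """Deterministic outcome valence: the condition's winning strategy is good."""
    condition = Condition(condition)
    strategy = Strategy(strategy)
    if condition is Condition.CBR_SUCCESS:
        return Valence.GOOD if strategy is Strategy.CBR else Valence.BAD
    return Valence.GOOD if strategy is Strategy.RULE else Valence.BAD


def make_trial(
    t: int,
    dilemma: DilemmaSpec,
    choice: Choice,
    condition: Condition,
    rating: float,
) -> Trial:
    """Build a Trial with all derived fields filled in consistently."""
    if not -100 <= rating <= 100:
        raise ValueError(f"rating {rating} outside [-100, 100]")
    strategy = strategy_of_choice(dilemma.framing, choice)
    return Trial(
        t=t,
        dilemma_id=dilemma.dilemma_id,
        framing=dilemma.framing,
        choice=Choice(choice),
        strategy=strategy,
        behaviour=behaviour_of_choice(choice),
        valence=outcome_valence(condition, strategy),
        rating=rating,
    )


def validate_participant(p: ParticipantData) -> None:
    """Check internal consistency of a participant's trial sequence.

    Raises ValueError on the first violated invariant: non-consecutive
    trial indices, derived fields inconsistent with (framing, choice),
    valence inconsistent with (condition, strategy), or rating out of range.
    """
    for i, tr in enumerate(p.trials, start=1):
        ctx = f"participant {p.participant_id!r}, trial {tr.t}"
        if tr.t != i:
            raise ValueError(f"{ctx}: trial indices must be consecutive from 1")
        if not -100 <= tr.rating <= 100:
            raise ValueError(f"{ctx}: rating {tr.rating} outside [-100, 100]")
        if tr.strategy != strategy_of_choice(tr.framing, tr.choice):
            raise ValueError(f"{ctx}: strategy inconsistent with framing/choice")
        if tr.behaviour != behaviour_of_choice(tr.choice):
            raise ValueError(f"{ctx}: behaviour inconsistent with choice")
        if tr.valence != outcome_valence(p.condition, tr.strategy):
            raise ValueError(f"{ctx}: valence inconsistent with condition/strategy")
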