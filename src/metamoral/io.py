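"""Dataset serialization and the pooled learning-curve statistic.

Trial data travel as a flat CSV with one row per trial:

    participant_id, condition, trial, dilemma_id, framing, choice,
    valence, rating

with condition in {cbr_success, rule_success}, framing in {cbr_action,
rule_action}, choice in {yes, no}, valence in {good, bad} and rating an
integer or real in [-100, 100]. Rows are grouped by participant and
ordered by trial; derived fields (strategy, behaviour, mj) are recomputed
on read and validated against the paradigm's outcome logic.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .paradigm import (
    Choice,
    Condition,
    DilemmaSpec,
    Framing,
    ParticipantData,
    Strategy,
    make_trial,
    validate_participant,
)

__all__ = [
    "DATASET_COLUMNS",
    "write_dataset",
    "read_dataset",
    "participants_to_frame",
    "learning_curve_stat",
    "LearningCurveResult",
]

DATASET_COLUMNS = [
    "participant_id",
    "condition",
    "trial",
    "dilemma_id",
    "framing",
    "choice",
    "valence",
    "rating",
]


def participants_to_frame(participants: Sequence[ParticipantData]) -> pd.DataFrame:
    rows = []
    for p in participants:
        for tr in p.trials:
            rows.append(
                {
                    "participant_id": p.participant_id,
                    "condition": p.condition.value,
                    "trial": tr.t,
                    "dilemma_id": tr.dilemma_id,
                    "framing": tr.framing.value,
                    "choice": tr.choice.value,
                    "valence": tr.valence.value,
                    "rating": tr.rating,
                }
            )
    return pd.DataFrame(rows, columns=DATASET_COLUMNS)


def write_dataset(participants: Sequence[ParticipantData], path: str | Path) -> None:
    participants_to_frame(participants).to_csv(path, index=False)


def read_dataset(path: str | Path) -> list[ParticipantData]:
    """Read and validate a trial-level CSV into participant records.

    Schema violations and paradigm inconsistencies (e.g. a valence that
    contradicts the condition's outcome logic) raise ValueError naming the
    offending rows.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset missing columns: {missing}")

    bad = df[~df["rating"].between(-100, 100)]
    if not bad.empty:
        raise ValueError(
            f"rating outside [-100, 100] at rows {list(bad.index + 2)}"  # 1-based + header
        )

    participants: list[ParticipantData] = []
    for pid, group in df.groupby("participant_id", sort=False):
        group = group.sort_values("trial")
        condition = Condition(group["condition"].iloc[0])
        if (group["condition"] != condition.value).any():
            raise ValueError(f"participant {pid!r}: mixed condition values")
        p = ParticipantData(participant_id=str(pid), condition=condition)
        for _, row in group.iterrows():
            dilemma = DilemmaSpec(int(row["dilemma_id"]), Framing(row["framing"]))
            trial = make_trial(
                t=int(row["trial"]),
                dilemma=dilemma,
                choice=Choice(row["choice"]),
                condition=condition,
                rating=float(row["rating"]),
            )
            if trial.valence.value != row["valence"]:
                raise ValueError(
                    f"participant {pid!r}, trial {trial.t}: stored valence "
                    f"{row['valence']!r} contradicts the condition's outcome logic "
                    f"(expected {trial.valence.value!r})"
                )
            p.trials.append(trial)
        validate_participant(p)
        participants.append(p)
    return participants


class LearningCurveResult:
    """Pooled logistic trend of P(choose the CBR option) over trials."""

    def __init__(self, slope: float, stderr: float, zvalue: float,
                 n_obs: int, separable: bool, predictor: str) -> None:
        self.slope = slope
        self.stderr = stderr
        self.zvalue = zvalue
        self.n_obs = n_obs
        self.separable = separable
        self.predictor = predictor

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"LearningCurveResult(slope={self.slope:.4g}, se={self.stderr:.4g}, "
            f"z={self.zvalue:.3g}, n={self.n_obs}, predictor={self.predictor!r})"
        )


def learning_curve_stat(
    participants: Sequence[ParticipantData],
    condition: Condition,
    log_trial: bool = True,
) -> LearningCurveResult:
    """Logistic trend of the CBR-option indicator on (log) trial number.

    Pools all trials of the given condition and fits a plain logistic
    regression of 1{strategy == CBR} on ln(trial) (or raw trial with
    ``log_trial=False``) with an intercept. A positive slope means
    participants increasingly choose the CBR option as trials accumulate.
    Complete separation is flagged (``separable=True``, slope set to
    +/-inf) rather than raised.
    """
    condition = Condition(condition)
    y, x = [], []
    for p in participants:
        if p.condition is not condition:
            continue
        for tr in p.trials:
            y.append(1.0 if tr.strategy is Strategy.CBR else 0.0)
            x.append(np.log(tr.t) if log_trial else float(tr.t))
    if len(set(x)) < 2:
        raise ValueError("need at least two distinct trial indices")
    y_arr = np.asarray(y)
    x_arr = np.asarray(x)
    predictor = "log_trial" if log_trial else "trial"
    if y_arr.min() == y_arr.max():
        # all choices identical: separated; sign from the constant outcome
        sign = 1.0 if y_arr[0] == 1.0 else -1.0
        return LearningCurveResult(sign * np.inf, np.nan, sign * np.inf,
                                   len(y), True, predictor)
    X = sm.add_constant(x_arr)
    try:
        fit = sm.GLM(y_arr, X, family=sm.families.Binomial()).fit()
    except Exception:
        return LearningCurveResult(np.nan, np.nan, np.nan, len(y), True, predictor)
    slope = float(fit.params[1])
    se = float(fit.bse[1])
    if not np.isfinite(se) or se > 1e4:
        return LearningCurveResult(np.sign(slope) * np.inf, np.nan,
                                   np.sign(slope) * np.inf, len(y), True, predictor)
    return LearningCurveResult(slope, se, slope / se, len(y), False, predictor)
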