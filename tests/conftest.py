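import numpy as np
import pytest

from metamoral.models import ModelId, ModelParams
from metamoral.paradigm import Condition
from metamoral.priors import sample_params
from metamoral.synthetic import simulate_participant


def params_for(model_id: ModelId, rng: np.random.Generator) -> ModelParams:
    return sample_params(model_id, rng)


@pytest.fixture(scope="session")
def mixed_participants():
    """One prior-sampled participant per model per condition (12 total)."""
    rng = np.random.default_rng(2024)
    out = []
    for model in ModelId:
        for condition in Condition:
            params = sample_params(model, rng)
            out.append(
                simulate_participant(
                    model, params, condition, rng,
                    participant_id=f"{model.value}_{condition.value}",
                )
            )
    return out
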