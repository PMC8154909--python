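"""Shared fixtures.

The trained-model fixtures are session-scoped and shared by every test
that needs a fitted network (learning, attention-localization and
wave-blanking checks), so the expensive desk-scale training runs once.
"""

from dataclasses import dataclass
from typing import Dict, List

import numpy as np
import pytest

from ecglens.experiments import StudyConfig, TaskModels, make_dataset, \
    train_task_models
from ecglens.synth import LabeledECG, PopulationSpec, generate_population

#: Desk-scale study conditions: 2000 median beats of the default
#: population, one desk-preset model per task.  Epochs per task reflect
#: how quickly each converges (amplitudes are near-linear readouts,
#: durations need longer).
STUDY_SEED = 11
STUDY_EPOCHS = {"QRS": 30, "R_amp": 12, "T_amp": 25, "sex": 20}


def study_config(n: int = 2000) -> StudyConfig:
    return StudyConfig(n=n, seed=STUDY_SEED,
                       tasks=("QRS", "R_amp", "T_amp", "sex"),
                       epochs_by_task=dict(STUDY_EPOCHS))


@dataclass
class Study:
    cfg: StudyConfig
    dataset: List[LabeledECG]
    models: TaskModels


@pytest.fixture(scope="session")
def study() -> Study:
    cfg = study_config()
    dataset = make_dataset(cfg)
    models = train_task_models(cfg, dataset)
    return Study(cfg, dataset, models)


@pytest.fixture(scope="session")
def population_small() -> List[LabeledECG]:
    """200 quiet median beats for cheap structural tests."""
    return generate_population(PopulationSpec(seed=5), 200, "median")


@pytest.fixture(scope="session")
def population_2000() -> List[LabeledECG]:
    """The distribution-check population (generator invariant scale)."""
    return generate_population(PopulationSpec(seed=21), 2000, "median")
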