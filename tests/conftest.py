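"""Shared fixtures: pipeline configuration and the staged phantom study.

The staged study (50 phantoms per stage at 512 px) is expensive, so it is
computed once per session and shared between the morphometry monotonicity
checks and the end-to-end ordinal-fidelity test.
"""

import numpy as np
import pytest

from fibroquant.pipeline import (
    RunConfig,
    staged_phantom_study,
    train_landmark_model_from_phantoms,
)

#: canvas for fast tests: 512 px at the native pitch is a 200 x 200 um
#: field (0.04 mm^2), so the tissue-area floor is scaled accordingly.
SMALL_CONFIG = dict(canvas_px=512, min_tissue_area_mm2=0.02)


@pytest.fixture(scope="session")
def pipeline_config() -> RunConfig:
    return RunConfig(**SMALL_CONFIG)


@pytest.fixture(scope="session")
def landmark_model(pipeline_config):
    return train_landmark_model_from_phantoms(pipeline_config, seed=101, n_phantoms=6)


@pytest.fixture(scope="session")
def staged_run(pipeline_config, landmark_model):
    """50 phantoms per stage, fully processed: (qfp DataFrame, stages)."""
    qfp, stages = staged_phantom_study(
        pipeline_config, n_per_stage=50, seed=2024, landmark_model=landmark_model
    )
    return qfp, np.asarray(stages)
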