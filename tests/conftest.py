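"""Shared fixtures: small synthetic sessions generated once per run."""

import numpy as np
import pytest

from marmonav.config import AnalysisConfig
from marmonav.synthetic import (GeneratorParams, UnitSpec, gen_behavior,
                                gen_session, frame_predictors)


@pytest.fixture(scope="session")
def small_session():
    """600 s session with a handful of tuned units (seed-fixed)."""
    params = GeneratorParams(duration_s=600.0, n_pyr=6, n_int=4, seed=11)
    bundle, truth = gen_session(params)
    return bundle, truth


@pytest.fixture(scope="session")
def behavior_300s():
    """300 s behavior-only trajectory plus ground-truth events."""
    params = GeneratorParams(duration_s=300.0, seed=7)
    pose, events = gen_behavior(params, np.random.default_rng(7))
    return params, pose, events


@pytest.fixture(scope="session")
def predictors_300s(behavior_300s):
    params, pose, _ = behavior_300s
    return frame_predictors(pose, params.maze)


@pytest.fixture()
def cfg():
    return AnalysisConfig()
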