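import numpy as np
import pytest

from exminmod.model_core import ModelParameters
from exminmod.simulate import ForcingFunction
from exminmod.synthetic_cohort import (
    build_schedule,
    default_exercise_trace,
    default_insulin_profile,
    generate_dataset,
)

# the selected variant's reported cross-subject medians; the reference
# virtual subject used throughout the suite
REFERENCE_PARAMS = dict(
    Gp0=32.1, p1=0.0021, p2=0.031, p3=1.6e-5, Insb=10.0, e1=1.60, e2=0.778
)


@pytest.fixture(scope="session")
def ref_params():
    return ModelParameters(**REFERENCE_PARAMS, variant=6)


@pytest.fixture(scope="session")
def schedule():
    return build_schedule()


@pytest.fixture(scope="session")
def session_60min():
    return default_exercise_trace(intensity=0.6, duration=60.0, t_start=1080.0)


@pytest.fixture(scope="session")
def basal_insulin(ref_params):
    return ForcingFunction.constant(ref_params.Insb, t=0.0)


@pytest.fixture(scope="session")
def study_dataset(ref_params):
    """One 14-point study-design dataset at 2% noise, fixed seed."""
    return generate_dataset(ref_params, seed=42, subject_id="S_ref")


@pytest.fixture(scope="session")
def insulin_profile(ref_params, session_60min):
    return default_insulin_profile(ref_params.Insb, session_60min)
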