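import numpy as np
import pytest

from masseg.experiment import ExperimentConfig, run_phantom_experiment
from masseg.phantom import PhantomSpec, generate_case


@pytest.fixture(scope="session")
def small_spec():
    """A 48-voxel phantom spec used for fast unit tests."""
    return PhantomSpec(
        shape=(48, 48, 48),
        body_semiaxes=(10.5, 10.0, 11.0),
        bone_halfwidths=(1.5, 7.0, 9.0),
        muscle_center=(7.0, 0.0, -1.0),
        muscle_semiaxes=(2.5, 4.0, 7.0),
    )


@pytest.fixture(scope="session")
def small_case(small_spec):
    return generate_case(small_spec, seed=11, case_id="small")


@pytest.fixture(scope="session")
def phantom_experiment():
    """The full scaled-down end-to-end study (several minutes of CPU).

    Session-scoped so that training runs once and every end-to-end check
    (loss decrease, held-out accuracy, cross-modal agreement) reuses it.
    """
    return run_phantom_experiment(seed=7, cfg=ExperimentConfig())
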