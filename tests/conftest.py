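import numpy as np
import pytest

import narsense as ns


@pytest.fixture(scope="session")
def space():
    return ns.default_factor_space()


@pytest.fixture(scope="session")
def ground_truth(space):
    return ns.draw_ground_truth(space, seed=11)


@pytest.fixture(scope="session")
def reference_context():
    return ns.ContextKey("M0", "S0", "P1", "R1")


@pytest.fixture(scope="session")
def noiseless_experiment(ground_truth, reference_context):
    return ns.generate_experiment(
        reference_context, ground_truth, ns.NoiseSpec(0.0, 0.0, 3), seed=21
    )


@pytest.fixture(scope="session")
def noisy_experiment(ground_truth, reference_context):
    return ns.generate_experiment(
        reference_context, ground_truth, ns.NoiseSpec(0.05, 0.01, 3), seed=22
    )
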