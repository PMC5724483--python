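import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def truncated_psi01_results():
    """Three seed replicates of the psi ~ U{0,1} buffered co-expansion
    leave-one-out experiment, shared across the acceptance assertions
    (expensive: most of the suite's runtime)."""
    from copulse.experiments import run_truncated_experiment

    return [
        run_truncated_experiment(seed=s, n_per_psi=14_000) for s in (101, 102, 103)
    ]
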