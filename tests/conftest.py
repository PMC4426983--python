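import numpy as np
import pytest

from rrpfit import FitConfig, MEPSCKernel, ModelParams, synthesize_trace

# 5 kHz keeps fitting tests fast while resolving the mEPSC kernel; the
# generator's 10 kHz default is exercised separately in the synthesis tests.
FAST_DT = 2e-4


@pytest.fixture(scope="session")
def default_params() -> ModelParams:
    """The canonical simulation parameter set."""
    return ModelParams()


@pytest.fixture(scope="session")
def kernel() -> MEPSCKernel:
    return MEPSCKernel(sample_dt=FAST_DT)


@pytest.fixture(scope="session")
def fast_config() -> FitConfig:
    return FitConfig(n_starts=1, seed=0, xatol=2e-4, fatol=1.0)


@pytest.fixture(scope="session")
def noisy_trace(default_params, kernel):
    """Default-set trace with the canonical 10 pA recording noise."""
    return synthesize_trace(default_params, kernel, noise_sd=10.0, seed=1,
                            duration=6.0, dt=FAST_DT, mode="constant_k1D")


@pytest.fixture(scope="session")
def noiseless_trace(default_params, kernel):
    return synthesize_trace(default_params, kernel, noise_sd=0.0,
                            duration=6.0, dt=FAST_DT, mode="constant_k1D")


@pytest.fixture(scope="session")
def fitted(noisy_trace, kernel, fast_config):
    """A completed stage-1 fit of the noisy default trace."""
    from rrpfit import fit_traces

    return fit_traces(noisy_trace, kernel, fast_config)


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
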