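import numpy as np
import pytest

from spikegof import SpikeTrain, TrialSet


@pytest.fixture
def toy_trials() -> TrialSet:
    """Two tiny deterministic trials on a 1 s window."""
    return TrialSet([SpikeTrain([0.1, 0.5], 1.0), SpikeTrain([0.2], 1.0)])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def poisson_trialset(rate: float, t_end: float, n: int,
                     rng: np.random.Generator) -> TrialSet:
    """Homogeneous Poisson trials simulated directly (independent of the
    package's thinning simulator, for use as an oracle input)."""
    trains = []
    for _ in range(n):
        k = rng.poisson(rate * t_end)
        trains.append(SpikeTrain(np.sort(rng.uniform(0, t_end, k)), t_end))
    return TrialSet(trains)
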