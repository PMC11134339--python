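import numpy as np
import pytest

from pacelock.phase import PhaseNeuron, TriangularIPRC


@pytest.fixture(scope="session")
def symmetric_neuron():
    """Noiseless 30 spikes/s pacemaker with the symmetric triangle iPRC
    (peak at 0.5, population-scale height 1.2 cycles/pC)."""
    return PhaseNeuron(rate=30.0, iprc=TriangularIPRC(0.5, 1.2), id="sym")


@pytest.fixture(scope="session")
def skewed_neuron():
    """Noiseless pacemaker with the rightward-skewed triangle (peak 0.9)."""
    return PhaseNeuron(rate=30.0, iprc=TriangularIPRC(0.9, 1.2), id="skew")


@pytest.fixture(scope="session")
def noisy_neuron():
    """Pacemaker with intrinsic diffusion noise giving an ISI CV near 0.08."""
    return PhaseNeuron(rate=30.0, iprc=TriangularIPRC(0.7, 1.2),
                       noise_sd=0.08 * np.sqrt(30.0), id="noisy")
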