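"""Ground-truth populations and the two stimulation protocols.

The generator emulates the study conditions that all downstream stages are
tested against, without any recorded data:

* autonomous pacemakers with intrinsic rates uniform on 10-40 spikes/s and
  heterogeneous, mostly-positive unimodal iPRCs (triangular, peak location
  theta ~ Uniform[0.4, 0.95], cycle-average 0.6 cycles/pC);
* the noise-pulse iPRC-estimation protocol: 40 episodes x 4 s of contiguous
  0.25 ms current pulses with i.i.d. N(0, 40 pA) amplitudes;
* the sinusoidal drive protocol: 1-100 Hz in 1 Hz steps, 10 s per frequency,
  20 pA amplitude.

Everything is fully determined by (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .errors import InputError
from .phase import PhaseNeuron, SinusoidStimulus, SpikeTrain, TriangularIPRC, simulate_spike_train

__all__ = [
    "MEAN_IPRC",
    "sample_population",
    "PulseRecord",
    "noise_pulse_protocol",
    "sinusoid_protocol",
    "smooth_iprc_population",
]

#: cycle-average iPRC magnitude of generated neurons (cycles/pC); see
#: docs/methods.md for the calibration argument behind this value.
MEAN_IPRC = 0.6
#: default intrinsic ISI coefficient of variation of generated neurons
DEFAULT_CV = 0.08

RATE_RANGE = (10.0, 40.0)
THETA_RANGE = (0.40, 0.95)


def sample_population(n: int, seed: int = 0,
                      rate_range: tuple[float, float] = RATE_RANGE,
                      theta_range: tuple[float, float] = THETA_RANGE,
                      mean_iprc: float = MEAN_IPRC,
                      isi_cv: float = DEFAULT_CV) -> list[PhaseNeuron]:
    """Draw ``n`` heterogeneous pacemakers.

    Rates are uniform on ``rate_range``; iPRCs are triangular with peak
    location uniform on ``theta_range`` and height 2*mean_iprc so the cycle
    average equals ``mean_iprc``.  Intrinsic noise is set so the unperturbed
    ISI coefficient of variation is ``isi_cv`` (diffusion SD isi_cv*sqrt(rate)).
    """
    if n < 1:
        raise InputError("population size must be >= 1")
    rng = np.random.default_rng(seed)
    rates = rng.uniform(*rate_range, size=n)
    thetas = rng.uniform(*theta_range, size=n)
    return [
        PhaseNeuron(rate=float(r),
                    iprc=TriangularIPRC(theta=float(th), height=2.0 * mean_iprc),
                    noise_sd=isi_cv * float(np.sqrt(r)),
                    id=i)
        for i, (r, th) in enumerate(zip(rates, thetas))
    ]


def smooth_iprc_population(n: int, seed: int = 0, **kwargs) -> list[PhaseNeuron]:
    """Alternative population with the smooth 7-parameter bump iPRC family
    instead of triangles (same rate/noise conventions).  The bump mimics the
    triangular shape (center at theta, mild skew) so downstream behaviour is
    comparable; every consumer accepts any :class:`~pacelock.phase.IPRC`."""
    from .phase import ParametricIPRC

    base = sample_population(n, seed, **kwargs)
    out = []
    for nrn in base:
        tri = nrn.iprc
        params = (0.0, tri.height, tri.theta, 0.45,
                  0.6 * (tri.theta - 0.5), 0.0, 0.0)
        out.append(PhaseNeuron(nrn.rate, ParametricIPRC(params),
                               nrn.noise_sd, nrn.id))
    return out


@dataclass(frozen=True)
class PulseRecord:
    """Record of the noise-pulse stimulus: pulse amplitudes (pA), pulse
    width (s), and the episode structure (episodes are contiguous in time)."""

    amplitudes: np.ndarray
    width: float
    episode_s: float
    n_episodes: int

    def __post_init__(self):
        object.__setattr__(self, "amplitudes",
                           np.asarray(self.amplitudes, dtype=float))

    @property
    def pulses_per_episode(self) -> int:
        return int(round(self.episode_s / self.width))

    @property
    def duration(self) -> float:
        return self.n_episodes * self.episode_s

    def cumulative_charge(self, t) -> np.ndarray:
        """Integral of the injected current from 0 to t (pC); piecewise
        linear with breakpoints at pulse edges."""
        t = np.asarray(t, dtype=float)
        csum = np.concatenate(([0.0], np.cumsum(self.amplitudes))) * self.width
        k = np.clip((t / self.width).astype(int), 0, self.amplitudes.size - 1)
        return csum[k] + (t - k * self.width) * self.amplitudes[k]

    def current_samples(self, dt: float) -> np.ndarray:
        """Current waveform sampled every ``dt``; dt must divide the pulse
        width so pulses are represented exactly."""
        per = self.width / dt
        if abs(per - round(per)) > 1e-9:
            raise InputError("dt must divide the pulse width")
        return np.repeat(self.amplitudes, int(round(per)))


def noise_pulse_protocol(neuron: PhaseNeuron, seed: int = 0,
                         n_episodes: int = 40, episode_s: float = 4.0,
                         pulse_width: float = 0.25e-3, amp_sd: float = 40.0,
                         dt: float = 0.05e-3) -> tuple[PulseRecord, SpikeTrain]:
    """Apply the noise-pulse iPRC-estimation protocol to ``neuron``.

    ``n_episodes`` episodes of ``episode_s`` seconds of contiguous
    ``pulse_width`` pulses, amplitudes i.i.d. N(0, amp_sd pA).  Episodes are
    simulated back to back; interspike intervals straddling an episode
    boundary are discarded downstream when building the charge matrix.
    """
    rng = np.random.default_rng(seed)
    n_pulses = n_episodes * int(round(episode_s / pulse_width))
    record = PulseRecord(rng.normal(0.0, amp_sd, size=n_pulses),
                         pulse_width, episode_s, n_episodes)
    train = simulate_spike_train(neuron, record.current_samples(dt),
                                 record.duration, dt=dt, seed=seed)
    return record, train


def sinusoid_protocol(neuron: PhaseNeuron,
                      freqs: Iterable[float] | None = None,
                      seed: int = 0, amplitude: float = 20.0,
                      duration: float = 10.0,
                      dt: float = 0.1e-3) -> dict[float, SpikeTrain]:
    """Drive ``neuron`` with one sinusoid per frequency (default 1..100 Hz in
    1 Hz steps, 10 s each, 20 pA) and return {frequency: spike train}."""
    if freqs is None:
        freqs = np.arange(1.0, 101.0)
    freqs = [float(f) for f in freqs]
    if not freqs:
        raise InputError("need at least one stimulus frequency")
    if any(f <= 0 for f in freqs):
        raise InputError("stimulus frequencies must be positive")
    out = {}
    for i, f in enumerate(freqs):
        stim = SinusoidStimulus(f, amplitude)
        out[f] = simulate_spike_train(neuron, stim, duration, dt=dt,
                                      seed=seed + i)
    return out
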