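"""Phase-oscillator representation of pacemaker neurons.

A pacemaker is reduced to a single phase variable phi in [0, 1) advancing at
its intrinsic rate f (spikes/s); a spike is emitted whenever phi crosses 1.
Injected current I(t) (pA) perturbs the phase through the neuron's
infinitesimal phase-response curve (iPRC) Z(phi), in cycles per pC:

    dphi/dt = f + I(t) * Z(phi)

so a depolarizing current delivered where Z > 0 advances the next spike.
Integration is forward Euler with linear interpolation of the threshold
crossing inside the final step; on a spike the phase is reset by subtracting
1 (the overshoot is kept, avoiding a systematic rate bias at coarse steps).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import _kernels
from .errors import InputError, InvalidIPRCError, NoSpikeError

__all__ = [
    "IPRC",
    "TriangularIPRC",
    "TabulatedIPRC",
    "ParametricIPRC",
    "PhaseNeuron",
    "SinusoidStimulus",
    "SpikeTrain",
    "PhaseSample",
    "evaluate_iprc",
    "spikes_to_phases",
    "integrate_to_next_spike",
    "simulate_spike_train",
]

#: default Euler step for deterministic return-map integration (s)
RETURN_MAP_DT = 0.05e-3
#: default Euler step for spike-train simulation (s)
TRAIN_DT = 0.1e-3
#: resolution of the lookup tables handed to the jitted integrators
TABLE_SIZE = 2048


class IPRC:
    """Periodic phase-response curve Z(phi), phi in cycles.

    Subclasses implement :meth:`_eval_unit` on phi already wrapped to [0, 1).
    Evaluation at phi and phi + 1 is identical by construction.
    """

    def __call__(self, phi):
        phi = np.asarray(phi, dtype=float)
        return self._eval_unit(phi - np.floor(phi))

    def _eval_unit(self, phi):  # pragma: no cover - abstract
        raise NotImplementedError

    def mean(self) -> float:
        """Temporal average of Z over one cycle."""
        grid = (np.arange(4096) + 0.5) / 4096
        return float(np.mean(self(grid)))

    def table(self, size: int = TABLE_SIZE) -> np.ndarray:
        """Dense lookup table at nodes k/size for the jitted integrators."""
        return np.asarray(self(np.arange(size) / size), dtype=float)


@dataclass(frozen=True)
class TriangularIPRC(IPRC):
    """Triangle that is 0 at phi = 0 and 1, peaking at ``theta``.

    ``height`` is the peak value in cycles/pC (the unity-height triangle is
    the canonical idealization; realistic curves are rescaled so the cycle
    average height/2 matches an empirical magnitude).
    """

    theta: float
    height: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.theta < 1.0:
            raise InvalidIPRCError(
                f"triangle peak must lie strictly inside (0, 1); got {self.theta}")

    def _eval_unit(self, phi):
        up = phi / self.theta
        down = (1.0 - phi) / (1.0 - self.theta)
        return self.height * np.where(phi <= self.theta, up, down)


@dataclass(frozen=True)
class TabulatedIPRC(IPRC):
    """iPRC tabulated at ``nbins`` equal bins of the cycle (50 in the
    estimation protocol); values sit at bin centers (k + 1/2)/nbins and are
    evaluated by periodic linear interpolation."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0 or not np.all(np.isfinite(v)):
            raise InvalidIPRCError("tabulated iPRC needs a 1-d finite table")
        object.__setattr__(self, "values", v)

    @property
    def nbins(self) -> int:
        return self.values.size

    def _eval_unit(self, phi):
        n = self.nbins
        u = phi * n - 0.5
        i = np.floor(u).astype(int)
        frac = u - i
        return self.values[i % n] * (1 - frac) + self.values[(i + 1) % n] * frac


def bump_family(params: Sequence[float], phi) -> np.ndarray:
    """Seven-parameter smooth periodic family used for parametric iPRC fits:
    baseline + skewed raised-cosine bump (amplitude, center, width, skew)
    + a first-harmonic cosine/sine correction."""
    base, amp, center, width, skew, fc, fs = params
    phi = np.asarray(phi, dtype=float)
    d = phi - center
    d -= np.round(d)  # wrapped to [-0.5, 0.5)
    w_left = max(width * (1.0 - skew), 1e-4)
    w_right = max(width * (1.0 + skew), 1e-4)
    u = np.where(d >= 0, d / w_right, d / w_left)
    bump = np.where(np.abs(u) < 1.0, np.cos(0.5 * np.pi * u) ** 2, 0.0)
    return (base + amp * bump
            + fc * np.cos(2 * np.pi * phi) + fs * np.sin(2 * np.pi * phi))


@dataclass(frozen=True)
class ParametricIPRC(IPRC):
    """Smooth 7-parameter iPRC (see :func:`bump_family`)."""

    params: tuple

    def __post_init__(self):
        p = tuple(float(v) for v in self.params)
        if len(p) != 7 or not np.all(np.isfinite(p)):
            raise InvalidIPRCError("parametric iPRC needs 7 finite parameters")
        object.__setattr__(self, "params", p)

    def _eval_unit(self, phi):
        return bump_family(self.params, phi)


def evaluate_iprc(iprc: IPRC, phi):
    """Evaluate Z at stimulus-cycle phase(s) ``phi`` (any real; wrapped mod 1)."""
    if not isinstance(iprc, IPRC):
        raise InvalidIPRCError(f"not an iPRC: {iprc!r}")
    return iprc(phi)


@dataclass(frozen=True)
class PhaseNeuron:
    """Autonomous pacemaker: intrinsic rate (spikes/s), iPRC, and intrinsic
    phase noise.

    ``noise_sd`` is a diffusion-style SD in cycles * s**-1/2; each Euler step
    adds Gaussian phase noise of SD noise_sd * sqrt(dt), which makes the
    neuron's ISI coefficient of variation (approximately noise_sd / sqrt(rate))
    independent of the step size.
    """

    rate: float
    iprc: IPRC
    noise_sd: float = 0.0
    id: int | str | None = None

    def __post_init__(self):
        if not self.rate > 0:
            raise InputError(f"intrinsic rate must be positive; got {self.rate}")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be nonnegative")

    @property
    def period(self) -> float:
        return 1.0 / self.rate


@dataclass(frozen=True)
class SinusoidStimulus:
    """A * sin(2 pi n [f t + phi]) current drive; A in pA, f in Hz."""

    frequency: float
    amplitude: float
    harmonic: int = 1

    def __post_init__(self):
        if not self.frequency > 0:
            raise InputError("stimulus frequency must be positive")
        if self.amplitude < 0:
            raise InputError("stimulus amplitude must be nonnegative")
        if self.harmonic < 1:
            raise InputError("harmonic index must be >= 1")

    def current(self, t, phase: float = 0.0) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.amplitude * np.sin(
            2 * np.pi * self.harmonic * (self.frequency * t + phase))


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times (s) on [0, duration), strictly increasing."""

    times: np.ndarray
    duration: float
    neuron_id: int | str | None = None
    meta: Mapping = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1:
            raise InputError("spike times must be a 1-d array")
        if t.size:
            if not np.all(np.diff(t) > 0):
                raise InputError("spike times must be strictly increasing")
            if t[0] < 0 or t[-1] >= self.duration:
                raise InputError("spike times must lie in [0, duration)")
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return self.times.size

    @property
    def rate(self) -> float:
        return self.times.size / self.duration

    def isis(self) -> np.ndarray:
        return np.diff(self.times)


@dataclass(frozen=True)
class PhaseSample:
    """Stimulus phases (cycles, in [0, 1)) at which spikes occurred."""

    phases: np.ndarray
    frequency: float

    def __post_init__(self):
        p = np.asarray(self.phases, dtype=float)
        if p.size and (p.min() < 0 or p.max() >= 1):
            raise InputError("phases must lie in [0, 1)")
        object.__setattr__(self, "phases", p)

    def __len__(self) -> int:
        return self.phases.size


def spikes_to_phases(train: SpikeTrain, f_stim: float) -> PhaseSample:
    """Convert spike times to stimulus phases phi_j = f * t_j mod 1."""
    if not f_stim > 0:
        raise InputError("stimulus frequency must be positive")
    return PhaseSample(np.mod(f_stim * train.times, 1.0), f_stim)


def integrate_to_next_spike(neuron: PhaseNeuron, stim: SinusoidStimulus,
                            phi_prev: float, dt: float = RETURN_MAP_DT) -> float:
    """Stimulus phase at the next spike, starting the neuron at phase 0 with
    the stimulus clock at ``phi_prev``.  Deterministic Euler integration;
    raises :class:`NoSpikeError` if the neuron does not spike within 10
    intrinsic periods (e.g. under strongly hyperpolarizing drive)."""
    out = _kernels.return_map_points(
        neuron.rate, neuron.iprc.table(), stim.frequency, stim.amplitude,
        stim.harmonic, dt, np.array([float(phi_prev) % 1.0]),
        10.0 * neuron.period)
    if np.isnan(out[0]):
        raise NoSpikeError(
            f"no spike within 10 intrinsic periods from phi_prev={phi_prev}")
    return float(out[0])


def simulate_spike_train(neuron: PhaseNeuron, stimulus, duration: float,
                         dt: float = TRAIN_DT, seed: int = 0,
                         stimulus_phase: float = 0.0) -> SpikeTrain:
    """Simulate a spike train under an arbitrary injected current.

    ``stimulus`` may be a :class:`SinusoidStimulus`, a current sample array
    (pA, one sample per Euler step), or None (autonomous firing).  Noise is
    the neuron's intrinsic phase noise; identical seeds give identical trains.
    """
    if duration <= 0:
        raise InputError("duration must be positive")
    n_steps = int(round(duration / dt))
    if stimulus is None:
        current = np.zeros(n_steps)
        meta = {"freq": None, "amp": 0.0}
    elif isinstance(stimulus, SinusoidStimulus):
        t = np.arange(n_steps) * dt
        current = stimulus.current(t, stimulus_phase)
        meta = {"freq": stimulus.frequency, "amp": stimulus.amplitude}
    else:
        current = np.asarray(stimulus, dtype=float)
        if current.ndim != 1 or current.shape[0] != n_steps:
            raise InputError(
                f"current waveform must have {n_steps} samples at dt={dt}")
        if not np.all(np.isfinite(current)):
            raise InputError("current waveform contains non-finite samples")
        meta = {"freq": None, "amp": None}
    times = _kernels.run_current_train(
        neuron.rate, neuron.iprc.table(), current, dt,
        neuron.noise_sd * np.sqrt(dt), int(seed))
    times = times[times < duration]
    meta.update({"dt": dt, "seed": int(seed)})
    return SpikeTrain(times, duration, neuron.id, meta)
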