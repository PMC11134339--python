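"""Entrainment machinery: circular statistics, return maps, noisy map
iteration, spike-phase distributions, and locking-phase extraction.

The return map sends the stimulus phase at one spike to the stimulus phase
at the next and is fully determined by the neuron's iPRC, intrinsic rate,
and the drive frequency and amplitude.  Phase locking appears as a fixed
point where the map crosses the identity with slope < 1; away from locking,
iterating the map with additive Gaussian noise (SD beta*sqrt(f), matched to
the observed spread at the locking frequency) reproduces the stationary
spike-phase distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from . import _kernels
from .errors import DegenerateMapError, InputError, NoSpikeError, \
    TuningError, UndefinedStatisticError
from .phase import PhaseNeuron, PhaseSample, SinusoidStimulus, SpikeTrain, \
    RETURN_MAP_DT, spikes_to_phases

__all__ = [
    "vector_strength", "vector_angle", "circular_sd",
    "ReturnMap", "compute_return_map", "LockingPoint", "find_locking_phase",
    "iterate_with_noise", "tune_beta",
    "SpikePhaseDistribution", "phase_distribution", "distribution_fit",
    "predict_phase_distribution", "entrainment_summary",
]


def _phases(sample) -> np.ndarray:
    if isinstance(sample, PhaseSample):
        return sample.phases
    return np.asarray(sample, dtype=float)


def vector_strength(sample) -> float:
    """Resultant length of the unit vectors at spike phases, in [0, 1]:
    1 means firing at the same phase on every cycle, 0 no phase preference."""
    p = _phases(sample)
    if p.size == 0:
        raise UndefinedStatisticError("vector strength of an empty sample")
    ang = 2 * np.pi * p
    return float(np.hypot(np.sin(ang).sum(), np.cos(ang).sum()) / p.size)


def vector_angle(sample) -> float:
    """Mean direction of the spike-phase vectors, wrapped to [0, 1);
    undefined (error) when the resultant vanishes."""
    p = _phases(sample)
    if p.size == 0:
        raise UndefinedStatisticError("vector angle of an empty sample")
    ang = 2 * np.pi * p
    s, c = np.sin(ang).sum(), np.cos(ang).sum()
    if np.hypot(s, c) / p.size < 1e-12:
        raise UndefinedStatisticError("vector angle undefined at VS = 0")
    va = float(np.mod(np.arctan2(s, c) / (2 * np.pi), 1.0))
    return 0.0 if va >= 1.0 else va  # float mod can land exactly on 1


def circular_sd(sample) -> float:
    """Circular standard deviation sqrt(-2 ln VS), in cycles/(2 pi) units."""
    vs = vector_strength(sample)
    if vs <= 0:
        raise UndefinedStatisticError("circular SD undefined at VS = 0")
    return float(np.sqrt(max(-2.0 * np.log(vs), 0.0)))


@dataclass(frozen=True)
class ReturnMap:
    """phi_next as a function of phi_prev on a uniform grid of start phases."""

    phi_prev: np.ndarray
    phi_next: np.ndarray
    frequency: float
    amplitude: float
    neuron_id: int | str | None = None

    def displacement(self) -> np.ndarray:
        """phi_next - phi_prev wrapped to [-0.5, 0.5)."""
        d = self.phi_next - self.phi_prev
        return d - np.round(d)

    @property
    def n_points(self) -> int:
        return self.phi_prev.size


def compute_return_map(neuron: PhaseNeuron, frequency: float, amplitude: float,
                       n_points: int = 400, dt: float = RETURN_MAP_DT,
                       harmonic: int = 1) -> ReturnMap:
    """Deterministic return map from ``n_points`` equidistant start phases.

    Each start phase launches an independent integration with the neuron
    phase at 0; the stimulus phase at the resulting spike is recorded.
    """
    stim = SinusoidStimulus(frequency, amplitude, harmonic)
    prev = np.arange(n_points) / n_points
    nxt = _kernels.return_map_points(
        neuron.rate, neuron.iprc.table(), stim.frequency, stim.amplitude,
        stim.harmonic, dt, prev, 10.0 * neuron.period)
    if np.any(np.isnan(nxt)):
        raise NoSpikeError("some start phases produced no spike within "
                           "10 intrinsic periods")
    return ReturnMap(prev, nxt, frequency, amplitude, neuron.id)


@dataclass(frozen=True)
class LockingPoint:
    psi: float
    slope: float

    @property
    def stable(self) -> bool:
        return abs(self.slope) < 1.0


def find_locking_phase(rmap: ReturnMap, tol: float = 1e-9) -> LockingPoint | None:
    """Stable fixed point of the return map, or None if the map has no
    identity crossing (e.g. rigid rotation at an off-resonant frequency).

    Crossings are located by sign changes of the wrapped displacement with
    linear interpolation; a crossing is stable when the local slope of the
    map is < 1 (displacement decreasing through zero).  A map whose
    displacement vanishes everywhere (undriven resonant case) has
    non-isolated fixed points and raises :class:`DegenerateMapError`.
    """
    d = rmap.displacement()
    if np.max(np.abs(d)) < tol:
        raise DegenerateMapError("displacement is zero everywhere: "
                                 "non-isolated fixed points")
    n = d.size
    h = 1.0 / n
    best = None
    for k in range(n):
        d0, d1 = d[k], d[(k + 1) % n]
        if d0 == 0.0 and d1 == 0.0:
            continue
        if d0 >= 0.0 > d1 or (d0 > 0.0 >= d1):
            frac = d0 / (d0 - d1)
            psi = (rmap.phi_prev[k] + frac * h) % 1.0
            slope = 1.0 + (d1 - d0) / h
            if best is None or (d0 - d1) > best[0]:
                best = ((d0 - d1), LockingPoint(psi, slope))
    return best[1] if best is not None else None


def iterate_with_noise(rmap: ReturnMap, beta: float, n_samples: int,
                       seed: int = 0, burn_in: int = 100) -> PhaseSample:
    """Iterate phi <- RMap(phi) + xi (mod 1) with xi ~ N(0, beta*sqrt(f)).

    The map is evaluated between grid points by periodic linear interpolation
    of its displacement; the first ``burn_in`` iterates are discarded.
    """
    if beta < 0:
        raise InputError("beta must be nonnegative")
    if n_samples < 1:
        raise InputError("need at least one sample")
    rng = np.random.default_rng(seed)
    phi0 = float(rng.random())
    noise_sd = beta * np.sqrt(rmap.frequency)
    phases = _kernels.iterate_map(rmap.displacement(), noise_sd,
                                  int(n_samples), int(burn_in),
                                  int(rng.integers(2 ** 31)), phi0)
    return PhaseSample(phases, rmap.frequency)


def tune_beta(rmap: ReturnMap, reference: PhaseSample,
              rel_tol: float = 0.02, seed: int = 0, n_samples: int = 20000,
              max_iter: int = 60) -> float:
    """Find beta so the circular SD of the iterated-map phases matches the
    reference sample's circular SD within ``rel_tol`` (relative).

    ``reference`` should be the spike phases observed at the neuron's locking
    frequency (the drive frequency maximizing VS), where the return-map
    prediction is most precise.  Monotone bisection; returns 0 for a
    zero-spread reference.
    """
    if len(reference) == 0:
        raise UndefinedStatisticError("empty reference sample")
    target = circular_sd(reference)
    if target <= 1e-6:  # spread indistinguishable from zero at float precision
        return 0.0

    def spread(beta):
        return circular_sd(iterate_with_noise(rmap, beta, n_samples, seed))

    lo, hi = 0.0, max(2.0 * target / np.sqrt(rmap.frequency), 1e-4)
    for _ in range(30):
        if spread(hi) >= target:
            break
        hi *= 2.0
    else:
        raise TuningError("could not bracket the target spread")
    if spread(lo) > target:
        return 0.0  # deterministic map already spreads more than the reference
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        s = spread(mid)
        if abs(s - target) <= rel_tol * target:
            return mid
        if s < target:
            lo = mid
        else:
            hi = mid
    raise TuningError("beta bisection did not converge")


@dataclass(frozen=True)
class SpikePhaseDistribution:
    """Normalized histogram P(phi; f) of stimulus phases at spikes."""

    edges: np.ndarray
    probs: np.ndarray
    frequency: float

    @property
    def nbins(self) -> int:
        return self.probs.size

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def mode_center(self) -> float:
        return float(self.centers[int(np.argmax(self.probs))])


def phase_distribution(sample: PhaseSample, nbins: int = 50) -> SpikePhaseDistribution:
    """Normalized spike-phase histogram on [0, 1)."""
    p = _phases(sample)
    if p.size == 0:
        raise UndefinedStatisticError("phase distribution of an empty sample")
    counts, edges = np.histogram(p, bins=nbins, range=(0.0, 1.0))
    freq = sample.frequency if isinstance(sample, PhaseSample) else np.nan
    return SpikePhaseDistribution(edges, counts / counts.sum(), freq)


def distribution_fit(predicted: SpikePhaseDistribution,
                     observed: SpikePhaseDistribution) -> float:
    """Pearson correlation between the two distributions' bin probabilities."""
    if predicted.nbins != observed.nbins:
        raise InputError("distributions must share their binning")
    a, b = predicted.probs, observed.probs
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedStatisticError("correlation with a constant vector")
    return float(stats.pearsonr(a, b).statistic)


def predict_phase_distribution(neuron: PhaseNeuron, frequency: float,
                               amplitude: float, beta: float,
                               nbins: int = 50, n_samples: int = 20000,
                               seed: int = 0) -> SpikePhaseDistribution:
    """Model-predicted spike-phase distribution at one drive frequency:
    deterministic return map, then noisy iteration, then histogram."""
    rmap = compute_return_map(neuron, frequency, amplitude)
    sample = iterate_with_noise(rmap, beta, n_samples, seed)
    return phase_distribution(sample, nbins)


def entrainment_summary(trains: Mapping[float, SpikeTrain]) -> pd.DataFrame:
    """Per-frequency VS, VA and mean firing rate for a sinusoid protocol."""
    rows = []
    for f, train in sorted(trains.items()):
        sample = spikes_to_phases(train, f)
        if len(sample) == 0:
            continue
        vs = vector_strength(sample)
        try:
            va = vector_angle(sample)
        except UndefinedStatisticError:
            va = np.nan
        rows.append({"frequency": f, "vs": vs, "va": va, "rate": train.rate})
    return pd.DataFrame(rows)


def locking_frequency(summary: pd.DataFrame) -> float:
    """Drive frequency maximizing VS (the frequency used to tune beta)."""
    return float(summary.loc[summary["vs"].idxmax(), "frequency"])
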