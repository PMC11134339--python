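"""Cross-intensity functions (CIFs) of commonly driven neuron pairs.

The CIF R12(tau) is the spike cross-correlation of two trains.  Restricted
to lags within one period T = 1/f of the common sinusoidal drive, the CIF of
two *independent* driven neurons equals the circular cross-correlation of
their spike-phase distributions,

    R12(tau; f) = int_0^1 P1(phi; f) P2(phi + f tau; f) dphi ,

so the pairwise correlation structure is fully inherited from the
single-neuron phase distributions.  Conventions used here:

* lag grid: symmetric, covering (-T/2, T/2] (equivalent to [0, T) by
  periodicity, but centered so in-phase and antiphase are visually centered);
* normalization: CIFs are rescaled to mean 1 over the period, making the
  amplitude a unitless modulation factor (comparisons use scale-free
  statistics throughout); the unnormalized rate density (spikes^2 s^-1) is
  available via ``normalize=False``;
* amplitude = max of the normalized CIF; phase delay = argmax lag times f,
  wrapped to (-0.5, 0.5], ties broken toward the smallest |delay|.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InputError, UndefinedStatisticError
from .entrainment import SpikePhaseDistribution, circular_sd
from .phase import SpikeTrain

__all__ = ["CIF", "CIFSummary", "empirical_cif", "predicted_cif",
           "cif_summary", "pair_survey", "amplitude_surface", "delay_pdfs"]


@dataclass(frozen=True)
class CIF:
    """Cross-intensity function on a lag grid spanning one stimulus period."""

    lags: np.ndarray
    values: np.ndarray
    frequency: float
    pair: tuple = (None, None)

    @property
    def nbins(self) -> int:
        return self.values.size

    @property
    def period(self) -> float:
        return 1.0 / self.frequency


def _lag_grid(f: float, nbins: int) -> np.ndarray:
    """Integer-shift lags m/(nbins f) for m = -floor((n-1)/2) .. ceil((n-1)/2),
    covering (-T/2, T/2]."""
    m = np.arange(nbins) - (nbins - 1) // 2
    return m / (nbins * f)


def empirical_cif(train1: SpikeTrain, train2: SpikeTrain, f: float,
                  nbins: int = 50, normalize: bool = True) -> CIF:
    """CIF estimated by counting spike-pair lags t2 - t1 within +-T/2.

    Lags are histogrammed on ``nbins`` bins covering (-T/2, T/2].  With
    ``normalize`` the histogram is rescaled to mean 1; otherwise it is the
    rate density: counts / (duration * bin width), whose mean over the
    period is rate1*rate2 for independent trains.
    """
    if len(train1) == 0 or len(train2) == 0:
        raise InputError("empty spike train")
    if not f > 0:
        raise InputError("stimulus frequency must be positive")
    T = 1.0 / f
    t1, t2 = train1.times, train2.times
    lo = np.searchsorted(t2, t1 - T / 2, side="right")
    hi = np.searchsorted(t2, t1 + T / 2, side="right")
    counts = hi - lo
    total = int(counts.sum())
    if total:
        start = np.repeat(np.cumsum(counts) - counts, counts)
        pos = np.arange(total) - start + np.repeat(lo, counts)
        lags = t2[pos] - np.repeat(t1, counts)
    else:
        lags = np.empty(0)
    # assign each lag to the circularly nearest grid point m/(nbins f)
    lo_m = -((nbins - 1) // 2)
    m = np.round(lags * nbins * f).astype(int)
    m = ((m - lo_m) % nbins)  # index into the lag grid
    values = np.bincount(m, minlength=nbins).astype(float)
    duration = min(train1.duration, train2.duration)
    if normalize:
        mean = values.mean()
        if mean == 0:
            raise UndefinedStatisticError("no spike pairs within one period")
        values = values / mean
    else:
        values = values / (duration * (T / nbins))
    return CIF(_lag_grid(f, nbins), values, f,
               (train1.neuron_id, train2.neuron_id))


def predicted_cif(p1: SpikePhaseDistribution, p2: SpikePhaseDistribution,
                  f: float, nbins: int | None = None) -> CIF:
    """Circular cross-correlation of two spike-phase distributions.

    R(m/(n f)) = n * sum_i p1[i] p2[(i+m) mod n]; with probability vectors
    this is automatically mean 1 over the period.
    """
    if p1.nbins != p2.nbins:
        raise InputError("distributions must share their binning")
    if nbins is not None and nbins != p1.nbins:
        raise InputError("lag bins must match the distribution bins")
    n = p1.nbins
    a, b = p1.probs, p2.probs
    m = np.arange(n) - (n - 1) // 2
    idx = (np.arange(n)[None, :] + m[:, None]) % n
    values = n * (a[None, :] * b[idx]).sum(axis=1)
    return CIF(_lag_grid(f, n), values, f)


@dataclass(frozen=True)
class CIFSummary:
    amplitude: float
    delay: float  # phase delay in cycles, (-0.5, 0.5]; NaN when flat
    gmean_rate: float = np.nan

    @property
    def delay_defined(self) -> bool:
        return np.isfinite(self.delay)


def cif_summary(cif: CIF, rates: tuple[float, float] | None = None,
                flat_tol: float = 0.01) -> CIFSummary:
    """Amplitude (max of the CIF) and phase delay (argmax lag x f, wrapped to
    (-0.5, 0.5]).  A flat CIF (peak-to-trough below ``flat_tol`` of the mean)
    has no meaningful delay and reports NaN."""
    v = cif.values
    amplitude = float(v.max())
    gmean = float(np.sqrt(rates[0] * rates[1])) if rates is not None else np.nan
    mean = v.mean()
    if mean <= 0 or (v.max() - v.min()) < flat_tol * mean:
        return CIFSummary(amplitude, np.nan, gmean)
    delays = cif.lags * cif.frequency
    delays = np.where(delays <= -0.5, delays + 1.0, delays)
    peak = np.flatnonzero(v == v.max())
    delay = float(delays[peak[np.argmin(np.abs(delays[peak]))]])
    return CIFSummary(amplitude, delay, gmean)


def pair_survey(trains: Mapping, rates: Mapping[object, float],
                nbins: int = 50) -> pd.DataFrame:
    """CIF summaries for all unordered pairs across frequencies.

    ``trains`` maps frequency -> {neuron id -> SpikeTrain}; ``rates`` maps
    neuron id -> intrinsic rate.  Returns one row per (frequency, pair) with
    amplitude, delay, and the pair's geometric-mean intrinsic rate.
    """
    ids = sorted(rates)
    if len(ids) < 2:
        raise InputError("need at least two neurons for a pair survey")
    rows = []
    for f in sorted(trains):
        by_id = trains[f]
        for a, b in combinations(ids, 2):
            ta, tb = by_id.get(a), by_id.get(b)
            if ta is None or tb is None or len(ta) == 0 or len(tb) == 0:
                continue
            try:
                cif = empirical_cif(ta, tb, f, nbins)
            except UndefinedStatisticError:
                continue
            s = cif_summary(cif, (rates[a], rates[b]))
            rows.append({"frequency": f, "a": a, "b": b,
                         "gmean_rate": s.gmean_rate,
                         "amplitude": s.amplitude, "delay": s.delay})
    return pd.DataFrame(rows)


def amplitude_surface(survey: pd.DataFrame, rate_bins: int = 8) -> pd.DataFrame:
    """Mean CIF amplitude binned over (drive frequency, geometric-mean rate):
    the surface whose diagonal ridge marks pairs driven near their rates."""
    df = survey.copy()
    df["rate_bin"] = pd.cut(df["gmean_rate"], bins=rate_bins)
    out = (df.groupby(["frequency", "rate_bin"], observed=True)["amplitude"]
             .mean().unstack("rate_bin"))
    return out


def delay_pdfs(survey: pd.DataFrame, nbins: int = 40) -> dict[float, tuple]:
    """Per-frequency histogram (density) of CIF phase delays on (-0.5, 0.5]."""
    out = {}
    edges = np.linspace(-0.5, 0.5, nbins + 1)
    for f, grp in survey.groupby("frequency"):
        d = grp["delay"].dropna().to_numpy()
        dens, _ = np.histogram(d, bins=edges, density=True)
        out[float(f)] = (0.5 * (edges[:-1] + edges[1:]), dens)
    return out


def delay_spread(survey: pd.DataFrame, f: float) -> float:
    """Circular SD of the delay distribution at one frequency."""
    d = survey.loc[survey["frequency"] == f, "delay"].dropna().to_numpy()
    if d.size == 0:
        raise UndefinedStatisticError("no defined delays at this frequency")
    return circular_sd(np.mod(d, 1.0))
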