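"""Estimate an iPRC from a noise-pulse experiment.

The estimator is a 50-bin charge-matrix multilinear regression: each
interspike interval (ISI) is divided into 50 equal-length phase bins, the
injected charge per bin is tabulated, and the normalized ISIs are regressed
on the charges,

    ISI_a / <ISI> = 1 - sum_i Q_{a,i} Z(phi_i) + eps_a .

Sign convention: a depolarizing charge delivered where Z > 0 advances the
phase and therefore *shortens* the ISI, so the reported iPRC is the negative
of the OLS coefficients of ISI_a/<ISI> - 1 on Q.  (Written with a plus sign
the same regression would make positive Z lengthen ISIs, contradicting the
phase equation this package integrates.)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.optimize import least_squares

from .errors import InputError, SingularDesignError
from .fourier import decompose
from .phase import IPRC, ParametricIPRC, SpikeTrain, TabulatedIPRC, bump_family
from .synthetic import PulseRecord

__all__ = ["ChargeMatrix", "IPRCEstimate", "build_charge_matrix",
           "estimate_iprc", "fit_parametric"]


@dataclass(frozen=True)
class ChargeMatrix:
    """Applied charge per ISI (rows) per phase bin (columns), in pC."""

    Q: np.ndarray
    isis: np.ndarray
    mean_isi: float

    @property
    def nbins(self) -> int:
        return self.Q.shape[1]

    @property
    def n_isis(self) -> int:
        return self.Q.shape[0]


@dataclass(frozen=True)
class IPRCEstimate:
    """Regression estimate of the iPRC on ``nbins`` phase-bin centers."""

    z_hat: np.ndarray
    se: np.ndarray
    n_isis: int

    @property
    def nbins(self) -> int:
        return self.z_hat.size

    @property
    def bin_centers(self) -> np.ndarray:
        n = self.nbins
        return (np.arange(n) + 0.5) / n

    def as_iprc(self) -> TabulatedIPRC:
        return TabulatedIPRC(self.z_hat)


def build_charge_matrix(record: PulseRecord, train: SpikeTrain,
                        nbins: int = 50) -> ChargeMatrix:
    """Tabulate the injected charge per phase bin for every usable ISI.

    Each ISI is divided into ``nbins`` equal-length bins; the charge in a bin
    is the integral of the injected current over it (pulses straddling a bin
    edge are apportioned by time overlap, via the cumulative charge).  ISIs
    that straddle an episode boundary are discarded (their stimulus record is
    not contiguous in the experiment being emulated).
    """
    t = train.times
    if t.size < 2:
        raise InputError("need at least 2 spikes to form ISIs")
    a, b = t[:-1], t[1:]
    keep = np.floor(a / record.episode_s) == np.floor(b / record.episode_s)
    a, b = a[keep], b[keep]
    if a.size == 0:
        raise InputError("no ISI lies fully inside an episode")
    isis = b - a
    if np.any(isis < record.width):
        warnings.warn("some ISIs are shorter than one stimulus pulse; "
                      "their rows are kept but poorly resolved")
    # bin edges for all ISIs at once: (n_isi, nbins+1)
    edges = a[:, None] + isis[:, None] * (np.arange(nbins + 1) / nbins)
    cum = record.cumulative_charge(edges)
    Q = np.diff(cum, axis=1)
    return ChargeMatrix(Q=Q, isis=isis, mean_isi=float(isis.mean()))


def estimate_iprc(cm: ChargeMatrix) -> IPRCEstimate:
    """Ordinary least squares of (ISI_a/<ISI> - 1) on the charge rows.

    No intercept (the constant 1 sits on the left side).  Returns the
    phase-advance-convention iPRC (negated coefficients) with per-bin
    standard errors.  A rank-deficient design (e.g. an all-zero stimulus)
    raises :class:`SingularDesignError`.
    """
    y = cm.isis / cm.mean_isi - 1.0
    if np.linalg.matrix_rank(cm.Q) < cm.nbins:
        raise SingularDesignError(
            "charge matrix is rank deficient; the stimulus does not span "
            "all phase bins")
    res = sm.OLS(y, cm.Q).fit()
    return IPRCEstimate(z_hat=-np.asarray(res.params),
                        se=np.asarray(res.bse), n_isis=cm.n_isis)


def _fit_bump(phi: np.ndarray, z: np.ndarray):
    span = float(z.max() - z.min())
    x0 = np.array([float(z.min()), span, float(phi[np.argmax(z)]),
                   0.25, 0.0, 0.0, 0.0])
    scale = max(span, abs(float(z.mean())), 1e-12)
    lo = [-np.inf, 0.0, -np.inf, 0.02, -0.9, -np.inf, -np.inf]
    hi = [np.inf, np.inf, np.inf, 0.49, 0.9, np.inf, np.inf]
    res = least_squares(lambda p: bump_family(p, phi) - z, x0,
                        bounds=(lo, hi), x_scale=np.maximum(np.abs(x0), 0.05))
    return res, scale


def fit_parametric(est: IPRCEstimate) -> IPRC:
    """Least-squares fit of the smooth 7-parameter family to the 50-bin
    estimate; downstream analyses use the fitted curve in place of the noisy
    table.  If the optimizer fails, falls back (with a warning) to a
    circularly smoothed tabulated iPRC."""
    phi = est.bin_centers
    z = est.z_hat
    try:
        res, scale = _fit_bump(phi, z)
        if not res.success:
            raise RuntimeError(res.message)
    except Exception as exc:  # optimizer failure -> smoothed table
        warnings.warn(f"parametric iPRC fit failed ({exc}); "
                      "falling back to a smoothed tabulated iPRC")
        kernel = np.array([0.15, 0.7, 0.15])
        smoothed = sum(w * np.roll(z, s) for w, s in zip(kernel, (-1, 0, 1)))
        return TabulatedIPRC(smoothed)
    p = res.x
    p[2] = p[2] % 1.0  # wrap the bump center into [0, 1)
    return ParametricIPRC(tuple(p))


def estimated_fundamental_angle(est: IPRCEstimate) -> float:
    """Angle of the fundamental Fourier mode of the (tabulated) estimate."""
    return float(decompose(est.as_iprc(), 1).angle[0])
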