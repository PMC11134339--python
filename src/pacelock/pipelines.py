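"""Canonical end-to-end experiments at desk scale.

These drivers wire the modules together the way the full study does —
generate a synthetic population, run a stimulation protocol, push the
results through the analysis stages — at problem sizes chosen to finish in
minutes on one core.  They are used by the acceptance script and the
integration tests; each returns plain numbers/dicts so callers can assert
or report them.

Problem sizes (see docs/methods.md for rationale): the emulated experiment
recorded 10 s per frequency because real pallidal neurons are strongly
modulated by a 20 pA drive; the synthetic population's high-frequency
modulation is weaker (its triangular iPRCs vanish at the spike phase), so
the pipeline drivers lengthen the simulated recordings instead of touching
the generator.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats

from . import entrainment as ent
from . import correlation as corr
from . import iprc as prc
from . import network as net
from .fourier import decompose
from .phase import PhaseNeuron, SinusoidStimulus, TriangularIPRC, \
    simulate_spike_train, spikes_to_phases
from .synthetic import MEAN_IPRC, noise_pulse_protocol, sample_population, \
    sinusoid_protocol

__all__ = [
    "locking_phase_experiment", "psi_vs_delta1_experiment",
    "low_freq_mode_experiment", "distribution_cif_experiment",
    "noise_tuning_experiment", "beta_recovery_experiment",
    "iprc_recovery_experiment", "network_decorrelation_experiment",
]

#: weak-drive amplitude (pA) for locking-phase analyses: the psi = D1
#: prediction is first order in the drive, so it is tested in the regime
#: where the first-order term dominates
WEAK_AMP = 2.0
#: frequency subset and per-frequency durations (s) for the distribution /
#: CIF comparison; durations grow with frequency so the empirical CIF
#: estimator converges where the modulation is weak
CIF_FREQS = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0, 50.0, 70.0)
CIF_DURATIONS = {5.0: 300.0, 10.0: 300.0, 15.0: 300.0, 20.0: 300.0,
                 25.0: 300.0, 30.0: 300.0, 35.0: 1500.0, 40.0: 1500.0,
                 50.0: 3000.0, 70.0: 5000.0}


def locking_phase_experiment(theta: float = 0.5, rate: float = 30.0,
                             amplitude: float = WEAK_AMP,
                             height: float = 2 * MEAN_IPRC) -> float:
    """Stable locking phase of a triangular-iPRC pacemaker driven by a weak
    sinusoid at its intrinsic rate (400-start-phase return map)."""
    neuron = PhaseNeuron(rate, TriangularIPRC(theta, height))
    rmap = ent.compute_return_map(neuron, rate, amplitude)
    lock = ent.find_locking_phase(rmap)
    if lock is None or not lock.stable:
        raise RuntimeError("no stable locking phase found")
    return float(lock.psi)


def psi_vs_delta1_experiment(n: int = 16, seed: int = 0,
                             amplitude: float = 5.0) -> dict:
    """Return-map locking phase vs fundamental-mode angle across a
    heterogeneous population, with the regression slope and Pearson r."""
    pop = sample_population(n, seed=seed)
    psis, d1s = [], []
    for nrn in pop:
        rmap = ent.compute_return_map(nrn, nrn.rate, amplitude)
        lock = ent.find_locking_phase(rmap)
        psis.append(lock.psi)
        d1s.append(float(decompose(nrn.iprc, 1).angle[0]))
    res = stats.linregress(d1s, psis)
    return {"slope": float(res.slope), "r": float(res.rvalue),
            "psi": np.array(psis), "delta1": np.array(d1s)}


def low_freq_mode_experiment(seed: int = 0, rate: float = 30.0,
                             theta: float = 0.7, f_stim: float = 8.0,
                             amplitude: float = 20.0, duration: float = 100.0,
                             nbins: int = 20) -> float:
    """Modal spike-phase bin center of a positive-mean-iPRC pacemaker driven
    far below its intrinsic rate (intrinsic noise tuned to ISI CV 0.08)."""
    quiet = PhaseNeuron(rate, TriangularIPRC(theta, 2 * MEAN_IPRC))
    noise_sd = net.tune_intrinsic_noise(quiet, seed=seed, duration=100.0)
    neuron = PhaseNeuron(rate, quiet.iprc, noise_sd)
    train = simulate_spike_train(neuron, SinusoidStimulus(f_stim, amplitude),
                                 duration, seed=seed)
    dist = ent.phase_distribution(spikes_to_phases(train, f_stim), nbins)
    return float(dist.mode_center())


def distribution_cif_experiment(seed: int = 0, n_neurons: int = 6,
                                amplitude: float = 20.0,
                                freqs=CIF_FREQS, nbins: int = 25) -> dict:
    """Predicted vs simulated spike-phase distributions and pairwise CIFs.

    For each neuron: simulate the sinusoid protocol over ``freqs``; tune the
    map-iteration noise (beta) against the spikes at the locking frequency;
    predict each distribution from the noisy return map.  For each pair and
    frequency: empirical CIF by pair counting vs CIF predicted from the two
    trains' own phase distributions.  Returns mean Pearson correlations and
    the amplitude correlation.
    """
    pop = sample_population(n_neurons, seed=seed)
    trains, emp_dists = {}, {}
    dist_rs = []
    for i, nrn in enumerate(pop):
        tr = {}
        for f in freqs:
            dur = CIF_DURATIONS.get(float(f), 300.0)
            tr.update(sinusoid_protocol(nrn, [f], seed=seed + 101 * i,
                                        amplitude=amplitude, duration=dur))
        summary = ent.entrainment_summary(tr)
        f_lock = ent.locking_frequency(summary)
        reference = spikes_to_phases(tr[f_lock], f_lock)
        rmap_lock = ent.compute_return_map(nrn, f_lock, amplitude)
        beta = ent.tune_beta(rmap_lock, reference, seed=seed + 7)
        trains[nrn.id] = tr
        for f in freqs:
            emp = ent.phase_distribution(spikes_to_phases(tr[f], f), nbins)
            pred = ent.predict_phase_distribution(
                nrn, f, amplitude, beta, nbins=nbins, n_samples=100000,
                seed=seed + 11)
            dist_rs.append(ent.distribution_fit(pred, emp))
            emp_dists[(nrn.id, f)] = emp
    cif_rs, amp_emp, amp_pred = [], [], []
    for f in freqs:
        for a, b in combinations([n.id for n in pop], 2):
            emp = corr.empirical_cif(trains[a][f], trains[b][f], f, nbins)
            pred = corr.predicted_cif(emp_dists[(a, f)], emp_dists[(b, f)], f)
            cif_rs.append(float(np.corrcoef(emp.values, pred.values)[0, 1]))
            amp_emp.append(corr.cif_summary(emp).amplitude)
            amp_pred.append(corr.cif_summary(pred).amplitude)
    return {"mean_dist_r": float(np.mean(dist_rs)),
            "mean_cif_r": float(np.mean(cif_rs)),
            "amplitude_r": float(np.corrcoef(amp_emp, amp_pred)[0, 1]),
            "dist_rs": np.array(dist_rs), "cif_rs": np.array(cif_rs)}


def noise_tuning_experiment(n: int = 10, seed: int = 0,
                            target_cv: float = 0.08) -> np.ndarray:
    """Achieved ISI CV per neuron after bisection noise tuning (200 s
    verification runs, seeds distinct from the tuning runs)."""
    pop = sample_population(n, seed=seed)
    cvs = []
    for i, nrn in enumerate(pop):
        quiet = PhaseNeuron(nrn.rate, nrn.iprc, 0.0, nrn.id)
        sd = net.tune_intrinsic_noise(quiet, target_cv=target_cv,
                                      seed=seed + i, duration=200.0)
        cvs.append(net._autonomous_cv(quiet, sd, 200.0, 1e-4,
                                      seed + 5000 + i))
    return np.array(cvs)


def beta_recovery_experiment(seed: int = 0, beta_star: float = 0.01) -> dict:
    """Plant a beta, generate a reference sample from the model itself, and
    recover it with the bisection tuner."""
    neuron = PhaseNeuron(30.0, TriangularIPRC(0.7, 2 * MEAN_IPRC))
    rmap = ent.compute_return_map(neuron, 30.0, 20.0)
    reference = ent.iterate_with_noise(rmap, beta_star, 50000, seed=seed + 42)
    beta_hat = ent.tune_beta(rmap, reference, seed=seed + 7)
    return {"beta_star": beta_star, "beta_hat": float(beta_hat)}


def iprc_recovery_experiment(n: int = 8, seed: int = 0) -> dict:
    """Full noise-pulse protocol on neurons spanning the population's iPRC
    skew range; per-neuron estimate/truth correlation and fundamental-angle
    error."""
    thetas = np.linspace(0.40, 0.95, n)
    rng = np.random.default_rng(seed)
    rates = rng.uniform(10.0, 40.0, size=n)
    rs, d1_errs = [], []
    for i, (theta, rate) in enumerate(zip(thetas, rates)):
        neuron = PhaseNeuron(float(rate),
                             TriangularIPRC(float(theta), 2 * MEAN_IPRC),
                             noise_sd=0.08 * np.sqrt(rate), id=i)
        record, train = noise_pulse_protocol(neuron, seed=seed + 13 * i)
        est = prc.estimate_iprc(prc.build_charge_matrix(record, train))
        truth = neuron.iprc(est.bin_centers)
        rs.append(float(np.corrcoef(est.z_hat, truth)[0, 1]))
        d1_hat = float(decompose(est.as_iprc(), 1).angle[0])
        d1_true = (0.75 - theta / 2) % 1.0
        err = abs(d1_hat - d1_true)
        d1_errs.append(min(err, 1.0 - err))
    return {"r": np.array(rs), "d1_err": np.array(d1_errs)}


def network_decorrelation_experiment(seed: int = 0, n: int = 100,
                                     freqs=(8.0, 35.0, 80.0),
                                     duration: float = 20.0) -> dict:
    """Connected vs unconnected vs barrage at desk scale; per-frequency
    median CIF amplitude and median delay for each configuration."""
    pop = sample_population(n, seed=seed)
    out = net.compare_configurations(pop, freqs=freqs, duration=duration,
                                     seed=seed)
    medians = {}
    for mode, survey in out["surveys"].items():
        grp = survey.groupby("frequency")
        medians[mode] = {
            "amplitude": grp["amplitude"].median().to_dict(),
            "delay": grp["delay"].median().to_dict(),
        }
    return {"medians": medians, "surveys": out["surveys"]}
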