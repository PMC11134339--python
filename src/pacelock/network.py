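"""Inhibitory phase-model network of pallidal pacemakers.

One thousand (by default) heterogeneous phase neurons are wired with a
directed small-world graph — each neuron receives synapses from its 10
nearest ring neighbors, 1% of edges rewired — and interact through
conductance synapses with instantaneous rise, 2.4 ms exponential decay,
quantal peaks ~ N(2.5, 1.75) nS truncated at 0, and a -73 mV reversal.  A
phase model has no membrane voltage, so synaptic conductance is converted to
current through a fixed nominal driving force (V_nominal = -55 mV, i.e.
-18 pA/nS); the scale this introduces is absorbed by the per-neuron
calibrations (noise tuned to ISI CV 0.08, bias current compensating the
inhibition-induced rate loss).

Three configurations isolate what connectivity does to pairwise
correlations under common sinusoidal drive: ``connected``, ``unconnected``
(synapses removed), and ``unconnected_barrage`` (synapses removed but each
neuron bombarded by Poisson inhibitory events at the mean rate it received
when connected, destroying the temporal structure).

The full-scale experiment (N=1000, 1-100 Hz, 100 s each) is exposed through
the same functions; the defaults used by :func:`compare_configurations` are
desk scale (N=100, f in {8, 35, 80} Hz, 20 s).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import networkx as nx

from . import _kernels
from .correlation import pair_survey
from .errors import ConfigurationError, TuningError
from .phase import PhaseNeuron, SpikeTrain, TABLE_SIZE

__all__ = ["NetworkConfig", "AdjacencyGraph", "build_graph",
           "tune_intrinsic_noise", "rate_compensation", "simulate_network",
           "NetworkResult", "compare_configurations"]

DESK_FREQS = (8.0, 35.0, 80.0)


@dataclass(frozen=True)
class NetworkConfig:
    """Network, synapse and integration parameters (defaults per the GPe
    model: small-world k=10 with 1% rewiring, tau=2.4 ms, quantal peaks
    N(2.5, 1.75) nS, E_rev=-73 mV, 20 pA drive, 0.1 ms Euler step)."""

    n: int = 1000
    k: int = 10
    rewire: float = 0.01
    architecture: str = "small_world"  # | random | rich_club
    tau_s: float = 2.4e-3
    q_mean: float = 2.5
    q_sd: float = 1.75
    e_rev: float = -73.0
    v_nominal: float = -55.0
    amplitude: float = 20.0
    dt: float = 0.1e-3
    configuration: str = "connected"  # | unconnected | unconnected_barrage
    seed: int = 0

    def __post_init__(self):
        if self.n < 2:
            raise ConfigurationError("need at least 2 neurons")
        if not 0 < self.k < self.n:
            raise ConfigurationError("in-degree must satisfy 0 < k < n")
        if not 0.0 <= self.rewire <= 1.0:
            raise ConfigurationError("rewiring fraction must lie in [0, 1]")
        if self.architecture not in ("small_world", "random", "rich_club"):
            raise ConfigurationError(f"unknown architecture {self.architecture}")
        if self.configuration not in ("connected", "unconnected",
                                      "unconnected_barrage"):
            raise ConfigurationError(
                f"unknown configuration {self.configuration}")

    @property
    def syn_gain(self) -> float:
        """pA of synaptic current per nS of open conductance (negative:
        inhibitory at the nominal operating voltage)."""
        return self.e_rev - self.v_nominal


@dataclass(frozen=True)
class AdjacencyGraph:
    """Directed edges presynaptic -> postsynaptic, CSR by source."""

    indptr: np.ndarray
    targets: np.ndarray
    n: int

    @property
    def n_edges(self) -> int:
        return self.targets.size

    def out_degrees(self) -> np.ndarray:
        return np.diff(self.indptr)

    def in_degrees(self) -> np.ndarray:
        return np.bincount(self.targets, minlength=self.n)

    def edges(self) -> np.ndarray:
        src = np.repeat(np.arange(self.n), self.out_degrees())
        return np.column_stack([src, self.targets])

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(map(tuple, self.edges()))
        return g


def _csr_from_edges(edges: set, n: int) -> AdjacencyGraph:
    arr = np.array(sorted(edges), dtype=np.int64)
    src, tgt = arr[:, 0], arr[:, 1]
    order = np.argsort(src, kind="stable")
    src, tgt = src[order], tgt[order]
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(indptr, src + 1, 1)
    indptr = np.cumsum(indptr)
    return AdjacencyGraph(indptr=indptr, targets=tgt, n=n)


def build_graph(config: NetworkConfig, seed: int | None = None) -> AdjacencyGraph:
    """Build the synaptic graph: exactly n*k directed edges, no self-edges.

    small_world: each neuron receives edges from its k nearest ring
    neighbors (k/2 per side), then round(rewire*n*k) edges have their
    *target* reassigned uniformly (no duplicates, no self-edges).
    random: k distinct random presynaptic sources per neuron.
    rich_club: out-degrees drawn from a truncated Zipf law (long-tailed
    number of postsynaptic targets per neuron) renormalized to n*k edges.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, k = config.n, config.k
    if config.architecture == "small_world":
        if k % 2:
            raise ConfigurationError("small-world ring needs an even k")
        edges = set()
        for j in range(n):  # j receives from its k nearest neighbors
            for off in range(1, k // 2 + 1):
                edges.add(((j - off) % n, j))
                edges.add(((j + off) % n, j))
        n_rewire = int(round(config.rewire * n * k))
        edge_list = sorted(edges)
        pick = rng.choice(len(edge_list), size=n_rewire, replace=False)
        for idx in pick:
            u, v = edge_list[idx]
            edges.discard((u, v))
            while True:
                w = int(rng.integers(n))
                if w != u and (u, w) not in edges:
                    edges.add((u, w))
                    break
    elif config.architecture == "random":
        edges = set()
        for j in range(n):
            pool = np.delete(np.arange(n), j)
            for u in rng.choice(pool, size=k, replace=False):
                edges.add((int(u), j))
    else:  # rich_club
        ranks = np.arange(1, n + 1, dtype=float)
        w = ranks ** -1.5  # truncated Zipf: long-tailed out-degree
        w = rng.permutation(w)
        quota = w / w.sum() * n * k
        deg = np.floor(quota).astype(int)
        rem = int(n * k - deg.sum())
        frac_order = np.argsort(quota - deg)[::-1]
        deg[frac_order[:rem]] += 1
        deg = np.minimum(deg, n - 1)
        short = int(n * k - deg.sum())
        while short > 0:  # degree cap pushed edges out; refill greedily
            room = np.flatnonzero(deg < n - 1)
            take = room[rng.integers(room.size)]
            deg[take] += 1
            short -= 1
        edges = set()
        for u in range(n):
            pool = np.delete(np.arange(n), u)
            for j in rng.choice(pool, size=deg[u], replace=False):
                edges.add((u, int(j)))
    graph = _csr_from_edges(edges, n)
    if graph.n_edges != n * k:
        raise ConfigurationError("edge bookkeeping failed")  # pragma: no cover
    return graph


def _autonomous_cv(neuron: PhaseNeuron, noise_sd: float, duration: float,
                   dt: float, seed: int) -> float:
    current = np.zeros(int(round(duration / dt)))
    times = _kernels.run_current_train(neuron.rate, neuron.iprc.table(),
                                       current, dt, noise_sd * np.sqrt(dt),
                                       seed)
    isis = np.diff(times)
    if isis.size < 10:
        raise TuningError("too few ISIs to measure a CV")
    return float(isis.std() / isis.mean())


def tune_intrinsic_noise(neuron: PhaseNeuron, target_cv: float = 0.08,
                         seed: int = 0, duration: float = 200.0,
                         dt: float = 0.1e-3, tol: float = 0.01,
                         max_iter: int = 30) -> float:
    """Diffusion noise SD (cycles s**-1/2) giving an unperturbed ISI CV of
    ``target_cv`` (within ``tol``), found by bisection against ``duration``-
    second autonomous simulations.  CV is monotone in the noise SD."""
    if target_cv <= 0:
        return 0.0

    def cv(sd):
        return _autonomous_cv(neuron, sd, duration, dt, seed)

    lo, hi = 0.0, 2.0 * target_cv * np.sqrt(neuron.rate)
    it = 0
    while cv(hi) < target_cv:
        hi *= 2.0
        it += 1
        if it > 10:
            raise TuningError("could not bracket the target CV")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        c = cv(mid)
        if abs(c - target_cv) <= tol:
            return mid
        if c < target_cv:
            lo = mid
        else:
            hi = mid
    raise TuningError("noise bisection did not converge")


def _single_neuron_rate(neuron: PhaseNeuron, bias: float, inh_rate: float,
                        config: NetworkConfig, duration: float,
                        seed: int) -> float:
    spk, counts, _ = _kernels.network_sim(
        np.array([neuron.rate]), neuron.iprc.table()[None, :],
        np.array([neuron.noise_sd * np.sqrt(config.dt)]),
        np.array([bias]), np.zeros(2, np.int64), np.zeros(0, np.int64),
        float(np.exp(-config.dt / config.tau_s)), config.syn_gain,
        config.q_mean, config.q_sd, 0.0, 1.0, config.dt,
        int(round(duration / config.dt)), seed,
        np.array([inh_rate]), False, inh_rate > 0,
        int(60 * duration) + 32)
    return counts[0] / duration


def rate_compensation(neuron: PhaseNeuron, inh_rate: float,
                      config: NetworkConfig, duration: float = 50.0,
                      seed: int = 0, rel_tol: float = 0.02,
                      max_iter: int = 40) -> float:
    """Constant excitatory current (pA) restoring the neuron's mean rate to
    its intrinsic rate (within ``rel_tol``) while it receives Poisson
    inhibitory events at ``inh_rate`` (events/s).  Bisection; the bias is
    monotone in the inhibitory event rate."""
    if inh_rate <= 0:
        return 0.0
    target = neuron.rate

    def rate(bias):
        return _single_neuron_rate(neuron, bias, inh_rate, config,
                                   duration, seed)

    lo = 0.0
    # expected mean inhibitory current: rate * mean quantal area * gain
    mean_q = _truncated_mean(config.q_mean, config.q_sd)
    hi = max(4.0 * abs(config.syn_gain) * inh_rate * mean_q * config.tau_s, 1.0)
    it = 0
    while rate(hi) < target:
        hi *= 2.0
        it += 1
        if it > 10:
            raise TuningError("could not bracket the compensation current")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r = rate(mid)
        if abs(r - target) <= rel_tol * target:
            return mid
        if r < target:
            lo = mid
        else:
            hi = mid
    raise TuningError("compensation bisection did not converge")


def _truncated_mean(mu: float, sd: float) -> float:
    """Mean of max(N(mu, sd), 0)."""
    from scipy.stats import norm
    a = mu / sd
    return mu * norm.cdf(a) + sd * norm.pdf(a)


@dataclass(frozen=True)
class NetworkResult:
    trains: list
    rates: np.ndarray
    inh_event_rates: np.ndarray
    config: NetworkConfig
    frequency: float
    duration: float


def simulate_network(population: Sequence[PhaseNeuron], graph: AdjacencyGraph,
                     config: NetworkConfig, f_stim: float, duration: float,
                     seed: int = 0, biases: np.ndarray | None = None,
                     barrage_rates: np.ndarray | None = None) -> NetworkResult:
    """Simulate the population under common sinusoidal drive.

    ``configuration='connected'`` uses the graph's synapses;
    ``'unconnected'`` removes them; ``'unconnected_barrage'`` replaces each
    neuron's presynaptic input with independent Poisson events at
    ``barrage_rates`` (events/s), typically the per-neuron mean inhibitory
    event rate measured in the connected run.
    """
    N = len(population)
    if graph is not None and graph.n != N:
        raise ConfigurationError("graph size does not match the population")
    mode = config.configuration
    use_syn = mode == "connected"
    use_bar = mode == "unconnected_barrage"
    if use_syn and graph is None:
        raise ConfigurationError("connected configuration needs a graph")
    if use_bar and barrage_rates is None:
        raise ConfigurationError("barrage configuration needs barrage_rates")
    f0s = np.array([nrn.rate for nrn in population])
    tables = np.stack([nrn.iprc.table(TABLE_SIZE) for nrn in population])
    sig_steps = np.array([nrn.noise_sd for nrn in population]) * np.sqrt(config.dt)
    biases = np.zeros(N) if biases is None else np.asarray(biases, float)
    if use_syn:
        indptr, targets = graph.indptr, graph.targets
    else:
        indptr, targets = np.zeros(N + 1, np.int64), np.zeros(0, np.int64)
    br = (np.asarray(barrage_rates, float) if use_bar else np.zeros(N))
    n_steps = int(round(duration / config.dt))
    spk, counts, n_events = _kernels.network_sim(
        f0s, tables, sig_steps, biases, indptr, targets,
        float(np.exp(-config.dt / config.tau_s)), config.syn_gain,
        config.q_mean, config.q_sd, config.amplitude, f_stim, config.dt,
        n_steps, int(seed), br, use_syn, use_bar,
        int(np.ceil(1.8 * max(f0s.max(), f_stim) * duration)) + 32)
    trains = []
    for i, nrn in enumerate(population):
        t = spk[i, :counts[i]]
        t = t[(t >= 0) & (t < duration)]
        trains.append(SpikeTrain(t, duration, nrn.id,
                                 {"freq": f_stim, "amp": config.amplitude,
                                  "seed": int(seed), "config": mode}))
    return NetworkResult(trains=trains, rates=counts / duration,
                         inh_event_rates=n_events / duration,
                         config=config, frequency=f_stim, duration=duration)


def calibrate_population(population: Sequence[PhaseNeuron],
                         graph: AdjacencyGraph, config: NetworkConfig,
                         seed: int = 0, tune_duration: float = 50.0
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Per-neuron (bias current, expected inhibitory event rate).

    The event rate each neuron receives in the compensated connected network
    is the sum of its presynaptic intrinsic rates (compensation restores
    every neuron to its intrinsic rate); the bias is then tuned against a
    Poisson barrage at that rate.
    """
    f0s = np.array([nrn.rate for nrn in population])
    in_rates = np.zeros(len(population))
    src = np.repeat(np.arange(graph.n), graph.out_degrees())
    np.add.at(in_rates, graph.targets, f0s[src])
    biases = np.array([
        rate_compensation(nrn, in_rates[i], config, duration=tune_duration,
                          seed=seed + i)
        for i, nrn in enumerate(population)])
    return biases, in_rates


def compare_configurations(population: Sequence[PhaseNeuron],
                           config: NetworkConfig | None = None,
                           freqs: Iterable[float] = DESK_FREQS,
                           duration: float = 20.0, seed: int = 0,
                           nbins: int = 50) -> dict:
    """Run connected / unconnected / unconnected_barrage under the same
    population and seeds and summarize all pairwise CIFs per configuration.

    Returns {'surveys': {config_name: DataFrame}, 'results': {...},
    'biases': ..., 'inh_rates': ...}.  The DataFrames come from
    :func:`pacelock.correlation.pair_survey`.
    """
    population = list(population)
    N = len(population)
    if config is None:
        config = NetworkConfig(n=N, seed=seed)
    if config.n != N:
        config = replace(config, n=N)
    graph = build_graph(config, seed=seed)
    biases, inh_rates = calibrate_population(population, graph, config,
                                             seed=seed)
    rates = {nrn.id: nrn.rate for nrn in population}
    surveys, results = {}, {}
    for mode in ("connected", "unconnected", "unconnected_barrage"):
        cfg = replace(config, configuration=mode)
        use_bias = mode in ("connected", "unconnected_barrage")
        trains = {}
        res_by_f = {}
        for j, f in enumerate(freqs):
            res = simulate_network(
                population, graph, cfg, float(f), duration,
                seed=seed + 1000 * j,
                biases=biases if use_bias else None,
                barrage_rates=inh_rates if mode == "unconnected_barrage" else None)
            trains[float(f)] = {tr.neuron_id: tr for tr in res.trains}
            res_by_f[float(f)] = res
        surveys[mode] = pair_survey(trains, rates, nbins=nbins)
        results[mode] = res_by_f
    return {"surveys": surveys, "results": results,
            "biases": biases, "inh_rates": inh_rates, "graph": graph}
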