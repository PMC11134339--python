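"""Circular statistics, return maps, noisy iteration, phase distributions."""

import numpy as np
import pytest

from pacelock.entrainment import (circular_sd, compute_return_map,
                                  distribution_fit, find_locking_phase,
                                  iterate_with_noise, phase_distribution,
                                  tune_beta, vector_angle, vector_strength)
from pacelock.errors import (DegenerateMapError, UndefinedStatisticError)
from pacelock.phase import PhaseSample, PhaseNeuron, TriangularIPRC


class TestCircularStatistics:
    def test_constant_phase_has_unit_vector_strength(self):
        s = PhaseSample(np.full(100, 0.3), 10.0)
        assert vector_strength(s) == pytest.approx(1.0)
        assert vector_angle(s) == pytest.approx(0.3)

    def test_antipodal_pair_cancels(self):
        s = PhaseSample(np.array([0.0, 0.5]), 10.0)
        assert vector_strength(s) == pytest.approx(0.0, abs=1e-12)
        with pytest.raises(UndefinedStatisticError):
            vector_angle(s)

    def test_quarter_turn_pair(self):
        s = PhaseSample(np.array([0.0, 0.25]), 10.0)
        assert vector_strength(s) == pytest.approx(np.sqrt(2) / 2)

    def test_mean_direction_of_two_vectors(self):
        assert vector_angle(PhaseSample(np.array([0.2, 0.4]), 1.0)) == \
            pytest.approx(0.3)

    def test_mean_direction_across_the_wrap(self):
        assert vector_angle(PhaseSample(np.array([0.9, 0.1]), 1.0)) == \
            pytest.approx(0.0, abs=1e-12)

    def test_empty_sample_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            vector_strength(PhaseSample(np.array([]), 1.0))


class TestReturnMap:
    def test_zero_amplitude_is_rigid_rotation(self, symmetric_neuron):
        rmap = compute_return_map(symmetric_neuron, 10.0, 0.0)
        assert rmap.n_points == 400
        expected = 10.0 / symmetric_neuron.rate
        assert np.max(np.abs(rmap.displacement() - expected)) < 1e-6

    def test_resonant_map_crosses_identity_below_unit_slope(
            self, symmetric_neuron):
        rmap = compute_return_map(symmetric_neuron, 30.0, 20.0)
        lock = find_locking_phase(rmap)
        assert lock is not None and lock.stable
        assert 0.5 > lock.slope > -1.0
        assert lock.psi == pytest.approx(0.5, abs=0.08)

    def test_halving_dt_convergence(self, skewed_neuron):
        a = compute_return_map(skewed_neuron, 25.0, 20.0, n_points=50)
        b = compute_return_map(skewed_neuron, 25.0, 20.0, n_points=50,
                               dt=0.025e-3)
        diff = np.abs(a.phi_next - b.phi_next)
        diff = np.minimum(diff, 1 - diff)  # circular distance
        assert np.max(diff) < 1e-3


class TestFindLockingPhase:
    def test_skewed_triangle_locks_slightly_above_quarter(self, skewed_neuron):
        rmap = compute_return_map(skewed_neuron, 30.0, 20.0)
        lock = find_locking_phase(rmap)
        assert 0.25 < lock.psi < 0.35

    def test_off_resonant_rotation_has_no_fixed_point(self, symmetric_neuron):
        rmap = compute_return_map(symmetric_neuron, 30.0 * np.sqrt(2), 0.0)
        assert find_locking_phase(rmap) is None

    def test_resonant_undriven_map_is_degenerate(self, symmetric_neuron):
        rmap = compute_return_map(symmetric_neuron, 30.0, 0.0)
        with pytest.raises(DegenerateMapError):
            find_locking_phase(rmap)


class TestIterateWithNoise:
    def test_zero_noise_matches_deterministic_iteration(self, skewed_neuron):
        rmap = compute_return_map(skewed_neuron, 24.0, 20.0)
        sample = iterate_with_noise(rmap, 0.0, 50, seed=3)
        # every iterate must satisfy the interpolated map exactly
        d = rmap.displacement()
        grid = rmap.phi_prev
        for prev, nxt in zip(sample.phases[:-1], sample.phases[1:]):
            disp = np.interp(prev, np.concatenate([grid, [1.0]]),
                             np.concatenate([d, [d[0]]]))
            assert nxt == pytest.approx((prev + disp) % 1.0, abs=1e-9)

    def test_same_seed_identical(self, symmetric_neuron):
        rmap = compute_return_map(symmetric_neuron, 28.0, 20.0)
        a = iterate_with_noise(rmap, 0.01, 500, seed=5)
        b = iterate_with_noise(rmap, 0.01, 500, seed=5)
        assert np.array_equal(a.phases, b.phases)

    def test_linearized_stationary_spread(self, symmetric_neuron):
        # near a stable fixed point with slope s, the iterated phases form an
        # AR(1) process with stationary SD sigma/sqrt(1-s^2)
        rmap = compute_return_map(symmetric_neuron, 30.0, 20.0)
        s = find_locking_phase(rmap).slope
        beta = 0.004
        sigma = beta * np.sqrt(30.0)
        sample = iterate_with_noise(rmap, beta, 200000, seed=11)
        observed = circular_sd(sample) / (2 * np.pi)
        assert observed == pytest.approx(sigma / np.sqrt(1 - s ** 2),
                                         rel=0.05)


class TestTuneBeta:
    def test_recovers_planted_beta(self, noisy_neuron):
        rmap = compute_return_map(
            PhaseNeuron(noisy_neuron.rate, noisy_neuron.iprc), 30.0, 20.0)
        beta_star = 0.01
        reference = iterate_with_noise(rmap, beta_star, 50000, seed=42)
        beta_hat = tune_beta(rmap, reference, seed=7)
        assert beta_hat == pytest.approx(beta_star, rel=0.10)

    def test_zero_spread_reference_gives_zero(self, symmetric_neuron):
        rmap = compute_return_map(symmetric_neuron, 30.0, 20.0)
        reference = PhaseSample(np.full(200, 0.44), 30.0)
        assert tune_beta(rmap, reference) == 0.0

    def test_monotone_in_reference_spread(self, symmetric_neuron):
        rmap = compute_return_map(symmetric_neuron, 30.0, 20.0)
        betas = []
        for beta_star in (0.004, 0.01, 0.025):
            ref = iterate_with_noise(rmap, beta_star, 30000, seed=1)
            betas.append(tune_beta(rmap, ref, seed=2))
        assert betas[0] < betas[1] < betas[2]


class TestPhaseDistribution:
    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(0)
        d = phase_distribution(PhaseSample(rng.random(1000), 10.0), 50)
        assert d.probs.sum() == pytest.approx(1.0)
        assert np.all(d.probs >= 0)

    def test_uniform_sample_is_flat_within_multinomial_bound(self):
        rng = np.random.default_rng(1)
        n, nbins = 100000, 20
        d = phase_distribution(PhaseSample(rng.random(n), 10.0), nbins)
        sd = np.sqrt((1 / nbins) * (1 - 1 / nbins) / n)
        assert np.max(np.abs(d.probs - 1 / nbins)) < 5 * sd

    def test_identical_distributions_correlate_perfectly(self):
        rng = np.random.default_rng(2)
        sample = PhaseSample(rng.beta(2, 5, 2000), 10.0)
        d = phase_distribution(sample, 25)
        assert distribution_fit(d, d) == pytest.approx(1.0)

    def test_reversal_of_asymmetric_distribution_decorrelates(self):
        rng = np.random.default_rng(3)
        sample = PhaseSample(rng.beta(2, 5, 2000), 10.0)
        d = phase_distribution(sample, 25)
        from pacelock.entrainment import SpikePhaseDistribution
        rev = SpikePhaseDistribution(d.edges, d.probs[::-1], d.frequency)
        assert distribution_fit(d, rev) < 1.0

    def test_constant_vector_is_undefined(self):
        from pacelock.entrainment import SpikePhaseDistribution
        edges = np.linspace(0, 1, 11)
        flat = SpikePhaseDistribution(edges, np.full(10, 0.1), 10.0)
        with pytest.raises(UndefinedStatisticError):
            distribution_fit(flat, flat)
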