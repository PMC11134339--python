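"""Cross-intensity functions: empirical counting vs the distribution
cross-correlation identity."""

import numpy as np
import pytest

from pacelock.correlation import (CIF, cif_summary, delay_pdfs, empirical_cif,
                                  pair_survey, predicted_cif)
from pacelock.entrainment import (SpikePhaseDistribution, phase_distribution)
from pacelock.errors import InputError
from pacelock.phase import (PhaseSample, SinusoidStimulus, SpikeTrain,
                            simulate_spike_train, spikes_to_phases)
from pacelock.synthetic import sample_population


def _dist(probs, f=10.0):
    probs = np.asarray(probs, dtype=float)
    edges = np.linspace(0, 1, probs.size + 1)
    return SpikePhaseDistribution(edges, probs / probs.sum(), f)


def _concentrated(center, nbins=50, f=10.0):
    probs = np.zeros(nbins)
    probs[int(center * nbins)] = 1.0
    return _dist(probs, f)


class TestPredictedCIF:
    def test_uniform_distributions_give_flat_cif(self):
        flat = _dist(np.ones(50))
        cif = predicted_cif(flat, flat, 10.0)
        assert np.allclose(cif.values, 1.0, atol=1e-12)

    def test_concentrated_distributions_peak_at_the_mode_offset(self):
        # P1 at 0.2, P2 at 0.5 under a 10 Hz drive: peak lag 0.03 s
        cif = predicted_cif(_concentrated(0.2), _concentrated(0.5), 10.0)
        assert cif.lags[np.argmax(cif.values)] == pytest.approx(0.03)
        assert cif_summary(cif).delay == pytest.approx(0.3)

    def test_matches_brute_force_double_sum(self):
        # independent oracle: explicit double sum over distribution bins
        rng = np.random.default_rng(4)
        p1 = _dist(rng.random(50) + 0.05)
        p2 = _dist(rng.random(50) + 0.05)
        cif = predicted_cif(p1, p2, 10.0)
        n = 50
        for k, tau in enumerate(cif.lags):
            shift = int(round(tau * 10.0 * n))
            brute = 0.0
            for i in range(n):
                brute += p1.probs[i] * p2.probs[(i + shift) % n]
            assert cif.values[k] == pytest.approx(n * brute, abs=1e-12)

    def test_mean_is_one_over_the_period(self):
        rng = np.random.default_rng(5)
        cif = predicted_cif(_dist(rng.random(40) + 0.1),
                            _dist(rng.random(40) + 0.1), 20.0)
        assert cif.values.mean() == pytest.approx(1.0, abs=1e-12)

    def test_mismatched_binning_rejected(self):
        with pytest.raises(InputError):
            predicted_cif(_dist(np.ones(50)), _dist(np.ones(40)), 10.0)


class TestEmpiricalCIF:
    def test_autocorrelation_peaks_at_zero_lag(self):
        rng = np.random.default_rng(6)
        t = np.sort((np.arange(500) + 0.3 + 0.01 * rng.standard_normal(500))
                    * 0.1)
        train = SpikeTrain(t, 51.0)
        cif = empirical_cif(train, train, 10.0, 50)
        assert cif.lags[np.argmax(cif.values)] == pytest.approx(0.0)

    def test_shifted_copy_peaks_at_the_shift(self):
        rng = np.random.default_rng(7)
        base = np.sort((np.arange(500) + 0.3
                        + 0.01 * rng.standard_normal(500)) * 0.1)
        shifted = base + 0.025  # T/4 at 10 Hz
        a = SpikeTrain(base, 52.0)
        b = SpikeTrain(shifted, 52.0)
        cif = empirical_cif(a, b, 10.0, 40)  # 0.025 s sits on the lag grid
        assert cif.lags[np.argmax(cif.values)] == pytest.approx(0.025)

    def test_unnormalized_mean_equals_rate_product(self):
        # conservation: independent Poisson trains have a flat CIF at r1*r2
        rng = np.random.default_rng(8)
        dur = 200.0
        t1 = np.sort(rng.uniform(0, dur, 3000))
        t2 = np.sort(rng.uniform(0, dur, 4000))
        a, b = SpikeTrain(t1, dur), SpikeTrain(t2, dur)
        cif = empirical_cif(a, b, 10.0, 50, normalize=False)
        r1r2 = (3000 / dur) * (4000 / dur)
        assert cif.values.mean() == pytest.approx(r1r2, rel=0.05)

    def test_matches_prediction_from_own_distributions(self):
        # ~1e4-spike driven pair: the counting estimator agrees with the
        # cross-correlation of the trains' own phase distributions.  The
        # pair is driven near (not exactly at) its intrinsic rates so the
        # distributions are modulated without collapsing to near-deltas
        # (binning a near-delta before cross-correlating smears its peak).
        from pacelock.phase import PhaseNeuron, TriangularIPRC
        pop = [PhaseNeuron(33.0, TriangularIPRC(0.55, 1.2),
                           0.08 * np.sqrt(33.0), 0),
               PhaseNeuron(28.0, TriangularIPRC(0.85, 1.2),
                           0.08 * np.sqrt(28.0), 1)]
        f, dur = 35.0, 350.0
        tr = [simulate_spike_train(n, SinusoidStimulus(f, 20.0), dur,
                                   seed=13 + i) for i, n in enumerate(pop)]
        assert min(len(t) for t in tr) > 3000
        dists = [phase_distribution(spikes_to_phases(t, f), 50) for t in tr]
        emp = empirical_cif(tr[0], tr[1], f, 50)
        pred = predicted_cif(dists[0], dists[1], f)
        r = np.corrcoef(emp.values, pred.values)[0, 1]
        assert r > 0.95

    def test_empty_train_rejected(self):
        good = SpikeTrain(np.array([0.1]), 1.0)
        with pytest.raises(InputError):
            empirical_cif(good, SpikeTrain(np.array([]), 1.0), 10.0)


class TestCIFSummary:
    def test_flat_cif_has_undefined_delay(self):
        cif = CIF(np.linspace(-0.045, 0.05, 20), np.ones(20), 10.0)
        s = cif_summary(cif)
        assert not s.delay_defined

    def test_ties_resolve_to_smallest_absolute_delay(self):
        lags = (np.arange(10) - 4) / (10 * 10.0)
        values = np.ones(10)
        values[1] = values[7] = 2.0  # delays -0.3 and +0.3: tie
        s = cif_summary(CIF(lags, values, 10.0))
        assert abs(s.delay) == pytest.approx(0.3)

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            p1 = _dist(rng.random(50) + 0.02)
            p2 = _dist(rng.random(50) + 0.02)
            d12 = cif_summary(predicted_cif(p1, p2, 10.0)).delay
            d21 = cif_summary(predicted_cif(p2, p1, 10.0)).delay
            # delays negate under a swap of the pair, modulo the wrap
            assert abs((d12 + d21 + 0.5) % 1.0 - 0.5) < 1e-9


class TestPairSurvey:
    def test_sixteen_neurons_make_120_pairs(self):
        rng = np.random.default_rng(10)
        dur = 30.0
        trains = {10.0: {}}
        rates = {}
        for i in range(16):
            t = np.sort(rng.uniform(0, dur, 300))
            trains[10.0][i] = SpikeTrain(t, dur, i)
            rates[i] = 30.0
        survey = pair_survey(trains, rates)
        assert len(survey) == 16 * 15 // 2

    def test_delay_pdfs_cover_the_frequencies(self):
        rng = np.random.default_rng(11)
        dur = 30.0
        trains = {f: {i: SpikeTrain(np.sort(rng.uniform(0, dur, 200)), dur, i)
                      for i in range(4)} for f in (5.0, 10.0)}
        survey = pair_survey(trains, {i: 20.0 for i in range(4)})
        pdfs = delay_pdfs(survey)
        assert set(pdfs) == {5.0, 10.0}
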