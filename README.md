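# pacelock

Phase-response-curve analysis of pacemaker neurons entrained by a common
oscillatory drive.

Neurons of the external globus pallidus (GPe) are autonomous pacemakers.
When many of them receive the same sinusoidal input — as happens when beta
oscillations sweep the basal ganglia in parkinsonism — pairs of GPe neurons
develop oscillatory spike correlations with a broad spread of pairwise phase
delays. `pacelock` implements, on fully synthetic data, the computational
chain showing that these delays follow from each neuron's *intrinsic*
phase-response curve rather than from the coupling between neurons:

1. **Phase model.** Each pacemaker is a phase variable φ ∈ [0, 1) obeying
   dφ/dt = f + I(t)·Z(φ), with intrinsic rate f (spikes/s), injected current
   I (pA), and infinitesimal phase-response curve (iPRC) Z (cycles/pC);
   a spike fires when φ crosses 1.
2. **iPRC estimation.** Z is recovered from a noise-pulse experiment
   (40 episodes × 4 s of contiguous 0.25 ms pulses, amplitudes
   N(0, 40 pA)) by a 50-bin charge-matrix regression:
   ISIₐ/⟨ISI⟩ = 1 − Σᵢ Q₍ₐ,ᵢ₎ Z(φᵢ) + εₐ.
3. **Fourier modes.** Z(φ) = Z̃₀ + Σₙ Z̃ₙ cos(2π[nφ + Δₙ]). Driving the
   neuron at n times its intrinsic rate interacts only with mode n, and a
   weak drive stably locks the spikes at stimulus phase ψ = Δₙ. For the
   unity-height triangular iPRC peaking at θ, Δ₁ = 3/4 − θ/2.
4. **Return maps and spike-phase distributions.** Integrating the phase
   equation yields the map φ_prev → φ_next of stimulus phases at successive
   spikes; iterating it with additive noise (SD β√f) reproduces the
   distribution P(φ; f) of spike phases at any drive frequency.
5. **Cross-intensity functions (CIFs).** For independent, commonly driven
   neurons, the pairwise spike cross-correlation within one stimulus period
   equals the circular cross-correlation of the two spike-phase
   distributions: R₁₂(τ; f) = ∫ P₁(φ) P₂(φ + fτ) dφ. Its peak lag is the
   pair's phase delay.
6. **Network model.** A small-world inhibitory network (N neurons, 10
   incoming synapses each, 1% rewired; conductance synapses with 2.4 ms
   decay, quantal peaks N(2.5, 1.75) nS, reversal −73 mV) shows that local
   connectivity *decorrelates* the population — CIF amplitudes drop — while
   leaving the phase delays essentially unchanged.

No recorded data are needed: `pacelock.synthetic` generates populations of
heterogeneous pacemakers (rates uniform on 10–40 spikes/s, triangular iPRCs
with peak location θ ~ U[0.4, 0.95]) and both stimulation protocols.

## Worked example

```python
from pacelock.phase import (PhaseNeuron, TriangularIPRC, SinusoidStimulus,
                            simulate_spike_train, spikes_to_phases)
from pacelock.fourier import decompose, predicted_locking_phase
from pacelock.entrainment import (compute_return_map, find_locking_phase,
                                  vector_strength, vector_angle)

neuron = PhaseNeuron(rate=30.0, iprc=TriangularIPRC(theta=0.9, height=1.2),
                     noise_sd=0.44)

modes = decompose(neuron.iprc, n_modes=3)
psi_pred, _ = predicted_locking_phase(modes, harmonic=1)
# fundamental mode: amplitude 0.417, angle Delta1 = 0.300
# predicted locking phase psi = Delta1 = 0.300

rmap = compute_return_map(neuron, frequency=30.0, amplitude=2.0)
lock = find_locking_phase(rmap)
# return-map locking phase psi = 0.298 (slope 0.919)

train = simulate_spike_train(neuron, SinusoidStimulus(30.0, 20.0),
                             duration=30.0, seed=1)
phases = spikes_to_phases(train, 30.0)
vector_strength(phases), vector_angle(phases)
# 899 spikes; VS = 0.939, VA = 0.280
```

Reading: the skewed triangle's fundamental Fourier angle (0.300) predicts
where the neuron locks; the full return-map computation agrees (0.298), and
a noisy 30 s simulation at the intrinsic rate indeed concentrates its spikes
near that stimulus phase (vector angle 0.280) with strong locking
(vector strength 0.94, where 1 means firing at the identical phase every
cycle).

A command-line wrapper exposes the same stages
(`pacelock simulate-neuron`, `make-fixtures`, `estimate-iprc`, `modes`,
`entrainment`, `return-map`, `cif`, `network`); see `pacelock --help`.

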