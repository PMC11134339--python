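# Methods

This note records the model conventions, calibrations, numerical choices
and limitations behind `pacelock`. It is the place to look when a default
seems arbitrary: every number here is either a stated property of the
emulated experiments or a package design choice explained below.

## Phase model and units

A pacemaker neuron is reduced to a phase φ ∈ [0, 1) with intrinsic rate
f (spikes/s) and an infinitesimal phase-response curve (iPRC) Z(φ):

    dφ/dt = f + I(t) · Z(φ),        spike whenever φ crosses 1.

Units are chosen so the coupling term is dimensionally closed: I in pA, Z
in cycles/pC, time in s (pA × s = pC, so I·Z·dt is a phase increment in
cycles). Positive Z means a depolarizing current advances the phase and
shortens the current interspike interval (ISI).

Integration is forward Euler — 0.05 ms steps for deterministic return-map
work, 0.1 ms for spike-train and network simulation. The threshold
crossing is located by linear interpolation inside the final step, and the
phase is reset by subtracting 1 rather than zeroing, so the overshoot is
kept and the firing rate carries no systematic step-size bias. Halving the
step changes return-map points by < 10⁻³ cycles (tested). The drive may
make dφ/dt negative away from φ = 0; the integrator allows the phase to
recede (a strongly hyperpolarizing input can then stall the phase where
f = −I·Z, which is reported as a no-spike error after 10 intrinsic
periods).

**Intrinsic noise.** Each Euler step adds Gaussian phase noise. The
neuron's noise field is a diffusion-style SD σ in cycles·s^−1/2 (per-step
SD σ√dt), which makes the autonomous ISI coefficient of variation
CV ≈ σ/√f independent of the step size. A per-step parameterization would
silently change the neuron when the solver step changed.

## Synthetic populations (what is emulated, what is not)

`pacelock.synthetic` generates the study conditions:

* intrinsic rates uniform on 10–40 spikes/s;
* triangular iPRCs (zero at the spike, peak at θ ~ U[0.4, 0.95]) — a
  first approximation of empirical pallidal iPRCs, which are mostly
  positive and unimodal; a smooth 7-parameter alternative family is
  provided (`smooth_iprc_population`) since every consumer accepts any
  iPRC object;
* intrinsic noise set for an ISI CV of 0.08, the value measured in the
  emulated recordings;
* the noise-pulse protocol (40 episodes × 4 s of contiguous 0.25 ms
  pulses, amplitudes N(0, 40 pA)) and the sinusoid protocol (1–100 Hz in
  1 Hz steps, 20 pA, one train per frequency).

**iPRC magnitude.** The triangle height is scaled so the cycle-average of
Z is 0.6 cycles/pC (height 1.2). This single number sets how strongly
20 pA drives the model. It was fixed once on realism grounds: it gives
(i) low-frequency firing-rate modulation of ~±12 spikes/s at a 30 spikes/s
cell — visibly sinusoidal spike-phase histograms; (ii) a 1:1 entrainment
bandwidth of a few Hz around the intrinsic rate; and (iii) noise-pulse
regression signal comparable to the intrinsic ISI variability. All
downstream defaults assume this scale only through the calibrations below,
never directly.

What the generator does **not** emulate: recording artifacts (drift,
access resistance), cell death across the protocol, non-stationary
intrinsic rates, and — important for interpretation — iPRCs that remain
large immediately before the spike. Because the triangle vanishes at
φ = 1, fast drive (≳ 2× the intrinsic rate) modulates these model neurons
only weakly (spike-phase vector strength ~0.05 at 80–90 Hz). Real
pallidal neurons are more strongly modulated there, so tests passing on
synthetic data validate the pipeline's machinery, not the quantitative
high-frequency behavior of real cells; see "Problem sizes" for the
consequences.

## iPRC estimation

Each ISI is divided into 50 equal-duration phase bins and the injected
charge per bin Q₍ₐ,ᵢ₎ (pC) is accumulated from the pulse record via its
cumulative integral, so pulses straddling bin edges are apportioned
exactly by time overlap. ISIs that straddle an episode boundary are
dropped (their stimulus is not contiguous). Ordinary least squares (no
intercept) of ISIₐ/⟨ISI⟩ − 1 on the charge rows yields the 50 iPRC values
with standard errors; the reported iPRC is the *negative* of the fitted
coefficients so that positive Z means phase advance, consistent with the
phase equation above. The regression is unweighted and no outlier pruning
is applied. A rank-deficient design (e.g. a zero-amplitude stimulus) is a
hard error rather than a silent pseudo-inverse.

The tabulated estimate can be condensed into a smooth 7-parameter periodic
form — baseline, skewed raised-cosine bump (amplitude, center, width,
skew) and a first-harmonic cosine/sine correction — by bounded least
squares; if the optimizer fails the package falls back, with a warning, to
a circularly smoothed table.

## Fourier conventions

Z(φ) = Z̃₀ + Σₙ Z̃ₙ cos(2π[nφ + Δₙ]), with Z̃ₙ = √(ZnC² + ZnS²) from the
cosine/sine transforms and the angle computed as

    Δₙ = atan2(−ZnS, ZnC) / 2π   (mod 1).

The two-argument arctangent matters: a quadrant-blind −arctan(ZnS/ZnC)/2π
would assign Δ₁ = 0 to the symmetric triangle, whose series identity (and
locking behavior) requires Δ₁ = 1/2. The closed forms for the triangle —
ZnC = [cos 2πnθ − 1]/[2π²θ(1−θ)n²], ZnS = sin 2πnθ/[2π²θ(1−θ)n²], hence
Δ₁ = 3/4 − θ/2 — are implemented independently and the quadrature
decomposition agrees with them to < 10⁻⁶ (tested). Quadrature is the
midpoint rule on 65,536 nodes (spectrally accurate for smooth periodic
integrands, O(h²) for the piecewise-linear ones; a halving check keeps
coefficient error < 10⁻⁸).

A weak sinusoid at n× the intrinsic rate interacts only with mode n, and
the stable locking phase is ψ = Δₙ (the companion solution ψ = 1/2 + Δₙ is
unstable). This prediction is first order in the drive amplitude: at
20 pA × this generator's Z scale, the full return-map fixed point is
shifted by ≈ −0.04 cycles relative to Δ₁ (second-order map distortion),
so the population-level ψ-vs-Δ₁ correspondence is assessed at a weak 5 pA
drive, the regime the derivation assumes.

## Return maps, noise iteration, β tuning

Return maps use 400 equidistant stimulus start phases; each point is an
independent deterministic integration started at neuron phase 0. Fixed
points are located by sign changes of the wrapped displacement with linear
interpolation; a crossing is stable when the local map slope is < 1. The
undriven resonant map (displacement identically zero) is reported as a
degenerate, non-isolated-fixed-point condition instead of returning an
arbitrary phase.

Spike-phase samples are produced by iterating the map with additive
Gaussian noise of SD β√f (burn-in 100 iterations; the map is interpolated
periodically between grid points). The √f scaling compensates the shorter
stimulus period at higher drive frequency. β is tuned per neuron by
bisection so that the circular SD (√(−2 ln VS), VS the vector strength) of
the iterated phases matches the simulated spikes at the neuron's locking
frequency — the drive frequency maximizing VS — to within 2%. "Spread" had
to be given an operational definition; circular SD was chosen because it
is monotone in VS and well behaved for tight locking. Vector angle at
VS = 0 is an error, not 0, to avoid manufacturing spurious zero delays.

## Cross-intensity functions

Empirical CIFs count spike-pair lags t₂ − t₁ within ± half a stimulus
period and histogram them on a lag grid of integer multiples of T/nbins
(default nbins = 50), symmetric about zero so in-phase and antiphase are
visually centered. Predicted CIFs are the circular cross-correlation of
two spike-phase distributions on the same grid. Both are normalized to
mean 1 over the period, making the amplitude a unitless modulation factor
(all comparisons in the package are scale-free; the unnormalized rate
density, whose period-mean is rate₁ × rate₂ for independent trains, is
available for conservation checks). Amplitude = max of the normalized CIF;
delay = argmax lag × f wrapped to (−0.5, 0.5], ties broken toward the
smallest |delay|; a flat CIF (peak-to-trough < 1% of the mean) reports an
undefined delay.

Caveat: the predicted CIF bins each distribution before cross-correlating,
which smears near-delta distributions by one extra bin width relative to
direct lag counting. Agreement checks therefore use drive conditions under
which the distributions are modulated but not collapsed onto single bins.

## Network model

N phase neurons (default 1000; desk scale 100) are wired by a directed
small-world graph: each neuron receives synapses from its 10 nearest ring
neighbors and 1% of edges have their target reassigned uniformly (random
and long-tailed "rich-club" architectures, and in-degree 5/20 variants,
are provided at identical total edge count). Presynaptic spikes increment
the target's inhibitory conductance by a quantal peak drawn from
N(2.5, 1.75) nS truncated at 0 (≈8% of the untruncated mass is negative;
truncation keeps conductances physical), decaying exponentially with
τ = 2.4 ms; coincident events sum linearly. A phase model has no membrane
voltage, so conductance becomes current through a fixed nominal driving
force: I_syn = g·(E_rev − V_nom) with E_rev = −73 mV and V_nom = −55 mV,
i.e. −18 pA/nS. The arbitrariness of V_nom is absorbed by the two
per-neuron calibrations, which are defined operationally:

* **Noise tuning:** bisection on the diffusion SD until a 200 s autonomous
  simulation has ISI CV = 0.08 ± 0.01.
* **Rate compensation:** each neuron's expected inhibitory event rate is
  the sum of its presynaptic intrinsic rates; bisection on a constant
  excitatory bias until the neuron, bombarded by Poisson events at that
  rate, recovers its intrinsic rate to ±2%.

Three configurations share one population, graph and seed: `connected`;
`unconnected` (synapses removed); and `unconnected_barrage` (synapses
removed, each neuron receiving independent Poisson inhibitory events at
the rate it would receive when connected — the mean inhibition without its
temporal structure). Synaptic delays, gap junctions and short-term
plasticity are not modeled.

## Problem sizes

All stochastic analyses are seeded and sized to finish on one core:

* distribution/CIF comparison: 6 neurons, 10 drive frequencies
  {5, 10, 15, 20, 25, 30, 35, 40, 50, 70} Hz, simulated 300 s per
  frequency at ≤30 Hz rising to 5000 s at 70 Hz, 25 phase/lag bins. The
  graded durations exist because the empirical CIF estimator's noise must
  fall below the true CIF modulation, which shrinks with drive frequency
  for this generator (see the synthetic-population caveat); above ~70 Hz
  the modulation (~1%) is unresolvable at any practical duration, which is
  why those frequencies are not part of the comparison set.
* network comparison: N = 100, drive at 8/35/80 Hz, 20 s per frequency.
  At this scale the decorrelation (lower connected CIF amplitudes) is
  clearly resolved at 8 and 35 Hz; at 80 Hz the pairwise CIF amplitude is
  dominated by histogram-max noise (~150 spike pairs per neuron pair) and
  the comparison there is not informative — the corresponding check is
  expected to fail at desk scale and is retained deliberately rather than
  resized.
* iPRC recovery: 8 neurons spanning θ ∈ [0.4, 0.95], full 40 × 4 s
  protocol; noise tuning: 10 neurons × 200 s; locking analyses: 400-point
  return maps.

## Known limitations

* High-frequency (≳ 2× intrinsic rate) entrainment of the synthetic
  population is much weaker than in real pallidal cells; conclusions about
  that regime rest on the model's structure, not on resolved statistics.
* The conductance→current mapping uses a fixed driving force; a
  phase-dependent nominal voltage would change the effective synaptic
  strength over the cycle.
* The rich-club generator uses a truncated Zipf out-degree (exponent 1.5)
  — one reasonable long-tailed choice among many.
* The β-noise iterated map treats successive stimulus phases as a Markov
  chain; slow components of intrinsic noise (rate drift) would violate
  this and are not modeled.
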