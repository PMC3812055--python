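# Methods

## Model overview

`cortexsim` simulates two interconnected cortical networks. Each network is
a two-dimensional sheet of excitatory pyramidal cells (PYs) with a matched
sheet of inhibitory interneurons (INs): 400×400 PYs / 200×200 INs per
network at full scale, 100×100 / 50×50 in the `desk` preset used throughout
the test suite. All neurons follow the canonical two-variable Izhikevich
model, integrated with a forward Euler step of Δt = 0.1 ms:

    v' = v + Δt (0.04 v² + 5 v + 140 − u + I)
    u' = u + Δt a (b v − u)
    if v' ≥ 30 mV:  v' ← c,  u' ← u' + d   (spike)

The total current I is the sum of synaptic current
G_EX (E_AMPA − v) + G_IN (E_GABA − v) with E_AMPA = 0 mV, E_GABA = −80 mV, a
constant per-neuron bias, a uniform noise term redrawn at every step
(U(0, 2) for PYs, U(0, 1.5) for INs), and — for PYs only — the tACS
sinusoid.

### Neuron heterogeneity

PYs: a = 0.02, b = 0.2 for all; the reset potential c and recovery increment
d are drawn comonotonically (one uniform p per neuron) from generalized-
Pareto quantile rules

    Q_c(p) = −65 + 15 (1 − p)²   (GPD μ = −50, σ = −30, ξ = −2; median −61.25 mV)
    Q_d(p) = 8 − 2 (1 − p)²      (GPD μ = 6,  σ = 4,  ξ = −2; median 7.50)

so most PYs are regular-spiking (c near −65, d near 8) with a tail of
intrinsically-bursting/chattering cells (c near −50, d near 6). The shared
uniform draw follows the standard Izhikevich heterogeneity recipe the
parameterization derives from; both marginals match the stated supports and
medians either way. INs: c = −65, d = 2, a ~ U(0.02, 0.1),
b ~ U(0.2, 0.25).

### Synapses

All afferents of a neuron are lumped into one excitatory and one inhibitory
conductance accumulator, decaying exponentially (τ_EX = 2 ms, τ_IN = 3 ms);
a presynaptic spike adds its weight on the delivery step. Delivery is at
t + 1 step for local (zero-delay) projections and t + delay for long-range
projections, which avoids within-step order dependence. In the compiled
kernel, conductances below 1e-12 are flushed to zero: the exponential tails
are physically irrelevant at that magnitude but would otherwise sit in the
denormal float range, costing roughly a 10× slowdown.

PY→PY synapses carry short-term depression: one resource variable D per
presynaptic PY multiplies all of its outgoing PY→PY weights. D recovers as
D ← 1 − (1 − D) exp(−Δt/τ_D) with τ_D = 300 ms (applied analytically each
step, so there is no Euler drift), and a spike consumes resources. Two
forms of the consumption rule are implemented:

* **reset** (default): D ← r with r = 0.6 — the fraction of resources
  available immediately after release is r regardless of history;
* **multiplicative**: D ← r·D — Tsodyks-style cumulative depletion.

Both satisfy the same verbal definition of r. The reset form is the default
because, in this network, cumulative depletion (r^k after k spikes within an
UP state) suppresses the synchronous re-ignition that produces the rapid-
fire (RF) regime: with the multiplicative rule the networks settle into
perpetual weak traveling waves, whereas the reset rule reproduces the
RF/SP/SW taxonomy and its dependence on delays. The multiplicative form
remains available via `SimConfig(depression_reset=False)`.

### Topology

* Local excitation: every PY connects to a random 30% subset of the (up to)
  120 cells in its 11×11 Chebyshev neighborhood (G_PY-PY = 0.06, no
  autapses). The neighborhood is truncated at the open grid boundary —
  boundary neurons connect to round(0.3 × eligible) neighbors — because
  open boundaries let rotors pin, as spiral-wave snapshots require.
* Inhibitory loops are globally random within a network: 25 PY→IN contacts
  per PY (weight 1e-4) and 49 IN→PY contacts per IN (weight 2e-4). The
  printed weight label for the feedback loop is read as the IN→PY weight.
* Long-range projections (LRPs): each local PY-PY connection is
  independently rewired with probability 1 − P(local) into an excitatory
  projection onto a uniformly random PY of the *other* network (or the
  homologous grid coordinate), with conductance G(LRP) and a conduction
  delay (fixed, or uniform over mean ± 20%/100%). Per-connection Bernoulli
  rewiring reproduces the expected fractions of PYs possessing at least one
  LRP (≈30% at P(local) = 0.99, ≈3.6% at 0.999 at full grid size).

### Input currents and the bias calibration

Every neuron receives a constant bias drawn once per run from the quantile
rule Q(p) = bias_max · p^k. The published description of this distribution
is internally inconsistent: its parameters are typographically garbled, the
stated median (0.19) is incompatible with the stated parameters, and —
decisive for the model — a support of [0, 1.5] leaves every PY below the
canonical Izhikevich rheobase (I = 4 with b = 0.2, given the noise mean of
1), while the bias's stated purpose is to create spontaneously firing PYs.
We verified by simulation (desk and full scale, several initial-condition
schemes) that with the [0, 1.5] support both networks fall permanently
silent after the initial transient: no spontaneous UP states, hence no slow
oscillation, no metastable states and no response to tACS. That reading is
therefore rejected.

The default is `NoiseSpec(bias_max=2.7, bias_exponent=3.85)`: the quantile
keeps the polynomial form and the stated median (2.7/2^3.85 ≈ 0.187), and
the support is extended just far enough that a small tail of PYs
(bias ≳ 2.8, roughly 1% of cells) is suprathreshold and acts as ignition
sites for UP states — the "regions of initiation" the model's phenomenology
requires. The pair (2.7, 3.85) was calibrated once against the model's own
stated operating point — an endogenous slow oscillation at ≈3 Hz with an
RF-dominant baseline in the absence of LRPs — and is frozen; no experiment
or test re-tunes it. The literal reading is kept as `NoiseSpec.printed()`
(support [0, 1.5], Q = 1.5 p³) for reference.

tACS is a sinusoidal current into all PYs (INs are not stimulated):
amplitude 1.0 ≡ 10 pA, 3 Hz, onset 2 s, duration 4 s in an 8 s run; the
antiphase protocol shifts network 2's waveform by 180°. Note that with the
canonical equations, amplitude 1.0 moves a passive membrane by ≈1.3 mV
(linearized gain at the resting node), not the ~100 µV sometimes quoted for
10 pA; the sanity test asserts a weak, subthreshold, amplitude-proportional
modulation rather than a specific magnitude.

### Determinism

All randomness is split into per-purpose streams (topology per network,
neuron parameters, bias, per-step noise), so changing recording options
never changes dynamics. The per-step noise uses a counter-based splitmix64
generator keyed by (seed, step, neuron), making records byte-identical for
equal seeds and independent of any threading or chunking.

## Analysis pipeline

### Activity profiles

Two profiles are derived from a record:

* the **spike-count profile** — spikes per 1 ms bin / N × 100 — used for
  spectrograms and cross-correlations (fine temporal resolution matters
  there);
* the **participation profile** — distinct PYs firing per 5 ms bin / N ×
  100, counted in the kernel so each neuron contributes at most once per
  bin — used for state classification.

The 5 ms participation bin is a deliberate resolution choice for the
percent-of-neurons-firing signal: with strictly local 11×11 coupling, a
network-wide UP state recruits the sheet through wave propagation over
several milliseconds, so no physically possible regime puts >60% of PYs in
a single 1 ms bin at full grid size; at 5 ms the synchronized-UP regime
classifies as RF while propagating-wave and rotor regimes remain below the
RF band. The value was fixed by calibrating once against the baseline
taxonomy (isolated desk networks RF-dominant, delayed-LRP runs showing SP
and extra transitions) and is configurable per run
(`SimConfig.participation_bin_ms`).

### States and transitions

UP-state peaks are local maxima of the profile above 1% of its maximum,
thinned with a 50 ms dead time (largest peak first; among closer peaks the
larger one is kept, ties to the earlier). Each 1 s bin is labeled by the
median amplitude of its peaks: RF > 60%, SP 15–60% (boundaries inclusive),
SW < 15%. Bins without peaks inherit the previous bin's label (a silent
second inside an SW epoch should not flip the state); a peakless first bin
defaults to SW, configurable. Transition frequency is the number of label
changes divided by the duration. Ensemble transition matrices condition the
state in a later 1 s window on the state in an earlier one (before onset,
after onset, final second); rows for unobserved source states are flagged
undefined rather than reported as 0/0.

### Spectral and correlation statistics

Spectrograms use complex Morlet wavelets (6 cycles) on the fixed grid
0.5–10 Hz in 0.5 Hz steps. Wavelets are truncated at ±4σ and L2-normalized,
so white noise has flat expected power across the grid; a cone-of-influence
mask flags samples within one wavelet half-support of the edges, and
time-averaged quantities (f_max, window powers) use the interior. The
profile mean is removed first, making the power offset-invariant and
quadratic in amplitude.

Cross-correlograms are zero-mean and unit-energy normalized (any signal's
zero-lag autocorrelation is exactly 1), evaluated over lags up to ±500 ms —
comfortably covering the ≈333 ms endogenous period. tACS contrasts use the
protocol windows before = [0, 2) s, during = [2, 6) s, after = [6, 8) s and
report log10 power ratios (during/before, after/before) at the stimulation
frequency per network, plus the windowed peak correlation and its lag.

Ensembles are clustered two ways: average-linkage agglomeration of the
scalar peak-correlation values (flat clusters cut at 90% of the maximum
merge height, labels ordered by descending cluster mean), and k-means
(k = 3, 10 restarts, seeded) over full correlogram vectors, whose clusters
are named from centroid morphology (most negative zero lag → "strong
antiphase"; larger remaining amplitude → "interspersed weak firing";
flat → "breaking from RF").

## Synthetic fixtures

The fixture generator produces profiles with known ground truth so the
analysis pipeline is testable without the simulator. The UP-state waveform
is a sharpened rectified sinusoid (positive lobe to the 6th power: ≈46 ms
half-width at 3 Hz, well inside the 50 ms dead time) at a per-segment
amplitude chosen inside one classifier band. Uniform noise rides on the
crest region only; troughs are exactly silent, as in real percent-firing
profiles where no neurons fire between UP states — trough-wide additive
noise would plant spurious low peaks that poison the per-bin median, a
failure mode real profiles do not have. Spike rasters are binomial
thinnings of a target profile; correlogram families are damped-cosine
templates with additive noise for the three antiphase-tACS morphologies.

What fixtures do not emulate: 2-D spatial structure (spirals, wave fronts),
amplitude drift within a state, and the skewed peak-amplitude distributions
of real runs near band edges. Passing fixture tests therefore validates the
peak/threshold/median logic, not the simulator's dynamics; the desk-scale
simulation tests cover the latter.

## Problem sizes and study conditions in the test suite

Dynamics tests run the `desk` preset (100×100 PYs, 50×50 INs per network;
25,000 neurons total across both networks) for 8 s; connection densities
per neuron are identical to full scale, so in-degrees and synaptic drive
match the 400×400 system. LRP-coupled runs use the exemplar condition
P(local) = 0.99, G(LRP) = 0.06 with delays 0 or 50 ms (10 ms for tACS
protocols). Ensemble statistics use 5–10 seeds per condition. Full-scale
ensembles (100 simulations per delay at 400×400) are supported by the same
code paths (`GridSpec`/`SweepSpec`) but are multi-hour jobs by nature and
are not part of the default suite.

## Known limitations

* The published input-current parameters are internally inconsistent under
  the canonical neuron equations (see the bias calibration above); the
  package's defaults restore the stated operating point but are a
  reconstruction, not a transcription.
* Spiral-wave (SW) epochs are identified purely by low median peak
  amplitude; no spatial rotor detection is attempted, so fragmented
  low-amplitude waves and true rotors are not distinguished.
* At desk scale SW is rare: the smaller sheet gives reentrant waves less
  room, so statistics specific to SW occupancy and persistence are
  full-scale quantities.
* The IN populations are recorded but, with the published inhibitory
  weights (1e-4/2e-4), feedback inhibition is far weaker than the other
  currents and contributes little to UP-state termination, which is
  carried by synaptic depression and spike-frequency adaptation.
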