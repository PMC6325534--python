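# Methods

This note documents the models, estimators and numerical choices behind
`striatal-gamma`: a delta–gamma phase–amplitude-coupling (PAC) analysis
pipeline for multichannel LFPs, and a striatal fast-spiking-interneuron (FSI)
network model whose reconstructed LFP is fed back through the same analysis.

## Analysis side

### Signals and filtering

All signals are uniformly sampled `TimeSeries` (default 1000 samples/s; the
rate is configurable everywhere — absolute-voltage fidelity is not
attempted). Band filtering uses a Butterworth design of order 4 applied
forward and backward (`sosfiltfilt`), so the net phase response is zero and
the effective magnitude is the squared design response. "Order 4" refers to
the designed filter before the forward–backward pass. Delta extraction is a
4 Hz low-pass (`BandSpec(0, 4)`); the named bands are alpha 8–12, beta 13–24,
beta-normalization 15–20, low gamma 25–55, and high gamma 60 Hz up to
min(100, 0.9 × Nyquist). The first and last `3·order` cycles of the band's
low cutoff (capped at 1 s) are contaminated by edge transients; event
detection near recording boundaries should be interpreted accordingly.

Instantaneous amplitude and phase come from the Hilbert analytic signal; the
phase is the four-quadrant angle in [−π, π). Phase convention throughout:
**0 is the delta peak, −π/2 the upsweep, +π/2 the downsweep** (the analytic
phase of a cosine-like oscillation). The generator, the model analysis and
all tables use this convention.

### Gamma events

A channel's gamma envelope is: zero-center → band-pass 25–55 Hz → full-wave
rectify → low-pass 15 Hz → z-score. One event is declared per contiguous
suprathreshold (> 2.5 SD) epoch, timed at the envelope argmax. Because the
threshold is relative to the channel's own envelope statistics, detection is
invariant to overall signal gain. Events whose epoch coincides with a
suprathreshold excursion of an alpha, beta or high-gamma envelope (same
pipeline, same threshold) are excluded as broadband artifacts. When
behavioral epoch labels are supplied, detection is restricted to them and
events straddling an epoch boundary are dropped. Channels with fewer than 50
events are dismissed from phase statistics (configurable; reduced-scale
model runs use a floor of 20 because a 20 s simulation cannot produce 50
events at the model's ~1.4 events/s).

Calibration: on stationary Gaussian noise band-limited to the acquisition
band (0.7–170 Hz), the event peaks amount to ≈ 0.6% of all local maxima of
the recording — the reading of "detected peaks" adopted here is local maxima
of the band-limited raw signal, which reproduces that figure; reading them
as envelope maxima instead gives ≈ 6.7% and was rejected.

### Circular statistics

The delta phase at each event peak forms a circular sample; its mean
resultant vector gives the locking strength r ∈ [0, 1] and preferred phase.
Non-uniformity is tested with the Rayleigh test using the standard finite-n
correction `p = exp(√(1+4n+4(n²−R²)) − (1+2n))`. Unimodality is tested with
Hartigan's dip: the circular sample is rotated so its circular mean sits at
0 and the angles on [−π, π) are then treated as linear (an interpretation;
the alternative — Watson-type circular tests — is out of scope). The dip
statistic is computed with the classic g.c.m./l.c.m. shrinking-interval
algorithm, validated in the test suite against an exact linear-programming
oracle derived from first principles (the optimal unimodal CDF is piecewise
linear with knots at the data points and one atom at the mode). Its p-value
is Monte-Carlo calibrated against the uniform null (500 replicates, seeded).

The flat-phase-difference null reference uses pairs of *white-noise* signals:
the delta phase of a Brownian (1/f²) signal advances too slowly for event
phases to decorrelate within a recording, which makes the Rayleigh test
anticonservative on that input; the Brownian generator is kept for spectral
nulls (its PSD slope is −2).

### Spectra and coherence

PSDs are Thomson multitaper estimates (DPSS tapers, NW = 4, 7 tapers —
configurable; the source analysis did not pin these) on segments whose
length sets the frequency increment to 0.503 Hz from 0.5 to 100 Hz, so no
grid point falls on the 60 Hz line. Each segment is demeaned. Two
normalizations: `beta_band` divides by the mean 15–20 Hz power (a band not
modulated at rest, removing channel-gain bias); `one_over_f2` multiplies by
f², flattening Brownian-like backgrounds. Spectral peaks above a floor
frequency are located on an optionally smoothed (5 Hz moving average)
spectrum; smoothing stabilizes the argmax of broad bumps.

Spectrograms convolve the signal with complex Morlet wavelets (q = 5 cycles,
σ_f = f₀/q, σ_t = 1/(2πσ_f), truncated at a total width of 4σ_t, center
frequencies 0.5–100 Hz in 0.5 Hz steps), keeping the real part. The
normalization constant 1/(√(2π)·σ_t·rate) makes the discrete convolution
approximate a unit-mass continuous kernel; display normalization (sum to 1)
is applied only when rendering.

Complex coherence is estimated over gamma-event epochs only (epochs padded
symmetrically with adjacent signal to ≥ 256 ms so 25 Hz is resolvable,
Hann-tapered), as the averaged cross-spectrum normalized by the auto-spectra,
restricted to 25–55 Hz. The sign convention makes the phase negative when
the second channel lags. A nonzero imaginary part excludes zero-lag (volume
conducted) coupling; the test suite verifies this on zero-lag-mixed vs
lagged surrogates.

## Model side

### FSI unit

Generalized leaky integrate-and-fire neuron with two internal currents and
an adaptive threshold:

    dI_j/dt = −k_j I_j                       k1 = 200/s, k2 = 20/s
    dV/dt   = (Ie + ΣI_j + I_syn + I_gap)/C − G (V − E_L)
    dΘ/dt   = a (V − E_L) − b (Θ − Θ_∞)      a = 5/s, b = 10/s

with C = 1 (currents in V/s), G = 50/s, E_L = −70 mV, Θ_∞ = −50 mV. On a
spike (V ≥ Θ): each current updates as I_j ← R_j·I_j + A_j (Class-2 set:
R1 = 0, R2 = 1, A1 = A2 = 0 — i.e. I1 reset, I2 kept; with zero initial
currents they stay zero and k1, k2 are inert, which is why they are inert
defaults rather than tuned values), Θ ← max(Θ, Θ_r = −60 mV), and the
membrane is held at the spike-time threshold value for 1 ms — approximating
the action-potential width so current can flow through gap junctions — then
reset to V_r = −70 mV. The threshold keeps evolving during the hold; V is
clamped. With this parameter set the unit is Class-2 excitable: the F–I
curve jumps from 0 to ≈ 17 Hz at rheobase (≈ 1.7 V/s), verified with a dt
convergence check (< 2% rate change when dt halves from 0.05 to 0.025 ms).

### Network

FSIs occupy a cubic mesh at 113 µm spacing (27 per side = 19,683 units at
full scale; density 693/mm³). Gap junctions: each unordered pair within
120 µm (the 6 axial neighbors) with probability 0.35 → mean degree ≈ 2.1.
GABAergic synapses: each ordered pair within 339 µm (122 lattice offsets)
with probability 0.58 → in-degree ≈ 71 in the interior. Synaptic weights are
truncated-normal (mean = the swept IPSP parameter g_s, CV 0.25, clipped at
0). No wraparound; edge units simply have fewer neighbors. Comparisons are
inclusive (distance ≤ radius).

Synapse kinetics are two-stage: ṡ_r = (−s_r + δ(t−t*))/τ_r,
ṡ_f = (−s_f + s_r)/τ_f with τ_r = 0.8 ms, τ_f = 12 ms; the inhibitory
current is −g_s·s_f (no reversal potential; g_s is the total charge, in V
with C = 1, withdrawn per presynaptic spike). Transmission delay is one time
step. Gap currents are I_gap,j = Σ_k ρ (V_k − V_j) over coupled neighbors —
pairwise charge conserving by construction; ρ is in normalized units (only
its scale relative to g_s and the drive matters).

Integration is forward Euler, dt = 0.05 ms default (0.1 ms for sweeps;
contract requires dt ≤ 0.1 ms). Initial membrane potentials are uniform in
[E_L, Θ_∞] given the seed. Each neuron additionally receives an independent
white membrane-noise current (spectral amplitude 0.002 V·s^−1/2 by default,
i.e. ~0.2 mV stationary SD; held constant over 0.5 ms blocks for speed)
standing in for background synaptic bombardment that the model does not
represent explicitly. This is the model's only deliberate departure from a
fully deterministic network: without it, identical units under identical
block drive synchronize trivially and the no-gap-junction control is not a
meaningful asynchronous baseline.

### Cortical drive

The drive is a cortical LFP preprocessed as: zero-mean → 4 Hz low-pass
(isolating the delta band) → half-wave rectify (only positive deflections
are injected) → divide by the SD (no re-centering, preserving
non-negativity) → scale by the cortico-FSI gain (CtxFSI). The low-pass is
applied *before* rectification: rectifying first would convert any
high-frequency input into a DC drive and reintroduce negative values at the
filter step. An input with no delta content yields zero drive. A 3×3×3 grid
of 27 cortical units projects topographically, each unit driving an
(n/3)³ block of FSIs; the shipped surrogate drive is a 1.5 Hz delta
oscillation with mild (15%) amplitude modulation and Brownian background
(`synthetic_delta_drive`), shared across units by default.

### LFP reconstruction

Electrode e's signal is V(e,t) = Σ_n ξ_n K(e,n) I_n(t) over that
electrode's neighborhood (Gaussian kernel, σ = 300 µm, prefactor
1/(√(2π)σ) as in the source formulation — a 1D prefactor applied to a 3D
kernel, kept as printed; zero beyond 1.5 mm), with I_n the per-neuron
synaptic current (subsampled to 1 kHz). The orientation affinity ξ_n is the
difference between the electrode distances of the origin and the tip of the
unit field vector (zenith ρ_n ∈ [0, π), azimuth φ_n ∈ [0, 2π); the standard
spherical unit vector — uniform in the angles, not on the sphere, with an
area-uniform option off by default). Composites: all fields toward the
electrode (ξ = 1), one shared random direction, or per-neuron random
directions; all three yield the same event statistics and an in-band gamma
peak on default simulations. The full-scale electrode array is 4×4×4 at
750 µm spacing; reduced-scale runs use 1–8 electrodes centered in the mesh.

### Operating regime and sweeps

The shipped defaults are ρ = 1000, g_s = 0.0008, CtxFSI = 1.25 on a 15³
mesh. In this regime the network fires sparse gamma-locked population
activity on delta upstrokes (~5–10 Hz per unit): a 25–55 Hz peak appears in
the beta-normalized reconstructed-LFP spectrum when gap junctions are
enabled and is absent when they are disabled (gamma-band power differs by
> 2×) — electrotonic coupling is what synchronizes the inhibitory network
against the membrane noise.

The frequency map sweeps (ρ, g_s) ∈ {600, 1000, 2000} × {0.0004, 0.0010,
0.0016} at CtxFSI = 1.0 on the 15³ mesh, 20 s per cell, 3 repeats with
random initial conditions, reporting the 5-Hz-smoothed beta-normalized
spectral peak above 20 Hz of the central electrode. Weak inhibition
(g_s = 0.0004) yields ≈ 43–44 Hz cells; stronger inhibition
(g_s = 0.0010–0.0016, ρ ≥ 1000) slows the rhythm to ≈ 28–31 Hz; ρ ≈ 3000
desynchronizes the network and much larger ρ drives tonic firing above
100 Hz, which is flagged non-physiologic and excluded (N/A cells). The
cortico-FSI gain sweep at the default cell shows gamma power rising from
gain 0.25 through ≈ 1.25–4 and declining by gain 8 as the network
approaches tonic firing. The gamma events of the reconstructed LFP lock to
the driving delta phase (Rayleigh p < 0.05 on all electrodes), with the
preferred phase moving from near the delta peak toward the upsweep (−π/2)
as the gain increases. Problem sizes (15³ units, 10–20 s, 1–3 repeats) are
the package's reduced standard scale; `n_side=27` and longer runs reproduce
the full-scale architecture.

## What the synthetic generator does and does not emulate

`gen_pac_lfp` builds: a delta carrier (default 1.5 Hz) with slow amplitude
modulation and phase-jitter random walk; Poisson-timed (default 0.5/s)
raised-cosine-windowed gamma tone bursts (default 40 Hz, 150 ms) whose
centers are snapped to von Mises draws (concentration κ, preferred phase)
around the carrier phase; plus white or Brownian background noise.
`gen_multichannel` shares the carrier across channels with a per-channel
lag and shares bursts with a configurable probability. Ground truth (burst
times and true phases) is returned for round-trip validation: the full
pipeline recovers injected preferred phases within ±0.25 rad for κ ≥ 1 and
estimated locking strength increases monotonically in κ.

The generator does not emulate: 1/f background other than Brownian,
behavioral-state transitions, cross-frequency directionality, electrode
drift or artifacts, or volume conduction between channels. Passing tests
therefore demonstrate correctness of the estimators under the generative
assumptions, not robustness to every property of real recordings.

## Known limitations

- The no-gap asynchronous baseline depends on the small membrane noise;
  a fully deterministic network with identical shared drive synchronizes
  without gap junctions at some scales.
- Within a gamma event the population-burst rate does not measurably slow
  toward the event's end at the reduced scale; event epochs are short (1–2
  gamma cycles above threshold), so the within-event frequency trend is not
  resolvable.
- The (ρ, g_s) frequency map is bimodal rather than smoothly graded at this
  scale: cells sit near either ~29 Hz or ~44 Hz, with mixed-mode cells in
  between.
- The dip test's circular adaptation (rotate-and-linearize) is one of
  several possible conventions.
- Hartigan dip p-values are Monte Carlo (500 replicates), so they are
  granular below ~0.002.
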