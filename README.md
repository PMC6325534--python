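# striatal-gamma

Delta–gamma phase–amplitude coupling (PAC) analysis for local field
potentials, and a striatal fast-spiking-interneuron (FSI) network model with
gap junctions whose reconstructed LFP runs through the same analysis.

In cortico-striatal recordings from behaving mice, transient bursts of
low-gamma (25–55 Hz) power occur preferentially at particular phases of the
slow delta (< 4 Hz) rhythm — a coupling that is reorganized in Huntington's
disease models. This package provides, for electrophysiologists and
modelers:

- **Gamma-event detection** — z-scored 25–55 Hz envelope, 2.5-SD threshold,
  cross-band (alpha/beta/high-gamma) artifact exclusion; detection is
  invariant to overall signal gain.
- **Circular statistics of event phases** — the mean resultant vector
  r·e^{iθ̄} of delta phases sampled at event peaks, the finite-n Rayleigh
  test of non-uniformity, and Hartigan's dip test of unimodality (circular
  sample rotated to its mean, then linearized). Convention: phase 0 is the
  delta peak, −π/2 the upsweep.
- **Spectral tools** — Thomson multitaper PSDs on a 60-Hz-skipping grid with
  beta-band (15–20 Hz) and 1/f² normalizations, Morlet spectrograms (q = 5
  cycles), and complex coherence restricted to gamma-event epochs (its
  imaginary part excludes zero-lag volume conduction).
- **An FSI network simulator** — generalized leaky integrate-and-fire
  Class-2 units (adaptive threshold, 1 ms spike hold) on a cubic mesh
  (113 µm spacing, 19,683 units at full scale) with distance-dependent gap
  junctions (ρ·(V_k − V_j), ≤ 120 µm, p = 0.35) and GABAergic synapses
  (two-stage 0.8/12 ms kinetics, ≤ 339 µm, p = 0.58), driven by a half-wave
  rectified delta-band cortical signal.
- **An LFP forward model** — per-neuron synaptic currents weighted by a
  spatial Gaussian kernel (σ ≈ 300 µm) and a field-orientation affinity,
  summed at a 4×4×4 electrode array, so model output feeds the identical
  analysis pipeline.
- **A synthetic-data generator** — surrogate recordings with von Mises
  phase-locked gamma bursts and known ground truth, for validating every
  analysis stage without any archival data.

The model reproduces the central mechanistic result: with gap junctions the
inhibitory network generates delta-nested gamma whose peak frequency is set
by gap-junction conductance and IPSP strength (≈ 43 Hz with weak
inhibition, ≈ 29–31 Hz with strong), and without gap junctions no gamma
peak emerges.

## Worked example

Detect gamma events in a surrogate recording with known coupling
(concentration κ = 4 at the delta peak) and measure their phase locking:

```python
import numpy as np
from striatal_gamma import *
from striatal_gamma.synthetic_data import SyntheticSpec, gen_pac_lfp
from striatal_gamma.signal_core import BANDS
from striatal_gamma.phase_circular import PhaseSeries

spec = SyntheticSpec(duration=600.0, kappa=4.0, preferred_phase=0.0, seed=42)
lfp, truth = gen_pac_lfp(spec)

env = gamma_envelope(lfp)
events = detect_events(env, threshold=2.5, channel_id="str0")
events = band_exclusion(events, lfp, channel_id="str0")

delta = zero_phase_filter(lfp.with_samples(lfp.samples - lfp.samples.mean()),
                          BANDS["delta"])
phase = PhaseSeries.from_analytic(analytic_signal(delta).phase, lfp.rate)
plv = phase_lock_vector(phases_at_events(phase, events))
print(f"events: {len(events)} (injected bursts: {len(truth['burst_times'])})")
print(f"vector strength r = {plv.r:.2f}, preferred phase = {plv.angle:+.2f} rad")
print(f"Rayleigh p = {plv.rayleigh_p:.2e}, dip = {plv.dip:.3f} (p = {plv.dip_p:.2f})")
```

Output:

```
events: 249 (injected bursts: 307)
vector strength r = 0.76, preferred phase = -0.04 rad
Rayleigh p = 4.47e-75, dip = 0.014 (p = 1.00)
```

The detector recovers most injected bursts (the remainder fall below the
2.5-SD threshold in noise), the preferred phase sits at the delta peak where
the bursts were injected, the Rayleigh test rejects uniformity, and the dip
test sees a single mode.

The same workflow from the shell:

```bash
striatal-gamma synth --preset hd_like --seed 0 --out rec.csv
striatal-gamma analyze rec.csv --outdir results/
striatal-gamma model-loop --seed 0 --outdir model_out/   # simulate + analyze
striatal-gamma sweep-gamma-map --out map.json            # (rho, g_s) peak map
```

`ModelLoopConfig`/`simulate` expose the network parameters (mesh side,
gap conductance ρ, IPSP mean g_s, cortico-FSI gain, seeds); reduced-scale
defaults (15³ units, 10–20 s) run in seconds per simulation, and
`n_side=27` reproduces the full-scale architecture.

See `docs/methods.md` for the model equations, estimator definitions,
parameter defaults and known limitations.

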