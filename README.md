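# spikeweave

Spiking pattern-recognition platforms with spatial STDP and a
coherence-based network-of-networks that decomposes superimposed
("intertwined") patterns into their source components.

`spikeweave` is for computational neuroscientists and neuromorphic-computing
researchers who want a self-contained, testable implementation of this class
of model: sinusoidal image encoding, sparse excitatory/inhibitory LIF
populations with AMPA/GABA synaptic kinetics and distance-dependent
coupling, unsupervised learning through a spatially modulated STDP window,
rate-based classification, and a phase-synchrony decision rule for
recognizing which source "datasets" contribute to a superimposed input.

## The model

**Encoding.** A grayscale image with N rows and M columns becomes a single
scalar "informative signal"

```
s(t) = Σ_{i=1..N} Σ_{j=1..M} (b_ij + c) · sin(2π F_j t + φ_i),
F_j = j·f_max/M,   φ_i = i·360°/N
```

so the column index sets the frequency, the row index the phase, and the
amplitude is pixel brightness plus a constant c. Signals of different images
add component-wise; images of different dimensions occupy different
frequency lattices, which is what makes superpositions separable. (Because
the phases span the full circle within each column, only the first
row-harmonic of every column survives the sum — see `docs/methods.md`.)
The rectified signal drives one independent inhomogeneous-Poisson input
channel per network neuron.

**Network.** The recognition layer is a rectangular grid of LIF neurons
(τ_m = 20/10 ms for pyramidal cells/interneurons, threshold 18 mV, reset
0 mV, refractory 2/1 ms), 80% excitatory, wired at connection probability
0.2. Each synaptic event kicks a two-stage AMPA or GABA current cascade
after a 1 ms latency, attenuated with distance as `exp(-r/D)`. Classifying
output neurons (one per class) receive full connections from the layer.
The membrane/synapse subsystem is linear, so the integrator advances it
with the exact per-step matrix-exponential propagator; spikes and synaptic
impulses are grid-aligned state jumps (default dt = 0.05 ms).

**Learning.** Pair-based STDP with a spatial factor `exp(+r/Ds)` that
*amplifies* updates for distant pairs: post-after-pre increases AMPA weights
(amplitude 0.06) and decreases GABA weights (amplitude 0.05), scaled by 0.4
when the target is an interneuron; pre-after-post mirrors the sign. The
online trace implementation reproduces the all-pairs double sum exactly.
Training is unsupervised: three epochs of pattern presentations with 100 ms
blanks, then one labeling epoch that assigns each output neuron the class
for which its mean firing rate is maximal; classification is the class of
the maximally firing output neuron.

**Coherence decision.** Each neuron's instantaneous phase is its fractional
position inside the current inter-spike interval; a population phase vector
φ is summarized by the Kuramoto-style order parameter
`R = |mean exp(2πi·φ)|` (R² = 1 − var(z) with z the unit phasors). A hub
network with the same architecture but no training is driven by the
combined signal; its local field potential (Σ |I_AMPA| + |I_GABA|) is
re-encoded as a Poisson rate into each trained platform, and a platform
whose pooled hub/platform R over a fixed shared-neuron set exceeds 0.8 is
declared a member of the superposition, its class read out by maximum
output rate.

## Worked example

```python
import numpy as np
from spikeweave import (CodingParams, encode_image, combine_signals,
                        signal_to_rate, poisson_spikes, recover_quadrature,
                        stdp_window, sync_measure, PlasticityParams)

rng = np.random.default_rng(0)
digit = rng.random((16, 16)).round()      # a toy 16x16 binary glyph
face  = rng.random((20, 15))              # a toy 20x15 gray texture
coding = CodingParams(f_max=40.0, brightness_constant=1.0, dt=1.0,
                      rate_scale=800.0)

mixed = combine_signals([encode_image(digit, coding),
                         encode_image(face, coding)])
_, rate = signal_to_rate(mixed, 0.0, 500.0, coding)
train = poisson_spikes(rate, coding.dt, n_channels=4, seed=1)
```

Querying the objects this builds (component counts, rate statistics,
`recover_quadrature`, `stdp_window`, `sync_measure`) prints:

```
digit signal: 256 sinusoids on the [2.5, 5.0, 7.5]... Hz lattice
mixed signal: 556 sinusoids from shapes [(16, 16), (20, 15)]
drive rate: mean 2130.4 spk/s, peak 15186.0 spk/s; 4 channels produced 4256 spikes in 500 ms
quadrature pair at 2.5 Hz: (1.230, -0.510)
STDP pyr->pyr at +0 ms lag, r=0: 0.0600
STDP pyr->pyr at +10 ms lag, r=5 (Ds=10): 0.0364
R of 500 identical phases: 1.000
R of 500 uniform phases:   2.84e-17
```

The 16×16 and 20×15 images occupy different frequency lattices inside one
scalar signal (556 = 256 + 300 components). The quadrature pair is the
per-frequency content that is exactly recoverable from the code. The STDP
numbers show the zero-lag pyramidal amplitude (0.06) and the spatial
amplification at distance 5 with one 10 ms time constant of temporal decay
(0.06·e^(0.5)·e^(−1) ≈ 0.036). The order parameter hits its analytic
limits: 1 for identical phases, 0 for uniformly spread phases.

A shell workflow over the same machinery:

```
spikeweave make-fixtures --out fixtures/
spikeweave train --manifest fixtures/glyphs/manifest.csv --config desk.yaml --out model
spikeweave eval  --model model --manifest fixtures/glyphs/manifest.csv
spikeweave stdp-window --lag-max 40 > window.tsv
```

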