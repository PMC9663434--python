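# Methods

This note records the model as implemented, the parameter choices that were
genuinely open, what the synthetic data emulate, the numerical scheme, and
the limits of what the desk-scale experiments can show.

## Signal encoding and its null space

An N×M image is encoded as one sinusoid per pixel: amplitude
`brightness + c`, frequency `j·f_max/M`, phase `i·360°/N` (1-based indices,
so the extremes f_max and 360° are attained). Within any column the phases
`i·360/N` traverse the full circle, and `Σ_i b_i·sin(ωt + 2πi/N)` keeps only
the first discrete row-harmonic of the column: column-constant content
(full-height bars, the brightness offset c itself) and every higher row
harmonic cancel identically. The code therefore transmits exactly one
quadrature pair — `(Σ b·cosφ, Σ b·sinφ)` — per column, which is what
`recover_quadrature` returns, and full pixel-level inversion is impossible
for N > 2. We state this prominently because it shapes everything
downstream: two images are distinguishable to the network only if their
per-column first row-harmonics differ, and the synthetic fixture prototypes
are designed accordingly.

Defaults: `brightness_constant = 1` on a [0,1] brightness scale (kept for
interface fidelity even though it cancels), `f_max = 100 Hz` in the library
and `40 Hz` in the desk-scale system (gamma-band ceiling, matching the
coherence readout's natural band), rate sampling `dt = 1 ms`. The
amplitude-to-rate gain `rate_scale` and the rectification mode (`relu`
default, `abs` optional) are plain plumbing the source model never fixes.

## Neuron, synapse and integrator

LIF membranes (τ_m 20/10 ms, threshold 18 mV, reset 0 mV, refractory
2/1 ms) driven by two-stage AMPA/GABA cascades; AMPA rise/decay 0.4/2 ms
and GABA 0.25/5 ms, the standard values of the LIF-with-synaptic-filter
model family this parameter set comes from. A presynaptic spike adds
`τ_m(post)·e^(−r/D)·J` to the target's auxiliary variable after a 1 ms
latency (no attenuation for the external drive); D defaults to 10 grid
units.

Between events the subsystem `(v, I_A, x_A, I_G, x_G)` is linear and
time-invariant, so each step applies the exact matrix-exponential
propagator (one 6×6 `expm` per neuron type at setup, the sixth column
carrying an optional constant drive). Impulses are state jumps at event
times rounded up to the next grid point; threshold crossings are detected
at step ends, with the spike recorded at that grid point; v is clamped at
reset during the refractory period while the synaptic states keep evolving.
Event-queue ties are resolved by accumulation (simultaneous deliveries
sum), and the weight used for an outgoing impulse is the stored weight at
the moment of spike emission, after any same-instant STDP update.

Exact propagation means the free membrane decay matches `e^(−t/τ_m)` to
machine precision at any dt, and the only dt-dependence left is event
timing (≤ one step per event). The step-halving contract is verified on a
50-neuron reference run with irregular, grid-aligned external drive so that
every spike is anchored to an input event; a free-running periodic neuron
is the one configuration that cannot satisfy such a contract, because the
grid quantizes each interspike interval upward and the offset accumulates
per cycle regardless of integration order.

## Spatial STDP

The pair window is `±amp·e^(r/Ds)·exp(−|x|/10 ms)` with the four
cell-type-specific rules (0.06 pyramidal-source, 0.05 interneuron-source,
0.4 interneuron-target scaling); post-after-pre potentiates AMPA and
depresses GABA, pre-after-post mirrors the signs, and a pair at exactly
zero lag contributes nothing (the convention under which the online
trace-based accumulation equals the batch all-pairs double sum to 1e-9,
which the tests verify). The spatial factor grows with distance — the
model's deliberate inversion of the coupling attenuation — with Ds = D by
default. Weights are stored as nonnegative magnitudes (the synapse kind
carries the sign) and clipped to [0, w_max]; unbounded growth is otherwise
guaranteed by the amplifying spatial factor. External input weights are
frozen; output-layer synapses learn under the same rules, with output
neurons counted as pyramidal targets.

The LTD amplitudes are not fixed by the source model. The symmetric choice
(A− = A+) diverges in practice: a driven network has causal
pre-before-post correlations, the LTP branch dominates every AMPA synapse,
GABA weights collapse, and all selectivity is erased. The desk-scale system
therefore uses depression-dominant amplitudes (A− = 2·A+, G− = 2·G_amp),
the standard stability condition for pair-based STDP; the library defaults
keep the symmetric window for interface fidelity.

## Desk-scale study conditions

The reference architecture (5000 neurons, ≈5·10⁶ synapses, 128×128 inputs)
is reachable through configuration; tests and the bundled study run a
300-neuron scaling on a 20×15 grid. Because the recurrent in-degree drops
~16-fold, initial weight scales are raised to keep summed synaptic drive
per neuron comparable (recurrent sd 2.0, output sd 3.0 against the
full-scale 0.2), the external gain is J_ext = 1 with rate_scale = 800, and
the output layer applies per-output charge balancing of its inhibitory
pathway (a synaptic-scaling-style initialization) so classifying neurons
read population activity contrasts rather than the common drive level.
Presentations last 300 ms with 100 ms blanks, three unsupervised epochs
plus one labeling epoch, rates counted after a 20 ms transient.

**Fixtures.** Three families with pairwise distinct dimensions (16×16,
12×10 glyphs; 20×15 smooth blob "faces"), four classes and 20 samples per
class, Gaussian pixel noise sd 0.05 clipped to [0,1], deterministic under
seed, with disjoint train/test splits by construction. Prototypes are
chosen for distinct per-column first-harmonic profiles (the only content
the code transmits) and are rescaled so all classes of a family produce
equal mean rectified signal power, making classification a test of
waveform shape rather than overall level. The fixtures emulate the one
property the intertwined recognizer needs — distinct frequency lattices per
family — and none of the visual richness of real handwriting or face
photographs; passing desk-scale tests demonstrates the machinery, not
benchmark-level recognition.

## Coherence readout

Phases are fractional positions inside the current interspike interval,
sampled on a 5 ms reference grid after a 100 ms transient; the order
parameter is `R = |mean exp(2πiφ)|` per reference time, averaged over the
window. For a (hub, platform) pair the two populations' phase samples at
the shared neuron indices are pooled before computing R — the minimal
two-population extension of a single-vector statistic. The hub LFP
(Σ|I_A|+|I_G| over the layer) is re-encoded as a Poisson rate
`g·LFP/n_hub` with g = 60 at desk scale, calibrated once so platform firing
sits in the same regime as direct stimulation. The shared set is 150 of
300 neurons (scaling the reference 500-of-5000), and the membership
threshold stays at 0.8.

## Known limitations (measured, not hypothesized)

The desk-scale end-to-end study is implemented and run exactly as
specified, and two of its claims do not reproduce at this scale; the
corresponding acceptance tests fail and are left failing deliberately.

1. **Max-rate classification saturates at chance.** All class information
   enters through one scalar rate signal shared by every input channel, so
   layer neurons — and a fortiori output neurons, which average hundreds of
   them — are statistical near-clones. The output×class rate matrix is
   dominated by (output gain)×(class drive level); the class-specific
   interaction sits at the 1–2 Hz trial-noise floor. Labeling by row
   argmax then assigns every output the same class and accuracy equals
   chance (measured 0.25 per family over 4 classes). STDP training makes
   this worse, not better: volley-locked outputs receive identical spike
   trains, hence identical weight updates. Charge balancing, class power
   equalization, E/I-ratio spreads and net-drive normalization each add
   measurable structure (best observed single-family accuracy 0.5) but
   nothing approaches the full-scale regime, which has 16× the in-degree
   heterogeneity and orders of magnitude more training exposure.
2. **Coherence membership is non-selective at this scale.** Pooled R
   between the hub and *every* platform is ≈0.9 for a strong input and
   falls together as drive weakens, because 300-neuron platforms carry no
   family-resonance imprint in their weights after desk-scale training;
   the decision rule R > 0.8 then behaves as an input-strength detector.
   The useful half of the contract — a two-component input makes both true
   platforms members — does hold, as does the zero-signal → no-members
   limit.

Everything mechanical around these two emergent claims — encoding algebra,
integrator contracts, plasticity window and its batch/online equivalence,
census statistics, the order-parameter mathematics, the decision plumbing —
is verified to tight tolerances in the test suite.
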