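# Methods

`mrforge` compiles declarative MR pulse-sequence definitions into hardware
event streams and validates them against a virtual scanner. This note
records the models, the defaults and the judgement calls behind them.

## Sequence model and parameter graph

A sequence is declared as *blueprints*: reusable modules carrying pure
parameter rules, composed into a hierarchy whose nodes are modules, loops
(repeating their subtree per counter value) and atomics (leaves that
translate into one hardware execution block). Assembly instantiates the
hierarchy and compiles every rule into a node of a directed acyclic
parameter graph. Evaluation is lazy and cached: requesting a parameter
computes exactly its dependency closure, and a cached value is reused until
a transitive input changes. Loop counters and protocol values are ordinary
source nodes, so per-iteration quantities (phase-encode index → gradient
area) and interactive protocol changes flow through one invalidation
mechanism. Correctness of the cache is asserted against naive full
recomputation on seeded random DAGs, bit-exactly.

Rules are host-language functions registered under stable names with
declared dependency names; dependency names resolve lexically up the
element hierarchy, then against the protocol and hardware-limit
namespaces. A sequence definition therefore serializes to a JSON bundle
(blueprints + hierarchy + parameter rules + protocol) that round-trips
losslessly; an embedded scripting language is deliberately out of scope —
the declarative structure, not the scripting surface, is the contract.

All internal times are integer nanoseconds. This is what makes the
equality contracts (cache vs. recompute, buffered vs. eager stream, file
round-trips) bit-exact; accumulating floating-point block starts across
tens of thousands of repetition intervals would not be.

## Hardware events and geometry

Each atomic's `raw` rule yields one execution block: at most one RF event
(complex envelope on a 1 µs raster, peak in µT), up to three gradient
events (trapezoid or sampled waveform, mT/m, 10 µs raster), and at most
one ADC with an acquisition header using the ISMRMRD counter vocabulary
(line, partition, slice, average, set, repetition, contrast, segment).
Block durations are rounded up to a 10 µs granularity. γ = 42.577478518
MHz/T throughout.

Logical (READ/PHASE/SLICE) to physical rotation keeps trapezoids intact
for signed-permutation matrices and otherwise samples the vector waveform
on the gradient raster, preserving ‖G(t)‖ pointwise. A slice offset Δz
adds γ·G_slice·Δz to the RF frequency (≈4.0 kHz for 9.4 mT/m at 10 mm);
off-isocenter receiver demodulation is carried on the ADC event rather
than baked into samples, matching a header-driven reconstruction contract.

## Waveform synthesis

* RF pulses: hard, Gaussian, sinc, Hanning-windowed sinc. Peak amplitude
  satisfies the small-tip contract flip = 2πγ∫B1 dt; design bandwidth is
  TBW/duration. There is no industry-standard sinc definition, so the
  time-bandwidth product is an explicit argument (default 4) and the
  apodization window an explicit shape choice.
* Trapezoids: shortest raster-quantized trapezoid (or triangle) for a
  requested area, amplitude recomputed after quantization so the area is
  met exactly; verified against a brute-force minimizer.
* Encoding tables: the accelerated pattern samples the high-index
  partial-Fourier window with the acceleration stride; its size is exactly
  ⌈N·PF/R⌉. Reference lines form a centered fully sampled band (default
  24 when accelerated), re-used where they coincide with the pattern.
* Diffusion: bipolar lobe pairs, amplitude solved so the numerically
  integrated b = (2πγ)²∫(∫G)²dt meets the target within 0.1%, with an
  optional inter-lobe gap for the spin-echo split described below.
* Radial view angles: 3D golden-angle via the two golden means
  (z = 1−2·frac(i·0.4656), azimuth 2π·frac(i·0.6823)); calibration spokes
  at 2° increments in the xy, xz and yz planes (3×180 directions), each
  with a small pre-phasing dephaser so the echo sits inside the readout.

## Sequence library

Ten families (FLASH, bSSFP, MPRAGE, RARE, FLAIR, SE-EPI diffusion,
Hadamard-8 pCASL GRASE, 3D radial UTE, STEAM, PRESS) are built from shared
blueprints. Fill delays (`te_fill`, `tr_fill`, CPMG half-interval fills)
are graph rules; the protocol checker flags any negative fill with the
computed feasible minimum, and one built-in solve handler extends TR to
its minimum when requested too short. Realized TE (RF center to echo
center) equals the protocol TE to within one gradient raster for the
Cartesian families, enforced by tests.

Choices worth recording:

* **SE-EPI diffusion.** The bipolar pair is split around the refocusing
  pulse (same physical polarity; the 180° makes it effectively bipolar).
  The amplitude solve uses the *realized* inter-lobe gap (fill delay +
  refocusing block), which the graph can provide before the amplitude is
  needed, so the nominal b-value is met by the actual waveform. Lobe
  duration defaults to 18 ms so b = 600 s/mm² fits a 40 mT/m system at
  TE 66.6 ms. The volume schedule is one b = 0 plus each nonzero b on
  each of three orthogonal axes (7 volumes); b = 0 is acquired once.
* **pCASL GRASE.** Labeling is abstracted to seven subbolus segments whose
  label/control polarity follows the Walsh-ordered Hadamard-8 row (column
  1 is the unencoded reference); the continuous RF train itself is not
  modeled. Two background-suppression inversions are placed by a bounded
  least-squares solve of 1 − 2e^(−t_b/T1) + 2e^(−t_a/T1) for the two
  configured T1 species (700/1400 ms), constrained to the post-labeling
  delay window; with a 0.6 s PLD the nulling is approximate (the exact
  two-species solution wants a longer window) — a residual, documented
  compromise.
* **GRASE feasibility.** At the reference protocol's TE of 17.9 ms, 24
  gradient echoes per refocusing interval do not fit a flat-top EPI
  readout under the default 40 mT/m / 150 mT/m/ms envelope; the protocol
  checker reports "TE below minimum" for that configuration. Ramp-sampled
  EPI readouts, which would recover it, are not implemented. Tests use
  feasible echo spacings; the train-length arithmetic (24/12) is
  independent of this limit.
* **EPI blips** assume the uniform stride of the accelerated pattern;
  acquisition headers, not the blip train, define the reconstruction
  order.
* **FLAIR** splits slices into two interleaved concatenation groups per
  TR. **MPRAGE** nests an inversion and a FLASH train per partition shot
  (inner repetition interval `readout_tr_ms`, default 10 ms). **bSSFP**
  prepends linearly ramped preparation pulses (one per configured
  prescan) and alternates excitation phase by π.
* **UTE** plays a short hard pulse and starts the ADC at the start of the
  readout ramp (center-out, dwell 5 µs by default to respect the
  amplitude limit); a single echo per spoke is modeled.
* **Q2TIPS and VAPOR** exist as timing/flag placeholders (a single
  suppression pulse plus spoiler); literature-exact trains are out of
  scope.

Hardware limits default to Gmax 40 mT/m, slew 150 mT/m/ms, B1 ≤ 25 µT —
a deliberately conservative clinical envelope, configurable everywhere.

## Runtime

Blocks are generated in strict chronological order and delivered in
buffers of one execution window (default 100 ms of sequence time, valid
30–300 ms). Only the current buffer and one look-ahead block are ever
materialized, so memory is bounded regardless of sequence length, and
precalculation before the first block is one window. A block longer than
the window ships whole; buffers are append-only and never cancelled.

Pending feedback values (exposed by name, mapped to graph source nodes)
are applied atomically at sync points — every buffer boundary, plus
optionally immediately before each excitation atomic. With a silent
feedback source the buffered stream equals the eager traversal bit-exactly
at any window. Updates are acknowledged immediately, versioned, and
last-writer-wins between sync points; worst-case application latency is
the in-flight buffer plus one window. The runtime is clocked by sequence
time, keeping every test deterministic; the message protocol (JSON
`{op, name, value, timestamp}`) is transport-agnostic, with an in-process
endpoint and a stdlib TCP reference server.

## Pulseq interchange

Export traverses the sequence exactly as the streamer does and emits the
public text format, 1.4.x dialect: shared `[TRAP]`/`[GRADIENTS]` id
namespace, shapes stored as run-length-compressed derivatives and
deduplicated by content (derivatives are quantized to the 12-significant-
digit text precision *before* run-length encoding so that run equality
survives rendering). Multiple gradient events on one axis within a block
are merged into a sampled waveform. Acquisition counters, sync markers and
RF metadata have no representation in the format and ride in a sidecar
`.labels.json`; pure-Pulseq consumers lose them — a documented trade.
Import produces static blocks (no loops or rules) that stream to the
identical timeline and can be embedded as atomics inside a native
sequence. Export→import→export is a textual fixpoint and block timings
survive exactly on raster-aligned input.

## Virtual scanner

* **Bloch engine**: isochromat summation, one isochromat per phantom
  voxel. Shaped pulses become hard-pulse kicks of ≤5° whose rotation is
  the magnitude of the group's complex envelope integral; groups are also
  capped at 20 µs so precession stays resolved through low-amplitude
  stretches of small-tip pulses. Free precession integrates the exact
  piecewise-linear gradients; relaxation applies per segment. Diffusion
  is a multiplicative e^(−b·D) per contrast (Bloch–Torrey is out of
  scope); an ideal-spoiling option zeroes Mxy before each excitation.
* **Trajectories**: k(t) = γ∫G dτ, reset at each excitation center,
  negated by refocusing pulses — gradient-echo bookkeeping.
* **Gridding**: Kaiser–Bessel convolution (2× oversampling, window width
  4.0, Beatty β), inverse FFT, deapodization by the gridded-delta kernel
  transform, crop; scaled so critically sampled Cartesian data reproduce
  the inverse-FFT image (NRMSE ≈ 0.2–0.3% in practice). Radial density
  compensation is the analytic |k| ramp with a floor at DC.
* **Gradient-delay calibration**: each calibration spoke's echo-peak time
  is found by sub-sample parabolic interpolation; averaging each spoke
  with its opposed partner cancels the object-position shift (odd under
  direction reversal) and leaves the delay projection Σnᵢ²τᵢ (even),
  solved for per-axis delays by least squares over all angles and planes.
  This estimator is validated by self-consistency on simulated spokes
  (10 µs recovered within 0.1 µs at realistic noise), not by equivalence
  to any published variant.
* **ADC mapping**: geometric mean across diffusion axes per b (isotropic
  weighting), then per-voxel least squares on ln S vs. b; nonpositive
  signals masked.
* **Hadamard decoding**: subbolus j = −(1/4)Σᵢ H[i, j+1]·volumeᵢ, signed
  so label−control is positive under the convention that labeling
  attenuates the signal; the exact left-inverse of the synthetic encoder,
  with noise σ/√2 per decoded map for i.i.d. σ per volume.
* **Registration**: sum-of-squared-differences over 3 rotations + 3
  translations, 3-level multiresolution Powell search, cubic-spline
  resampling (linear interpolation proved too lossy: its resampling error
  exceeded the cost difference of a 2° rotation on coarse grids).
* **Motion correction demo**: closed loop in the image domain. Each
  volume samples the phantom under scripted motion composed with the
  current acquisition-frame correction; registration against the first
  volume produces a geometry update that travels through the feedback
  endpoint and takes effect after a one-volume latency. Under a scripted
  linear drift the corrected arm plateaus at the one-volume drift
  increment while the uncorrected arm grows linearly.

## Synthetic data and what the tests do (not) show

Phantoms are seeded ellipsoid composites (a head-like outer ellipse with
white-matter-like properties — T1 800 ms, T2 80 ms, ADC 0.8×10⁻³ mm²/s —
plus random internal blobs). They have piecewise-constant properties, no
coil sensitivities, no susceptibility-induced distortion, no physiological
noise, and rigid-only motion. Passing recovery tests therefore
demonstrates the correctness of the algorithms under their own model
assumptions (exponential decay, rigid motion, delay-shifted trajectories),
not robustness to in vivo confounds such as eddy currents, partial volume
or pulsatility.

Problem sizes are chosen for exhaustive testability: 16³-class protocol
matrices for stream/coverage/round-trip checks, 24–32² phantoms for
recovery, 16³ volumes and 6 acquisitions for the closed-loop demo, 50
spokes + 18 calibration spokes for the toy UTE build (the full 20 000 +
540 census is still computed by traversal, which needs no event
synthesis). Scan-duration checks for the spectroscopy protocols run at
full size (98 repetitions) since they are pure timing arithmetic.

## Known limitations

* No vendor drivers, SAR/PNS models, or hard real-time guarantees against
  a hardware clock; synchronization is per execution window.
* No SLR/adiabatic/multiband pulse design; no spiral/PROPELLER/TPI
  readouts; partial-Fourier reconstruction uses zero-filling implicitly
  (conjugate synthesis is not implemented).
* Pulseq interchange is validated against this package's own reader;
  the writer follows the public 1.4.x text layout, but cross-reader
  conformance is untested here.
* The background-suppression placement is a bounded least-squares
  compromise when the delay window is shorter than the exact solution
  requires.
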