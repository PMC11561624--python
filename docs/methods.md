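# Methods

This note records the models, conventions and numerical choices behind
each module, what the synthetic generators do and do not emulate, and the
known limitations.

## Complexity statistics

Binary sequences are obtained from a channel X(t) by thresholding with
strict `>`; ties map to 0. The default threshold is the median of the
series — scale-free, so one rule serves pCa, pH and voltage channels alike
— with mean-split and fixed-threshold alternatives. Irregular sampling is
handled by using the arithmetic mean Δt̄ of consecutive timestamp
differences; no resampling is performed.

The phrase count c(x) uses the Lempel–Ziv 1976 exhaustive-history parsing
(Kaspar–Schuster pointer algorithm): a new phrase begins whenever the
current word cannot be copied, with overlap allowed, from the preceding
history; the final incomplete phrase counts. The implementation is checked
in the test suite against an independent brute-force parser on *all*
binary strings up to length 12 and on random longer strings.

The per-symbol complexity estimate defaults to
K = c(x)·(log₂ c(x) + 1)/n. The classical asymptotic normalization
c(x)·log₂(n)/n is available behind `normalization="sequence_log"`; both
approach 1 on incompressible input and 0 on trivially regular input, but
they differ at finite n (≈ 0.82 vs ≈ 1.03 for fair-coin sequences at
n = 10⁴), so reports carry the normalization used.

Entropy is the binary Shannon entropy of the proportion of 1s, with
0·log₂0 ≡ 0; the entropy rate is H/Δt̄ in bits/s. The chaos trace is the
absolute second-order finite difference, which annihilates affine
signals; its spread is summarized by the sample standard deviation
(n−1 denominator — the estimator is stated because summaries from other
sources rarely say which they used).

## Logic gates

Because pCa and pH both *fall* as calcium activity and acidity rise, the
crystallization-active encoding defaults to polarity `below` on both
channels: bit = 1 when the solution is more acidic than the threshold.
Equality maps to 0 (deterministic tie-break); both polarities are
exposed, and a two-threshold Schmitt mode is provided for noisy traces.
No numeric thresholds are built in — they are user parameters, with the
channel means of the presets as natural starting points.

Traces on different grids are aligned by previous-value (zero-order)
hold onto the grid with the largest mean time step, restricted to the
overlap of the time ranges. Circuits are DAGs of gate nodes evaluated in
topological order (networkx), so node declaration order is irrelevant;
cycles and unresolved references raise. Gate output is the instantaneous
reading; `cumulative_output` integrates a trace over time as a proxy for
accumulated mineral mass, for workflows that prefer an integrated
readout.

## Electrochemistry

Capacitor impedance is the ideal law Z = 1/(j·2πf·C): phase −90°,
|Z|·2πfC = 1. Specific capacitance divides C by the disk area π(d/2)²
and volume area·thickness; because published per-area/per-volume figures
are not always consistent with the printed C and geometry, the function
accepts expected values and flags disagreements beyond a factor of two
rather than silently adopting either number.

Spectrum summaries are arithmetic means over the sweep. Phase is reported
in degrees in (−180°, 180°]; since instrument summaries sometimes quote
unwrapped means below −180°, the summary additionally reports the mean of
the unwrapped phase. The capacitance plateau is the mean over the lowest
frequency decade of the sweep — a single reduction rule chosen once so
plateau summaries are comparable across profiles.

The frequency response H(ω) = F{v_out}/F{v_in} uses a rectangular window;
it is intended for records spanning an integer number of stimulus
periods, where the window incurs no leakage. Bins with input power below
10⁻⁶ of the maximum are discarded rather than divided, which avoids noise
blow-up at unexcited frequencies. Quartiles use the linear-interpolation
convention throughout.

Electrode calibration inverts E = intercept + slope·log₁₀(c) with a
default Nernstian slope of 29.58 mV per decade (divalent ion, 25 °C) and
a default validity window of 3–4.75 mM; out-of-range results warn rather
than raise, since extrapolation can be deliberate.

## Voronoi packing

Thresholding defaults to Otsu's method. The Euclidean distance transform
of the foreground is negated and watershed-flooded from seeds (supplied
centers, or local maxima of the distance map); flooding is not masked, so
the regions tile the whole frame like Voronoi cells, and the watershed
lines carry label 0. Regions use 8-connectivity. For synthetic equal
disks the boundary lies within 1 px of the analytic perpendicular
bisector (tested).

Cell area is the pixel count times px_size²; perimeter is the weighted
boundary-length estimator of `skimage.measure.regionprops` (straight
steps 1, diagonal √2), within 5% of the true circumference on rasterized
disks of radius ≥ 20 px (tested). Border-touching cells correspond to
unbounded Voronoi cells and are excluded from summary statistics. Because
boundary pixels belong to no cell, measured mean areas on a hexagonal
lattice of spacing s sit below the ideal (√3/2)s² by roughly 2/s
(one-pixel line shared between neighbors); the 2% closure property is
therefore tested at s ≥ 100 px.

The hexagonal ideal is the densest-packing Voronoi cell: the regular
hexagon whose inscribed-circle diameter equals the sphere diameter d
(area (√3/2)d², perimeter 2√3·d). The mean free path uses the standard
kinetic-theory form λ = 1/(√2·π·d²·ρₙ) with ρₙ the number density from
the molar concentration (1 L = 10²⁴ nm³); the √2 relative-motion factor
is configurable (`kinetic_factor=1.0` gives the fixed-target form).

## Synthetic generators

Every generator is a pure function of its parameter object, seed
included, and is phenomenological: it reproduces the *statistics* of the
recordings, not the physics. No nucleation/growth kinetics are modeled.

**pCa/pH.** The composite preset holds pCa at mean 2.452 and drifts pH
linearly from 8.551 to 8.520 over 1526 s — endpoints and duration are
the reported facts, and a linear drift is the minimal shape consistent
with them. The control preset holds pH flat at 8.282; its pCa mean is set
to 2.523 = −log₁₀(3×10⁻³), matching the 3 mM concentration scale of the
system, since no control pCa is reported. Noise is a discretized
Ornstein–Uhlenbeck process (stationary initialization, default SD 0.05,
correlation time 60 s, sampled at 1 s): zero-mean colored drift is the
simplest realistic model for slow electrode fluctuations. With T = 1526 s
and τ = 60 s a single trace mean has SE ≈ sd·√(2τ/T) ≈ 0.014, so
10-replicate grand means land within ±0.01 of the preset mean with high
probability — that is a property of the chosen noise scale, not a tuned
constant.

**Harmonics.** Inputs are A·sin(2πhf·t + φ) with a 1-minute fundamental
and amplitude 1 V, for h ∈ {2, 3, 6, 10, 12, 15, 16}; records default to
10 fundamental periods at dt = 0.25 s (Nyquist-safe for h = 16). The
output channel is gain·nonlinearity(input) + white noise, with a
normalized-tanh soft clip and a cubic polynomial (even + odd distortion)
as the nonlinear options — enough structure to exercise the
frequency-response and distribution analyses without claiming a device
model.

**Spectra.** Impedance profiles follow a single-dispersion R‖C shape
|Z|(f) = R/√(1+(f/f_c)²) with a fixed 1 kHz corner; since the sweep mean
is linear in R, R is back-solved exactly so the mean |Z| over the default
1 Hz–1 MHz, 10 points/decade grid equals the reference per-sample mean
(closure is exact to rounding, tested at 10⁻⁹ relative). Capacitive
profiles use C(f) = C₀/(1 + f/f_c) with C₀ back-solved the same way
against the lowest-decade mean; the implied |Z| = 1/(2πf|C|) is then
strictly decreasing in f. Noise is multiplicative in log₁₀ space. The
reported negative proteinoid plateau is represented verbatim as a
negative C₀; no transient-injection microphysics is modeled.

**Images.** 8-bit disks at intensity 200 on background 30 (fixed for
test stability), on a hexagonal lattice (row spacing s·√3/2, alternate
rows offset s/2) or by random sequential adsorption with a strict 2r
minimum center distance and bounded retries. Ground-truth centers are
returned in (row, col), 0-based.

What passing tests on these generators show: the analysis stack recovers
known ground truth and printed summary constants under controlled,
well-behaved conditions. What they do not show: robustness to electrode
drift nonstationarity, spectral dispersion beyond a single corner,
non-spherical or overlapping particles, uneven illumination — real
recordings and micrographs can fail in ways the emulators do not produce.

## Pipeline

Runs are one JSON/YAML document: a seed, an optional output directory and
an ordered stage list; analysis stages reference generator stages by
name. Per-stage seeds are seed + stage index, so any stage can be re-run
in isolation. Validation returns a list of schema/dependency diagnostics
(empty iff runnable). JSON reports serialize floats at 9 significant
digits, making repeated runs byte-identical across platforms; logging
goes to stderr, results never do.

## Problem sizes

Defaults were chosen so that each analysis is statistically meaningful at
interactive scale: 1527-sample traces, 10 (closure) or 20 (drift
recovery) replicates, 61-point spectra, 2¹⁴-sample response records,
256–704 px images with 25 spheres, and the exhaustive LZ76 cross-check
over all 8190 binary strings up to length 12.

## Known limitations

- The reference complexity values and chaos-trace SDs from the real
  recordings are not reproduced: the original binarization and
  preprocessing are unspecified, and the statistics are sensitive to
  both. The complexity module therefore exposes its conventions
  (binarization method, normalization, threshold) in every report.
- The printed mean-free-path value in the source material is not
  reconstructible from its stated inputs under any standard form of the
  formula; the package documents and tests its own kinetic-theory form
  instead and makes the √2 factor explicit.
- Published per-area (10.5 μF/cm²) and per-volume (25.0 μF/cm³) specific
  capacitances are tenfold larger than C/area and C/volume computed from
  the printed capacitance and geometry; `specific_capacitance` reports
  the computed values and its consistency flag fires on the published
  pair.
- Gate readout is a threshold abstraction: no physical model links gate
  output to crystal mass or density, and no crystallization delay is
  modeled.
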