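# Methods

## Measurement model

A spectroscopic photon-counting detector records a 3D count array
`counts[k, i, j]`: energy bin k, pixel row i, pixel column j. The energy axis
is uniform; bin k spans the half-open interval `[offset + k·w, offset + (k+1)·w)`
keV and is represented by its **center** `offset + (k + 0.5)·w`. Using the bin
center as the representative energy is the unbiased choice for a uniform bin;
for the typical 1 keV binning the alternative (lower edge) would shift every q
by under 2 % at 30 keV and was rejected to avoid a systematic bias.

Pixel (i, j) occupies `[i, i+1) × [j, j+1)` in pitch units, its center at
`(i + 0.5, j + 0.5)`; the transmitted-beam location is given in the same
fractional coordinate system and may lie off the sensor (beam-stop
arrangements commonly park it just beyond a corner). The scattering angle of a
pixel is

    2θ = arctan(r / SDD),    r = pitch · |pixel center − beam center|,

a flat-detector approximation that represents each pixel by its center and
ignores solid-angle and energy variation across a pixel. Momentum transfer
follows the Bragg convention with θ equal to **half** the scattering angle:

    q = 4π E sin(2θ/2) / hc.

Only this convention maps caffeine's published d-spacings (7.53–7.40 Å,
3.37–3.30 Å) onto its known peak positions 8.4 and 18.6 nm⁻¹ via q = 2π/d.
`hc` defaults to the conventional rounded 1.24 keV·nm so that results match
the usual desk arithmetic; `PhysicalConstants.codata()` supplies the
full-precision 1.2398 keV·nm for users who prefer it.

## Reduction

Every count at (k, i, j) whose energy-bin center lies inside the analysis
window is assigned the cell's q(k, i, j) and accumulated into the half-open q
bin containing it. All intervals in the package — energy windows, the
analysis range, q bins — are half-open `[lo, hi)`, which makes tiling
partitions exactly additive and double-count-free; this is load-bearing for
the invariants below. Consequences worth knowing:

- with no mask, the full energy range, and a q grid covering
  `[0, max q + ε]`, the output pattern total equals the frame total *exactly*
  (integer counts are only rearranged, never scaled);
- summing patterns over a tiling window partition reproduces the full-range
  pattern bin-by-bin;
- the vectorized reduction is tested for exact equality against a naive
  per-cell triple loop, which serves as the independent reference
  implementation.

**Energy parameters.** The analysis range `[binStart, binEnd)` is tiled by
windows of `energyWindow` keV; the range must be an integer multiple of the
window width (checked, with the remainder reported). `binWidth` — "data
points every N keV" — is implemented as optional integer re-aggregation of
adjacent native detector bins before reduction; it must be an integer
multiple of the native bin width. Totals are preserved exactly by the
re-binning.

**q grid.** Default bin width 0.1 nm⁻¹ from 0 to just past the detector's
geometric maximum q at the top of the analysis range, user-overridable. 0.1
nm⁻¹ resolves peaks separated by ~10 nm⁻¹ (the caffeine pair) with two orders
of margin; pattern rows report bin-center q.

**Background.** A background measurement is subtracted frame-wise (3D,
element-wise) before reduction, with no exposure-time scaling — exposure
metadata is carried but unused, matching direct count removal. Because
reduction is linear, subtracting in frame space or in pattern space is
numerically identical (tested); a single subtraction point keeps the 1D
pattern and the 2D detector image consistent with each other. Negative
differences are retained in all numeric outputs and clamped only when
rendering images.

## Scan maps

A raster scan is a folder of per-position frames, loaded in natural-sort
filename order (digit runs compared numerically, so `pos_2` < `pos_10`) —
a total order independent of filesystem enumeration. The user declares the
grid shape; frame f is placed at `(f // cols, f % cols)` (row-major default)
or with odd rows reversed (`serpentine`) to match either raster convention.
Each position is scored by the **area under the peak**: the plain sum of
pattern counts over q bins whose center lies in the user q-range, with no
baseline subtraction — for histogrammed counts a sum is the natural area and
is invariant to re-binning up to bin-boundary effects. One shared background
frame, if supplied, is subtracted at every position. There is no per-window
map; the energy range is pre-selected once before mapping.

## Forward simulator

The synthetic generator emulates a powder measurement: Debye–Scherrer rings
under a polychromatic spectrum with Poisson counting noise, on the default
validation bench of SDD 250 mm, 80 × 80 pixels at 0.25 mm pitch, beam center
(−2, −2) fractional pixels (just off one corner, as with a beam stop). That
geometry puts both caffeine-like rings on-detector within 30–45 keV.

The Poisson rate of cell (k, i, j) is

    λ = background_rate + Σ_rings intensity · w(E_k) · exp(−(q(k,i,j) − q₀)² / 2σ_q²) / Z,

with w the spectrum's per-bin weight (tabulated, interpolated onto bin
centers, normalized to unit sum) and Z chosen per ring so that the ring's
expected **on-detector** total equals its `intensity`. Two deliberate
choices:

- **Gaussian in q, not in radius.** The injected ground truth then lives in
  the same coordinate the reduction measures, so peak-recovery tests are
  exact by construction rather than approximations through the nonlinear
  r(q, E) mapping.
- **On-detector normalization.** Ring intensities are expected *recorded*
  counts, which makes intensity ratios across simulated scan positions exact
  in expectation — the property the scan-map rank test relies on.

The default spectrum is flat over the analysis range: the reduction math is
spectrum-shape-agnostic, so a flat weight validates it as well as a modeled
tungsten tube output would; arbitrary tabulated spectra are accepted but not
physically modeled. The simulator does **not** model charge sharing, pulse
pileup, Compton or multiple scattering, detector fluorescence escape, sample
absorption, or transmission/thickness effects. Passing tests therefore
demonstrate the correctness of the geometry → q mapping, binning, windowing,
background handling, and map assembly — not robustness to real-detector
artifacts, which are assumed corrected upstream.

Determinism: a frame is fully determined by its seed; scans spawn independent
child streams per position from one seed.

## Numerical and interface choices

- Raw frames carry non-negative integer counts (int64); any derived frame is
  float64. Validation enforces this at construction.
- Frame files: HDF5 container (`/counts` 3D dataset + energy-axis attributes,
  written with `track_times=False` so identical frames give identical bytes)
  or raw binary + JSON sidecar. Both round-trip bit-exactly; the importer
  boundary is deliberately format-light so other detectors can be adapted.
- Pattern/map CSVs print 10 significant digits; re-parsing reproduces counts
  to 1e-9 relative.
- Window/range divisibility checks use a 1e-9 relative tolerance so that
  float keV inputs like 0.1-width bins do not spuriously fail.
- Degenerate inputs fail loudly: empty scan folders, unreadable scan members
  (never skipped silently), grid/file-count mismatches (both numbers
  reported), q-ranges containing no bin center, kinematically unreachable q
  at a given energy.

## Problem sizes in tests

Unit and property tests run on 10 × 8 × 8 frames where exact loop-oracle
comparison is cheap, and on full 200 × 80 × 80 frames for count conservation;
ring-recovery and scan-map checks use 15 × 80 × 80 frames (30–45 keV at 1 keV)
with ≥ 20 000 expected ring counts, sizes at which the Poisson argmax is
stable across seeds. The whole suite completes in well under a minute.

## Known limitations

- No absolute intensity calibration, azimuthal sectoring, flat-field,
  polarization or solid-angle corrections.
- No detector tilt/rotation calibration; the beam center is a required user
  input, not fitted.
- Background subtraction is unscaled; measurements with differing exposure
  must be normalized by the user first.
- High-AUP artifacts at strongly scattering sample-holder edges (e.g. well
  rims) are reproduced faithfully, not corrected.
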