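# Methods

## Problem and approach

Wide-cone dental CBCT detects a large amount of X-ray scatter from the
patient's head. Scatter adds a smooth, object-dependent background to every
projection, which after log transformation and filtered backprojection shows
up as cupping (depressed values toward the center of homogeneous regions)
and loss of air–bone and bone–tissue contrast. Because the scatter field is
dominated by low spatial frequencies, a scatter image simulated once for a
standard head phantom can stand in for the scatter of many patients. This
package implements that scheme end to end on synthetic data:

1. **Monte Carlo simulation** of the scanner produces, per view, a primary
   image `P_sim` (photons that reached the detector with zero interactions
   inside the object) and a scatter image `S_sim` (one or more interactions).
2. **Correction** of a measured projection `I_exp`:
   smooth `S_sim` with a Gaussian low-pass (`S'_sim`), rescale to experiment
   intensity through the blank-scan ratio
   `S_exp = S'_sim · I_b,exp / I_b,sim`, cap the scatter fraction at
   `SF_max` (`S ← min(S, SF_max · I_exp)`), and subtract with a global
   weighting factor: `I_C = I_exp − w · S_exp`.
3. **FDK reconstruction** of `p = ln(I_b,exp / I_C)` with a Shepp-Logan
   apodized ramp filter, and
4. **metrics**: ROI contrast, cupping percentage, absolute percentage change.

## Scanner model

Circular full-scan cone-beam geometry: source–isocenter distance 482 mm,
isocenter–detector 226 mm, flat detector of 480 × 384 pixels at 0.508 mm
pitch, 360 views at 1° steps, cone half-angle limited to 14°, 0.6 mm disc
focal spot. The frame is right-handed with the rotation axis along +z, the
source starting on −x, and angles counter-clockwise from +z; detector pixel
(i, j) indexes horizontal/vertical with the origin at the lower-left as seen
from the source, arrays stored v-major. Scaled-down studies keep the same
distances and detector *area* while rebinning pixels (e.g. 64 × 48 at
3.81 mm), so scatter-to-primary geometry is preserved.

## Photon transport

Analog photon-only transport, no variance reduction, between 10 and 100 keV
with a 5 keV kill cutoff (configurable):

* **Free paths** by Woodcock delta-tracking against a per-phantom,
  per-energy majorant attenuation; exact for heterogeneous voxel grids.
* **Photoelectric** events absorb the photon locally (no fluorescence, no
  electron follow-up: the tally counts photon arrivals only).
* **Compton** scattering uses the free-electron Klein-Nishina law sampled
  with Kahn's rejection method; no incoherent scattering function, no
  Doppler broadening.
* **Rayleigh** scattering uses the Thomson `(1 + cos²θ)` angular shape with
  unchanged energy; atomic form factors are deliberately omitted and the
  choice is documented here precisely because it over-scatters at large
  angles relative to form-factor models — acceptable for a low-frequency
  scatter background.
* The **detector is an ideal photon counter**: every photon crossing the
  detector plane inside the pixel grid scores 1 regardless of energy.
  Conversion efficiency and electronic noise are not modeled.

Photon bookkeeping is exact per run:
`emitted = absorbed + missed + primary + scatter`.

Reproducibility: each view gets an independent 31-bit stream seed derived
from (base seed, view index) via `numpy.random.SeedSequence`; within a view
the kernel consumes a single sequential stream, so a fixed seed gives
bit-identical tallies.

## Attenuation data

Mass attenuation tables for air, soft tissue (water-equivalent),
cortical-bone-equivalent and aluminum are packaged as text files on a 1 keV
grid (10–100 keV), split into photoelectric / Compton / Rayleigh partials
whose sum defines the total exactly. They are produced by a parametric
model — exact Klein-Nishina for the incoherent part, power laws in effective
Z and energy for the other two, anchored to standard water values (see
`src/cbctscatter/data/README.md`). Interpolation between knots is log-log
linear, which is positive by construction. Material classes follow fixed
density bands: air [0, 0.3), soft tissue [0.3, 1.2), bone [1.2, ∞) g/cm³
(lower-inclusive), with densities above 1.95 g/cm³ clamped for transport
only; transport always uses the per-voxel continuous density times the
class's mass coefficients.

## Spectrum

Spectra are two-column text tables (keV, relative fluence) on a uniform
grid; sampling returns bin centers. The bundled fixture is a Kramers-law
bremsstrahlung shape at 90 kVp filtered by 10.6 mm of aluminum
(characteristic lines are not modeled); its aluminum HVL computes to
≈7.4 mm. `compute_hvl`/`match_hvl` work in narrow-beam geometry (pure
exponential, no buildup): HVL here is a beam-quality descriptor used to
harden a calculated spectrum toward a measured system, not a transport
result. The measured HVL of a real system is an input parameter; no default
is asserted.

## Analytic projector

A deterministic Siddon ray-tracer provides noiseless Beer-Lambert
projections `scale · Σ_E f(E) exp(−Σ μ(E)ℓ)`, used both as the synthetic
"experimental" primary signal and as the Monte Carlo oracle. The blank
response is flat by default (the blank-scan ratio in the correction cancels
first-order geometric falloff); an optional mode applies the cos³θ
solid-angle factor, and `expected_primary_counts` converts transmission maps
into absolute expected MC counts (sub-pixel supersampling averages the
transmission over each pixel, which matters at object edges on coarse
detectors).

## Correction chain details

Defaults `w = 0.8` and `SF_max = 0.8` are global scalars; per-case
optimization is out of scope. The Gaussian width default is 8 px at 0.508 mm
pitch (4 px in the rebinned demo), border mode reflect; scatter is so smooth
that the result is insensitive to this choice within a factor of a few. The
scatter-fraction cap is applied to `S_exp` **before** the weight — this
order makes the positivity bound `I_C ≥ (1 − w·SF_max)·I_exp` provable and
is pinned by a regression test. Corrected intensities are floored at
`epsilon_floor = 1` count before the log transform to keep `ln` defined on
noisy pixels. Measured and simulated stacks are paired by nearest view angle
(warning beyond 0.5°). A low-resolution scatter estimate is bicubically
upsampled (integer factors only) to match high-resolution measured data,
with negative overshoot clamped at zero.

## FDK reconstruction

Cosine pre-weighting `D/√(D² + u² + v²)`, row-wise ramp filtering with
Shepp-Logan apodization and a hard cutoff at a fraction of the detector
Nyquist frequency (presets: 0.7 at 0.4 mm voxels, 0.5 at 0.2 mm), then
voxel-driven backprojection with bilinear detector interpolation and the
`(D_SO/U)²` distance weight; full 360° scans only. Numerical choices: the
row filter is realized through the band-limited **spatial** Shepp-Logan
kernel `h(n) = 2/(π²Δ²(1−4n²))` transformed to the frequency domain —
direct frequency sampling of `|f|` zeroes the DC sample and was measured to
bias reconstructed values low by ~4% on the cylinder oracle; projections are
zero-padded to the next power of two to avoid circular-convolution wrap.
With these choices the monoenergetic water-cylinder oracle reconstructs its
interior to the true μ within 0.1% with < 2% coefficient of variation.
Reconstructed values are linear attenuation (1/mm); the grayscale offset of
any particular scanner is not modeled, so metrics on synthetic data are
asserted in relative terms.

## Metrics

Cupping is `100 · (edge − center)/edge` on a profile through a homogeneous
region, using the outer 10% and the central 10% of the profile span as
bands; the formula is a documented choice (the field uses several variants)
and is invariant to positive rescaling but not to offsets. For cylinder
experiments the profile span is restricted to 80% of the known radius to
exclude the partial-volume rim. Percent changes are rounded half-up to two
decimals, matching the precision such tables are printed at.

## Scaled-down study conditions

The bundled end-to-end demonstration uses a 100 mm diameter, 100 mm tall
water cylinder at 2 mm voxels, 36 views, 10⁵ photons per view on the
64 × 48 rebinned detector, 64³ volume at 2 mm voxels, and a blank level of
2 × 10⁴ counts. The synthetic "measurement" is the analytic primary plus a
true scatter field taken from an independently seeded MC run (smoothed to
its expectation and put on the experiment scale through the same blank
ratio the correction assumes); the correction then uses the other MC
stream's scatter, so estimate and truth carry independent noise. At this
view count the reconstruction has a genuine sparse-view artifact: a ~−6%
"capping" baseline (center spike) present identically in the scatter-free,
uncorrected and corrected volumes (it disappears at 120 views on a finer
detector). End-to-end comparisons therefore quantify *scatter-induced*
cupping — the cupping difference from the scatter-free reference — which the
correction at w = 0.8 reduces from ≈3–5 percentage points to below 2.

## What the synthetic data does and does not show

The generator reproduces the geometry, spectrum shape, material bands and
photon physics of a real scan, and the scatter fields it produces have the
defining low-frequency property (≥ 80% of non-DC spectral power below ¼
Nyquist at adequate statistics). It does not reproduce detector energy
response, electronic noise, the bowtie filter (absent by design), patient
anatomy, or absolute grayscale calibration; passing tests demonstrate the
correctness of the algorithm chain under its stated physics model, not
clinical image quality.

## Known limitations

* Free-electron Compton and Thomson-shaped Rayleigh mildly misshape the
  angular distribution at low energies; both are swappable sampling points.
* Photons between the 5 keV cutoff and the 10 keV table floor reuse the
  10 keV coefficients (they are absorbed within millimeters either way).
* No short-scan (Parker) weighting, truncation handling, or iterative
  reconstruction; no beam-hardening correction (visible as a few-percent
  effect with the polyenergetic fixture).
* The scatter-fraction cap makes the chain mildly nonlinear, so corrected
  stacks are not exactly scale-invariant.
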