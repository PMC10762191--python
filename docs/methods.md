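# Methods

This note documents the models, numerical choices, and limitations behind
`holorbc`: an off-axis digital holographic microscopy (DHM) reconstruction
pipeline for red-blood-cell quantitative phase imaging, together with the
synthetic hologram generator used to exercise it.

## Forward model

A hologram is the two-beam interference intensity

    I = E_0s^2 + E_0r^2 + 2 E_0s E_0r cos(phi_s - phi_r),
    phi_r(x, y) = 2 pi (f_x x + f_y y),

sampled on the camera grid, with additive zero-mean Gaussian noise in
counts (residual speckle after a rotating diffuser; optional multiplicative
speckle term, off by default) and 8-bit quantization. Quantization scales
the ideal noise-free dynamic range [(E_0s - E_0r)^2, (E_0s + E_0r)^2] onto
[0, 255] with round-half-away-from-zero and clipping, so noise can saturate
at the rails exactly as on a real camera.

The sample phase of a cell of thickness T is `phi = (2 pi / lambda) n T`.
`n` is a single *effective* index. Its default is 0.5, the approximate
refractive-index contrast of dried hemoglobin against air, because the
phase a transmissive object imprints is governed by the index *difference*
between cell and surround: with the literal surrounding-medium index
(n = 1.0) a 2 um cell would imprint ~20 rad at 632.8 nm, which bends the
local fringe frequency beyond the Nyquist limit of any realistic
carrier/sampling combination — such a hologram is unrecordable, and
reconstruction then provably loses a multiple of 2 pi at the rim (we
verified the identical failure with an independent unwrapper, so it is a
property of the data, not of the algorithm). Whether `n` "should" be a
medium index, a cell index, or their difference is left to the user; it is
one number in the configuration, used consistently in both the generator
and the thickness conversion. A `reflection_factor` (default 1; 2 for
double-pass reflection geometries) is available in the thickness
conversion.

### Phantom geometry

Normal erythrocytes are biconcave discs, 6-8 um across and about 2 um
thick at the rim. The radial thickness profile is an Evans-Fung-style form

    T(rho) = A * sqrt(1 - rho^2) * (alpha + rho^2),      rho = r / R,

with `alpha` solved (by bisection, deterministically) so that the
center-to-rim ratio matches the requested dimple depth, and `A` normalized
so the rim maximum equals the requested edge thickness. A zero dimple
degenerates to the monotone dome `sqrt(1 - rho^2)`.

The rim additionally tapers to zero over a `rim_taper_frac` fraction of
the radius (smootherstep; default 0.35, 0.40 for microcytic cells). A
strict square-root rim has a vertical tangent, i.e. unbounded local
spatial frequency; no band-limited imaging system can record it, and a
phantom must stay representable at the configured sampling for the
round-trip comparison against ground truth to be meaningful. The taper
width was chosen, together with the magnification and carrier defaults
below, so that carrier + phase bandwidth stays below Nyquist with margin.

Thalassemia-related classes are qualitative: microcytic (4-5.5 um,
thinner), hypochromic (normal size, 1.0-1.4 um rim), codocyte (a central
smooth bump — the target-cell bullseye — added to a dimpled profile).
No quantitative thickness/diameter distributions for thalassemic cells
were available to calibrate against; these classes are plausible
placeholders, not population models.

### Default optical parameters

| parameter | default | why |
|---|---|---|
| wavelength | 0.6328 um | He-Ne source |
| pixel pitch | 5.2 um | camera specification |
| sensor format | 1024 x 1280 | dataset convention |
| magnification | 120 | 10x Mirau objective x ~12 effective microsphere gain; chosen so a 7 um cell spans ~160 px and its phase gradient stays well below pi/px. The true per-image value varies with microsphere position and is not calibrated — treat absolute lateral scales on real data as configurable. |
| carrier (f_x, f_y) | (-0.32, -0.16) cyc/px | separates the sideband from the zero-order term; the *negative* tilt makes the positive-xi sideband (the one selected by the deterministic rule below) carry `e^{+i phi_s}`, so recovered phase has the sample's sign |
| noise sigma | 2 counts | residual speckle level used for the noisy study condition |
| aberration | 0 (generator); datasets sample small tilt/defocus/astigmatism per exposure pair | aberrations are constant between the object and its paired reference exposure, which is what makes reference subtraction cancel them |

## Reconstruction

- **Transforms.** Unnormalized forward DFT, 1/N^2 inverse (the numpy
  convention); spectra are stored DC-centered. Any self-consistent pair
  realizes the continuous transform relations; fixing one makes runs
  bit-reproducible.
- **Sideband choice.** Either conjugate sideband is physically valid; the
  peak with positive xi is chosen (ties to positive eta), the mirrored
  choice is a flag (it conjugates the recovered phase). The peak search
  excludes a disc of `dc_exclusion_bins` (default 8) around DC and fails
  loudly if nothing rises above the DC-leakage floor (e.g. a zero-contrast
  hologram).
- **Mask.** Hard-edged circular binary mask of radius half the
  carrier-to-DC distance (overridable); an optional raised-cosine edge
  exists but is off by default. Centering is an integer-bin circular
  shift; the sub-bin residual carrier cancels in the reference
  subtraction, which is why the reference hologram is demodulated with the
  *object's* sideband selection.
- **Propagation.** Exact angular-spectrum transfer function; evanescent
  bins are zeroed rather than exponentially decayed (stability; they carry
  no propagating energy). d = 0 is the exact identity.
- **Autofocus.** Coarse scan of the normalized amplitude variance
  (var|E| / mean|E|^2) over a user range, then a bounded scalar
  refinement around the coarse winner. Deterministic; a flat metric warns
  and returns mid-range. Off by default (synthetic holograms are generated
  in focus at z = 0).
- **Phase.** Two-argument arctangent, range (-pi, pi], half-open at -pi
  everywhere (`wrap(x) = -((-x + pi) mod 2 pi - pi)`). Zero-amplitude
  pixels get phase 0 with a logged count.
- **Reference subtraction** is a wrapped difference, performed *before*
  unwrapping.

### Goldstein unwrapping

Residues are the rounded 2 pi-normalized sums of wrapped differences
around each elementary 2x2 loop. Branch cuts: residues are visited in
lexicographic order; an unbalanced residue starts a group and an
expanding-box search (radius doubling each step) absorbs further residues
— joined to the nearest group member by a cut — until the net charge is
zero or the border (an infinite-capacity sink) is reached. Cuts are
rasterized as 8-connected barred-pixel chains, which a 4-connected
integration path cannot cross. Unwrapping is a FIFO flood fill adding
`wrap(phi_b - phi_a)` across each step; pixels isolated by cuts are then
unwrapped coherently per connected region and shifted by the 2 pi multiple
that the *majority* of the region's boundary contacts vote for (a single
noisy crossing cannot offset a whole region). Finally every value is
snapped onto `input + 2 pi k`, so rewrapping reproduces the wrapped input
exactly at every pixel. The result is defined up to a global constant; the
pipeline fixes it by zeroing the median over a cell-free region (explicit
mask, or the lowest-variance tile of an 8x8 partition).

Known limitation: Goldstein unwrapping is quality-blind. Where the
band-limited field's amplitude dips (steep rims under noise), small
patches can still pick up 2 pi offsets; at the default noise level this
contributes an ~8-9% RMS thickness error floor, comparable to what a
quality-guided unwrapper achieves on the same maps.

## Morphometry

Thickness maps are leveled by subtracting a least-squares plane fitted
over a background mask (>= 5% of pixels; the pipeline derives it as the
complement of a dilated provisional segmentation). Segmentation thresholds
at 25% of the robust (99.5th percentile) maximum, keeps the largest
8-connected component and fills holes — fixed defaults with config
overrides, no adaptive thresholding, for determinism. Features: projected
area, equivalent diameter `2 sqrt(A/pi)`, max/mean thickness, volume
`sum T dA`, circularity `4 pi A / P^2` (clipped into (0, 1]; discrete
perimeters of tiny masks overshoot), and dimple depth (mask maximum minus
the value at the mask centroid). Cross-sections use bilinear interpolation
at quarter-pixel steps. The exact feature formulas are this package's
choices; no reference values for real cells were available to calibrate
against.

## What the tests show — and what they don't

All study conditions are synthetic. The generator reproduces the
*statistical structure* the reconstruction relies on (carrier fringes,
shared-aberration exposure pairs, additive noise, 8-bit quantization) but
not: microsphere imaging physics (Newton-ring artifacts, field-dependent
magnification, aberrations beyond low-order polynomials), spatially
correlated speckle, camera nonlinearity, or multiple cells per field with
debris. Passing the round-trip criteria therefore demonstrates the
numerical chain is correct and stable under the modelled noise, not that
real-data reconstructions reach the same accuracy. Problem sizes used by
the test suite and the acceptance script: 16x16 grids against O(N^4)
direct-sum transform oracles, 64-256 px grids for property checks, and the
full 1024x1280 sensor frame for the end-to-end phantom recovery (RMS
thickness error inside the segmented cell mask: well under 5% of maximum
thickness noise-free, under 10% at 2 counts of noise).
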