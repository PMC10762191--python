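# holorbc

Off-axis digital holographic microscopy (DHM) reconstruction and
morphometry of red blood cells, with a synthetic hologram generator for
fully self-contained testing.

## The problem

A DHM records the interference of a sample beam
`E_0s e^{i phi_s}` with a tilted reference beam `E_0r e^{i phi_r}`:

    I(x, y) = E_0s^2 + E_0r^2 + 2 E_0s E_0r cos(phi_s - phi_r)

The tilt puts the object wave on a spatial-frequency carrier, so the
complex amplitude — and hence the quantitative phase, which a plain camera
cannot record — can be recovered numerically from a single 8-bit image.
This package implements the standard reconstruction chain used for
hologram datasets of normal and thalassemic erythrocytes (8-bit BMPs,
1280 x 1024 px, folders `nRBC/` and `tRBC/`):

1. **Angular spectrum**: forward Fourier transform of the hologram
   (`F{E_s} = ∫∫ E_s e^{-2 pi i (xi x + eta y)} dx dy`).
2. **Sideband filtering**: a hard circular binary mask selects one of the
   two conjugate image sidebands (deterministically the positive-xi one),
   which is then shifted to the spectrum center to remove the carrier.
3. **Free-space propagation** to the best-focus plane with the exact
   transfer function `exp(i k d sqrt(1 - lambda^2 xi^2 - lambda^2 eta^2))`,
   zeroing evanescent components; an autofocus search over a distance
   range is available.
4. **Phase extraction**: `phi = atan2(Im E, Re E)`, wrapped into (-pi, pi].
5. **Aberration cancellation** by subtracting the wrapped phase of a
   paired cell-free reference hologram.
6. **Goldstein branch-cut unwrapping**: +-1 residues on elementary 2x2
   loops, dipole pairing by expanding-box search, flood-fill integration
   that never crosses a cut.
7. **Thickness conversion** `T = lambda phi / (2 pi n)` with an effective
   refractive index `n`, followed by background plane leveling, cell
   segmentation, cross-sectional profiles, and shape features (projected
   area, equivalent diameter, thickness statistics, volume, circularity,
   dimple depth).

The synthetic generator builds biconcave-disc phantoms for the four
morphology classes seen in normal and thalassemia-minor smears (normal,
microcytic, hypochromic, codocyte), forward-simulates the interference
pattern with configurable carrier, system aberrations, residual speckle
noise and 8-bit quantization, and writes datasets in the same BMP/folder
convention with plain-text ground-truth thickness sidecars.

## Worked example

Simulate one normal and one thalassemic cell (noise switched off to show
the clean round trip), then reconstruct the normal cell against its paired
reference hologram:

```sh
$ printf 'noise_sigma: 0.0\ngrid_shape: [256, 256]\n' > cfg.yaml
$ holorbc simulate --n-normal 1 --n-thal 1 --seed 7 --out data --config cfg.yaml
wrote 2 holograms under data: {'nRBC': 1, 'tRBC': 1}
$ holorbc reconstruct data/nRBC/nrbc_0000.bmp \
      --reference data/nRBC/nrbc_0000_ref.bmp --config cfg.yaml --out out
max thickness 1.966 um, equivalent diameter 5.70 um, volume 36.6 um^3
```

The generated phantom's true maximum thickness is 1.973 um, so the whole
chain (interference, 8-bit quantization, sideband filtering, unwrapping,
reference subtraction, leveling) recovers the thickness map to a fraction
of a percent; the RMS error inside the cell mask is 0.25% of the maximum
thickness. The equivalent diameter (5.70 um) is the diameter of a disc
with the area of the segmented mask, which sits at the 25%-of-maximum
thickness contour and therefore inside the faint cell rim. `out/` also
contains the wrapped and unwrapped phase maps and the thickness map as
plain-text matrices, 16-bit PNG previews, a one-row features CSV, and a
JSON run log recording every automatic decision (chosen sideband bin, mask
radius, focus distance).

With the default residual noise of 2 counts the same recovery is accurate
to about 9% RMS — the price of single-shot off-axis holography at 8-bit
depth.

Batch mode processes a whole dataset tree into one CSV:

```sh
holorbc batch data --out out    # out/features.csv, one row per cell
```

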