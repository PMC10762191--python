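"""Synthetic off-axis holograms of biconcave red-blood-cell phantoms.

The generator builds ground-truth thickness maps for the morphology classes
seen in normal and thalassemic blood smears (normal biconcave discs,
microcytic, hypochromic, and codocyte/target cells), converts them to phase,
and forward-simulates two-beam interference on a tilted reference carrier:

    I = E_0s^2 + E_0r^2 + 2 E_0s E_0r cos(phi_s - phi_r),
    phi_r(x, y) = 2 pi (f_x x + f_y y),

followed by additive residual-speckle noise and 8-bit quantization. A
paired cell-free reference hologram shares the carrier, aberration phase,
and noise seed, emulating the paired-exposure aberration-cancellation
trick. Everything is bit-reproducible under a fixed seed.

Normal phantom geometry follows the textbook erythrocyte: 6-8 um diameter,
about 2 um thickness at the rim, with a central dimple. The radial profile
is an Evans-Fung-style form T(r) = sqrt(1 - (r/R)^2) * polynomial((r/R)^2),
with coefficients solved so the rim maximum and dimple depth match the
requested cell.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import brentq

from .config import SimulationConfig
from .io import DatasetManifest, Hologram, scan_dataset, write_hologram_bmp
from .morphometry import ThicknessMap, thickness_to_phase
from .unwrap import PhaseMap

__all__ = [
    "PhantomCell",
    "MORPHOLOGY_CLASSES",
    "make_biconcave_phantom",
    "thickness_to_phase",
    "aberration_phase",
    "interference_intensity",
    "add_speckle_noise",
    "quantize_8bit",
    "simulate_off_axis_hologram",
    "make_reference_hologram",
    "generate_dataset",
]

logger = logging.getLogger(__name__)

MORPHOLOGY_CLASSES = ("normal", "microcytic", "hypochromic", "codocyte")


@dataclass
class PhantomCell:
    """Geometric description of one phantom erythrocyte.

    ``center_xy_um`` is the (x, y) offset of the cell center from the grid
    center, in object-plane micrometres.
    """

    center_xy_um: Tuple[float, float] = (0.0, 0.0)
    diameter_um: float = 7.0
    edge_thickness_um: float = 2.0
    dimple_depth_frac: float = 0.5
    morphology_class: str = "normal"
    #: fraction of the radius over which the rim tapers smoothly to zero.
    #: A strict square-root rim has a vertical tangent, which no band-limited
    #: imaging system can record (the local fringe frequency would exceed
    #: Nyquist); real cell edges have finite slope.
    rim_taper_frac: float = 0.35

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValueError("diameter_um must be positive")
        if self.edge_thickness_um <= 0:
            raise ValueError("edge_thickness_um must be positive")
        if not 0.0 <= self.dimple_depth_frac <= 1.0:
            raise ValueError("dimple_depth_frac must lie in [0, 1]")
        if self.morphology_class not in MORPHOLOGY_CLASSES:
            raise ValueError(
                f"morphology_class must be one of {MORPHOLOGY_CLASSES}"
            )
        if self.morphology_class == "normal":
            if not 6.0 <= self.diameter_um <= 8.0:
                raise ValueError("normal cells have diameter in [6, 8] um")
            if not 1.5 <= self.edge_thickness_um <= 2.5:
                raise ValueError("normal cells are ~2 um thick at the rim")


def _biconcave_radial_profile(dimple_depth_frac: float):
    """Radial profile f(rho) on rho = r/R in [0, 1], normalized to max 1.

    Uses f(rho) = sqrt(1 - u) * (alpha + u), u = rho^2, with alpha solved so
    that f(0) / max(f) equals 1 - dimple_depth_frac. dimple 0 degenerates to
    the monotone dome sqrt(1 - u).
    """
    d = float(dimple_depth_frac)
    if d <= 1e-9:
        def profile(u):
            return np.sqrt(np.clip(1.0 - u, 0.0, None))

        return profile

    def ratio(alpha):
        u_star = (2.0 - alpha) / 3.0
        if u_star <= 0:
            return 1.0
        peak = np.sqrt(1.0 - u_star) * (alpha + u_star)
        return alpha / peak

    if d >= 1.0 - 1e-9:
        alpha = 0.0  # full dimple: thickness vanishes at the center
    else:
        alpha = brentq(lambda a: ratio(a) - (1.0 - d), 1e-12, 2.0 - 1e-12, xtol=1e-12)
    u_star = (2.0 - alpha) / 3.0
    peak = np.sqrt(1.0 - u_star) * (alpha + u_star)

    def profile(u):
        return np.sqrt(np.clip(1.0 - u, 0.0, None)) * (alpha + u) / peak

    return profile


def make_biconcave_phantom(
    cell: PhantomCell,
    grid_shape: Tuple[int, int],
    sampling_um_per_px: float,
) -> ThicknessMap:
    """Rasterize a phantom cell's thickness map onto a pixel grid.

    The map is nonnegative, zero outside the cell disc, has its maximum in
    an annulus near the rim, and a central depression of relative depth
    ``dimple_depth_frac``. Codocytes additionally get a central bump (the
    target-cell bullseye).
    """
    if sampling_um_per_px <= 0:
        raise ValueError("sampling_um_per_px must be positive")
    ny, nx = grid_shape
    radius = cell.diameter_um / 2.0
    cx = (nx - 1) / 2.0 + cell.center_xy_um[0] / sampling_um_per_px
    cy = (ny - 1) / 2.0 + cell.center_xy_um[1] / sampling_um_per_px
    r_px = radius / sampling_um_per_px
    if not (
        r_px <= cx <= nx - 1 - r_px and r_px <= cy <= ny - 1 - r_px
    ):
        raise ValueError("cell extends beyond the grid")
    yy, xx = np.mgrid[0:ny, 0:nx]
    r2 = ((xx - cx) ** 2 + (yy - cy) ** 2) * sampling_um_per_px**2
    u = np.clip(r2 / radius**2, 0.0, None)
    inside = u < 1.0
    profile = _biconcave_radial_profile(cell.dimple_depth_frac)
    values = np.where(inside, profile(np.clip(u, 0.0, 1.0)), 0.0)
    if cell.rim_taper_frac > 0:
        # smootherstep rim taper: bounds the edge slope so the phantom's
        # phase stays representable at the configured sampling
        rho = np.sqrt(u)
        t = np.clip((1.0 - rho) / cell.rim_taper_frac, 0.0, 1.0)
        values = values * (t**3 * (10.0 - 15.0 * t + 6.0 * t**2))
    if cell.morphology_class == "codocyte":
        # central bump restoring most of the dimple: the bullseye
        rho = np.sqrt(u)
        bump = cell.dimple_depth_frac * np.clip(1.0 - (rho / 0.35) ** 2, 0.0, None) ** 2
        values = np.where(inside, values + bump, 0.0)
    # normalize so the global maximum equals the requested rim thickness
    values = values * (cell.edge_thickness_um / max(values.max(), 1e-30))
    return ThicknessMap(values=values, sampling_um_per_px=sampling_um_per_px)


def aberration_phase(config: SimulationConfig, grid_shape: Optional[Tuple[int, int]] = None) -> np.ndarray:
    """Low-order system aberration phase (tilt + defocus + astigmatism), radians.

    Coefficients act on grid coordinates normalized to [-1, 1]; the same
    map enters the object and the paired reference exposure, mimicking
    aberrations that stay constant between exposures.
    """
    ny, nx = grid_shape if grid_shape is not None else config.grid_shape
    tx, ty, dfc, a0, a45 = config.aberration_rad
    u = np.linspace(-1.0, 1.0, nx)[None, :]
    v = np.linspace(-1.0, 1.0, ny)[:, None]
    return tx * u + ty * v + dfc * (u**2 + v**2) + a0 * (u**2 - v**2) + a45 * u * v


def interference_intensity(phase: PhaseMap, config: SimulationConfig) -> np.ndarray:
    """Noise-free two-beam interference pattern on the tilted carrier."""
    if phase.wrap_state != "unwrapped":
        raise ValueError("sample phase must be unwrapped")
    fx, fy = config.fringe_freq_cyc_per_px
    if max(abs(fx), abs(fy)) >= 0.5:
        raise ValueError("carrier frequency at or above Nyquist: fringes would alias")
    ny, nx = phase.values.shape
    x = np.arange(nx)[None, :]
    y = np.arange(ny)[:, None]
    phi_r = 2.0 * np.pi * (fx * x + fy * y)
    e_s, e_r = config.beam_amp_sample, config.beam_amp_ref
    return e_s**2 + e_r**2 + 2.0 * e_s * e_r * np.cos(phase.values - phi_r)


def add_speckle_noise(
    intensity: np.ndarray,
    noise_sigma: float,
    rng_seed: int,
    speckle_contrast: float = 0.0,
) -> np.ndarray:
    """Residual-noise model: additive zero-mean Gaussian (in counts), with an
    optional multiplicative speckle term (off by default).

    ``noise_sigma = 0`` with zero speckle contrast is the identity.
    Deterministic under a fixed seed.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if noise_sigma == 0 and speckle_contrast == 0:
        return np.asarray(intensity, dtype=float)
    rng = np.random.default_rng(rng_seed)
    out = np.asarray(intensity, dtype=float)
    if speckle_contrast > 0:
        out = out * (1.0 + speckle_contrast * rng.standard_normal(out.shape))
    if noise_sigma > 0:
        out = out + noise_sigma * rng.standard_normal(out.shape)
    return out


def quantize_8bit(
    intensity: np.ndarray, span: Optional[Tuple[float, float]] = None
) -> np.ndarray:
    """Quantize to 8-bit counts.

    ``span`` is the ideal noise-free dynamic range mapped affinely onto
    [0, 255] (defaults to the input's own min/max); rounding is
    half-away-from-zero and out-of-range values (e.g. after noise) are
    clipped. A constant input has no contrast to scale and maps to mid-gray
    128 with a warning.
    """
    intensity = np.asarray(intensity, dtype=float)
    lo, hi = span if span is not None else (intensity.min(), intensity.max())
    if hi <= lo:
        warnings.warn("degenerate contrast: constant input quantized to 128", stacklevel=2)
        return np.full(intensity.shape, 128, dtype=np.uint8)
    scaled = 255.0 * (intensity - lo) / (hi - lo)
    rounded = np.sign(scaled) * np.floor(np.abs(scaled) + 0.5)
    return np.clip(rounded, 0, 255).astype(np.uint8)


def simulate_off_axis_hologram(
    phase: PhaseMap,
    config: SimulationConfig,
    include_aberration: bool = True,
) -> Hologram:
    """Forward-simulate an 8-bit off-axis hologram of a sample phase map.

    The quantization span is the ideal interference range
    [(E_0s - E_0r)^2, (E_0s + E_0r)^2], so noise can clip at the rails as on
    a real camera. Bit-reproducible under ``config.rng_seed``.
    """
    total = phase
    if include_aberration and any(config.aberration_rad):
        total = PhaseMap(
            values=phase.values + aberration_phase(config, phase.values.shape),
            wrap_state="unwrapped",
            sampling_um_per_px=phase.sampling_um_per_px,
        )
    ideal = interference_intensity(total, config)
    noisy = add_speckle_noise(
        ideal, config.noise_sigma, config.rng_seed, config.speckle_contrast
    )
    e_s, e_r = config.beam_amp_sample, config.beam_amp_ref
    pixels = quantize_8bit(noisy, span=((e_s - e_r) ** 2, (e_s + e_r) ** 2))
    return Hologram(
        pixels=pixels,
        pixel_pitch_um=config.pixel_pitch_um,
        source_label="synthetic",
    )


def make_reference_hologram(
    config: SimulationConfig, grid_shape: Optional[Tuple[int, int]] = None
) -> Hologram:
    """Cell-free reference exposure: aberration phase only, same carrier and
    noise realization as the paired object hologram (same seed)."""
    shape = grid_shape if grid_shape is not None else config.grid_shape
    flat = PhaseMap(
        values=np.zeros(shape),
        wrap_state="unwrapped",
        sampling_um_per_px=config.sampling_um_per_px,
    )
    return simulate_off_axis_hologram(flat, config, include_aberration=True)


def _derived_seed(base_seed: int, name: str) -> int:
    return (base_seed * 1000003 + zlib.crc32(name.encode())) % (2**31)


def _sample_cell(rng: np.random.Generator, morphology: str) -> PhantomCell:
    taper = 0.35
    if morphology == "normal":
        d = rng.uniform(6.0, 8.0)
        e = rng.uniform(1.8, 2.2)
        dim = rng.uniform(0.4, 0.7)
    elif morphology == "microcytic":
        d = rng.uniform(4.0, 5.5)
        e = rng.uniform(1.2, 1.6)
        dim = rng.uniform(0.4, 0.7)
        taper = 0.40  # smaller cells need a relatively wider rim
    elif morphology == "hypochromic":
        d = rng.uniform(6.0, 8.0)
        e = rng.uniform(1.0, 1.4)
        dim = rng.uniform(0.6, 0.85)
    else:  # codocyte
        d = rng.uniform(6.0, 8.0)
        e = rng.uniform(1.6, 2.0)
        dim = rng.uniform(0.5, 0.8)
    return PhantomCell(
        center_xy_um=(float(rng.uniform(-1, 1)), float(rng.uniform(-1, 1))),
        diameter_um=float(d),
        edge_thickness_um=float(e),
        dimple_depth_frac=float(dim),
        morphology_class=morphology,
        rim_taper_frac=taper,
    )


def _sample_aberration(rng: np.random.Generator) -> Tuple[float, ...]:
    return (
        float(rng.uniform(-1.0, 1.0)),
        float(rng.uniform(-1.0, 1.0)),
        float(rng.uniform(-2.0, 2.0)),
        float(rng.uniform(-0.5, 0.5)),
        float(rng.uniform(-0.5, 0.5)),
    )


def generate_dataset(
    n_normal: int,
    n_thal: int,
    config: SimulationConfig,
    root: str | Path,
    rng_seed: Optional[int] = None,
) -> DatasetManifest:
    """Write a synthetic dataset tree in the deposited-data convention.

    ``<root>/nRBC/`` gets ``n_normal`` normal-cell holograms and
    ``<root>/tRBC/`` gets ``n_thal`` holograms with morphology drawn among
    microcytic/hypochromic/codocyte. Each object hologram ``X.bmp`` comes
    with a paired cell-free reference ``X_ref.bmp`` (same carrier,
    aberration, and noise seed) and a ground-truth thickness sidecar
    ``X.truth.txt`` (plain-text micrometre matrix). Byte-deterministic
    under a fixed seed.
    """
    if n_normal < 0 or n_thal < 0:
        raise ValueError("counts must be nonnegative")
    root = Path(root)
    base_seed = config.rng_seed if rng_seed is None else rng_seed
    import dataclasses as _dc

    thal_classes = ("microcytic", "hypochromic", "codocyte")
    jobs = [("nRBC", f"nrbc_{i:04d}", "normal") for i in range(n_normal)]
    jobs += [("tRBC", f"trbc_{i:04d}", None) for i in range(n_thal)]
    for label, stem, morphology in jobs:
        seed = _derived_seed(base_seed, stem)
        rng = np.random.default_rng(seed)
        if morphology is None:
            morphology = thal_classes[int(rng.integers(len(thal_classes)))]
        cell = _sample_cell(rng, morphology)
        cfg = _dc.replace(
            config, rng_seed=seed, aberration_rad=_sample_aberration(rng)
        )
        truth = make_biconcave_phantom(cell, cfg.grid_shape, cfg.sampling_um_per_px)
        phase = thickness_to_phase(truth, cfg)
        holo = simulate_off_axis_hologram(phase, cfg)
        ref = make_reference_hologram(cfg, cfg.grid_shape)
        folder = root / label
        folder.mkdir(parents=True, exist_ok=True)
        write_hologram_bmp(holo, folder / f"{stem}.bmp")
        write_hologram_bmp(ref, folder / f"{stem}_ref.bmp")
        np.savetxt(folder / f"{stem}.truth.txt", truth.values, fmt="%.6f")
    for label in ("nRBC", "tRBC"):
        (root / label).mkdir(parents=True, exist_ok=True)
    return scan_dataset(root)
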