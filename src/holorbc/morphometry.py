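"""Phase-to-thickness conversion and red-blood-cell shape measurements.

An unwrapped phase map converts to optical thickness through
``T(x, y) = lambda * phi(x, y) / (2 pi * n * reflection_factor)`` with
``n`` the effective refractive index. The default reflection factor is 1
(phase read directly as a single-pass optical path); a factor of 2 is
available for reflection-mode geometries where the beam traverses the
sample twice.

Downstream utilities level the background plane, segment the cell, sample
cross-sectional profiles, and compute the morphometric descriptors used for
erythrocytes: projected area, equivalent diameter, thickness statistics,
volume, circularity, and dimple depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage import measure

from .config import SimulationConfig
from .unwrap import PhaseMap

__all__ = [
    "ThicknessMap",
    "CellFeatures",
    "thickness_from_phase",
    "thickness_to_phase",
    "level_background",
    "segment_cell",
    "cross_section_profile",
    "cell_features",
    "min_resolvable_na",
]


@dataclass
class ThicknessMap:
    """Per-pixel sample thickness in micrometres."""

    values: np.ndarray
    sampling_um_per_px: float = 1.0
    medium_index_used: Optional[float] = None
    reflection_factor_used: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("thickness values must be 2D")
        if not np.isfinite(self.values).all():
            raise ValueError("thickness values must be finite")
        if self.sampling_um_per_px <= 0:
            raise ValueError("sampling_um_per_px must be positive")


@dataclass
class CellFeatures:
    projected_area_um2: float
    equivalent_diameter_um: float
    max_thickness_um: float
    mean_thickness_um: float
    volume_um3: float
    circularity: float
    dimple_depth_um: float

    def as_dict(self) -> dict:
        return {
            "projected_area_um2": self.projected_area_um2,
            "equivalent_diameter_um": self.equivalent_diameter_um,
            "max_thickness_um": self.max_thickness_um,
            "mean_thickness_um": self.mean_thickness_um,
            "volume_um3": self.volume_um3,
            "circularity": self.circularity,
            "dimple_depth_um": self.dimple_depth_um,
        }


def thickness_from_phase(
    phase: PhaseMap, config: SimulationConfig, reflection_factor: int = 1
) -> ThicknessMap:
    """Invert the phase-thickness relation: T = lambda * phi / (2 pi n r)."""
    if phase.wrap_state != "unwrapped":
        raise ValueError("thickness conversion needs unwrapped phase")
    n = config.medium_index
    if n <= 0:
        raise ValueError("medium index must be positive")
    values = config.wavelength_um * phase.values / (2.0 * np.pi * n * reflection_factor)
    return ThicknessMap(
        values=values,
        sampling_um_per_px=phase.sampling_um_per_px,
        medium_index_used=n,
        reflection_factor_used=reflection_factor,
    )


def thickness_to_phase(thickness: ThicknessMap, config: SimulationConfig) -> PhaseMap:
    """Forward phase-thickness relation: phi = (2 pi / lambda) * n * T."""
    values = np.asarray(thickness.values, dtype=float)
    if values.min() < 0:
        raise ValueError("thickness must be nonnegative")
    rf = thickness.reflection_factor_used or 1
    phase = 2.0 * np.pi * config.medium_index * rf * values / config.wavelength_um
    return PhaseMap(
        values=phase,
        wrap_state="unwrapped",
        sampling_um_per_px=thickness.sampling_um_per_px,
    )


def level_background(thickness: ThicknessMap, background_mask: np.ndarray) -> ThicknessMap:
    """Subtract the least-squares plane fitted over the background pixels.

    After leveling, the background median is ~0, as a cell-free region
    should read. The mask must cover at least 5% of the pixels so the plane
    fit is well conditioned.
    """
    background_mask = np.asarray(background_mask, dtype=bool)
    if background_mask.shape != thickness.values.shape:
        raise ValueError("background mask shape mismatch")
    frac = background_mask.mean()
    if frac < 0.05:
        raise ValueError(
            f"background mask covers {frac:.1%} of pixels; need at least 5%"
        )
    ny, nx = thickness.values.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    a = np.column_stack(
        [xx[background_mask], yy[background_mask], np.ones(background_mask.sum())]
    )
    coef, *_ = np.linalg.lstsq(a, thickness.values[background_mask], rcond=None)
    plane = coef[0] * xx + coef[1] * yy + coef[2]
    return ThicknessMap(
        values=thickness.values - plane,
        sampling_um_per_px=thickness.sampling_um_per_px,
        medium_index_used=thickness.medium_index_used,
        reflection_factor_used=thickness.reflection_factor_used,
    )


def segment_cell(thickness: ThicknessMap, threshold_frac: float = 0.25) -> np.ndarray:
    """Segment the cell: threshold at a fraction of the robust maximum,
    keep the largest 8-connected component, fill holes. Deterministic."""
    v = thickness.values
    robust_max = float(np.percentile(v, 99.5))
    if robust_max <= 0:
        warnings.warn("no thickness signal above zero; returning empty mask", stacklevel=2)
        return np.zeros_like(v, dtype=bool)
    candidate = v >= threshold_frac * robust_max
    if not candidate.any():
        warnings.warn("no pixels above segmentation threshold", stacklevel=2)
        return candidate
    labels, n = ndimage.label(candidate, structure=np.ones((3, 3), dtype=int))
    sizes = ndimage.sum_labels(np.ones_like(v), labels, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    return ndimage.binary_fill_holes(labels == largest)


def cross_section_profile(
    thickness: ThicknessMap,
    p0: Tuple[float, float],
    p1: Tuple[float, float],
    step_px: float = 0.25,
) -> Tuple[np.ndarray, np.ndarray]:
    """Thickness along a line segment, bilinearly interpolated.

    ``p0``/``p1`` are (row, col) pixel coordinates. Returns
    ``(distance_um, thickness_um)``; distances are object-plane micrometres
    from ``p0``.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    ny, nx = thickness.values.shape
    for p in (p0, p1):
        if not (0 <= p[0] <= ny - 1 and 0 <= p[1] <= nx - 1):
            raise ValueError(f"profile endpoint {tuple(p)} outside the grid")
    length_px = float(np.hypot(*(p1 - p0)))
    if length_px == 0:
        raise ValueError("degenerate profile: endpoints coincide")
    n_samples = int(np.ceil(length_px / step_px)) + 1
    t = np.linspace(0.0, 1.0, n_samples)
    coords = np.outer(1 - t, p0) + np.outer(t, p1)
    vals = ndimage.map_coordinates(thickness.values, coords.T, order=1, mode="nearest")
    dist = t * length_px * thickness.sampling_um_per_px
    return dist, vals


def cell_features(thickness: ThicknessMap, mask: np.ndarray) -> CellFeatures:
    """Morphometric descriptors of a segmented cell.

    Volume integrates thickness over the mask; circularity is
    ``4 pi A / P^2`` (clipped into (0, 1], since discrete perimeters of
    very small masks can overshoot).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != thickness.values.shape:
        raise ValueError("mask shape mismatch")
    n_px = int(mask.sum())
    if n_px == 0:
        raise ValueError("empty mask: no cell to measure")
    s = thickness.sampling_um_per_px
    area = n_px * s**2
    equiv_diameter = 2.0 * np.sqrt(area / np.pi)
    vals = thickness.values[mask]
    volume = float(np.clip(vals, 0, None).sum() * s**2)
    perimeter_px = measure.perimeter(mask)
    if perimeter_px <= 0:  # single pixel or degenerate mask
        perimeter_px = 4.0
    circularity = float(np.clip(4.0 * np.pi * n_px / perimeter_px**2, 1e-12, 1.0))
    # dimple depth: rim maximum minus the value at the mask centroid
    ci, cj = ndimage.center_of_mass(mask)
    center_val = float(thickness.values[int(round(ci)), int(round(cj))])
    dimple = max(float(vals.max()) - center_val, 0.0)
    return CellFeatures(
        projected_area_um2=float(area),
        equivalent_diameter_um=float(equiv_diameter),
        max_thickness_um=float(vals.max()),
        mean_thickness_um=float(vals.mean()),
        volume_um3=volume,
        circularity=circularity,
        dimple_depth_um=dimple,
    )


def min_resolvable_na(wavelength_um: float, grating_period_um: float) -> float:
    """Minimum effective numerical aperture needed to resolve a grating:
    NA = lambda / d."""
    if wavelength_um <= 0:
        raise ValueError("wavelength must be positive")
    if grating_period_um <= 0:
        raise ValueError("grating period must be positive")
    return wavelength_um / grating_period_um
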