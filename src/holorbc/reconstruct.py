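"""Spectral stage of off-axis hologram reconstruction.

An off-axis hologram carries the object wave on a spatial-frequency carrier.
Reconstruction forms the hologram's angular spectrum (forward Fourier
transform with kernel ``e^{-2 pi i (xi x + eta y)}``), selects one sideband
with a hard circular binary mask, shifts it to the spectrum center
(demodulation), inverse-transforms, and numerically propagates the complex
field with the exact free-space transfer function

    H(xi, eta; d) = exp( i k d sqrt(1 - lambda^2 xi^2 - lambda^2 eta^2) ),

zeroing the evanescent components (lambda^2 (xi^2 + eta^2) > 1).

Transform normalization is fixed for reproducibility: unnormalized forward,
1/N^2 inverse (the numpy convention). Spectra are stored DC-centered.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Tuple

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "ComplexField",
    "Spectrum",
    "SidebandSelection",
    "SidebandDetectionError",
    "forward_spectrum",
    "inverse_spectrum",
    "detect_sideband",
    "filter_and_center",
    "angular_spectrum_propagate",
    "autofocus_distance",
    "intensity_map",
]

logger = logging.getLogger(__name__)


class SidebandDetectionError(RuntimeError):
    """No off-DC sideband peak rises above the DC-leakage floor."""


@dataclass
class ComplexField:
    """Complex amplitude over object-plane coordinates at distance ``z_um``
    from the hologram plane."""

    values: np.ndarray
    sampling_um_per_px: float
    z_um: float = 0.0
    wavelength_um: float = 0.6328

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.ndim != 2:
            raise ValueError("field values must be 2D")
        if self.sampling_um_per_px <= 0:
            raise ValueError("sampling_um_per_px must be positive")
        if self.wavelength_um <= 0:
            raise ValueError("wavelength_um must be positive")


@dataclass
class Spectrum:
    """Complex grid over spatial frequencies (xi, eta), DC-centered by default.

    ``dfreq_*`` are the frequency bin spacings in cycles/um:
    ``1 / (N * sampling)`` along each axis. Field metadata is carried through
    so the inverse transform can rebuild a :class:`ComplexField`.
    """

    values: np.ndarray
    dfreq_x: float
    dfreq_y: float
    dc_centered: bool = True
    sampling_um_per_px: float = 1.0
    z_um: float = 0.0
    wavelength_um: float = 0.6328

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.ndim != 2:
            raise ValueError("spectrum values must be 2D")

    @property
    def dc_bin(self) -> Tuple[int, int]:
        """(row, col) index of the zero-frequency bin."""
        if self.dc_centered:
            return (self.values.shape[0] // 2, self.values.shape[1] // 2)
        return (0, 0)


@dataclass
class SidebandSelection:
    """Chosen sideband peak and its circular binary mask."""

    peak_bin: Tuple[int, int]  # (row, col) in the DC-centered spectrum
    mask_radius_bins: float
    mask: np.ndarray


def forward_spectrum(field: ComplexField) -> Spectrum:
    """Angular spectrum of a complex field (forward DFT, DC-centered)."""
    if not np.isfinite(field.values).all():
        raise ValueError("field contains non-finite values")
    values = np.fft.fftshift(np.fft.fft2(field.values))
    ny, nx = field.values.shape
    return Spectrum(
        values=values,
        dfreq_x=1.0 / (nx * field.sampling_um_per_px),
        dfreq_y=1.0 / (ny * field.sampling_um_per_px),
        dc_centered=True,
        sampling_um_per_px=field.sampling_um_per_px,
        z_um=field.z_um,
        wavelength_um=field.wavelength_um,
    )


def inverse_spectrum(spectrum: Spectrum) -> ComplexField:
    """Inverse DFT back to the object plane (1/N^2 normalization)."""
    values = spectrum.values
    if spectrum.dc_centered:
        values = np.fft.ifftshift(values)
    return ComplexField(
        values=np.fft.ifft2(values),
        sampling_um_per_px=spectrum.sampling_um_per_px,
        z_um=spectrum.z_um,
        wavelength_um=spectrum.wavelength_um,
    )


def detect_sideband(
    spectrum: Spectrum,
    dc_exclusion_bins: int = 8,
    mask_radius_bins: Optional[float] = None,
    negative_half_plane: bool = False,
) -> SidebandSelection:
    """Locate one interference sideband in the spectrum of a real hologram.

    The spectrum of a real-valued off-axis hologram holds three regions: the
    zero-order term around DC and two conjugate sidebands (virtual and real
    image). Either sideband is usable; for reproducibility the peak with
    positive xi is chosen (ties broken by positive eta), or the mirrored one
    when ``negative_half_plane`` is set — that choice flips the sign of the
    recovered phase.

    The default mask radius is half the carrier-to-DC distance.
    """
    if not spectrum.dc_centered:
        raise ValueError("detect_sideband expects a DC-centered spectrum")
    mag = np.abs(spectrum.values)
    ny, nx = mag.shape
    ic, jc = spectrum.dc_bin
    rows = np.arange(ny)[:, None] - ic  # eta index offset
    cols = np.arange(nx)[None, :] - jc  # xi index offset

    allowed = (cols > 0) | ((cols == 0) & (rows > 0))
    if negative_half_plane:
        allowed = (cols < 0) | ((cols == 0) & (rows < 0))
    allowed &= (rows**2 + cols**2) > dc_exclusion_bins**2

    masked = np.where(allowed, mag, -1.0)
    flat = int(np.argmax(masked))
    ip, jp = divmod(flat, nx)
    dc_mag = mag[ic, jc]
    if masked[ip, jp] <= 0 or masked[ip, jp] <= 1e-9 * max(dc_mag, 1.0):
        raise SidebandDetectionError(
            "no off-DC sideband peak above the DC-leakage floor; "
            "use a larger region of interest or supply the peak manually"
        )
    dist = float(np.hypot(ip - ic, jp - jc))
    radius = float(mask_radius_bins) if mask_radius_bins is not None else dist / 2.0
    mask = (rows - (ip - ic)) ** 2 + (cols - (jp - jc)) ** 2 <= radius**2
    return SidebandSelection(peak_bin=(ip, jp), mask_radius_bins=radius, mask=mask)


def filter_and_center(spectrum: Spectrum, selection: SidebandSelection) -> Spectrum:
    """Apply the binary sideband mask and shift the peak to the DC bin.

    Masking suppresses the zero-order term and the conjugate (twin) image;
    the integer-bin circular shift removes the carrier tilt exactly up to a
    sub-bin residual, which reference-phase subtraction cancels downstream.
    """
    if selection.mask.shape != spectrum.values.shape:
        raise ValueError("selection mask shape does not match spectrum shape")
    ic, jc = spectrum.dc_bin
    if selection.mask[ic, jc]:
        warnings.warn(
            "sideband mask covers the DC bin; zero-order contamination likely",
            stacklevel=2,
        )
    filtered = spectrum.values * selection.mask
    ip, jp = selection.peak_bin
    centered = np.roll(filtered, shift=(ic - ip, jc - jp), axis=(0, 1))
    return Spectrum(
        values=centered,
        dfreq_x=spectrum.dfreq_x,
        dfreq_y=spectrum.dfreq_y,
        dc_centered=True,
        sampling_um_per_px=spectrum.sampling_um_per_px,
        z_um=spectrum.z_um,
        wavelength_um=spectrum.wavelength_um,
    )


def angular_spectrum_propagate(field: ComplexField, d_um: float) -> ComplexField:
    """Free-space propagation by the exact angular-spectrum transfer function.

    Negative ``d_um`` back-propagates. Evanescent frequency bins
    (``lambda^2 (xi^2 + eta^2) > 1``) are zeroed; over the propagating band
    the transfer function has unit modulus, so energy there is conserved and
    propagation by ``-d`` undoes propagation by ``+d``.
    """
    if d_um == 0.0:  # e^0 = 1 for every component, evanescent included
        return ComplexField(
            values=field.values.copy(),
            sampling_um_per_px=field.sampling_um_per_px,
            z_um=field.z_um,
            wavelength_um=field.wavelength_um,
        )
    lam = field.wavelength_um
    ny, nx = field.values.shape
    fx = np.fft.fftfreq(nx, d=field.sampling_um_per_px)
    fy = np.fft.fftfreq(ny, d=field.sampling_um_per_px)
    fxx, fyy = np.meshgrid(fx, fy)
    arg = 1.0 - (lam * fxx) ** 2 - (lam * fyy) ** 2
    propagating = arg >= 0.0
    k = 2.0 * np.pi / lam
    transfer = np.where(
        propagating, np.exp(1j * k * d_um * np.sqrt(np.where(propagating, arg, 0.0))), 0.0
    )
    out = np.fft.ifft2(np.fft.fft2(field.values) * transfer)
    return ComplexField(
        values=out,
        sampling_um_per_px=field.sampling_um_per_px,
        z_um=field.z_um + d_um,
        wavelength_um=field.wavelength_um,
    )


def _normalized_amplitude_variance(field: ComplexField) -> float:
    amp = np.abs(field.values)
    mean = amp.mean()
    if mean == 0:
        return 0.0
    return float(amp.var() / mean**2)


def autofocus_distance(
    field: ComplexField,
    d_min: float,
    d_max: float,
    n_steps: int = 21,
    metric: Optional[Callable[[ComplexField], float]] = None,
) -> float:
    """Search for the best-focus propagation distance.

    Scans ``n_steps`` distances in ``[d_min, d_max]`` maximizing a focus
    metric (default: normalized amplitude variance, which peaks where
    amplitude structure is sharpest), then refines with a bounded scalar
    search around the coarse winner. Deterministic.
    """
    if not d_min < d_max:
        raise ValueError("require d_min < d_max")
    if n_steps < 3:
        raise ValueError("n_steps must be >= 3")
    metric = metric or _normalized_amplitude_variance
    grid = np.linspace(d_min, d_max, n_steps)
    scores = np.array([metric(angular_spectrum_propagate(field, d)) for d in grid])
    span = scores.max() - scores.min()
    if span <= 1e-12 * max(abs(scores.max()), 1e-30):
        warnings.warn(
            "focus metric is flat over the search range; returning mid-range",
            stacklevel=2,
        )
        return float(0.5 * (d_min + d_max))
    best = int(np.argmax(scores))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, n_steps - 1)]
    res = minimize_scalar(
        lambda d: -metric(angular_spectrum_propagate(field, d)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": (hi - lo) * 1e-3},
    )
    return float(res.x)


def intensity_map(field: ComplexField) -> np.ndarray:
    """Microscopy-like intensity image |E|^2."""
    return np.abs(field.values) ** 2
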