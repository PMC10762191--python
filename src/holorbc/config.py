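"""Configuration objects for simulation and the reconstruction pipeline.

All distances are in micrometres unless a name says otherwise; spatial
frequencies are in cycles per camera pixel. Defaults mirror the optical
setup the package models: a 632.8 nm He-Ne source, a 5.2 um pixel-pitch
8-bit camera, and a 10x Mirau objective whose effective magnification is
raised by a contact microsphere.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import yaml

__all__ = ["SimulationConfig", "PipelineConfig"]


@dataclass
class SimulationConfig:
    """Physical and numerical parameters of the off-axis hologram forward model.

    Parameters
    ----------
    wavelength_um : float
        Vacuum wavelength of the source (default: He-Ne, 0.6328 um).
    medium_index : float
        Effective refractive index ``n`` in the phase <-> thickness relation
        ``phi = (2 pi / lambda) * n * T``. Defaults to 0.5, the approximate
        refractive-index contrast of an air-dried cell against air: the
        phase a transmissive sample imprints scales with the index
        *difference*, and using the literal surrounding-medium index (1.0
        for air) would make a 2 um cell imprint a physically impossible
        ~20 rad at visible wavelengths. See the methods note for the
        ambiguity this single effective parameter absorbs.
    magnification : float
        Lateral magnification mapping object-plane micrometres to camera
        pixels. Nominal objective power times the microsphere gain.
    pixel_pitch_um : float
        Camera pixel pitch (default 5.2 um).
    fringe_freq_cyc_per_px : (float, float)
        Carrier frequency ``(f_x, f_y)`` of the tilted reference beam in
        cycles per pixel. Must stay below Nyquist (0.5). The default tilt is
        negative so that the sideband at positive xi — the one the
        reconstruction selects by default — carries ``e^{+i phi_s}`` and the
        recovered phase has the sample's sign.
    beam_amp_sample, beam_amp_ref : float
        Amplitudes ``E_0s`` and ``E_0r`` of the sample and reference beams.
    noise_sigma : float
        Standard deviation, in counts, of the additive residual-speckle
        noise applied before 8-bit quantization.
    speckle_contrast : float
        Optional multiplicative speckle contrast (0 disables it; default 0).
    rng_seed : int
        Seed for every random draw in the simulator.
    grid_shape : (int, int)
        Sensor format as (rows, cols); the deposited data convention is
        1024 x 1280.
    aberration_rad : (float, float, float, float, float)
        Low-order system aberration phase shared by object and reference
        exposures: (tilt_x, tilt_y, defocus, astigmatism_0, astigmatism_45)
        coefficients in radians over normalized [-1, 1] grid coordinates.
    """

    wavelength_um: float = 0.6328
    medium_index: float = 0.5
    magnification: float = 120.0
    pixel_pitch_um: float = 5.2
    fringe_freq_cyc_per_px: Tuple[float, float] = (-0.32, -0.16)
    beam_amp_sample: float = 1.0
    beam_amp_ref: float = 1.0
    noise_sigma: float = 2.0
    speckle_contrast: float = 0.0
    rng_seed: int = 0
    grid_shape: Tuple[int, int] = (1024, 1280)
    aberration_rad: Tuple[float, float, float, float, float] = (0.0, 0.0, 0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.wavelength_um <= 0:
            raise ValueError("wavelength_um must be positive")
        if self.medium_index <= 0:
            raise ValueError("medium_index must be positive")
        if self.magnification <= 0:
            raise ValueError("magnification must be positive")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")
        fx, fy = self.fringe_freq_cyc_per_px
        if abs(fx) + abs(fy) == 0:
            raise ValueError("carrier frequency must be nonzero")
        if max(abs(fx), abs(fy)) >= 0.5:
            raise ValueError(
                "carrier frequency at or above Nyquist (0.5 cyc/px): "
                f"{self.fringe_freq_cyc_per_px}"
            )
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def sampling_um_per_px(self) -> float:
        """Object-plane sampling: camera pitch divided by magnification."""
        return self.pixel_pitch_um / self.magnification


@dataclass
class PipelineConfig:
    """Full pipeline configuration: simulation plus reconstruction options.

    Every field has a working default, so an empty config file is valid.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # sideband selection
    dc_exclusion_bins: int = 8
    mask_radius_bins: Optional[float] = None  # default: half carrier-to-DC distance
    negative_half_plane: bool = False  # pick the conjugate sideband (flips phase sign)
    # focusing
    autofocus: bool = False
    focus_distance_um: float = 0.0
    autofocus_range_um: Tuple[float, float] = (-200.0, 200.0)
    autofocus_steps: int = 21
    # morphometry
    segmentation_threshold_frac: float = 0.25
    reflection_factor: int = 1
    # bookkeeping
    output_dir: str = "holorbc_out"
    log_level: str = "INFO"

    _SIM_FIELDS = {f.name for f in dataclasses.fields(SimulationConfig)}

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        """Build from a flat mapping; simulation keys may appear at top level."""
        data = dict(data or {})
        sim_kwargs = {k: data.pop(k) for k in list(data) if k in cls._SIM_FIELDS}
        sim_kwargs.update(data.pop("simulation", {}) or {})
        if "fringe_freq_cyc_per_px" in sim_kwargs:
            sim_kwargs["fringe_freq_cyc_per_px"] = tuple(sim_kwargs["fringe_freq_cyc_per_px"])
        if "grid_shape" in sim_kwargs:
            sim_kwargs["grid_shape"] = tuple(sim_kwargs["grid_shape"])
        if "aberration_rad" in sim_kwargs:
            sim_kwargs["aberration_rad"] = tuple(sim_kwargs["aberration_rad"])
        known = {f.name for f in dataclasses.fields(cls) if not f.name.startswith("_")}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "autofocus_range_um" in data:
            data["autofocus_range_um"] = tuple(data["autofocus_range_um"])
        return cls(simulation=SimulationConfig(**sim_kwargs), **data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = dataclasses.asdict(self.simulation)
        return d
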