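"""Reading and writing holograms in the dataset's storage convention.

The deposited recordings are 8-bit grayscale BMP files, 1280 x 1024 px,
organized in two folders named ``nRBC`` and ``tRBC``. This module reads
both true-grayscale and palette-indexed 8-bit BMPs (the palette must be a
gray ramp), always writes palette-indexed 8-bit BMPs with an identity gray
ramp, and normalizes the in-memory row order to a top-left origin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
from PIL import Image

__all__ = [
    "Hologram",
    "DatasetManifest",
    "HologramFormatError",
    "read_hologram_bmp",
    "write_hologram_bmp",
    "scan_dataset",
    "DATASET_LABELS",
]

logger = logging.getLogger(__name__)

DATASET_LABELS = ("nRBC", "tRBC")
_VALID_LABELS = ("nRBC", "tRBC", "synthetic", "unknown")

#: reference holograms written by the simulator carry this suffix and are
#: treated as companions of their object hologram, not dataset entries
REFERENCE_SUFFIX = "_ref"


class HologramFormatError(ValueError):
    """Raised when a file is not an 8-bit grayscale/gray-palette BMP."""


@dataclass
class Hologram:
    """A recorded (or simulated) interference pattern.

    ``pixels`` holds the detected intensity counts, row 0 at the top.
    """

    pixels: np.ndarray
    pixel_pitch_um: float = 5.2
    source_label: str = "unknown"
    source_path: Optional[Path] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D grid")
        if self.pixels.shape[0] < 8 or self.pixels.shape[1] < 8:
            raise ValueError("hologram must be at least 8 x 8 pixels")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("pixel values must lie in [0, 255]")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")
        if self.source_label not in _VALID_LABELS:
            raise ValueError(
                f"source_label must be one of {_VALID_LABELS}, got {self.source_label!r}"
            )
        self.pixels = self.pixels.astype(np.uint8)

    @property
    def height_px(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width_px(self) -> int:
        return int(self.pixels.shape[1])


@dataclass
class DatasetManifest:
    """Deterministic listing of a dataset tree's hologram files."""

    entries: List[Tuple[Path, str]] = field(default_factory=list)

    @property
    def counts(self) -> dict:
        c = {label: 0 for label in DATASET_LABELS}
        for _, label in self.entries:
            c[label] = c.get(label, 0) + 1
        return c

    def __len__(self) -> int:
        return len(self.entries)


def _label_from_path(path: Path) -> str:
    name = path.parent.name
    return name if name in _VALID_LABELS else "unknown"


def read_hologram_bmp(path: str | Path, pixel_pitch_um: float = 5.2) -> Hologram:
    """Read an 8-bit BMP hologram.

    Accepts true 8-bit grayscale and palette-indexed BMPs whose palette is a
    gray ramp; rejects anything deeper than 8 bits per pixel or with a color
    palette. Pillow normalizes BMP bottom-up row storage, so ``pixels``
    always has row 0 at the top.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"hologram file not found: {path}")
    with Image.open(path) as img:
        if img.format != "BMP":
            raise HologramFormatError(f"not a BMP file (format={img.format}): {path}")
        if img.mode == "L":
            pixels = np.asarray(img, dtype=np.uint8)
        elif img.mode == "P":
            palette = np.asarray(img.getpalette(), dtype=np.int64).reshape(-1, 3)
            if not (palette[:, 0] == palette[:, 1]).all() or not (
                palette[:, 1] == palette[:, 2]
            ).all():
                raise HologramFormatError(
                    f"palette is not grayscale (R/G/B entries differ): {path}"
                )
            indices = np.asarray(img, dtype=np.int64)
            pixels = palette[indices, 0].astype(np.uint8)
        else:
            raise HologramFormatError(
                f"unsupported pixel format (mode={img.mode}, expected 8-bit gray): {path}"
            )
    return Hologram(
        pixels=pixels,
        pixel_pitch_um=pixel_pitch_um,
        source_label=_label_from_path(path),
        source_path=path,
    )


def write_hologram_bmp(hologram: Hologram, path: str | Path) -> Path:
    """Write a hologram as a palette-indexed 8-bit BMP with identity gray ramp.

    Re-reading with :func:`read_hologram_bmp` recovers the pixel grid
    bit-exactly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = Image.fromarray(hologram.pixels, mode="P")
    ramp = list(range(256))
    img.putpalette([v for g in ramp for v in (g, g, g)])
    try:
        img.save(path, format="BMP")
    except OSError as exc:
        raise OSError(f"cannot write hologram to {path}: {exc}") from exc
    return path


def scan_dataset(root: str | Path) -> DatasetManifest:
    """Enumerate ``<root>/nRBC/*.bmp`` and ``<root>/tRBC/*.bmp``.

    Ordering is lexicographic within each label folder (nRBC first), so two
    scans of the same tree always yield identical manifests. Files named
    ``*_ref.bmp`` are paired reference exposures, not dataset entries, and
    are skipped.
    """
    root = Path(root)
    if not root.exists():
        raise FileNotFoundError(f"dataset root not found: {root}")
    entries: List[Tuple[Path, str]] = []
    found_any_folder = False
    for label in DATASET_LABELS:
        folder = root / label
        if not folder.is_dir():
            continue
        found_any_folder = True
        for bmp in sorted(folder.glob("*.bmp")):
            if bmp.stem.endswith(REFERENCE_SUFFIX):
                continue
            entries.append((bmp, label))
    if not found_any_folder:
        logger.warning("neither nRBC/ nor tRBC/ found under %s; manifest is empty", root)
    return DatasetManifest(entries=entries)
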