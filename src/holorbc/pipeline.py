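"""End-to-end reconstruction runs: hologram file(s) in, thickness and
features out, with a JSON log of every automatic decision."""

from __future__ import annotations

import csv
import json
import logging
import warnings
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
from PIL import Image
from scipy import ndimage

from . import morphometry, reconstruct, unwrap
from .config import PipelineConfig
from .io import Hologram, read_hologram_bmp, scan_dataset
from .simulate import generate_dataset

__all__ = ["reconstruct_hologram", "run_reconstruct", "run_batch", "run_simulate"]

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = [
    "path",
    "label",
    "projected_area_um2",
    "equivalent_diameter_um",
    "max_thickness_um",
    "mean_thickness_um",
    "volume_um3",
    "circularity",
    "dimple_depth_um",
]


def _hologram_to_field(holo: Hologram, config: PipelineConfig) -> reconstruct.ComplexField:
    sim = config.simulation
    return reconstruct.ComplexField(
        values=holo.pixels.astype(float),
        sampling_um_per_px=sim.sampling_um_per_px,
        z_um=0.0,
        wavelength_um=sim.wavelength_um,
    )


def _demodulate(
    holo: Hologram,
    config: PipelineConfig,
    selection: Optional[reconstruct.SidebandSelection] = None,
) -> Tuple[reconstruct.ComplexField, reconstruct.SidebandSelection]:
    spectrum = reconstruct.forward_spectrum(_hologram_to_field(holo, config))
    if selection is None:
        selection = reconstruct.detect_sideband(
            spectrum,
            dc_exclusion_bins=config.dc_exclusion_bins,
            mask_radius_bins=config.mask_radius_bins,
            negative_half_plane=config.negative_half_plane,
        )
    filtered = reconstruct.filter_and_center(spectrum, selection)
    return reconstruct.inverse_spectrum(filtered), selection


def reconstruct_hologram(
    object_holo: Hologram,
    reference_holo: Optional[Hologram],
    config: PipelineConfig,
) -> dict:
    """Run the full numerical reconstruction on in-memory holograms.

    Returns a dict with the complex field, wrapped/unwrapped phase, leveled
    thickness map, segmentation mask, features, and the decision log.
    """
    field, selection = _demodulate(object_holo, config)
    log: dict = {
        "sideband_peak_bin": [int(b) for b in selection.peak_bin],
        "mask_radius_bins": float(selection.mask_radius_bins),
    }

    if config.autofocus:
        d_lo, d_hi = config.autofocus_range_um
        focus = reconstruct.autofocus_distance(
            field, d_lo, d_hi, n_steps=config.autofocus_steps
        )
    else:
        focus = config.focus_distance_um
    log["focus_distance_um"] = float(focus)
    if focus != 0.0:
        field = reconstruct.angular_spectrum_propagate(field, focus)

    phase_obj = unwrap.wrapped_phase(field)
    if reference_holo is not None:
        # the object's sideband selection demodulates the reference too, so
        # both share the same residual carrier and it cancels on subtraction
        ref_field, _ = _demodulate(reference_holo, config, selection=selection)
        if focus != 0.0:
            ref_field = reconstruct.angular_spectrum_propagate(ref_field, focus)
        phase_ref = unwrap.wrapped_phase(ref_field)
        phase_cell = unwrap.subtract_reference_phase(phase_obj, phase_ref)
        log["reference"] = "paired hologram"
    else:
        warnings.warn(
            "no reference hologram: skipping aberration subtraction", stacklevel=2
        )
        phase_cell = phase_obj
        log["reference"] = None

    unwrapped = unwrap.unwrap_phase_goldstein(phase_cell)
    unwrapped = unwrap.zero_phase_offset(unwrapped)

    thickness = morphometry.thickness_from_phase(
        unwrapped, config.simulation, reflection_factor=config.reflection_factor
    )
    provisional = morphometry.segment_cell(
        thickness, threshold_frac=config.segmentation_threshold_frac
    )
    background = ~ndimage.binary_dilation(provisional, iterations=3)
    if background.mean() < 0.05:
        background = np.ones_like(background)
    thickness = morphometry.level_background(thickness, background)
    mask = morphometry.segment_cell(
        thickness, threshold_frac=config.segmentation_threshold_frac
    )
    features = morphometry.cell_features(thickness, mask) if mask.any() else None
    log["background_fraction"] = float(background.mean())
    return {
        "field": field,
        "phase_wrapped": phase_cell,
        "phase_unwrapped": unwrapped,
        "thickness": thickness,
        "mask": mask,
        "features": features,
        "log": log,
    }


def _save_png_preview(values: np.ndarray, path: Path) -> None:
    lo, hi = float(values.min()), float(values.max())
    scale = 65535.0 / (hi - lo) if hi > lo else 0.0
    img = ((values - lo) * scale).astype(np.uint16)
    Image.fromarray(img).save(path)
    with open(path.with_suffix(".scale.json"), "w", encoding="utf-8") as fh:
        json.dump({"min": lo, "max": hi, "levels": 65536}, fh)


def run_reconstruct(
    object_path: str | Path,
    reference_path: Optional[str | Path],
    config: PipelineConfig,
    out_dir: Optional[str | Path] = None,
) -> dict:
    """Reconstruct one hologram file and write the output bundle."""
    object_path = Path(object_path)
    out_dir = Path(out_dir) if out_dir is not None else Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    holo = read_hologram_bmp(object_path, pixel_pitch_um=sim.pixel_pitch_um)
    ref = (
        read_hologram_bmp(reference_path, pixel_pitch_um=sim.pixel_pitch_um)
        if reference_path is not None
        else None
    )
    result = reconstruct_hologram(holo, ref, config)

    stem = object_path.stem
    np.savetxt(out_dir / f"{stem}_phase_wrapped.txt", result["phase_wrapped"].values, fmt="%.9e")
    np.savetxt(out_dir / f"{stem}_phase_unwrapped.txt", result["phase_unwrapped"].values, fmt="%.9e")
    np.savetxt(out_dir / f"{stem}_thickness_um.txt", result["thickness"].values, fmt="%.9e")
    _save_png_preview(
        reconstruct.intensity_map(result["field"]), out_dir / f"{stem}_intensity.png"
    )
    _save_png_preview(result["thickness"].values, out_dir / f"{stem}_thickness.png")

    features_csv = out_dir / f"{stem}_features.csv"
    with open(features_csv, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=FEATURE_COLUMNS)
        writer.writeheader()
        if result["features"] is not None:
            row = {"path": str(object_path), "label": holo.source_label}
            row.update(result["features"].as_dict())
            writer.writerow(row)

    runlog = dict(result["log"])
    runlog["config"] = config.to_dict()
    runlog["object_path"] = str(object_path)
    runlog["reference_path"] = str(reference_path) if reference_path else None
    with open(out_dir / f"{stem}_runlog.json", "w", encoding="utf-8") as fh:
        json.dump(runlog, fh, indent=2, sort_keys=True)
    return result


def _auto_reference(holo: Hologram, config: PipelineConfig) -> Hologram:
    """Cell-free-tile stand-in reference for unpaired (real) holograms.

    Picks the lowest-intensity-variance tile of an 8x8 partition and tiles
    it periodically to the full frame. A heuristic emulation of cropping a
    cell-free region of the recording as the reference hologram.
    """
    px = holo.pixels.astype(float)
    ny, nx = px.shape
    ti, tj = max(ny // 8, 8), max(nx // 8, 8)
    best, best_var = (0, 0), np.inf
    for i in range(0, ny - ti + 1, ti):
        for j in range(0, nx - tj + 1, tj):
            var = px[i : i + ti, j : j + tj].var()
            if var < best_var:
                best, best_var = (i, j), var
    i, j = best
    tile = holo.pixels[i : i + ti, j : j + tj]
    reps = (int(np.ceil(ny / ti)), int(np.ceil(nx / tj)))
    full = np.tile(tile, reps)[:ny, :nx]
    return Hologram(pixels=full, pixel_pitch_um=holo.pixel_pitch_um, source_label="unknown")


def run_batch(
    root: str | Path,
    config: PipelineConfig,
    out_dir: Optional[str | Path] = None,
) -> Path:
    """Reconstruct every hologram in a dataset tree; aggregate one CSV.

    References are auto-paired by the ``<stem>_ref.bmp`` convention
    (synthetic data); otherwise a cell-free tile of the hologram itself is
    used. Per-file failures are logged and skipped.
    """
    root = Path(root)
    out_dir = Path(out_dir) if out_dir is not None else Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = scan_dataset(root)
    if len(manifest) == 0:
        raise RuntimeError(f"no holograms found under {root}")
    rows = []
    n_failed = 0
    for path, label in manifest.entries:
        try:
            holo = read_hologram_bmp(path, pixel_pitch_um=config.simulation.pixel_pitch_um)
            ref_path = path.with_name(path.stem + "_ref.bmp")
            if ref_path.exists():
                ref = read_hologram_bmp(ref_path, pixel_pitch_um=config.simulation.pixel_pitch_um)
            else:
                ref = _auto_reference(holo, config)
            result = reconstruct_hologram(holo, ref, config)
            if result["features"] is None:
                raise RuntimeError("segmentation found no cell")
            row = {"path": str(path), "label": label}
            row.update(result["features"].as_dict())
            rows.append(row)
        except Exception as exc:  # per-file failures must not kill the batch
            n_failed += 1
            logger.error("failed to process %s: %s", path, exc)
    if not rows:
        raise RuntimeError("no holograms could be processed")
    csv_path = out_dir / "features.csv"
    with open(csv_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=FEATURE_COLUMNS)
        writer.writeheader()
        writer.writerows(rows)
    logger.info("batch: %d processed, %d failed", len(rows), n_failed)
    return csv_path


def run_simulate(
    n_normal: int,
    n_thal: int,
    config: PipelineConfig,
    root: str | Path,
    rng_seed: Optional[int] = None,
):
    """Generate a synthetic dataset tree (thin wrapper over the generator)."""
    return generate_dataset(n_normal, n_thal, config.simulation, root, rng_seed=rng_seed)
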