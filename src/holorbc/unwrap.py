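"""Wrapped-phase extraction, reference subtraction, and Goldstein unwrapping.

The phase of the reconstructed complex field is known only modulo 2*pi
(two-argument arctangent of imaginary over real part, range (-pi, pi]).
System aberrations are cancelled by subtracting the phase of a paired
cell-free reference hologram *before* unwrapping (wrapped difference).
Unwrapping uses Goldstein's branch-cut algorithm: +-1 residues on
elementary 2x2 loops are paired by an expanding-box search (or discharged
to the image border), cuts bar the integration paths, and a flood fill
integrates wrapped neighbor differences without crossing a cut.

Wrap convention everywhere: ``wrap(x)`` maps into (-pi, pi], half-open at
-pi.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "PhaseMap",
    "ResidueMap",
    "BranchCutSet",
    "wrap",
    "wrapped_phase",
    "subtract_reference_phase",
    "compute_residues",
    "place_branch_cuts",
    "goldstein_unwrap",
    "unwrap_phase_goldstein",
    "zero_phase_offset",
]

logger = logging.getLogger(__name__)

_TWO_PI = 2.0 * np.pi


def wrap(x):
    """Wrap angles into (-pi, pi], half-open at -pi."""
    return -((-np.asarray(x, dtype=float) + np.pi) % _TWO_PI - np.pi)


def _wrapdiff(d):
    # increment form used during integration: d - 2*pi*round(d / 2*pi)
    return d - _TWO_PI * np.round(d / _TWO_PI)


@dataclass
class PhaseMap:
    """Real phase grid in radians, flagged wrapped or unwrapped."""

    values: np.ndarray
    wrap_state: str = "wrapped"
    sampling_um_per_px: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("phase values must be 2D")
        if self.wrap_state not in ("wrapped", "unwrapped"):
            raise ValueError("wrap_state must be 'wrapped' or 'unwrapped'")
        if self.wrap_state == "wrapped":
            v = self.values
            if v.size and (v.min() <= -np.pi or v.max() > np.pi):
                raise ValueError("wrapped phase must lie in (-pi, pi]")


@dataclass
class ResidueMap:
    """Integer winding charge of each elementary 2x2 pixel loop.

    Entry (i, j) is the residue of the loop whose top-left pixel is (i, j);
    the grid is one smaller than the phase grid along each axis.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)

    @property
    def positions(self) -> np.ndarray:
        """(k, 2) array of (i, j) loop corners with nonzero charge."""
        return np.argwhere(self.values != 0)


@dataclass
class BranchCutSet:
    """Branch cuts discharging the residues.

    ``cuts`` lists segments in loop-corner coordinates, each joining two
    residues or a residue to the border; ``mask`` is the rasterized grid of
    barred pixels the unwrapping flood fill may not enter (8-connected
    chains, so a 4-connected integration path cannot slip through).
    """

    cuts: List[Tuple[Tuple[int, int], Tuple[int, int]]] = field(default_factory=list)
    mask: Optional[np.ndarray] = None


def wrapped_phase(field) -> PhaseMap:
    """Per-pixel phase of a complex field: atan2(Im E, Re E), in (-pi, pi].

    Pixels where the field is exactly zero get phase 0; their count is
    logged because the phase is undefined there.
    """
    values = np.asarray(field.values)
    n_zero = int(np.count_nonzero(values == 0))
    if n_zero:
        logger.info("wrapped_phase: %d zero-amplitude pixels mapped to phase 0", n_zero)
    phase = np.arctan2(values.imag, values.real)
    phase[phase <= -np.pi] = np.pi  # enforce the half-open convention
    return PhaseMap(
        values=phase,
        wrap_state="wrapped",
        sampling_um_per_px=getattr(field, "sampling_um_per_px", 1.0),
    )


def subtract_reference_phase(object_phase: PhaseMap, reference_phase: PhaseMap) -> PhaseMap:
    """Wrapped difference wrap(phi_obj - phi_ref).

    With a cell-free reference exposure sharing the object hologram's
    optical train, this cancels the aberration phase (and any sub-bin
    residual carrier) and leaves the cell's phase alone.
    """
    if object_phase.wrap_state != "wrapped" or reference_phase.wrap_state != "wrapped":
        raise ValueError("both phases must be wrapped")
    if object_phase.values.shape != reference_phase.values.shape:
        raise ValueError(
            f"shape mismatch: {object_phase.values.shape} vs {reference_phase.values.shape}"
        )
    return PhaseMap(
        values=wrap(object_phase.values - reference_phase.values),
        wrap_state="wrapped",
        sampling_um_per_px=object_phase.sampling_um_per_px,
    )


def compute_residues(phase: PhaseMap) -> ResidueMap:
    """Residues: (1/2pi) sum of wrapped phase differences around each 2x2 loop."""
    if phase.wrap_state != "wrapped":
        raise ValueError("residues are defined on wrapped phase")
    p = phase.values
    d_right = wrap(p[:, 1:] - p[:, :-1])  # (i, j) -> (i, j+1)
    d_down = wrap(p[1:, :] - p[:-1, :])  # (i, j) -> (i+1, j)
    # clockwise loop from top-left corner (i, j):
    loop = d_right[:-1, :] + d_down[:, 1:] - d_right[1:, :] - d_down[:, :-1]
    return ResidueMap(values=np.rint(loop / _TWO_PI))


def _raster_line(mask: np.ndarray, p0: Tuple[int, int], p1: Tuple[int, int]) -> None:
    """Mark an 8-connected chain of pixels from p0 to p1 on the mask."""
    (i0, j0), (i1, j1) = p0, p1
    n = max(abs(i1 - i0), abs(j1 - j0)) + 1
    ii = np.rint(np.linspace(i0, i1, n)).astype(int)
    jj = np.rint(np.linspace(j0, j1, n)).astype(int)
    mask[ii, jj] = True


def _border_exit(pos: Tuple[int, int], shape: Tuple[int, int]) -> Tuple[int, int]:
    """Nearest point on the array border, along one axis."""
    i, j = pos
    ny, nx = shape
    choices = [
        ((0, j), i),
        ((ny - 1, j), ny - 1 - i),
        ((i, 0), j),
        ((i, nx - 1), nx - 1 - j),
    ]
    choices.sort(key=lambda c: (c[1], c[0]))
    return choices[0][0]


def place_branch_cuts(residues: ResidueMap, max_search_radius: Optional[int] = None) -> BranchCutSet:
    """Goldstein branch-cut placement by expanding-box dipole search.

    Residues are visited in lexicographic order. Each unbalanced residue
    starts a group; a box search of doubling radius looks for opposite-sign
    partners (joined by a cut and absorbed into the group) until the group's
    net charge is zero or the border is closer than any partner, in which
    case the group is discharged to the border. Every nonzero residue ends
    up an endpoint of at least one cut. The border acts as an
    infinite-capacity sink, so placement always terminates.
    """
    charges = residues.values
    shape = charges.shape
    phase_shape = (shape[0] + 1, shape[1] + 1)
    mask = np.zeros(phase_shape, dtype=bool)
    cuts: List[Tuple[Tuple[int, int], Tuple[int, int]]] = []
    positions = [tuple(p) for p in np.argwhere(charges != 0)]
    if not positions:
        return BranchCutSet(cuts=[], mask=mask)
    if max_search_radius is None:
        max_search_radius = max(shape)
    balanced = {}
    for pos in positions:
        balanced[pos] = False

    def border_distance(pos):
        i, j = pos
        return min(i, j, shape[0] - 1 - i, shape[1] - 1 - j) + 1

    for start in positions:
        if balanced[start]:
            continue
        group = [start]
        balanced[start] = True
        net = int(charges[start])
        radius = 1
        grounded = False
        while net != 0 and not grounded and radius <= max_search_radius:
            for member in list(group):
                if border_distance(member) <= radius:
                    cuts.append((member, _border_exit(member, shape)))
                    _raster_line(mask, member, _border_exit(member, shape))
                    grounded = True
                    net = 0
                    break
                i, j = member
                i0, i1 = max(0, i - radius), min(shape[0], i + radius + 1)
                j0, j1 = max(0, j - radius), min(shape[1], j + radius + 1)
                box = np.argwhere(charges[i0:i1, j0:j1] != 0)
                for bi, bj in box:
                    cand = (int(bi) + i0, int(bj) + j0)
                    if balanced[cand]:
                        continue
                    cuts.append((member, cand))
                    _raster_line(mask, member, cand)
                    group.append(cand)
                    balanced[cand] = True
                    net += int(charges[cand])
                    if net == 0:
                        break
                if net == 0:
                    break
            radius *= 2
        if net != 0:
            # exhausted the search radius: ground the group at the border
            member = min(group, key=border_distance)
            exit_pt = _border_exit(member, shape)
            cuts.append((member, exit_pt))
            _raster_line(mask, member, exit_pt)
    return BranchCutSet(cuts=cuts, mask=mask)


def _itoh_unwrap_no_cuts(p: np.ndarray) -> np.ndarray:
    """Vectorized unwrap for residue-free maps: first column, then each row."""
    out = np.empty_like(p)
    col0 = np.concatenate(([p[0, 0]], p[0, 0] + np.cumsum(_wrapdiff(np.diff(p[:, 0])))))
    row_steps = _wrapdiff(np.diff(p, axis=1))
    out[:, 0] = col0
    out[:, 1:] = col0[:, None] + np.cumsum(row_steps, axis=1)
    return out


def _region_unwrap(p: np.ndarray, region: np.ndarray, seed: Tuple[int, int]) -> np.ndarray:
    """Internally coherent unwrap of one connected pixel region (BFS)."""
    ny, nx = p.shape
    vals = np.full_like(p, np.nan)
    si, sj = seed
    vals[si, sj] = p[si, sj]
    todo = deque([(si, sj)])
    pending = region.copy()
    pending[si, sj] = False
    while todo:
        i, j = todo.popleft()
        base = vals[i, j]
        pij = p[i, j]
        for ni, nj in ((i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)):
            if 0 <= ni < ny and 0 <= nj < nx and pending[ni, nj]:
                d = p[ni, nj] - pij
                vals[ni, nj] = base + (d - _TWO_PI * round(d / _TWO_PI))
                pending[ni, nj] = False
                todo.append((ni, nj))
    return vals


def _fill_isolated(unwrapped: np.ndarray, p: np.ndarray, cut_mask: np.ndarray) -> None:
    """Fill cut pixels and cut-isolated regions, in place.

    Each unfilled connected region is unwrapped internally, then shifted by
    the 2*pi multiple that the majority of its boundary contacts with the
    already-filled area vote for — a single noisy crossing cannot offset a
    whole region. Regions with no filled neighbor (fully enclosed by other
    unfilled area) wait for a later pass; a region disconnected from
    everything is pinned to its own wrapped values.
    """
    ny, nx = p.shape
    four = ndimage.generate_binary_structure(2, 1)
    while np.isnan(unwrapped).any():
        remaining = np.isnan(unwrapped)
        labels, nlab = ndimage.label(remaining, structure=four)
        progressed = False
        for lab in range(1, nlab + 1):
            region = labels == lab
            seed = tuple(np.argwhere(region)[0])
            vals = _region_unwrap(p, region, seed)
            deltas = []
            for i, j in np.argwhere(region & ndimage.binary_dilation(~remaining, four)):
                for ni, nj in ((i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)):
                    if 0 <= ni < ny and 0 <= nj < nx and not remaining[ni, nj]:
                        d = p[i, j] - p[ni, nj]
                        step = d - _TWO_PI * round(d / _TWO_PI)
                        deltas.append(unwrapped[ni, nj] + step - vals[i, j])
            if deltas:
                offset = _TWO_PI * np.round(np.median(deltas) / _TWO_PI)
                unwrapped[region] = vals[region] + offset
                progressed = True
        if not progressed:
            region = labels == 1
            unwrapped[region] = _region_unwrap(p, region, tuple(np.argwhere(region)[0]))[region]


def goldstein_unwrap(
    phase: PhaseMap,
    cuts: Optional[BranchCutSet] = None,
    seed_pixel: Optional[Tuple[int, int]] = None,
) -> PhaseMap:
    """Flood-fill integration of wrapped differences, never crossing a cut.

    The output is defined up to a global additive 2*pi integer (and shares
    the seed pixel's value with the input); rewrapping it reproduces the
    wrapped input exactly at every pixel, because each unwrapped value is
    snapped onto ``input + 2*pi*k`` with integer ``k``. Pixels isolated by
    cuts (including cut pixels themselves) are filled last from their
    nearest unwrapped neighbor.
    """
    if phase.wrap_state != "wrapped":
        raise ValueError("goldstein_unwrap expects wrapped input")
    p = phase.values
    ny, nx = p.shape
    if cuts is None:
        cuts = place_branch_cuts(compute_residues(phase))
    cut_mask = cuts.mask if cuts.mask is not None else np.zeros_like(p, dtype=bool)

    if not cut_mask.any():
        unwrapped = _itoh_unwrap_no_cuts(p)
    else:
        unwrapped = np.full_like(p, np.nan)
        visited = cut_mask.copy()
        if seed_pixel is not None and cut_mask[seed_pixel]:
            seed_pixel = None  # reseed automatically
        if seed_pixel is None:
            free = np.argwhere(~cut_mask)
            if free.size == 0:
                raise ValueError("all pixels barred by cuts; cannot unwrap")
            seed_pixel = tuple(free[0])
        si, sj = seed_pixel
        unwrapped[si, sj] = p[si, sj]
        visited[si, sj] = True
        queue = deque([(si, sj)])
        while queue:
            i, j = queue.popleft()
            base = unwrapped[i, j]
            pij = p[i, j]
            for ni, nj in ((i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)):
                if 0 <= ni < ny and 0 <= nj < nx and not visited[ni, nj]:
                    d = p[ni, nj] - pij
                    unwrapped[ni, nj] = base + (d - _TWO_PI * round(d / _TWO_PI))
                    visited[ni, nj] = True
                    queue.append((ni, nj))
        _fill_isolated(unwrapped, p, cut_mask)

    # snap onto input + 2*pi*integer so rewrapping is exact
    k = np.rint((unwrapped - p) / _TWO_PI)
    return PhaseMap(
        values=p + _TWO_PI * k,
        wrap_state="unwrapped",
        sampling_um_per_px=phase.sampling_um_per_px,
    )


def unwrap_phase_goldstein(phase: PhaseMap) -> PhaseMap:
    """Convenience: residues -> branch cuts -> unwrap in one call."""
    residues = compute_residues(phase)
    cuts = place_branch_cuts(residues)
    return goldstein_unwrap(phase, cuts)


def zero_phase_offset(
    phase: PhaseMap, background_mask: Optional[np.ndarray] = None, tile: int = 8
) -> PhaseMap:
    """Fix the global phase offset: background median -> 0.

    If no background mask is given, the cell-free region is estimated as the
    lowest-variance tile of a ``tile x tile`` partition of the map.
    """
    v = phase.values
    if background_mask is None:
        ny, nx = v.shape
        ti, tj = max(ny // tile, 1), max(nx // tile, 1)
        best, best_var = None, np.inf
        for i in range(0, ny - ti + 1, ti):
            for j in range(0, nx - tj + 1, tj):
                var = v[i : i + ti, j : j + tj].var()
                if var < best_var:
                    best, best_var = (i, j), var
        background_mask = np.zeros_like(v, dtype=bool)
        i, j = best
        background_mask[i : i + ti, j : j + tj] = True
    offset = np.median(v[background_mask])
    out = v - offset
    if phase.wrap_state == "wrapped":
        out = wrap(out)
    return PhaseMap(
        values=out,
        wrap_state=phase.wrap_state,
        sampling_um_per_px=phase.sampling_um_per_px,
    )
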