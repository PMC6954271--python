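"""Serpentine tile ordering, translation-only stitching, panorama assembly.

Frames are collected on a boustrophedon (serpentine) stage path so that
consecutive frames are always grid-adjacent.  Tiles of one panel are
stitched by pure translation: nominal stage offsets, optionally refined
by phase correlation over the overlap strips.  Panels are then
concatenated in rotation order — starting at the posterior center — into
the rolled-out circumference panorama.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from skimage.registration import phase_cross_correlation

__all__ = [
    "PanelImage",
    "RolledOutPanorama",
    "serpentine_coords",
    "refine_offsets",
    "stitch_panel",
    "assemble_rollout",
    "default_anatomical_labels",
]

GridPos = tuple[int, int]
Offset = tuple[float, float]  # (dx, dy) in px

#: Compass anchors on the unrolled circumference (fraction of a turn from
#: the posterior-center start azimuth).
_COMPASS = [(0.0, "posterior"), (0.25, "left"), (0.5, "anterior"),
            (0.75, "right"), (1.0, "posterior")]


@dataclass
class PanelImage:
    """One stitched per-rotation strip."""

    image: np.ndarray
    panel_index: int = 0
    nominal_width_mm: float | None = None
    length_mm: float | None = None
    frame_offsets: dict[GridPos, Offset] = field(default_factory=dict)


@dataclass
class RolledOutPanorama:
    """Concatenated circumference image with panel bookkeeping."""

    image: np.ndarray
    panel_boundaries: list[int]
    anatomical_labels: list[str]

    def __post_init__(self) -> None:
        if any(b >= nb for b, nb in zip(self.panel_boundaries,
                                        self.panel_boundaries[1:])):
            raise ValueError("panel boundaries must be strictly increasing")

    @property
    def total_pixels(self) -> int:
        return int(self.image.size)


def serpentine_coords(nx: int, ny: int) -> list[GridPos]:
    """Boustrophedon visit order of an nx × ny grid.

    Rows are scanned in order; the x direction alternates per row, so
    every consecutive pair of positions differs by exactly one grid step.
    """
    if nx < 1 or ny < 1:
        raise ValueError("grid dimensions must be >= 1")
    order: list[GridPos] = []
    for iy in range(ny):
        xs = range(nx) if iy % 2 == 0 else range(nx - 1, -1, -1)
        order.extend((ix, iy) for ix in xs)
    return order


def _overlap_regions(
    ref: np.ndarray, mov: np.ndarray, rel: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray] | None:
    """Nominal overlap strips of a tile pair given their relative offset."""
    dx, dy = rel
    h, w = ref.shape
    x0, x1 = max(dx, 0), min(w, mov.shape[1] + dx)
    y0, y1 = max(dy, 0), min(h, mov.shape[0] + dy)
    if x1 - x0 < 1 or y1 - y0 < 1:
        return None
    return ref[y0:y1, x0:x1], mov[y0 - dy: y1 - dy, x0 - dx: x1 - dx]


def refine_offsets(
    tiles: Mapping[GridPos, np.ndarray],
    nominal_offsets: Mapping[GridPos, Offset],
    overlap_fraction: float,
    min_overlap_px: int = 8,
) -> dict[GridPos, Offset]:
    """Refine tile placements by phase correlation on overlap strips.

    Tiles are chained in serpentine order; each tile is registered against
    its already-placed left (or top) neighbour.  Only translations are
    estimated.  Degenerate overlaps — narrower than ``min_overlap_px`` or
    featureless — keep their nominal offset with a warning.
    """
    if overlap_fraction <= 0:
        return {k: tuple(v) for k, v in nominal_offsets.items()}
    nx = max(ix for ix, _ in tiles) + 1
    ny = max(iy for _, iy in tiles) + 1
    refined: dict[GridPos, Offset] = {}
    for ix, iy in serpentine_coords(nx, ny):
        pos = (ix, iy)
        if not refined:
            refined[pos] = tuple(nominal_offsets[pos])
            continue
        # prefer an already-refined grid neighbour
        neighbours = [(ix - 1, iy), (ix + 1, iy), (ix, iy - 1)]
        anchor = next((nb for nb in neighbours if nb in refined), None)
        if anchor is None:
            refined[pos] = tuple(nominal_offsets[pos])
            continue
        rel = (
            int(round(nominal_offsets[pos][0] - nominal_offsets[anchor][0])),
            int(round(nominal_offsets[pos][1] - nominal_offsets[anchor][1])),
        )
        regions = _overlap_regions(tiles[anchor], tiles[pos], rel)
        correction = (0.0, 0.0)
        if regions is None or min(regions[0].shape) < min_overlap_px:
            warnings.warn(f"tile {pos}: overlap too small, keeping nominal offset")
        elif regions[0].std() < 1e-9 or regions[1].std() < 1e-9:
            warnings.warn(f"tile {pos}: featureless overlap, keeping nominal offset")
        else:
            shift, _, _ = phase_cross_correlation(
                regions[0], regions[1], normalization=None
            )
            correction = (float(shift[1]), float(shift[0]))  # (dx, dy)
        refined[pos] = (
            refined[anchor][0] + rel[0] + correction[0],
            refined[anchor][1] + rel[1] + correction[1],
        )
    return refined


def _feather_weight(shape: tuple[int, int]) -> np.ndarray:
    """Linear ramp weight: distance to the nearest tile edge, plus one."""
    h, w = shape
    wy = np.minimum(np.arange(h), np.arange(h)[::-1]) + 1.0
    wx = np.minimum(np.arange(w), np.arange(w)[::-1]) + 1.0
    return np.minimum.outer(wy, wx)


def stitch_panel(
    tiles: Mapping[GridPos, np.ndarray],
    offsets: Mapping[GridPos, Offset],
    blend: Literal["feather", "overwrite"] = "feather",
    panel_index: int = 0,
) -> PanelImage:
    """Place tiles on a common canvas at the given (translation-only) offsets.

    The canvas is the bounding box of all placed tiles.  ``feather``
    averages overlaps with a linear edge ramp; ``overwrite`` keeps the
    last tile placed (serpentine order), so every output pixel equals some
    input pixel exactly.
    """
    if not tiles:
        raise ValueError("no tiles to stitch")
    nx = max(ix for ix, _ in tiles) + 1
    ny = max(iy for _, iy in tiles) + 1
    order = [p for p in serpentine_coords(nx, ny) if p in tiles]
    missing = [p for p in serpentine_coords(nx, ny) if p not in tiles]
    if missing:
        raise ValueError(f"missing tiles at grid positions {missing}")
    for p in order:
        if p not in offsets:
            raise ValueError(f"missing offset for tile {p}")

    ox = {p: int(round(offsets[p][0])) for p in order}
    oy = {p: int(round(offsets[p][1])) for p in order}
    x0 = min(ox.values())
    y0 = min(oy.values())
    x1 = max(ox[p] + tiles[p].shape[1] for p in order)
    y1 = max(oy[p] + tiles[p].shape[0] for p in order)
    canvas = np.zeros((y1 - y0, x1 - x0), dtype=float)

    if blend == "overwrite":
        for p in order:
            t = tiles[p]
            canvas[oy[p] - y0: oy[p] - y0 + t.shape[0],
                   ox[p] - x0: ox[p] - x0 + t.shape[1]] = t
    elif blend == "feather":
        weight = np.zeros_like(canvas)
        for p in order:
            t = np.asarray(tiles[p], dtype=float)
            wgt = _feather_weight(t.shape)
            sl = np.s_[oy[p] - y0: oy[p] - y0 + t.shape[0],
                       ox[p] - x0: ox[p] - x0 + t.shape[1]]
            canvas[sl] += t * wgt
            weight[sl] += wgt
        np.divide(canvas, weight, out=canvas, where=weight > 0)
    else:
        raise ValueError(f"unknown blend mode {blend!r}")

    return PanelImage(
        image=canvas,
        panel_index=panel_index,
        frame_offsets={p: (float(ox[p] - x0), float(oy[p] - y0)) for p in order},
    )


def stitch_acquisition(
    acquisitions: Sequence,
    overlap_fraction: float,
    blend: Literal["feather", "overwrite"] = "feather",
    refine: bool = True,
) -> tuple[list[PanelImage], RolledOutPanorama]:
    """Reconstruct, stitch and assemble a simulated (or loaded) acquisition.

    Each element must expose ``tiles`` (grid position → frame triplet),
    ``tile_positions_px`` and ``panel_index`` — the interface of the
    phantom's per-panel acquisition records.  Returns the stitched panels
    and the rolled-out panorama.
    """
    from circumscan.sim_recon import square_law_reconstruct

    panels: list[PanelImage] = []
    for pa in acquisitions:
        tiles = {k: square_law_reconstruct(t).image for k, t in pa.tiles.items()}
        nominal = {k: (float(v[0]), float(v[1]))
                   for k, v in pa.tile_positions_px.items()}
        offsets = (refine_offsets(tiles, nominal, overlap_fraction)
                   if refine else nominal)
        panels.append(stitch_panel(tiles, offsets, blend, pa.panel_index))
    return panels, assemble_rollout(panels)


def default_anatomical_labels(n_panels: int) -> list[str]:
    """Nearest compass label per panel, starting at the posterior center.

    Panel p sits at azimuth ``p/n`` of a turn from the posterior start;
    the sequence for the default 10-rotation protocol runs posterior →
    left → anterior → right → back to posterior.
    """
    labels = []
    for p in range(n_panels):
        frac = p / n_panels
        labels.append(min(_COMPASS, key=lambda a: abs(a[0] - frac))[1])
    return labels


def assemble_rollout(
    panels: Sequence[PanelImage],
    organ_labels: Sequence[str] | None = None,
    pad_limit_fraction: float = 0.1,
) -> RolledOutPanorama:
    """Concatenate panel strips into the rolled-out circumference panorama.

    Panels are joined left-to-right in rotation order.  Height mismatches
    up to ``pad_limit_fraction`` of the tallest panel are zero-padded at
    the bottom; larger mismatches raise.
    """
    if not panels:
        raise ValueError("no panels to assemble")
    heights = [p.image.shape[0] for p in panels]
    hmax = max(heights)
    if min(heights) < hmax * (1.0 - pad_limit_fraction):
        raise ValueError(
            f"panel height mismatch beyond pad limit: {heights}"
        )
    padded = [
        np.pad(p.image, ((0, hmax - p.image.shape[0]), (0, 0)))
        for p in panels
    ]
    widths = [im.shape[1] for im in padded]
    boundaries = list(np.cumsum([0] + widths))
    labels = (
        list(organ_labels)
        if organ_labels is not None
        else default_anatomical_labels(len(panels))
    )
    if len(labels) != len(panels):
        raise ValueError("label count must equal panel count")
    return RolledOutPanorama(
        image=np.concatenate(padded, axis=1),
        panel_boundaries=boundaries,
        anatomical_labels=labels,
    )
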