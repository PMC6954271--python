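"""Fiducial detection, inter-panel alignment and slippage detection.

Panels are aligned using ink fiducials painted on the specimen through a
stencil: one central line along the circumference plus hash marks every
10 mm.  Ink is a fluorescence void, so markers are detected as *dark*
ridges.  Axial (vertical) slippage of the specimen on its mounting rod
shows up as a displaced central line; rotational slippage shows up as
duplicated content on adjacent panels, detected by sliding normalized
cross-correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from circumscan.mosaic import PanelImage

__all__ = [
    "MarkerSet",
    "AlignmentResult",
    "detect_fiducials",
    "measure_hash_spacing",
    "align_panels",
    "apply_alignment",
    "detect_duplicate_overlap",
]


@dataclass
class MarkerSet:
    """Fiducials found on one panel."""

    central_line_y_px: float | None
    hash_x_positions_px: np.ndarray
    confidence: float

    def __post_init__(self) -> None:
        self.hash_x_positions_px = np.asarray(self.hash_x_positions_px, dtype=float)
        if np.any(np.diff(self.hash_x_positions_px) <= 0):
            raise ValueError("hash positions must be strictly increasing")

    @property
    def n_hashes(self) -> int:
        return len(self.hash_x_positions_px)


@dataclass
class AlignmentResult:
    """Per-panel correction offsets and adjacent-pair duplicate flags."""

    axial_offsets_px: list[float]
    circumferential_shifts_px: list[float]
    duplicate_flags: list[dict] = field(default_factory=list)


def _runs_to_centers(cols: np.ndarray) -> list[float]:
    """Centers of consecutive-index runs in a sorted integer array."""
    if cols.size == 0:
        return []
    splits = np.where(np.diff(cols) > 1)[0] + 1
    return [float(run.mean()) for run in np.split(cols, splits)]


def _flanked_darkness(proj: np.ndarray, guard: int, flank: int) -> np.ndarray:
    """Score of being a dark dip *between* bright flanks along a profile.

    For each position the mean of a ``flank``-wide window on either side
    (offset by ``guard``) is computed; the score is the smaller flank mean
    minus the local value.  A dip inside an unlit region scores ~0 because
    its flanks are dark too, which makes the operator robust to panels
    whose out-of-contact surround reconstructs to zero.
    """
    n = proj.size
    smooth = ndimage.uniform_filter1d(proj, size=flank, mode="nearest")
    off = guard + flank // 2
    before = np.full(n, -np.inf)
    after = np.full(n, -np.inf)
    before[off:] = smooth[: n - off]
    after[: n - off] = smooth[off:]
    return np.minimum(before, after) - proj


def detect_fiducials(
    panel: PanelImage | np.ndarray,
    ink_polarity: Literal["dark", "bright"] = "dark",
    line_prominence: float = 0.15,
    guard_px: int = 4,
    flank_px: int = 9,
) -> MarkerSet:
    """Locate the central ink line and hash marks on a panel.

    The central line is the dominant dark ridge along the circumferential
    axis: the row whose mean intensity dips furthest below its flanking
    rows (ink is a fluorescence void between bright tissue).  The dip must
    reach ``line_prominence`` of the panel's dynamic range, otherwise an
    empty, zero-confidence MarkerSet is returned with a warning.  Hash
    marks are found the same way along the column projection of a band
    around the line, the line rows themselves excluded.
    """
    img = np.asarray(panel.image if isinstance(panel, PanelImage) else panel,
                     dtype=float)
    if img.size == 0:
        raise ValueError("empty panel")
    if ink_polarity == "bright":
        img = img.max() - img
    h, w = img.shape
    rng_ = max(float(img.max() - img.min()), 1e-12)

    row_proj = img.mean(axis=1)
    row_score = _flanked_darkness(row_proj, guard_px, flank_px)
    cy = int(np.argmax(row_score))
    depth = row_score[cy] / rng_
    if not np.isfinite(depth) or depth < line_prominence:
        warnings.warn("no fiducial line detected")
        return MarkerSet(None, np.empty(0), 0.0)
    confidence = float(min(2.0 * depth, 1.0))

    # exclude the line rows, then project a band around the line
    dip = row_score[cy]
    line_rows = np.where(
        (np.abs(np.arange(h) - cy) <= 2 * guard_px)
        & (row_proj < row_proj[cy] + 0.5 * dip)
    )[0]
    half_band = max(4 * (line_rows.max() - line_rows.min() + 1), 8)
    band = np.zeros(h, dtype=bool)
    band[max(cy - half_band, 0): cy + half_band + 1] = True
    band[line_rows] = False
    if not band.any():
        return MarkerSet(float(cy), np.empty(0), confidence)

    col_proj = img[band].mean(axis=0)
    col_score = _flanked_darkness(col_proj, guard_px, flank_px)
    thresh = line_prominence * rng_
    centers = _runs_to_centers(np.where(col_score > thresh)[0])
    # refine each run center to its local score maximum
    refined = []
    for c in centers:
        lo, hi = max(int(c) - guard_px, 0), min(int(c) + guard_px + 1, w)
        refined.append(lo + float(np.argmax(col_score[lo:hi])))
    return MarkerSet(float(cy), np.asarray(sorted(set(refined))), confidence)


def measure_hash_spacing(markers: MarkerSet, mm_per_px: float) -> float:
    """Mean spacing between adjacent hash marks, in mm."""
    if markers.n_hashes < 2:
        raise ValueError("need at least 2 hash marks to measure spacing")
    return float(np.mean(np.diff(markers.hash_x_positions_px))) * mm_per_px


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom < 1e-12:
        return 0.0
    return float(a @ b / denom)


def _masked_ncc(a: np.ndarray, b: np.ndarray, lit_thresh: float,
                min_pixels: int = 64) -> float:
    """NCC restricted to pixels lit in both regions.

    Panels share non-tissue structure — the unlit out-of-contact surround
    and any ink marks — that would correlate even between unrelated
    panels; only jointly lit (tissue) pixels are compared.
    """
    sel = (a > lit_thresh) & (b > lit_thresh)
    if sel.sum() < min_pixels:
        return 0.0
    return _ncc(a[sel], b[sel])


def detect_duplicate_overlap(
    panel_a: PanelImage | np.ndarray,
    panel_b: PanelImage | np.ndarray,
    repeat_threshold: float = 0.5,
    ncc_threshold: float = 0.6,
    min_overlap_fraction: float = 0.05,
) -> dict:
    """Estimate how much of two adjacent panels shows the same tissue.

    Slides one panel over the other along the circumferential axis (both
    directions, so the measure is symmetric), scoring each candidate
    overlap span by normalized cross-correlation.  The reported
    ``overlap_fraction`` is the best-scoring span as a fraction of the
    narrower panel; if no span correlates above ``ncc_threshold`` the
    overlap is reported as 0.  ``is_repeat`` flags panels sharing at least
    ``repeat_threshold`` of their width, the signature of rotational
    slippage re-imaging the previous aspect.
    """
    a = np.asarray(panel_a.image if isinstance(panel_a, PanelImage) else panel_a,
                   dtype=float)
    b = np.asarray(panel_b.image if isinstance(panel_b, PanelImage) else panel_b,
                   dtype=float)
    h = min(a.shape[0], b.shape[0])
    a, b = a[:h], b[:h]
    wa, wb = a.shape[1], b.shape[1]
    wmin = min(wa, wb)
    min_ov = max(int(round(min_overlap_fraction * wmin)), 4)
    lit = 0.05 * max(float(a.max()), float(b.max()), 1e-12)

    best_ncc, best_ov = 0.0, 0
    # positive s: b starts s px into a (b-left vs a-right); negative: reverse
    for s in range(-(wb - min_ov), wa - min_ov + 1):
        if s >= 0:
            ov = min(wa - s, wb)
            ra, rb = a[:, s: s + ov], b[:, :ov]
        else:
            ov = min(wb + s, wa)
            ra, rb = a[:, :ov], b[:, -s: -s + ov]
        score = _masked_ncc(ra, rb, lit)
        if score > best_ncc:
            best_ncc, best_ov = score, ov
    if best_ncc < ncc_threshold:
        return {"overlap_fraction": 0.0, "is_repeat": False, "ncc": best_ncc}
    frac = best_ov / wmin
    return {
        "overlap_fraction": float(frac),
        "is_repeat": bool(frac >= repeat_threshold),
        "ncc": best_ncc,
    }


def align_panels(
    panels: Sequence[PanelImage | np.ndarray],
    marker_sets: Sequence[MarkerSet] | None = None,
    hash_spacing_mm: float = 10.0,
    mm_per_px: float | None = None,
) -> AlignmentResult:
    """Compute per-panel correction offsets from fiducials.

    Axial offsets move each panel's central line onto the median line
    position across panels, making the lines collinear.  Circumferential
    shifts adjust each panel (relative to its left neighbour) so the hash
    spacing across the seam equals the stencil spacing; they require
    ``mm_per_px``, otherwise seam shifts are reported as 0.  Panels with
    no detected markers fall back to phase correlation of the seam edge
    strips against the previous panel; a warning is emitted.
    """
    imgs = [np.asarray(p.image if isinstance(p, PanelImage) else p, dtype=float)
            for p in panels]
    if marker_sets is None:
        marker_sets = [detect_fiducials(im) for im in imgs]
    if len(marker_sets) != len(imgs):
        raise ValueError("one MarkerSet required per panel")

    line_ys = [m.central_line_y_px for m in marker_sets]
    known = [y for y in line_ys if y is not None]
    ref_y = float(np.median(known)) if known else 0.0
    axial: list[float] = []
    for i, y in enumerate(line_ys):
        if y is not None:
            axial.append(ref_y - y)
        else:
            warnings.warn(f"panel {i}: no markers; edge-correlation fallback")
            if i == 0:
                axial.append(0.0)
            else:
                strip_w = min(16, imgs[i - 1].shape[1], imgs[i].shape[1])
                hh = min(imgs[i - 1].shape[0], imgs[i].shape[0])
                shift, _, _ = phase_cross_correlation(
                    imgs[i - 1][:hh, -strip_w:], imgs[i][:hh, :strip_w],
                    normalization=None,
                )
                axial.append(axial[i - 1] + float(shift[0]))

    circ: list[float] = [0.0]
    duplicates: list[dict] = []
    for i in range(1, len(imgs)):
        ma, mb = marker_sets[i - 1], marker_sets[i]
        shift = 0.0
        if mm_per_px is not None and ma.n_hashes and mb.n_hashes:
            seam_px = (imgs[i - 1].shape[1] - ma.hash_x_positions_px[-1]
                       + mb.hash_x_positions_px[0])
            spacing_px = hash_spacing_mm / mm_per_px
            # seam spacing modulo one stencil period
            shift = -((seam_px - spacing_px / 2) % spacing_px - spacing_px / 2)
        circ.append(float(shift))
        duplicates.append(detect_duplicate_overlap(imgs[i - 1], imgs[i]))
    return AlignmentResult(
        axial_offsets_px=axial,
        circumferential_shifts_px=circ,
        duplicate_flags=duplicates,
    )


def apply_alignment(
    panels: Sequence[PanelImage],
    result: AlignmentResult,
    repeat_policy: Literal["trim", "drop"] = "trim",
) -> list[PanelImage]:
    """Apply correction offsets; trim or drop panels flagged as repeats.

    Axial offsets are applied as integer shifts with zero fill.  A panel
    whose content duplicates its left neighbour (``is_repeat``) is either
    trimmed by the duplicated span (default, keeping any novel remainder)
    or dropped entirely.
    """
    out: list[PanelImage] = []
    for i, p in enumerate(panels):
        img = p.image
        dy = int(round(result.axial_offsets_px[i]))
        if dy:
            shifted = np.zeros_like(img)
            if dy > 0:
                shifted[dy:] = img[: img.shape[0] - dy]
            else:
                shifted[:dy] = img[-dy:]
            img = shifted
        flag = result.duplicate_flags[i - 1] if i >= 1 else None
        if flag and flag["is_repeat"]:
            if repeat_policy == "drop":
                continue
            dup_px = int(round(flag["overlap_fraction"] * img.shape[1]))
            img = img[:, dup_px:]
            if img.shape[1] == 0:
                continue
        out.append(PanelImage(image=img, panel_index=p.panel_index,
                              nominal_width_mm=p.nominal_width_mm,
                              length_mm=p.length_mm))
    return out
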