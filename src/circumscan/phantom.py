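"""Synthetic phantoms emulating circumferential SIM acquisition of an organ.

The phantom lives in *unrolled-cylinder coordinates*: a rectangle of
width ``pi*d`` (circumference, x axis, wrapping) by ``L`` (apex-to-base
length, y axis), the same frame in which the final "rolled-out" panorama
is displayed.  Panel 0 starts at the posterior-center azimuth.

Three stages are modelled:

1. :func:`generate_surface` — a ground-truth fluorescence map with
   tissue-like feature classes: bright curvilinear nerve tracts
   (~130 µm wide), dark circular adipose voids, and punctate nuclei
   (~10 µm), over a smooth stromal background.
2. :func:`apply_fiducials` — dark histological-ink marks: one central
   line along the circumference plus hash marks every 10 mm, as painted
   through a stencil band wrapped around the specimen.
3. :func:`simulate_acquisition` — the forward imaging model: per panel, a
   serpentine grid of phase-shifted sinusoidal frame triplets.  Pixels
   inside the compressed contact patch (clipped disc from the geometry
   model) receive modulated signal ``B + truth*(1 + m*sin(phi + 2*pi*i/3))``;
   pixels outside receive only unmodulated, defocus-blurred background,
   which square-law reconstruction rejects.  Optional slippage events
   shift a panel's source window rotationally and/or axially, emulating
   the specimen slipping on its mounting rod.

All randomness flows through a single seed; identical configurations
yield bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from circumscan.geometry import AcquisitionPlan, CompressibleOrgan
from circumscan.mosaic import serpentine_coords
from circumscan.sim_recon import FrameTriplet

__all__ = [
    "GroundTruthSurface",
    "FiducialSpec",
    "SlippageEvent",
    "OpticsConfig",
    "PanelAcquisition",
    "generate_surface",
    "apply_fiducials",
    "simulate_acquisition",
    "save_acquisition",
]


@dataclass
class GroundTruthSurface:
    """Ground-truth unrolled organ surface (fluorescence in [0, 1])."""

    image: np.ndarray
    mm_per_px: float
    diameter_mm: float
    length_mm: float
    feature_log: list[dict] = field(default_factory=list)

    @property
    def width_px(self) -> int:
        return self.image.shape[1]

    @property
    def height_px(self) -> int:
        return self.image.shape[0]


@dataclass(frozen=True)
class FiducialSpec:
    """Ink fiducial pattern: one central line plus evenly spaced hash marks."""

    central_line_mm: float | None = None  # axial position; None = mid-length
    hash_spacing_mm: float = 10.0
    hash_length_mm: float = 2.0
    line_width_mm: float = 0.2
    ink_intensity: float = 0.02

    def __post_init__(self) -> None:
        if self.hash_spacing_mm <= 0:
            raise ValueError("hash_spacing_mm must be > 0")


@dataclass(frozen=True)
class SlippageEvent:
    """Rotational and/or axial slip of the specimen on its rod at one panel."""

    panel_index: int
    rotational_deg: float = 0.0
    axial_mm: float = 0.0


@dataclass(frozen=True)
class OpticsConfig:
    """Forward-model optics: pattern, modulation, background and noise."""

    grid_period_px: float = 12.0
    modulation_depth: float = 0.9
    background_level: float = 0.05
    defocus_scale: float = 0.25
    defocus_sigma_px: float = 8.0
    photon_noise: float = 0.0  # photons per unit intensity; 0 disables noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_period_px < 4:
            raise ValueError(
                f"grid_period_px={self.grid_period_px} unresolvable (< 4 px)"
            )
        if not 0.0 < self.modulation_depth <= 1.0:
            raise ValueError("modulation_depth must be in (0, 1]")


@dataclass
class PanelAcquisition:
    """All simulated data for one rotation ("panel").

    ``tiles`` maps serpentine grid positions (ix, iy) to frame triplets;
    ``tile_positions_px`` gives each tile's top-left corner in panel
    pixel coordinates; ``truth`` and ``contact_mask`` are the ground-truth
    crop and the in-contact pixel mask for the whole panel.
    """

    panel_index: int
    tiles: dict[tuple[int, int], FrameTriplet]
    tile_positions_px: dict[tuple[int, int], tuple[int, int]]
    grid_shape: tuple[int, int]  # (nx, ny)
    truth: np.ndarray
    contact_mask: np.ndarray
    x_start_px: int  # panel's start column in the unrolled surface
    width_px: int
    fov_px: int
    step_px: int


DEFAULT_FEATURES: dict[str, dict] = {
    "nerve": {"density_per_mm2": 0.05, "width_mm": 0.13, "intensity": 0.95,
              "length_mm": 4.0},
    # adipose is lipid-rich and stains weakly: dim relative to stroma but
    # above the unlit background, as in real fluorescence images
    "adipose": {"density_per_mm2": 0.05, "radius_mm": 0.35, "intensity": 0.2},
    "nucleus": {"density_per_mm2": 20.0, "size_mm": 0.01, "intensity": 0.9},
}


def generate_surface(
    diameter_mm: float,
    length_mm: float,
    mm_per_px: float = 0.02,
    feature_params: dict[str, dict] | None = None,
    seed: int = 0,
) -> GroundTruthSurface:
    """Render a ground-truth unrolled surface with tissue-like features.

    Feature counts are Poisson draws at the requested densities over the
    surface area ``pi*d*L``; every placed feature is recorded in
    ``feature_log``.  Raises if the pixel scale is too coarse to render
    the smallest requested feature (less than half a pixel).
    """
    if diameter_mm <= 0 or length_mm <= 0 or mm_per_px <= 0:
        raise ValueError("diameter_mm, length_mm, mm_per_px must be > 0")
    params = {k: dict(v) for k, v in DEFAULT_FEATURES.items()}
    if feature_params:
        for k, v in feature_params.items():
            params.setdefault(k, {}).update(v)
    for name, p in params.items():
        if p.get("density_per_mm2", 0) <= 0:
            continue
        size = p.get("width_mm") or p.get("size_mm") or p.get("radius_mm")
        if size is not None and size < 0.5 * mm_per_px:
            raise ValueError(
                f"mm_per_px={mm_per_px} too coarse to render feature "
                f"{name!r} of size {size} mm"
            )

    rng = np.random.default_rng(seed)
    width_px = int(round(math.pi * diameter_mm / mm_per_px))
    height_px = int(round(length_mm / mm_per_px))
    area_mm2 = math.pi * diameter_mm * length_mm

    # smooth stromal background in [0.25, 0.45]
    base = rng.uniform(size=(height_px, width_px))
    base = ndimage.gaussian_filter(base, sigma=6.0, mode="wrap")
    lo, hi = base.min(), base.max()
    img = 0.25 + 0.20 * (base - lo) / max(hi - lo, 1e-12)

    log: list[dict] = []

    def px(mm: float) -> float:
        return mm / mm_per_px

    # nerve tracts: bright curvilinear random walks of ~width_mm
    p = params.get("nerve")
    if p and p["density_per_mm2"] > 0:
        n = rng.poisson(p["density_per_mm2"] * area_mm2)
        half_w = max(int(round(px(p["width_mm"]) / 2)), 1)
        n_steps = max(int(px(p["length_mm"])), 2)
        for _ in range(n):
            y, x = rng.uniform(0, height_px), rng.uniform(0, width_px)
            theta = rng.uniform(0, 2 * math.pi)
            ys, xs = [y], [x]
            for _ in range(n_steps):
                theta += rng.normal(0, 0.08)
                y = min(max(y + math.sin(theta), 0), height_px - 1)
                x = (x + math.cos(theta)) % width_px
                ys.append(y)
                xs.append(x)
            yi = np.clip(np.rint(ys).astype(int), 0, height_px - 1)
            xi = np.rint(xs).astype(int) % width_px
            for dy in range(-half_w, half_w + 1):
                yy = np.clip(yi + dy, 0, height_px - 1)
                img[yy, xi] = p["intensity"]
            log.append({"type": "nerve", "y_px": int(yi[0]), "x_px": int(xi[0]),
                        "length_mm": p["length_mm"], "width_mm": p["width_mm"]})

    # adipose voids: dark discs
    p = params.get("adipose")
    if p and p["density_per_mm2"] > 0:
        n = rng.poisson(p["density_per_mm2"] * area_mm2)
        yy, xx = np.mgrid[0:height_px, 0:width_px]
        for _ in range(n):
            cy, cx = rng.uniform(0, height_px), rng.uniform(0, width_px)
            rad = px(p["radius_mm"]) * rng.uniform(0.6, 1.4)
            dx = np.abs(xx - cx)
            dx = np.minimum(dx, width_px - dx)  # circumferential wrap
            mask = dx * dx + (yy - cy) ** 2 <= rad * rad
            img[mask] = p["intensity"]
            log.append({"type": "adipose", "y_px": int(cy), "x_px": int(cx),
                        "radius_mm": rad * mm_per_px})

    # nuclei: punctate bright single pixels (sub-resolution at coarse scales)
    p = params.get("nucleus")
    if p and p["density_per_mm2"] > 0:
        n = rng.poisson(p["density_per_mm2"] * area_mm2)
        ys = rng.integers(0, height_px, size=n)
        xs = rng.integers(0, width_px, size=n)
        img[ys, xs] = p["intensity"]
        for y, x in zip(ys, xs):
            log.append({"type": "nucleus", "y_px": int(y), "x_px": int(x)})

    np.clip(img, 0.0, 1.0, out=img)
    return GroundTruthSurface(
        image=img,
        mm_per_px=mm_per_px,
        diameter_mm=diameter_mm,
        length_mm=length_mm,
        feature_log=log,
    )


def apply_fiducials(
    surface: GroundTruthSurface, spec: FiducialSpec = FiducialSpec()
) -> GroundTruthSurface:
    """Paint the ink fiducial pattern onto a copy of the surface.

    One dark central line runs along the full circumference at the given
    axial position; ``floor(pi*d / spacing)`` hash marks cross it at exact
    ``hash_spacing_mm`` intervals starting at x = 0 (posterior center).
    Ink pixels are strictly darker than any tissue background.
    """
    mpp = surface.mm_per_px
    if spec.hash_spacing_mm / mpp < 2:
        raise ValueError("hash spacing below 2 px at this resolution")
    img = surface.image.copy()
    h, w = img.shape
    cy_mm = (
        spec.central_line_mm
        if spec.central_line_mm is not None
        else surface.length_mm / 2.0
    )
    cy = int(round(cy_mm / mpp))
    line_hw = max(int(round(spec.line_width_mm / mpp / 2)), 1)
    img[max(cy - line_hw, 0): cy + line_hw + 1, :] = spec.ink_intensity

    circumference_mm = math.pi * surface.diameter_mm
    n_hashes = int(math.floor(circumference_mm / spec.hash_spacing_mm))
    hash_hl = max(int(round(spec.hash_length_mm / mpp / 2)), 1)
    log = list(surface.feature_log)
    hash_x = []
    for k in range(n_hashes):
        x = int(round(k * spec.hash_spacing_mm / mpp)) % w
        img[max(cy - hash_hl, 0): cy + hash_hl + 1,
            max(x - line_hw, 0): x + line_hw + 1] = spec.ink_intensity
        hash_x.append(x)
    log.append({
        "type": "fiducials",
        "central_line_y_px": cy,
        "hash_x_px": hash_x,
        "hash_count": n_hashes,
        "hash_spacing_mm": spec.hash_spacing_mm,
    })
    return GroundTruthSurface(
        image=img,
        mm_per_px=mpp,
        diameter_mm=surface.diameter_mm,
        length_mm=surface.length_mm,
        feature_log=log,
    )


def _panel_bounds(width_px: int, n_panels: int) -> list[tuple[int, int]]:
    """Integer panel column ranges partitioning the circumference exactly."""
    edges = [int(round(p * width_px / n_panels)) for p in range(n_panels + 1)]
    return [(edges[p], edges[p + 1]) for p in range(n_panels)]


def _tile_starts(extent: int, fov: int, step: int) -> list[int]:
    """Tile start positions covering [0, extent) with the last tile clamped."""
    if extent <= fov:
        return [0]
    starts = list(range(0, extent - fov, step))
    if starts[-1] != extent - fov:
        starts.append(extent - fov)
    return starts


def simulate_acquisition(
    surface: GroundTruthSurface,
    plan: AcquisitionPlan,
    organ: CompressibleOrgan,
    optics: OpticsConfig = OpticsConfig(),
    slippage: Sequence[SlippageEvent] = (),
) -> list[PanelAcquisition]:
    """Run the forward imaging model over all panels of the plan.

    For each panel the source window is a contiguous column range of the
    unrolled surface (wrapping circumferentially), optionally shifted by a
    slippage event.  The contact patch — the geometry module's clipped
    disc of radius ``a = r*sqrt(2c - c^2)`` and azimuthal half-width
    ``w = r*(1-c)*tan(pi/n)``, drawn in unrolled mm at the panel center —
    receives pattern-modulated signal; everything else receives
    defocus-blurred unmodulated background only.  The sinusoidal pattern
    phase is continuous across tiles of a panel.
    """
    mpp = surface.mm_per_px
    img = surface.image
    h, w_total = img.shape
    n = plan.n_panels
    slip_by_panel = {s.panel_index: s for s in slippage}
    for s in slippage:
        if not 0 <= s.panel_index < n:
            raise ValueError(f"slippage panel_index {s.panel_index} out of range")

    r, c = organ.radius_mm, organ.compressibility
    a_px = r * math.sqrt(2 * c - c * c) / mpp
    w_px = r * (1 - c) * math.tan(math.pi / n) / mpp

    blurred = ndimage.gaussian_filter(img, sigma=optics.defocus_sigma_px, mode="wrap")
    fov_px = max(int(round(plan.frame_fov_mm / mpp)), 1)
    step_px = max(int(round(fov_px * (1.0 - plan.overlap_fraction))), 1)

    rng = np.random.default_rng(optics.seed)
    m = optics.modulation_depth
    B = optics.background_level
    panels: list[PanelAcquisition] = []

    for p, (x0, x1) in enumerate(_panel_bounds(w_total, n)):
        wp = x1 - x0
        slip = slip_by_panel.get(p)
        src_x0 = x0
        dy_px = 0
        if slip is not None:
            src_x0 = x0 + int(round(slip.rotational_deg / 360.0 * w_total))
            dy_px = int(round(slip.axial_mm / mpp))
        cols = (np.arange(src_x0, src_x0 + wp)) % w_total
        truth = img[:, cols]
        defocus = blurred[:, cols]
        if dy_px:
            truth = ndimage.shift(truth, (dy_px, 0), order=0, cval=0.0)
            defocus = ndimage.shift(defocus, (dy_px, 0), order=0, cval=0.0)

        # contact mask in panel-local coordinates (mask does not slip:
        # it is fixed to the slide, not the specimen)
        yy, xx = np.mgrid[0:h, 0:wp]
        dxc = xx - (wp - 1) / 2.0
        dyc = yy - (h - 1) / 2.0
        mask = (dxc * dxc + dyc * dyc <= a_px * a_px) & (np.abs(dxc) <= w_px)

        # modulated in-contact signal vs unmodulated defocused background
        phase = 2.0 * math.pi * xx / optics.grid_period_px
        tiles: dict[tuple[int, int], FrameTriplet] = {}
        positions: dict[tuple[int, int], tuple[int, int]] = {}
        xs = _tile_starts(wp, fov_px, step_px)
        ys = _tile_starts(h, fov_px, step_px)
        frames = []
        for i in range(3):
            mod = 1.0 + m * np.sin(phase + 2.0 * math.pi * i / 3.0)
            fi = np.where(mask, B + truth * mod, B + optics.defocus_scale * defocus)
            frames.append(fi)
        for ix, iy in serpentine_coords(len(xs), len(ys)):
            tx, ty = xs[ix], ys[iy]
            sub = [f[ty: ty + fov_px, tx: tx + fov_px] for f in frames]
            if optics.photon_noise > 0:
                sub = [
                    rng.poisson(s * optics.photon_noise) / optics.photon_noise
                    for s in sub
                ]
            tiles[(ix, iy)] = FrameTriplet(
                sub[0], sub[1], sub[2], grid_period_px=optics.grid_period_px
            )
            positions[(ix, iy)] = (tx, ty)
        panels.append(
            PanelAcquisition(
                panel_index=p,
                tiles=tiles,
                tile_positions_px=positions,
                grid_shape=(len(xs), len(ys)),
                truth=truth,
                contact_mask=mask,
                x_start_px=x0,
                width_px=wp,
                fov_px=fov_px,
                step_px=step_px,
            )
        )
    return panels


def save_acquisition(panels: Sequence[PanelAcquisition], outdir: str | Path,
                     mm_per_px: float) -> Path:
    """Write tile triplets as TIFFs plus a CSV manifest; returns manifest path."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = ["panel,ix,iy,phase_index,stage_x_mm,stage_y_mm,mm_per_px,filename"]
    for pa in panels:
        for (ix, iy), trip in pa.tiles.items():
            tx, ty = pa.tile_positions_px[(ix, iy)]
            for k, frame in enumerate(trip.frames):
                name = f"panel{pa.panel_index:02d}_x{ix:02d}_y{iy:02d}_p{k}.tif"
                tifffile.imwrite(
                    outdir / name,
                    np.clip(frame * 65535 / max(frame.max(), 1e-9), 0, 65535)
                    .astype(np.uint16),
                )
                rows.append(
                    f"{pa.panel_index},{ix},{iy},{k},"
                    f"{(pa.x_start_px + tx) * mm_per_px:.6f},"
                    f"{ty * mm_per_px:.6f},{mm_per_px},{name}"
                )
    manifest = outdir / "manifest.csv"
    manifest.write_text("\n".join(rows) + "\n")
    return manifest
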