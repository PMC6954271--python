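"""Tissue-coverage quantification and per-case summary statistics.

The imaged tissue area is measured by Otsu-thresholding the fluorescence
panorama (tissue is bright, background dark) and counting mask pixels at
the calibrated pixel size.  The reference surface area of the whole
specimen comes from a triangulated 3D-scan mesh.  Coverage is the ratio
of the two, in percent.

Per-case summaries report mean ± population standard deviation (divisor
N) for each column, the imaging throughput ``mean area / mean time`` per
handling method, and the throughput ratio between methods.  A bundled
per-case summary table of 15 manually handled and 2 automated
(rotation-stage, "apps") prostate cases is available via
:func:`load_reference_cases`; the automated cases lack their own 3D scans
and their coverage is computed against the manual cohort's mean surface
area (marked by convention with an asterisk in the source table).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

__all__ = [
    "CaseRecord",
    "CoverageReport",
    "SurfaceMesh",
    "otsu_tissue_mask",
    "area_from_mask",
    "mesh_surface_area",
    "coverage_percent",
    "summarize_cases",
    "load_reference_cases",
    "pathology_sampling_fraction_pct",
]


@dataclass
class CaseRecord:
    """One imaged specimen: areas in cm², elapsed imaging time in minutes."""

    case_id: str
    method: str  # "manual" or "apps"
    sim_area_cm2: float
    surface_area_cm2: float | None = None
    coverage_pct: float | None = None
    elapsed_min: float | None = None

    def __post_init__(self) -> None:
        if self.sim_area_cm2 < 0:
            raise ValueError("sim_area_cm2 must be >= 0")
        if self.surface_area_cm2 is not None and self.surface_area_cm2 <= 0:
            raise ValueError("surface_area_cm2 must be > 0")
        if self.coverage_pct is None and self.surface_area_cm2 is not None:
            self.coverage_pct = _round_half_up(
                coverage_percent(self.sim_area_cm2, self.surface_area_cm2), 2
            )


@dataclass
class CoverageReport:
    """Per-method mean ± SD summaries and imaging throughputs.

    ``stats[method][column]`` is a ``(mean, sd)`` pair; SDs are population
    standard deviations (divisor N).  Throughput is mean imaged area over
    mean elapsed time, in cm²/min.
    """

    stats: dict[str, dict[str, tuple[float, float]]]
    throughput_cm2_per_min: dict[str, float]
    throughput_ratio: float | None


@dataclass
class SurfaceMesh:
    """Triangulated specimen surface, coordinates in mm."""

    vertices: np.ndarray  # (n, 3)
    faces: np.ndarray  # (m, 3) vertex indices

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=int).reshape(-1, 3)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")

    @classmethod
    def from_file(cls, path: str | Path) -> "SurfaceMesh":
        """Load a PLY/OBJ/STL mesh (via trimesh)."""
        import trimesh

        m = trimesh.load_mesh(str(path))
        return cls(vertices=m.vertices, faces=m.faces)


def otsu_tissue_mask(image: np.ndarray, nbins: int = 256) -> np.ndarray:
    """Binary tissue mask: pixels above the Otsu threshold.

    The threshold maximizes between-class variance of the ``nbins``-bin
    intensity histogram; under fluorescence, tissue is the bright class.
    A constant image has no threshold and yields an all-background mask
    with a warning.
    """
    image = np.asarray(image)
    if image.min() == image.max():
        warnings.warn("constant image: Otsu mask is empty")
        return np.zeros(image.shape, dtype=bool)
    t = threshold_otsu(image, nbins=nbins)
    return image > t


def area_from_mask(mask: np.ndarray, pixel_size_um: float) -> float:
    """Masked area in cm²: ``count * pixel_size_um² * 1e-8``."""
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    return float(np.count_nonzero(mask)) * pixel_size_um**2 * 1e-8


def mesh_surface_area(mesh: SurfaceMesh) -> float:
    """Total triangle area of a mesh in cm² (vertices in mm).

    Half-cross-product rule per triangle; degenerate (zero-area) faces
    contribute nothing.
    """
    if len(mesh.faces) == 0:
        raise ValueError("empty mesh")
    v = mesh.vertices
    tri = v[mesh.faces]  # (m, 3, 3)
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    area_mm2 = 0.5 * np.linalg.norm(cross, axis=1).sum()
    return float(area_mm2) / 100.0


def coverage_percent(sim_area_cm2: float, surface_area_cm2: float) -> float:
    """Imaged fraction of the specimen surface, in percent."""
    if surface_area_cm2 <= 0:
        raise ValueError("surface_area_cm2 must be > 0")
    return 100.0 * sim_area_cm2 / surface_area_cm2


def _round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal-style rounding (half away from zero), as printed tables use."""
    scale = 10.0**ndigits
    r = math.floor(abs(x) * scale + 0.5) / scale * math.copysign(1.0, x)
    return r if ndigits > 0 else int(r)


def _mean_sd(values: list[float]) -> tuple[float, float]:
    a = np.asarray(values, dtype=float)
    return float(a.mean()), float(a.std(ddof=0))


def summarize_cases(records: list[CaseRecord]) -> CoverageReport:
    """Per-method mean ± population SD, throughputs and throughput ratio.

    Area and coverage statistics are rounded to 2 decimals, elapsed times
    to whole minutes, throughputs and their ratio to 1 decimal — the
    precision at which such summary tables are conventionally printed.
    The *population* standard deviation (divisor N) is used throughout.
    """
    if not records:
        raise ValueError("no case records")
    stats: dict[str, dict[str, tuple[float, float]]] = {}
    throughput: dict[str, float] = {}
    methods = sorted({r.method for r in records},
                     key=[r.method for r in records].index)
    for method in methods:
        rs = [r for r in records if r.method == method]
        cols: dict[str, tuple[float, float]] = {}
        m, s = _mean_sd([r.sim_area_cm2 for r in rs])
        cols["sim_area_cm2"] = (_round_half_up(m, 2), _round_half_up(s, 2))
        surf = [r.surface_area_cm2 for r in rs if r.surface_area_cm2 is not None]
        if surf:
            m, s = _mean_sd(surf)
            cols["surface_area_cm2"] = (_round_half_up(m, 2), _round_half_up(s, 2))
        cov = [r.coverage_pct for r in rs if r.coverage_pct is not None]
        if cov:
            m, s = _mean_sd(cov)
            cols["coverage_pct"] = (_round_half_up(m, 2), _round_half_up(s, 2))
        times = [r.elapsed_min for r in rs if r.elapsed_min is not None]
        if times:
            m, s = _mean_sd(times)
            cols["elapsed_min"] = (_round_half_up(m), _round_half_up(s))
            throughput[method] = _round_half_up(
                float(np.mean([r.sim_area_cm2 for r in rs])) / m, 1
            )
        stats[method] = cols
    ratio = None
    if "manual" in throughput and "apps" in throughput:
        ratio = _round_half_up(throughput["apps"] / throughput["manual"], 1)
    return CoverageReport(
        stats=stats, throughput_cm2_per_min=throughput, throughput_ratio=ratio
    )


def load_reference_cases(path: str | Path | None = None) -> list[CaseRecord]:
    """Load the bundled per-case summary table (or a CSV of the same schema).

    Columns: method, case_id, sim_area_cm2, surface_area_cm2 (blank where
    no 3D scan exists), elapsed_min.  Coverage for cases without their own
    surface scan is computed against the mean surface area of the cases
    that have one.
    """
    if path is None:
        src = resources.files("circumscan").joinpath("data/reference_cases.csv")
        df = pd.read_csv(src.open())
    else:
        df = pd.read_csv(path)
    scanned = df["surface_area_cm2"].dropna()
    ref_surface = float(scanned.mean()) if len(scanned) else None
    records = []
    for _, row in df.iterrows():
        surface = row["surface_area_cm2"]
        surface = None if pd.isna(surface) else float(surface)
        rec = CaseRecord(
            case_id=str(row["case_id"]),
            method=str(row["method"]),
            sim_area_cm2=float(row["sim_area_cm2"]),
            surface_area_cm2=surface,
            elapsed_min=float(row["elapsed_min"]),
        )
        if rec.coverage_pct is None and ref_surface is not None:
            # no per-case scan: coverage against the scanned cohort mean
            rec.coverage_pct = _round_half_up(
                coverage_percent(rec.sim_area_cm2, ref_surface), 2
            )
        records.append(rec)
    return records


def pathology_sampling_fraction_pct(
    section_um: float = 4.0, block_um: float = 3000.0
) -> float:
    """Surface fraction sampled by conventional slide-based pathology, in %.

    One ``section_um``-thick cross-section is examined per ``block_um``
    gross tissue block, so at most ``section/block`` of the margin surface
    is ever looked at — 0.133% at the standard 4 µm / 3000 µm.
    """
    if section_um <= 0 or block_um <= 0:
        raise ValueError("thicknesses must be > 0")
    return 100.0 * section_um / block_um
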