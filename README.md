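# circumscan

Computational toolkit for **automated circumferential surface microscopy of
excised organs** — the workflow in which a freshly resected, compressible
specimen (the motivating case is the prostate after radical prostatectomy)
is mounted on a rotating rod, lowered onto a glass slide, and imaged strip
by strip with structured-illumination microscopy (SIM) over *n* rotations,
yielding a continuous "rolled-out" gigapixel panorama of the entire
circumferential surgical margin.

The package is aimed at researchers building or evaluating such systems. It
implements the analysis chain end to end, together with a synthetic phantom
generator so that every stage is testable without tissue:

- **`circumscan.geometry`** — surface-coverage models and acquisition
  planning. A specimen of radius *r* flattens by depth *h = rc* under its
  own weight (*c* = compressibility coefficient); the tissue–glass contact
  patch is the base disc of a spherical cap, radius *a* = √(2rh − h²) =
  *r*√(2c − c²). Four-aspect imaging covers *S_I* = 2c − c² of the sphere,
  valid up to *c* = 1 − 1/√2 where the four discs touch (coverage exactly
  50%). For *n*-rotation strip imaging, each face's disc is clipped to the
  azimuthal half-width *w* = *r*(1 − c)·tan(π/n); the n → ∞ band limit is
  (1 − c)·√(2c − c²). Panel width is πd/n; frame grids follow from the
  camera field of view and overlap.
- **`circumscan.sim_recon`** — square-law optical sectioning
  I_SIM = √[(x₁−x₂)² + (x₁−x₃)² + (x₂−x₃)²] from three frames with the
  illumination pattern phase-stepped by one-third of a period, plus
  flat-field correction, 16-bit rescaling, and USAF-1951 calibration
  utilities.
- **`circumscan.phantom`** — synthetic ground-truth surfaces with
  tissue-like features (nerve tracts, adipose, nuclei), ink fiducials
  (central line + hash marks every 10 mm), and a seeded forward model of
  the full tiled acquisition, including rod-slippage artifacts.
- **`circumscan.mosaic`** — serpentine tile ordering, translation-only
  stitching with phase-correlation refinement, panorama assembly with
  anatomical labels (posterior → left → anterior → right).
- **`circumscan.registration`** — fiducial detection, inter-panel
  alignment, hash-spacing measurement, duplicate-panel (rotational
  slippage) detection and correction.
- **`circumscan.coverage`** — Otsu tissue masking, pixel-area and
  triangulated-mesh surface area, coverage percentages, and per-case
  summary statistics (mean ± population SD, throughput in cm²/min).

## Worked example

```
$ circumscan coverage-model --c 0.2 --n 10
compressibility c = 0.2
         four_aspect: 0.3600 (36.0%)
     polygonal(n=10): 0.4804 (48.0%)
          band_limit: 0.4800 (48.0%)
  max four-aspect c: 0.2929 (coverage 0.5000)
```

At the default compressibility of 20%, imaging four orthogonal faces can
cover 36% of a spherical specimen's surface, while ten-rotation strip
imaging raises this to 48%; no four-aspect protocol can exceed 50%, reached
only at the 29% compressibility where the four flattened faces meet.

```
$ circumscan cases
manual:
        sim_area_cm2: 21.95 ± 5.18
    surface_area_cm2: 67.56 ± 11.49
        coverage_pct: 33.27 ± 9.56
         elapsed_min: 43 ± 6
          throughput: 0.5 cm²/min
apps:
        sim_area_cm2: 28.64 ± 2.01
        coverage_pct: 42.39 ± 2.97
         elapsed_min: 36 ± 4
          throughput: 0.8 cm²/min
throughput ratio: 1.6×
```

This summarizes the bundled per-case reference table: manually handled
specimens averaged 21.95 cm² of imaged tissue (33.27% of the 3D-scanned
surface) in 43 minutes, while the automated rotation protocol averaged
28.64 cm² (42.39% of the cohort-mean surface) in 36 minutes — a 1.6×
throughput improvement, and roughly 318× the 0.133% surface fraction that
conventional slide-based pathology examines.

A full synthetic acquisition can be simulated, stitched and quantified:

```
circumscan phantom --config cfg.yaml --out acq/
circumscan stitch --manifest acq/manifest.csv --out panorama.tif
circumscan coverage --panorama panorama.tif --pixel-um 20 --report cov.json
```

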