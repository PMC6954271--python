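# Methods

## Coverage geometry

The specimen is idealized as a homogeneous sphere of radius *r* that
flattens, without volume bookkeeping, wherever it is pressed against a
rigid plane. The flattening depth is written *h = rc* with *c* the
dimensionless compressibility coefficient, so the tissue–glass contact
patch is the base disc of a spherical cap:

    a = √(2rh − h²) = r·√(2c − c²),   A = πa².

**Four-aspect imaging.** Imaging the specimen on four orthogonal faces
covers S_I = 4A / 4πr² = 2c − c² of the surface. The formula is valid only
while the four discs are disjoint, i.e. for c ≤ 1 − 1/√2 ≈ 0.293, where
a = r/√2 and neighbouring discs become tangent; coverage there is exactly
1/2. Beyond the bound the model raises rather than clamping, since the
formula would double-count overlapping discs and the bound is the physical
upper limit of the protocol.

**n-rotation strip imaging.** With the specimen rotated in 360°/n steps,
each tangent face images at most the strip of azimuthal half-width
w = r(1 − c)·tan(π/n) (the compressed cross-section's circumscribing
n-gon). Two constructions are provided:

- *clipped disc* (default): per-face area is the contact disc clipped to
  |x| ≤ w, i.e. πa² when w ≥ a, else 2[w√(a² − w²) + a²·asin(w/a)];
  coverage = n·area/4πr². At c = 0.2, n = 10 this gives 0.4804422
  (verified against trapezoid integration with 2 × 10⁶ points).
- *band limit*: the n → ∞ closed form (1 − c)·√(2c − c²) — compressed
  circumference 2πr(1 − c) times contact chord 2a over sphere area —
  which gives exactly 0.48 at c = 0.2.

Both round to 48%; the clipped-disc model reduces exactly to the
four-aspect formula whenever w ≥ a (e.g. n = 4 at c = 0.2). Coverage
fractions are independent of r; contact areas scale as r². A midpoint-grid
numerical oracle (`coverage_numeric_oracle`) integrates the clipped disc
directly and is used in tests as an independent check (agreement < 10⁻³).

The default compressibility is c = 0.2, a typical value for dense
glandular tissue resting under its own weight; it is a parameter
everywhere.

**Acquisition planning.** Specimen diameter and length are rounded *up* to
whole millimetres before planning — the bench measurement convention,
which guarantees the panels never under-cover the circumference. Panel
width is πd/n (arc of the 360°/n central angle); frame counts are
ceilings of panel extent over the step fov·(1 − overlap). The frame
overlap default is 10%; the camera defaults (2048² px at 0.645 µm → 1.3 mm
field of view, lateral resolution 3 px ≈ 1.95 µm, USAF group 9 element 1 =
512 lp/mm) describe a 10×/0.45 NA epi-fluorescence SIM system.

## Optical sectioning

Square-law demodulation of three sinusoidally patterned frames
phase-stepped by 2π/3 rejects any component common to the three frames
(defocused background, stray light) *exactly*, and maps a modulation of
amplitude M to √(9/2)·M irrespective of the local pattern phase (the
identity Σ_{i<j}(sin φ_i − sin φ_j)² = 9/2 for 120° steps). All internal
math is floating point; conversion to 16-bit happens only at export, by
min–max rescaling (a constant image maps to zeros with a warning, keeping
batch runs alive). Flat-field correction divides by a unit-mean reference
image; it may be applied either to the raw frames before demodulation
(default, since illumination non-uniformity multiplies the raw signal) or
to the reconstructed section — both orders are exposed because either is
defensible and they differ only through the pattern term.

## Phantom

The phantom lives in unrolled-cylinder coordinates: a rectangle of width
πd (circumference, wrapping) by L (apex–base length), with panel 0 at the
posterior-center azimuth — the same frame as the final panorama, which
makes ground-truth comparison a pixelwise operation. Default pixel scale
is 20 µm/px: ~30× coarser than the real instrument, chosen so a full
ten-panel acquisition simulates in seconds while every stage (pattern
demodulation, overlap stitching, fiducial detection, Otsu masking) still
operates on meaningfully textured images.

The ground truth has three feature classes over a smooth stromal
background (intensity 0.25–0.45): bright curvilinear nerve tracts
(~130 µm wide, random-walk paths), adipose regions (discs, intensity 0.2 —
dim relative to stroma but above the unlit background, as lipid-rich
tissue stains weakly in fluorescence), and punctate nuclei (~10 µm).
Feature counts are Poisson draws at configurable densities; every placed
feature is logged. Ink fiducials (intensity 0.02, a fluorescence void) are
a central line along the circumference plus ⌊πd/spacing⌋ hash marks at
exactly 10 mm spacing starting at x = 0.

The forward model gives in-contact pixels (the geometry module's clipped
disc, drawn at the panel center) the patterned signal
B + truth·(1 + m·sin(φ + 2πi/3)) with continuous phase across tiles, and
out-of-contact pixels an *unmodulated* defocus-blurred copy of the truth
(Gaussian σ = 8 px, scale 0.25) — not pure black, so that background
rejection and Otsu segmentation are tested honestly. Slippage events
shift a panel's source window circumferentially (degrees of rod rotation)
and/or axially (mm along the rod); the contact mask itself does not move,
as it is fixed to the slide. Optional Poisson photon noise is off by
default so forward/inverse identities hold to machine precision. All
randomness flows through one seed; identical configurations are
bit-identical.

What the phantom does **not** emulate: optical PSF blur within the focal
plane, tissue deformation at panel edges, staining heterogeneity,
autofocus error, or camera read noise. Pipeline tests passing on the
phantom therefore demonstrate correctness of the *computational* chain,
not robustness to all real-tissue imaging physics.

## Stitching and registration

Stitching is translation-only: nominal stage offsets, optionally refined
by phase correlation on the nominal overlap strips, chained from tile to
tile in serpentine order. Degenerate overlaps (< 8 px or featureless,
e.g. fully out-of-contact tiles) keep their nominal offsets with a
warning — stage coordinates are trusted where the image carries no
information. Blending is a linear edge-ramp feather by default; an
overwrite mode (every output pixel equals some input pixel) is kept for
exactness tests.

Fiducials are detected as dark ridges *flanked by bright tissue*: the
row (column) projection minus the lesser of its two offset-window flank
means. This operator scores ~0 in unlit regions, which makes it work on
reconstructed panels where everything outside the contact patch is
rejected to zero; a mark at the circumferential wrap seam (x = 0) has no
left flank and may be missed. Axial alignment moves each panel's central
line to the cohort median; panels without markers fall back to
edge-strip phase correlation. Duplicate detection slides one panel over
the other (both directions, so the measure is symmetric) and scores each
overlap span by normalized cross-correlation restricted to pixels lit in
both regions — unlit surround and ink are excluded because they are
common to all panels and would correlate even between unrelated ones. A
span correlating above 0.6 is reported; panels sharing ≥ 50% of their
width are flagged as repeats (rotational slippage) and are trimmed by the
duplicated span (default) or dropped.

## Coverage quantification

Tissue pixels are segmented by Otsu's threshold on a 256-bin histogram
(tissue is the bright class under fluorescence); area is pixel count ×
(pixel size)². Reference surface area comes from a triangulated 3D-scan
mesh via the half-cross-product rule (cross-checked against trimesh in
tests). Per-case summaries report mean ± **population** standard
deviation (divisor N) — the convention of the bundled reference table,
whose printed ± values reproduce exactly with divisor N and not with
N − 1 — with areas and coverages at 2 decimals, times at whole minutes,
and throughput (mean area / mean time) at 1 decimal, using half-up
rounding as printed tables do. Cases without their own 3D scan are
assigned coverage against the scanned cohort's mean surface area.

## Numerical and design choices

- Panel boundaries are `round(p·W/n)` so integer pixel widths partition
  the circumference exactly.
- The last tile in each row/column is clamped to the panel edge, so tile
  grids cover panels exactly regardless of divisibility.
- Coverage ∈ [0, 1] is enforced by construction; degenerate inputs
  (constant images, empty meshes, < 2 hashes) raise or warn as documented
  per function.
- Coverage–geometry comparisons in tests use *unmarked* phantoms: fiducial
  inking was a separate experiment from coverage quantification, and ink
  voids would otherwise bias the measured tissue fraction low by design.
- The phantom's spherical specimen uses L = d, for which the unrolled
  rectangle's area πd·L equals the sphere area 4πr², so the panorama's
  tissue fraction is directly comparable to the geometric coverage
  fraction.

## Known limitations

- The compressible-sphere abstraction ignores ellipsoidal or irregular
  specimen shapes and any contact mechanics beyond rigid-plane
  flattening.
- Registration is rigid (translation per panel); deformable warping at
  seams is out of scope.
- The clipped-disc strip model assumes the contact patch is centred in
  each face; precession or off-axis mounting is not modelled.
- Real-tissue figures in the bundled reference table (per-case areas,
  elapsed times) are inputs, not quantities the phantom can regenerate.
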