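# Methods

## Live-cell pipeline

### Detection

Cells are detected per frame by *local watershed segmentation upon
smoothing*: the frame is Gaussian-smoothed (`smoothing_sigma`, default 2 px
— matched to the optical blur of a 20–63× epifluorescence image), seeds are
the smoothed image's intensity maxima after h-maxima suppression (depth
`h_frac`, default 5% of the dynamic range), and the watershed floods the
inverted smoothed image inside an Otsu foreground mask, yielding one object
per intensity peak region. Seeds are derived from a copy smoothed at twice
`smoothing_sigma`: seeding at a coarser scale than flooding prevents
residual noise maxima from splitting one cell into fragments while leaving
genuinely separate cells (whose peaks are farther apart than the smoothing
scale) intact. Objects use 8-connectivity; objects smaller than
`min_object_area` (default 100 px) are discarded as debris. A structureless
frame (zero dynamic range, or no surviving seeds) yields an empty labelling
rather than an error.

Background structures that survive the watershed are removed by an
intensity-similarity rule: an object is kept only if its mean intensity is
at least `(1 + tol)` times the whole-image mean (default `tol` = 0.2). The
rule is multiplicative so it is invariant to detector gain, and the
whole-image mean includes the object's own pixels (the simplest reading of
"similar to the average intensity of the whole image"; for realistically
small cells the difference to a leave-object-out mean is negligible).

Fixed-cell spread areas are measured separately by plain thresholding
(user-supplied value, or Otsu when absent) and 8-connected component
labelling — this mode replicates an interactive ImageJ measurement, so no
watershed is involved.

### Tracking

Objects are linked frame-to-frame by maximal pixel overlap, one-to-one,
requiring at least one shared pixel. Ties on overlap go to the candidate
with larger area, then to the lower label id (deterministic, arbitrary).
When a detection is lost, the track's last seen mask is tested against
every subsequent frame's unclaimed objects; the track resumes at the first
overlap, provided the run of absent frames does not exceed `max_gap`
(default 5). The last *seen* mask, not a motion extrapolation, is used —
spreading cells move slowly relative to their size, so their masks still
overlap after several missed frames. Gap frames contribute no
measurements: time series carry explicit missing values, and
protrusion/retraction and Δσ_n pair only consecutive *present* frames.
Merges and splits are not modelled; cells neither divide nor fuse on the
few-hour timescale of a spreading assay, and the generator never creates
touching cells.

Manual validation is represented as a per-track boolean flag applied from a
decisions table; metric tables can be restricted to validated tracks.

### Metrics

- Area: pixel count of the mask. Standardisation divides all areas by the
  mean first-frame area of a designated control group, so the control group
  starts at exactly 1.0 and treated groups are fold-changes.
- Spreading rate *m*: ordinary least-squares slope of area vs time over
  the points with t ≤ `rate_window` (default 30 min, inclusive — 7 points
  at 5-min sampling), converted to per-hour. With fewer than 2 points in
  the window *m* is undefined (NaN in tables).
- Protrusion/retraction: set differences of consecutive masks. Fractions
  divide by the area in the *second* frame; the conservation identity
  A(t+1) = A(t) + P − R is exact by construction.
- Cell centre: area centroid of the mask — "cell centre" admits several
  readings (nucleus, bounding-box centre); the centroid is deterministic
  and needs no extra channel.
- Boundary: mask pixels with at least one non-mask 4-neighbour, image
  borders counting as non-mask; distances are between pixel centres.
- Circle ratio = area / (π r_max²) with r_max the largest centroid-to-
  boundary-pixel distance. A single-pixel mask returns 1.0 by convention.
  Rasterization lets values exceed 1 by up to ~3% on small disks.
- σ_n = population sd of the boundary distances divided by their mean.
  Population (not sample) sd because the boundary is the complete contour,
  not a sample from it. Normalising by the mean makes σ_n scale-free
  (verified invariant within 0.01 under 2× upsampling).
- Δσ_n = mean of |σ_n(t+1) − σ_n(t)| over consecutive present-frame pairs.
  The *absolute* difference is used: a signed mean telescopes to
  (σ_n(end) − σ_n(start))/n for any trajectory and would read ≈ 0 for every
  cell regardless of how much it remodels; only the magnitude makes the
  metric a remodelling rate that separates dynamic from stable cells.
- Field mode: the per-frame mean area over all tracked objects, means taken
  over whichever tracks have a defined area at each frame.

## Fixed-cell FA pipeline

The cell outline comes from thresholding the phalloidin counterstain (or
the paxillin channel itself in dual stains): largest connected component,
holes filled. FA puncta are detected on the paxillin/vinculin signal after
subtracting a 10-px-scale Gaussian-smoothed copy (top-hat-style flattening
of the diffuse cytoplasmic signal — puncta are ~1–3 px-radius objects, an
order of magnitude below that scale), followed by the same
h-maxima-seeded watershed. FA objects must have 4–400 px, must not touch
the cell edge (an object whose 1-px dilation reaches outside the cell is a
punctum straddling the boundary and is dropped), and must not intersect any
user-specified exclusion disc (which removes falsely detected nuclear
spots).

Intensity arithmetic, in order: (1) camera background = mean intensity
outside the cell, subtracted from the whole image and clamped at zero
(negative corrected pixels are noise below the floor, not signal);
(2) cellular background = mean corrected intensity inside the cell
excluding FA pixels; (3) normalised FA level = total corrected FA
intensity / cellular background. Division (rather than subtraction) by the
cellular background is what makes the quantity dimensionless and robust to
exposure, which is why intensities are only comparable within a staining's
fixed exposure conditions but normalised levels are comparable across
cells. The level is invariant under global gain and under global offset
(the latter removed by camera subtraction) — asserted on constructed
images.

In dual stains the paxillin-derived FA labels are reused as the pixel mask
for the phospho-channel; each channel gets its own camera and cellular
backgrounds, and the reported ratio is normalised-secondary /
normalised-primary. Per-cell phospho/total ratios use summed FA intensities
in both numerator and denominator; because both use the same pixel set the
ratio is identical whether sums or means are used. Vinculin/paxillin from
*single* stains is a condition-level ratio (mean normalised vinculin over
mean normalised paxillin), since the two proteins are measured in different
cells. Cross-experiment standardisation divides all pooled values by the
grand mean of a reference condition.

## Synthetic-data generator

The generator defines the package's study conditions; its defaults are
fixed and are what the test suite and acceptance script exercise.

**Spreading movies.** A cell is a star-shaped region r(θ, t) = R(t)(1 +
Σ_k a_k cos kθ + b_k sin kθ). R(t) follows a saturating area law A(t) =
A₀ + (A_max − A₀)(1 − e^(−g·t/(A_max−A₀))): the initial slope is exactly the
growth rate g and the area approaches the plateau smoothly, mirroring fast
early spreading followed by a steady state. The base radius is corrected by
the factor (1 + ½Σc²)^(-½) so the planted harmonics do not inflate the
area. Harmonic coefficients evolve as an Ornstein–Uhlenbeck process with
relaxation time 25 min (shape features persist across a few 5-min frames,
then turn over). Isotropic mode: stationary amplitude 0.01 — effectively a
disk, protrusion only. Anisotropic mode: 4 lobes at total amplitude 0.22 —
pronounced lobes whose stochastic turnover produces both protrusion and
retraction. Defaults: 512×512 field, initial radius 30 px, 5-min frames,
37 frames (3 h), growth 60 px²/min, plateau 12 000 px². Imaging: mask ×
peak 100 over background 10, Gaussian blur σ 2 px, additive Gaussian noise
sd 10 (SNR 10; SNR here = peak amplitude / noise sd). Ground truth (masks,
areas, protrusion/retraction pixels, σ_n by an independent boundary
enumeration) is exported per frame; one seed fixes the whole trajectory.

**Field movies** place several such cells (smaller: initial radius 14 px,
plateau 1800 px², mild 0.05 harmonics) on a jittered grid and add a
bounded random walk of each centre (sd 1 px/frame, capped at 6 px total
excursion). The cap is included in the grid spacing, so cells can never
touch and consecutive true masks always overlap — the regime the overlap
tracker assumes; tracking failures on such movies are therefore
tracker defects, not staging artefacts.

**FA scenes** are a disk cell (radius 80 px in a 256² field) with additive
intensity layers: outside level 10 (camera floor), +cytoplasm 50 inside the
cell, +punctum amplitude 150 on each of 12 non-overlapping 2.5-px-radius
puncta placed in the 0.55–0.85 R peripheral band, optional decoy puncta
inside a central 30-px exclusion disc, optional second channel with its own
levels. No blur is applied so every background/normalisation quantity has
an exact closed form from the planted values (e.g. normalised level =
n_FA_px · (cyto + amp)/cyto when no decoys are present); noise is optional
additive Gaussian.

What the generator does *not* emulate — photobleaching, stage drift,
uneven illumination, cell–cell contact, division, out-of-focus light,
detector shot-noise statistics — bounds what green tests mean: they
demonstrate correctness of the measurement definitions and robustness at
the stated SNRs on this imaging model, not performance on arbitrary real
microscopy.

## Numerical and interface choices

- All intensities are processed as float64 regardless of stored dtype;
  TIFF round-trips are lossless for integer data.
- CSV is the single tabular format; floats are written at full repr
  precision and read back with round-trip parsing, so repeated runs with
  identical inputs produce byte-identical tables (verified end to end).
- Degenerate inputs fail loudly (empty masks, <2 boundary pixels, zero
  reference means, non-positive cellular background) rather than returning
  silent NaNs, except where a missing value is meaningful (undefined *m*,
  fractions of an empty second mask).
- Test and acceptance workloads use scaled-down scenes (192–256 px fields,
  6–37 frames, 10–50 replicates) — chosen as the smallest sizes at which
  the discreteness of rasterized masks stops dominating the metrics.

## Known limitations

- The Otsu foreground step assumes cells are bright on a darker background;
  brightfield or inverted-contrast data are out of scope.
- Overlap tracking assumes slow motion relative to cell size; fast-moving
  or densely packed cells need assignment-based tracking, deliberately not
  modelled here.
- The background-similarity filter can discard genuinely dim cells whose
  mean intensity is within `tol` of the image mean.
- FA detection reports pixel sets, not adhesion morphology (length,
  orientation, maturation state).
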