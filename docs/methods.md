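# Methods

## Data model

All images are held as `VolumeImage`: an unsigned 8-bit intensity grid
in canonical `(z, y, x, channel)` order with a physical voxel size
`(dz, dy, dx)` in µm. 2D sections are volumes with z-extent 1, so
segmentation, region statistics and distances share one code path. The
8-bit range is load-bearing: every threshold in the pipeline (30–255
for the postsynapse ROI mask; 20/6/22/20–255 for channel binarization)
is defined on the 0–255 grayscale, so deeper data are rejected unless
the caller explicitly requests a linear rescale. Voxel size is read
from OME metadata but an explicit argument always wins, because
acquisition geometry is normally known per experiment (typical values
here: 0.785 × 0.785 µm laterally with 1, 1.04 or 1.2 µm z-steps).

## Accumulation analysis (2D)

The postsynapse channel is median-filtered with a radius-1 (3×3)
kernel — "1-pixel kernel" in the ImageJ sense — using edge replication
at borders. Pixels within the inclusive 30–255 band form the NMJ mask;
8-connected components (the ImageJ particle-analysis convention) of at
least `min_roi_area_px` (default 20 px) become ROIs, sorted by centroid
for deterministic reports.

The original workflow outlines a muscle-fiber reference region by hand;
how is not recorded. We use the ring obtained by dilating the ROI with
a square structuring element of radius `fiber_ring_radius_px` (default
10 px), minus the ROI itself and minus any pixel of any other ROI. A
junction whose ring is empty is flagged "undefined fiber region" and
excluded from percentage denominators, never silently dropped.

The positivity call is `mean_NMJ > mean_fiber + sd_fiber`, strict at
the boundary ("higher than"). SD is the population SD (ddof = 0); the
choice is not pinned by the original description and does not affect
the call's two key properties, strictness at equality and invariance
under positive affine intensity transforms. ROIs touching the image
border are retained here — edge exclusion is specific to the 3D
distance analysis.

## Classical 3D segmentation

Per-channel binarization uses inclusive intensity bounds (defaults:
BGT 20–255, TH 6–255, neurofilament L 22–255, VAChT 20–255). Connected
components are labeled in 3D; the connectivity is configurable (6, 18,
26) with 26 as the default, since the original tool does not state its
adjacency rule. Object sizes are voxel counts with inclusive bounds:
50–20,000,000 for the postsynapse role, 3–2,000,000,000 for marker
roles (filamentous markers form single huge objects, hence the large
maximum). Objects touching any x, y or z face of the grid are removed
from the postsynapse channel only; for single-slice volumes, z-face
contact is ignored (otherwise every object would be excluded), a
degenerate case the 3D workflow never meets. Labels are consecutive
integers in raster order of each object's first voxel, so all
downstream reports are deterministic.

## Edge-to-edge proximity

The distance between two objects is the minimum anisotropy-weighted
Euclidean distance between **border-voxel centers**, where a border
voxel has at least one face neighbor outside its object; objects that
share a voxel (possible after independent per-channel segmentation) are
at distance 0. This is the least discretization-dependent convention
available without a sub-voxel surface model; its voxelization error is
bounded by one voxel diagonal (≈ 1.49 µm at 0.785 × 0.785 × 1 µm) and
is typically far smaller, which the parameter-recovery tests assert
directly. The nearest-marker search uses one KD-tree over all marker
border voxels and is tested to agree exactly with the brute-force
all-pairs minimum; ties between equally near markers break toward the
lower object id.

The summary statistic is the fraction of postsynapses at a distance
*strictly* below the cutoff (default 2 µm). Junctions with no marker
object anywhere get an infinite distance: they stay in the denominator,
are counted as a separate histogram overflow, and are reported, never
discarded. Histogram bins are right-open `[k·w, (k+1)·w)` (default
w = 0.5 µm), and the empirical CDF at the cutoff equals the proximity
fraction by construction.

## Synthetic generator

The generator emulates what the stainings look like, not their
biophysics. Geometry is laid out in continuous µm coordinates — this
analytic layout is the authoritative ground truth — and only then
voxelized:

- **Postsynapses**: spheres of radius 3 µm (plaque-like at these
  resolutions), placed by rejection sampling without overlap (minimum
  surface separation 4 µm, so blurred neighbors never merge) inside a
  synapse band occupying the central 20% of the y-extent, with a
  face margin that keeps blurred objects off the volume edges.
  Rendered as hollow shells (1 µm wall) in 3D — the marker typically
  outlines the postsynaptic plaque — and filled discs in 2D sections.
- **Positivity**: exactly `round_half_up(fraction × n)` junctions are
  positive, chosen by a seeded shuffle. Deterministic rounding avoids
  binomial jitter swamping small test images; replicate-to-replicate
  variability then reflects rendering noise, not assignment noise.
- **Apposed markers** (VAChT-like): one sphere of radius 1.5 µm per
  positive junction, surface gap drawn uniformly from
  `apposition_gap_um` (default [0, 0.5] µm). Placement directions are
  rejection-sampled so that every marker keeps at least `far_gap_um`
  (default 5 µm) of surface clearance from every *negative* junction;
  if that is geometrically infeasible the generator raises rather than
  silently degrading the truth labels.
- **Filamentous markers** (TH/NFL-like): background axons run along x
  with a jittering course at a configurable density (`axon_density`,
  µm of axon per µm² of section — a free parameter, no reference value
  exists), plus one dedicated branch routed past each positive junction
  at its sampled gap. Tube radius 0.4 µm.
- **Diffuse enrichment** (receptor-like, and the 2D accumulation
  renderer): marker baseline at the fiber level (40) with perisynaptic
  discs (intensity 120) at positive junctions.
- **Negative control** (primary antibody omitted): the marker channel
  is a low autofluorescence floor (intensity 2) plus noise — omitting
  the primary removes specific and diffuse staining alike. At the
  stated thresholds this channel segments to zero retained objects.
- **Rendering**: structures at fixed intensities (postsynapse plaque
  200, apposed marker 200, filament 120) over a diffuse background of
  10; Gaussian blur of `psf_sigma_um` (default 0.5 µm) converted per
  axis to voxel units so anisotropy is respected; then Poisson noise
  (scale 1.0) and additive Gaussian noise (SD 2.0); clipped to 0–255.
  With zero blur and zero noise, structure voxels carry their
  configured intensities exactly, which the recovery tests exploit.

True surface gaps are recorded from the continuous geometry, before
voxelization, so recovery tolerances are explicit: a voxelized gap can
differ from the analytic one by at most one voxel diagonal.

The developmental time-course defaults store, per marker and postnatal
age, the fraction of positive junctions: TH rising 0.40 → 0.90 and NPY
0.08 → 0.60 from birth to adulthood, the β2-adrenergic receptor at 0.85
up to P30 then 0.70, VAChT at 0.95 throughout. The endpoint values
follow the reported developmental series; intermediate ages are
monotone interpolations chosen here, not reference values.

## Pipeline, determinism, problem sizes

One integer seed drives all randomness through the generator; analysis
stages are seed-free by construction, so a fixed configuration + seed
reproduces every output file byte for byte (asserted in the tests).
Every run writes a provenance record: configuration hash, seed, package
version, and per-stage retained/removed object counts — warnings such
as empty fiber regions or infinite distances are counted, never
silently dropped. Statistical comparison between ages is deliberately
out of scope (the original significance procedure is unspecified);
time-courses report mean ± SEM over replicates only.

Default study sizes were chosen to keep full validation runs at desk
scale: the headline apposition-recovery study uses one
32 × 448 × 448-voxel volume (≈ 31 × 350 × 350 µm) holding 200
postsynapses, which runs in a few seconds; unit and property tests use
24³–128³ grids. At these sizes the rejection sampler stays far from its
packing limit (≈ 20% of random-sequential-addition saturation).

## Known limitations

- The point-spread stand-in is an isotropic Gaussian; real confocal
  PSFs are elongated in z and the original 3D workflow additionally
  deconvolved its stacks. The generator applies forward blur instead,
  so the pipeline is validated against blurred-but-not-deconvolved
  data.
- No spectral bleed-through, tissue-clearing artifacts, depth-dependent
  attenuation, or tile-stitching seams are simulated; passing tests
  show the *analysis* is correct given its input model, not that the
  thresholds are optimal for any particular microscope.
- The fiber reference region is a dilation ring, one defensible reading
  of an under-specified manual step; absolute percentages from real
  tissue could shift with a different fiber-region convention, though
  the classifier's affine invariance limits the damage from global
  intensity changes.
- Edge-to-edge distances are border-voxel-center distances; sub-voxel
  surface localization is out of scope, and distances below one voxel
  pitch are not meaningful individually (only in aggregate).
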