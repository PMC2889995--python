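# Methods

`granuloc` quantifies object-based co-localization and co-trafficking of
fluorescently labeled RNA granules and proteins in multichannel confocal
stacks. This note documents the models and procedures, the parameters that
matter, the synthetic-data generator, and the numerical choices made where
the design was genuinely open.

## Coordinates and geometry

All arrays are indexed 0-based `(z, y, x)` with half-open ranges. Physical
calibration travels in a `VoxelGeometry` (µm per pixel in-plane, optical
section interval in µm, optional field extent and frame interval), supplied
via config rather than parsed from vendor TIFF tags: proprietary microscope
containers are out of scope, and an explicit geometry makes analyses
reproducible from plain multipage TIFFs. The declared TIFF dialect is
interleaved-by-slice, channel index fastest. When a field size is given, it
must agree with `pixel_size × pixel_count` to within 1%.

## Seven-color segmentation

Each pixel of a three-channel composite is an RGB vector. It is assigned to
whichever of seven *edge vectors* — the saturated corners of the RGB cube:
red (255,0,0), green (0,255,0), blue (0,0,255), yellow (255,255,0), magenta
(255,0,255), cyan (0,255,255), white (255,255,255) — subtends the smallest
angle with it. Primaries mark single targets, secondaries pairwise overlap,
and white triple overlap; writing each class to its own binary
*pseudo-channel* turns one unreadable composite into seven interpretable
images.

Numerical choices:

- Angles are computed in double precision from the cosine similarity of the
  unnormalized vectors (angles are scale-free, so no normalization of the
  pixel is needed).
- Ties within 1e-9 degrees are broken by the fixed class order above. Ties
  occur only on a measure-zero set of directions; determinism matters more
  than the particular choice.
- Pixels whose post-subtraction vector norm is at or below
  `background_threshold` (default 0) are left *unclassified*: the angle is
  undefined at the origin, and background carries no color. Unclassified
  pixels appear in no pseudo-channel, so the seven masks partition exactly
  the classified pixels.

Two background-subtraction models are offered, since the appropriate model
depends on the acquisition: `constant_percentile` (subtract a global
intensity percentile; right for flat backgrounds) and `rolling_ball`
(grayscale morphological opening residue — white top-hat with a disk
footprint — which removes any background structure wider than the disk).
The top-hat formulation was chosen over a paraboloid-geometry rolling ball
because it has an exact, independently checkable definition (`img −
grey_opening(img)`), which the test suite verifies against
`scipy.ndimage.grey_opening` as a second route.

## Puncta detection

A punctum is a connected set of voxels whose intensity is **strictly
greater than the local background mean plus two standard deviations**. The
local statistics are moving-window mean and SD over a `window × window`
in-plane neighborhood (mirror-padded, computed per z-slice, via
`scipy.ndimage.uniform_filter`). Foreground voxels are *not* masked out of
the background estimate — the simplest faithful reading of a local
mean + 2·SD rule; with a window much larger than a punctum the induced bias
is small and conservative (it raises the threshold near bright objects).

Parameters and defaults:

| parameter      | default | rationale |
|----------------|---------|-----------|
| `window`       | 31 px   | ≫ punctum diameter (~3–5 px), ≪ soma scale, so it tracks background, not signal |
| `min_size`     | 4 voxels| suppresses single-voxel noise excursions; manual counting implies visible foci |
| `connectivity` | face (6-neighbor 3D, 4-neighbor 2D) | conservative splitting of adjacent granules |
| threshold      | mean + 2·SD, strict `>` | the operational definition of a punctum |

A tiny absolute guard (1e-6) is added to the threshold so floating-point
rounding inside the moving average cannot promote exactly-at-threshold
voxels on flat regions; meaningful exceedances are O(1) intensity unit, so
the guard never changes a real decision. Centroids are intensity-weighted
on background-corrected intensity (`clip(I − mean_map, 0)`), which removes
the bias the flat background offset would otherwise exert toward the
region's shape center. On zero-noise simulations this recovers planted
centroids to ≈0.15 px.

Total event counts over a gridded field use the stated extrapolation:
sample mean per grid square × number of squares. The grid-square size is a
free parameter of the study design, not of this package. The pipeline warns
when fewer than 1500 puncta were analyzed, the sample size below which
percent co-localization becomes noisy.

## Object-based co-localization

The overlap fraction of two puncta from different channels is
`|A ∩ B| / min(|A|, |B|)` — normalized by the smaller object, which makes
the criterion symmetric and counts a small granule sitting inside a larger
cluster as fully overlapping. Two puncta are co-localized when this
fraction **strictly exceeds** the threshold (default 0.30): a punctum pair
sharing exactly 30% is *not* co-localized.

*Percent co-localization is directional*: a reference punctum counts as one
event if it has ≥1 co-localized partner, and the percentage is
100 × events / |reference population|. Because the two channels have
different population sizes, A→B and B→A generally differ. A reference
punctum overlapping two partners at 20% each is not an event: overlaps are
evaluated per pair, never pooled.

Triple co-localization counts first-channel puncta pairwise co-localized
with at least one punctum in *each* of the other two channels — the
quantity a three-channel white pseudo-channel marks. Analysis runs in
native voxel space (3D when the stack has depth, 2D otherwise); projecting
first would manufacture false overlaps between objects at different depths.
Intensity-correlation coefficients (Pearson, Manders) are deliberately not
the headline outputs; the method is number-based.

Line intensity profiles sample all channels along the Bresenham
rasterization of a user-drawn segment, so every channel returns the same
number of samples.

## Projection

`slice_spacing(pixel_count, z_interval, field_size) = pixel_count ×
z_interval / field_size` converts the optical-section interval into
xy-pixel units (512-px, 90-µm field at 0.5 µm → 2.844 px, rendered as 2.84
in reports). The rotation series rescales z by this factor (so rotation
happens in an isotropic frame), rotates about the y axis, and takes the
brightest-point projection; trilinear interpolation when `interpolate` is
on, nearest-neighbor otherwise. The 0° frame is by construction the plain
maximum projection, bit-exactly. Defaults (64 views, 10° increment) mirror
common turntable-rendering settings; both are exposed because acquisitions
disagree on the arc. Depth cueing is available as an optional linear
attenuation along the viewing axis and is off by default — it is cosmetic
and enters no quantitative result.

## Tracking

Live-imaging granules are linked frame-to-frame by greedy nearest-centroid
matching: candidate links sorted by (distance, previous punctum id, current
punctum id), accepted while both ends are free, rejected beyond `max_step`
µm. Gap tolerance is 0 frames — a missed detection terminates the track,
which avoids identity switches at the cost of track fragmentation. Tracking
is 2D (single-plane time lapse). Chains seen in only one frame are dropped
(a track needs ≥2 observations to have a displacement). Travel distance is
the summed Euclidean step length × pixel size; co-trafficking is the
fraction of reference tracks with a target track within `max_sep` µm on at
least `min_overlap_frames` concurrent frames (`cotrafficking_fraction`
takes the pixel size as an explicit argument because tracks store centroids
in pixels).

This deliberately omits Kalman/LAP tracking: granules in these data are
sparse and slow relative to the frame interval, where greedy matching is
provably identical to global matching once separations exceed twice the
step bound (asserted by test).

## Synthetic-data generator

The generator stands in for undeposited microscopy data. It emulates:
diffraction-limited puncta as 3D Gaussians (in-plane σ default 1.2 px;
axial σ doubled, the standard confocal elongation), a planar background
(level 20 + 10 intensity units per 100 px along x), Gaussian read noise
(σ 4 by default; amplitude 150 gives peak SNR ≈ 37, and σ 30 gives the
SNR-5 stress regime), and 8-bit quantization consistent with the 0–255
color model of the segmentation. Default stack shape 8×256×256 with 200
puncta per channel and pixel size 90/512 ≈ 0.176 µm/px match the package's
standard evaluation conditions.

Structure of the planted truth:

- `ceil(coloc_fraction × n)` puncta per channel pair share a site, each
  member jittered < 0.5 px, so paired centroids sit within one σ.
- In 3-channel stacks, `ceil(triple_fraction × n)` of those sites are
  shared by all three channels and count toward each pairwise fraction.
- All distinct sites keep ≥ 4σ in-plane separation (rejection sampling with
  a grid hash), so chance overlap is negligible and
  `expected_coloc = 100 × pairings / n` is a clean recovery target.
- Axial placement keeps the rendered Gaussian inside the volume
  (margin 3.5σ_z); in shallow stacks this collapses the z range toward the
  central plane. A granule truncated by the volume boundary genuinely has a
  biased centroid, so boundary placement would test the simulator, not the
  detector.

Time-lapse simulation moves granules along random constant-velocity
headings with optional positional jitter; a `paired_fraction` of channel-0
granules co-move with a channel-1 granule. Paths that would exit the frame
are truncated with a warning.

What the simulator does *not* emulate — and hence what passing tests do not
show about real tissue: realistic PSFs (Gibson–Lanni), photobleaching,
autofluorescence texture, dendrite morphology, granule intensity
heterogeneity, or clustered (non-uniform) spatial statistics. Recovery
results certify the *analysis chain*, not detection performance on tissue.

## Evaluation conditions

The standard recovery evaluation simulates 3-channel 256×256×8 stacks with
200 puncta/channel at planted pairwise fractions {0, 0.15, 0.30}, 10 seeds
each; mean recovered directional percent lands within ±5 percentage points
of the planted value (measured: within ±0.2) and at chance (< 5%,
measured 0%) for fraction 0. Detection is evaluated on 50 planted spots:
exact count and < 0.5 px centroid error at zero noise, ≥ 95% recall at peak
SNR 5 over 10 seeds. Triple counts are verified against an exhaustive
all-pairs oracle at 150 puncta/channel. The travel-distance example
simulates one granule at 0.0057 µm/s observed for 310.5 s (11 frames,
31.05 s apart), a planted path of 1.77 µm; with ~0.9 px steps the tracker
recovers it within 2% — at much smaller per-frame steps, centroid
quantization error (~0.05 px) would dominate the step length and inflate
summed distances, so sub-pixel-step regimes should be measured over longer
frame intervals.

## Known limitations

- Background statistics include foreground voxels; iterative masking would
  sharpen thresholds in dense fields and is a natural extension.
- No watershed splitting: merged granules count once.
- Greedy linking has no gap closing; blinking granules fragment.
- The >30% overlap rule and the smaller-object denominator are operational
  conventions; both are parameters (`overlap_threshold`, and the denominator
  is documented here) rather than physical constants.
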