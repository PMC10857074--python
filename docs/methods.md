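# Methods

## The measurement model

A camera looks straight down at a light-emitting acrylic panel
(default 900 × 600 mm) laser-etched with a 10 × 10 mm glowing grid. Fish
passing over the panel appear as dark silhouettes on a bright, structured
background. Three facts carry the whole method:

1. the grid's physical cell size is known, so the median spacing of
   detected grid lines gives a pixels-per-metric conversion
   `mm_per_px = cell_mm / median_spacing_px`;
2. the panel/fish contrast is strong by construction, so classical
   intensity thresholding suffices for instance segmentation;
3. for a rigid, roughly flat fish the long side of the oriented bounding
   box equals body length, the short side body width, and the pixel count
   times `mm_per_px²` gives area.

The pipeline is frame-synchronous and stateless across frames (no
identity tracking): each frame independently yields per-fish length,
width, area, an inside-grid verdict, and an in-grid count.

Assumptions: the camera is zoomed and centred so perspective distortion
over the panel is negligible (no homography is fitted); the fish swims
close to the panel plane, so one global scale applies; the panel is the
brightest large structure in the view.

## Calibration

* Panel location: Otsu threshold on the whole image (the histogram is
  computed on a ≤ 1024² subsampled view and applied at full resolution);
  the panel polygon is the bounding box of the largest connected bright
  component. Dark fish inside the panel do not perturb the bounds.
* Line detection: the panel crop is collapsed to a 1-D mean-intensity
  profile per axis; local maxima with prominence ≥ 0.25 × (max − median)
  are grid lines. Sub-pixel positions come from intensity-weighted
  centroiding in a window of a quarter of the median peak spacing —
  robust to the flat-topped profiles of lines wider than one pixel.
* Scale: per-axis `mm_per_px = cell_mm / median(consecutive spacings)`.
  The median makes the estimate immune to a few missed or spurious peaks,
  which is what fish occlusion produces (verified: calibration with three
  fish on the grid moves the scale by < 1 %). Lengths use the geometric
  mean of the two axis scales; areas use their product, so mild
  anisotropy cancels correctly in both. Axis disagreement > 5 % sets
  `anisotropy_warning` on the record.
* A fixed, externally measured scale can be supplied instead
  (`fixed_scale_calibration` / `PipelineConfig.fixed_mm_per_px`), and
  sequences can optionally recalibrate per frame; drift > 5 % between
  frames is logged.

## Segmentation

The design intent was a parameter-free Otsu cut between the luminous
panel and the dark fish. In practice the panel-region histogram is
trimodal — fish (dark), cell interiors (bright), etched lines
(brightest) — and a plain two-class Otsu splits interiors from lines,
flooding the foreground. The segmenter therefore takes the lowest
boundary of a three-class multi-Otsu, capped at `dark_fraction` (default
0.5) × the median panel intensity. The cap is what keeps a fish-free
frame empty: without fish the lowest multi-Otsu cut falls between
interior and line intensities, above the cap, and nothing is darker than
half the median panel brightness.

Post-processing: morphological closing with a disk of radius ≈ half the
grid-line width (default 1 mm line → 2–3 px), hole filling, 8-connected
labelling, sort by descending area. The closing window is edge-padded so
that foreground legitimately touching the panel-region border is not
eroded by the operator's zero boundary. Components below
`min_area_mm2` (default 500 mm², about 4 % of the smallest benchmark
fish) are dropped as noise.

Masks produced by an external detector (e.g. a fine-tuned neural
segmenter) enter through `import_masks` (16-bit labelled PNG) and flow
through the identical morphometry/gating stages; no learned model ships
with this package.

## Morphometry

Orientation is the principal eigenvector of the second central moments of
the pixel coordinates (PCA), with angle 0 as the tie-break for isotropic
masks; box sides are the extents of pixel centres projected on the
principal axes plus one pixel to close the half-open raster. A
rotating-calipers-style exhaustive rotation search is kept in the test
suite as an independent oracle, not used in the implementation. On
rasterised ellipses the principal-axis box matches the minimum-area box's
long side to < 2 px and is rotation- and scale-invariant to < 2 %.

## Gating and counting

A fish is *inside* the grid when ≥ 99 % of its mask pixels fall in the
panel polygon (half-open test; boundary pixels on the top/left edge count
as inside). Raw IoU against the panel is recorded but deliberately not
used as the gate statistic — a small fish has a tiny IoU with a large
panel no matter where it lies. Masks produced by the built-in segmenter
that touch the panel-crop border are additionally gated out as
*truncated*: the crop cannot see how far the fish extends beyond the
measurable region, so neither its measurement nor its count is trusted.

Merged silhouettes are flagged as *overlapping* when the component's area
strictly exceeds `max_single_area_mm2` (default 1.6 × the largest
configured single-fish body area) or its solidity falls below 0.75.
Solidity is computed as mask area over the convex-hull polygon area of
the boundary pixel centres (padded by the half-pixel rim so a convex
raster scores ≈ 1). Flagged components are excluded from length
statistics and from the clean count; each in-grid flagged component
contributes 2 to the separately reported `count_min` (a merged blob holds
at least two fish). Splitting merged instances (e.g. watershed) is out of
scope.

## Synthetic scenes and what they do (not) show

`scene_synth` renders: background at 0.05, panel interior at 0.55, grid
lines at 1.0, fish at 0.12 (all relative intensities; the blue-LED panel
is modelled as a single intensity channel), then Gaussian blur (default
σ = 0.5 px, a minimal camera point-spread) and additive Gaussian sensor
noise (default σ = 0.03, ~3 % of full scale) clipped to [0, 1], from a
fixed seed. Fish are fusiform: an ellipse of the specified length × width
(area analytically π L W / 4), optionally with a linearly tapered tail
lobe that preserves both extents. Ground-truth masks are the exact
rasterisations recorded before blur/noise. Sequences move fish on a
circular arc (emulating tank circulation) with tangent-aligned
orientation; frames are seeded independently from a spawned seed
sequence, so any frame regenerates bit-identically.

The generator reproduces the geometry and contrast of the real system,
not its optics: no water-surface refraction or ripple, no perspective or
lens distortion, no colour, no shadows, and rigid silhouettes rather than
undulating bodies. Passing tests therefore demonstrate the correctness of
calibration, segmentation logic, morphometry and gating under the stated
contrast model — they do not certify performance on real footage with
optical distortion or body flexion.

## Benchmark protocol and numerical choices

`run_size_benchmark` renders the five model-fish lengths
{600, 450, 448, 315, 270} mm (width = length / 4.5, a typical fusiform
aspect ratio; the mock-ups' true widths are not specified anywhere, so
this is a declared choice) one per scene, 20 poses each, uniformly random
orientation and position keeping the whole body ≥ 15 mm inside the panel
(orientations that cannot fit — a 600 mm fish nearly vertical on a
600 mm-tall panel — are rejection-resampled). Scenes use the full
900 × 600 mm geometry at 0.2 mm/px (4550 × 3050 px with margin) and the
default noise/blur; every scene is self-calibrated from its own image.
All randomness derives from `SeedSequence([seed, size_index, pose])`, so
runs are exactly reproducible and each scene is independent. True area
for the accuracy statistic is the ground-truth mask's pixel count times
the true scale squared, so it measures segmentation + conversion error,
not rasterisation error.

Degenerate inputs are rejected early with typed errors: grids whose cell
would span < 4 px (unresolvable), fish extending off-image (unless the
caller opts into clipping, as sequences do), empty masks, uniform or
all-dark images, fewer than two detected lines.

## Known limitations

* Fish partially off the panel are measured from the visible part only
  and gated out of the count; there is no extrapolation.
* The classical segmenter assumes the fish is the darkest structure on
  the panel; debris or heavy shadowing would need the external-mask path.
* Counting is per-frame; the same physical fish is counted in every frame
  it occupies, and no across-frame identity or growth trajectory is
  maintained.
* Solidity-based overlap detection misses two fish merged in a near-convex
  configuration (e.g. perfectly parallel, touching flank-to-flank) if
  their combined area stays under the area ceiling.
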