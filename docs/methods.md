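# Methods

## Problem and model

A spheroid/immune-cell co-culture image is an RGB confocal maximum
projection: green marks DiO-stained tumour spheroid cells, red marks
DiI-stained immune cells (splenocytes), and the blue plane carries no
signal of interest and is discarded at channel splitting. All images are
reduced to 8-bit intensities at load time (deeper integer images divided
linearly by their full bit range) so that one intensity scale feeds both
the histogram thresholding and the pixel classifier.

Two confounds shape the whole design. First, tumour cells emit
substantial red fluorescence (spectral bleed-through), so raw red
intensity overstates immune presence everywhere the tumour is. Second,
some pixels saturate in both channels, destroying the red/green
relationship entirely. Each trafficking index addresses these
differently: TIS by restricting attention to the tumour mask and taking
the red/green *ratio* (bleed-through sets a floor rather than a bias that
scales with spheroid size), TIC by giving saturated pixels their own
class so they bias neither tumour nor immune counts.

## Segmentation and morphometrics

Noise reduction is an iterated 2-D median filter. Defaults: kernel 3×3
(the smallest standard kernel — the iteration count, not the kernel,
supplies the smoothing strength) and 200 iterations. Borders use
reflect (symmetric) padding, which avoids the artificial dark frame that
zero padding would wrap around a bright spheroid touching the frame.
Iterated median filtering converges to a root signal; the implementation
stops as soon as one pass leaves the image unchanged, which is
bit-identical to running the full iteration count and is why the default
200 passes are cheap on realistic images.

Otsu's threshold is computed in-house over the 256-bin histogram
(cumulative-moment form), minimising the pixel-weighted within-class
variance of the ≤t / >t split. When several thresholds tie, the smallest
is returned (deterministic, favours larger foreground). Foreground is
strictly greater than the threshold. A constant channel has no
information to threshold; it yields an empty mask with a `degenerate`
flag rather than an error, because blank wells are a real observation
whose area is legitimately zero.

No morphological post-processing and no largest-component selection are
applied anywhere: fragmented spheroids are biology, and the minimal
bounding box (hence the extent) is taken over the union of all
fragments. Area normalisation divides by the same well's area at the
reference time (24 h by default); wells lacking a usable reference are
flagged and skipped, not fatal.

Note two deliberate small-scale behaviours of the median filter:
structures smaller than the kernel's majority (isolated pixels, 2×2
patches) are erased in one pass, and convex corners of rectangles are
rounded over many passes. Perfect-contrast geometric fixtures are
therefore segmented with `iterations=0` where exact shapes matter.

## TIS

Both channels are segmented with the same filter settings as the area
pipeline. The filtered images exist only to produce the masks; the
red/green ratio is evaluated on the raw intensities, since filtering
would smear the very signal being measured. The normaliser is the
intersection itself, making TIS the *mean* ratio over the intersection —
scale-free in the intersection size; the alternative normalisation by
the tumour-mask size is computed and reported alongside
(`tis_tumour_norm`). The denominator guard `max(green, 1)` keeps the
ratio finite and bounded by the red intensity on the rare intersection
pixels whose raw green is 0.

## TIC

The classifier is plain Lloyd k-means, k = 4, on raw (red, green) pairs
with no standardisation (both axes already share the 8-bit scale).
Stopping: maximum centroid coordinate displacement between consecutive
iterates below 10⁻⁶ — with integer-valued data Lloyd reaches exact
assignment stability, so displacement hits zero and termination is
finite. Initialisation is k-means++ from the supplied seed; because
Lloyd only finds local optima and the saturated class can be under 1% of
training pixels, ten independent starts are run and the lowest
within-class sum of squares wins (the reported iteration count and
objective trace describe the winning run). An emptied class is re-seeded
from the point farthest from its nearest centroid and logged. Centroids
are stored sorted lexicographically by (red, green), which fixes all
nearest-centroid tie-breaks.

Roles are assigned by a deterministic rule: background minimises
red+green; saturated is the centroid maximising min(red, green) when
that minimum reaches the saturation level (default 250), else the
brightest centroid; of the remaining two, immune has the larger
red−green. Exact ties resolve to the lower sorted index. The rule can be
overridden by constructing a `PixelClassifier` with explicit roles.

Training pools one image drawn uniformly at random per (group, time)
cell — 28 images for a 7-group × 4-time experiment — and samples 10,000
pixels per image without replacement (configurable; the value balances
class coverage of the rare saturated pixels against training cost).

The "surrounded by cancer" test reads the 11 × 11 square literally as
*surroundings*: the centre pixel is excluded, leaving 120 neighbours.
Majority means strict plurality among the four roles; exact tied
pluralities count for nothing (conservative and deterministic). Pixels
within 5 of the border have incomplete windows and are excluded and
counted (`excluded_border`), not padded — padding would fabricate
context around a spheroid that is usually central anyway. The
implementation uses integral-image window sums, is exact, and is checked
against a brute-force double loop in the tests.

## Synthetic data

The generator emulates what the analysis must be robust to, not optics:

- a disk spheroid of radius 55 px in a 256×256 frame (about the relative
  scale of a well-centred spheroid at ×10), optionally split into k
  disjoint equal-area fragments on a ring, optionally hollowed;
- immune cells as disks of radius 3 px (splenocyte scale relative to the
  spheroid); an *exact* round(f·n) of the n cells are placed wholly
  inside the spheroid, the rest wholly outside a small clearance margin,
  so the true infiltration fraction equals the requested one rather than
  fluctuating binomially — this keeps ground truth exactly controlled at
  small replicate counts;
- intensity model: tumour pixels green ≈ 180 with red bleed-through
  ≈ 60 (matching the strong red-in-tumour scatter seen in real control
  images); immune pixels red ≈ 220 with low green ≈ 30 (immune cells are
  modelled as displacing, not overlaying, the tumour signal, which keeps
  the four colour classes well-formed); background ≈ 10; all with
  Gaussian jitter (sd 10) and background noise (sd 8), clipped to
  [0, 255];
- 2% of tumour pixels driven to (255, 255) to exercise the saturated
  class.

All randomness flows from one seed through `numpy.random.SeedSequence`;
time series and experiments derive child seeds per image, so any image
is independently reproducible. Growth is modelled by scaling the radius
by √(growth factor), making true area ratios equal the factors up to
rasterisation.

What the generator does *not* model — point-spread blur, light
scattering in thick samples, spatially structured bleed-through, cell
clumping, uneven illumination — bounds what passing tests show: they
validate the algorithms against their own stated semantics and their
sensitivity to true infiltration under realistic intensity statistics,
not performance on degraded real optics.

## Pipeline

`analyze_experiment` produces one row per image (area, normalised area,
extent, TIS, TIC, border-exclusion count, flags), ordered by (group as
declared, time, replicate), plus a per-(group, time) mean ± SEM summary
(SD with n−1 denominator). Degenerate images flag rather than fail; hard
errors skip the row and are logged. CSV floats are written with fixed
`%.6f` formatting so re-runs are byte-identical. Group-comparison
statistics are deliberately out of scope; the CSV is the hand-off point.

## Problem sizes used in validation

The validation suite runs the full pipeline at moderate scale chosen as
representative while keeping the suite quick: 256×256 synthetic images,
experiments of up to 7 groups × 4 time points, 10,000 training pixels
per image, 10 replicates per infiltration level for the monotonicity
check, and exhaustive/brute-force oracles on 64×64 (Otsu) and 40×40
(TIC) inputs.

## Known limitations

- The iterated median filter erases structures below kernel scale, so
  immune cells smaller than ~2 px radius never reach the red mask; TIS
  still sees them through the raw-intensity ratio inside the tumour
  intersection.
- One classifier per experiment assumes acquisition settings are stable
  across the experiment; images acquired under different gain need
  retraining.
- TIS is reported unnormalised against bleed-through; its zero-
  infiltration floor is the tumour's own red/green ratio and comparisons
  are meaningful within, not across, staining protocols.
- Extent conflates fragmentation with elongation: two far-apart
  fragments and one eccentric spheroid can score alike.
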