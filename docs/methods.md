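# Methods

## Image model and segmentation

Input images are 8-bit grayscale rasters of dark seeds on a light
background, acquired at a known, square resolution in dots per inch.
Color scans are accepted and reduced by ITU-R 601 luminance with a
warning; 16-bit scans are rescaled to 8-bit. Resolution precedence is
explicit override > file metadata (TIFF resolution tags / PNG pHYs) >
error, since the operator usually knows the scanner setting. PNG stores
resolution in dots per meter, so near-integral dpi values read back from
metadata are snapped to the integer.

Thresholding uses Otsu's criterion computed on the full 256-bin
histogram: the integer cut `t` in 1..255 maximizing the between-class
variance `w0*w1*(mu0-mu1)^2` of the classes `[0,t)` and `[t,255]`. Ties
take the lowest `t` (smaller, more conservative foreground). A histogram
with a single occupied bin has no valid split and returns an undefined
flag. In batch operation the per-image thresholds are averaged —
undefined entries excluded, logged — and the single mean threshold
binarizes every image, which stabilizes sparse plates whose own
histogram is nearly unimodal. A pixel is foreground iff its intensity is
*strictly below* the threshold (a polarity flag inverts this for light
objects on dark media). Foreground components are maximal 8-connected
sets, labeled in row-major order of first pixel (via `scipy.ndimage`,
relabeled to guarantee the ordering); components touching the image
border are flagged and excluded by default as truncated seeds, since
their axes are not measurable.

## Morphometry

Each component's area is its exact pixel count. Axes are those of the
ellipse with the same normalized second central moments as the pixel
set: form the 2x2 covariance of pixel-center coordinates, add 1/12 to
each diagonal term (the variance of a unit-width uniform distribution,
spreading each sample over its pixel's extent so a single pixel measures
`4*sqrt(1/12) ~ 1.15` rather than 0), take eigenvalues `l1 >= l2`, and
report `major = 4*sqrt(l1)`, `minor = 4*sqrt(l2)`. This is the
convention of the mainstream region-measurement tools (MATLAB
`regionprops`; scikit-image uses the same ellipse without the pixel
term, and the two agree to <0.5% at seed scale, which a test checks).
Orientation is the major-axis angle versus the column axis in
(-pi/2, pi/2].

Filtering applies, in order: border exclusion (optional, default on); an
optional pixel-area gate; ellipse consistency — pixel area within a
relative tolerance of the modeled ellipsoidal area `pi*major*minor/4`;
and the aspect rule — keep iff `major/minor <= 2.5`, an inclusive bound
(ratios *more than* 2.5 are rejected). The conjunction is
order-independent; the order only structures the per-stage rejection
counts in run summaries. All components are emitted with their flags so
rejected objects remain auditable.

**Ellipse tolerance 0.10.** A perfect digital ellipse at seed scale
(minor axis >= ~20 px) deviates under 3% from its moment-ellipse area,
while strongly concave unions (two fused seeds) deviate 10-22%, so 0.10
separates the classes with margin on both sides. It is configurable; the
synthetic suite documents the observed margins.

**Size gate.** Small compact debris is geometrically indistinguishable
from a seed by the two shape rules alone — a round speck passes both. A
minimum-area gate is therefore available and, for synthetic fields,
`FieldSpec.filter_config()` derives it as one quarter of the median
modeled seed area (`pi*a*b/4` at the spec's nominal axis lengths):
generated debris lies below that bound by construction and real seeds
sit several-fold above it. The gate defaults to off for real images,
where the analyst should set it from the plate's known seed scale.

## Phenotype aggregation

Accepted records are averaged per line and replicate (mean, SD, count of
the three traits in mm/mm^2); the final per-line value is the unweighted
mean of replicate means, so a replicate with many more seeds does not
dominate — the replicate, not the seed, is the unit of replication. A
pooled per-seed mode is available behind a flag for comparison. Export
is a sorted CSV (line_id, area, major_axis, minor_axis, n_seeds,
n_replicates) shaped to paste into a standard QTL cross file. QTL
mapping itself is out of scope; mature statistical-genetics packages do
it from this table.

## Heritability

One-way random-effects ANOVA over lines, unbalanced design:

    MS_M = sum_i n_i (ybar_i - ybar)^2 / (a-1)
    MS_E = sum_ij (y_ij - ybar_i)^2 / (N-a)
    n0   = (N - sum_i n_i^2 / N) / (a-1)
    V_A  = max(0, (MS_M - MS_E) / n0)
    H2   = V_A / (V_A + V_E)

`n0` reduces to the common group size for balanced designs. `V_A` is a
moment estimator and is floored at zero: a negative value is sampling
noise, not a variance. The default environmental-variance estimator is
`V_E = MS_E`, labeled `V_E_method=MS_E` in every output; published
variance tables sometimes report a differently derived `V_E`, so `H2`
can also be computed directly from externally supplied `(V_A, V_E)`,
where the ratio is exact. `H2` is undefined (NaN) when total variance is
zero, and is reported to three decimals in summary tables. Inputs with
fewer than two lines, or without any within-line degree of freedom, are
rejected.

## Synthetic fields

The generator emulates a reflective flatbed scan: background ~220, seed
foreground ~60, Gaussian intensity noise sd 8, clipped to [0,255] —
roughly brown seeds on a clear dish over a white lid. Objects are
rendered as coverage-weighted (4x4 subsampled) anti-aliased shapes so
edge digitization resembles a real scan rather than a hard mask.
Defaults: 3200 dpi, seed axes 0.55 x 0.30 mm with 5% relative scatter,
uniform orientation, 1600x1600 px canvas, 50 single seeds. Placement is
rejection-sampled with non-overlapping bounding circles; impossible
densities raise an error suggesting a larger canvas. Everything is
deterministic given the spec's `rng_seed`.

Artifact classes:

* **Touching pairs** are two seed ellipses in *angled* contact: relative
  orientation uniform in 50-90 degrees, centers offset along the first
  seed's major axis at 0.90x the sum of the two shapes' extents along
  that line. The outlines overlap into one 8-connected component whose
  pixel area misses its fitted-ellipse area by >= ~12% — robustly
  failing the 0.10 consistency test over noise. A same-orientation
  end-to-end pair was deliberately rejected as the default geometry: its
  fused shape deviates only 7-10% (analytically, at most ~10.6% at exact
  tangency), i.e. it *passes* a 0.10 ellipse test, and near-tangent
  contacts also split into two components under noise. Physically
  touching seeds meet at essentially random relative angles, so the
  angled geometry is also the more realistic one.
* **Scratches** are thin rotated rectangles 16-40x longer than wide —
  aspect far beyond 2.5.
* **Debris** are small mildly elongated blobs with area 5-15% of the
  median seed model area, below the quarter-median size gate.

The ground-truth manifest records each object's kind, center, true
geometry and whether filtering should accept it (singles only).

What the generator does **not** model: seed-coat texture and color,
shadows and illumination gradients, mucilage halos, clustered clumps of
3+ seeds, dust fields, or non-square pixels. Passing tests on these
fields therefore validate the geometry, thresholding and filter logic —
not robustness to real-scan photometric artifacts, which the batch
threshold and tolerances are designed to absorb but which only real
images can demonstrate.

## Simulated populations and test scale

`sample_population` draws `y_ij = mu + g_i + e_ij` with
`g_i ~ N(0, V_A)` and `e_ij ~ N(0, V_W)` — exactly the random-effects
structure the one-way ANOVA assumes, i.e. near-homozygous lines with
purely additive line effects and iid environmental noise; no
genotype-by-environment interaction, maternal effects or measurement
error structure. Recovery tests run 160 lines x 200 seeds over 20
replicate simulations, a deliberate scale-down of real experiments
(~10^3 seeds per line) that keeps the estimator's relative error well
inside the 15% acceptance band while the whole suite stays fast.

## Numerical and degenerate-input choices

* Otsu ties -> lowest threshold; single-bin histogram -> undefined flag.
* All-undefined batch -> error instructing a manual threshold, not a
  silent fallback.
* Blank noisy images produce no components at a typical batch threshold
  (the background sits ~10 sd above it); their own Otsu value would be
  meaningless, which is precisely why the batch protocol averages.
* `V_A` floored at 0; `H2` NaN when `V_A + V_E = 0`; two lines minimum.
* Unit conversions: `mm = px * 25.4 / dpi`; areas use the square.
  Physical units are canonical outputs, pixel values retained alongside.

## Known limitations

Touching seeds are rejected, not split — throughput comes from seed
count, not completeness, and fused pairs would bias the size traits if
admitted. The ellipse tolerance and size gate need adjustment for seed
stocks far from the default scale. The heritability estimator treats
every accepted seed as an independent observation within its line;
plate- or image-level batch effects are not modeled.
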