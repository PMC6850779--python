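# Methods

This note records the models, conventions and parameter choices behind
the package, what the synthetic generators do and do not emulate, and
the numerical decisions a maintainer would otherwise have to reverse
engineer.

## Cilia segmentation

The detector operates on the max-z projection of the cilia-marker
channel. Projection first, segmentation second, reflects how thin
(~0.2–0.5 µm wide, 2–10 µm long) cilia appear in confocal stacks: the
marker is bright in only a few focal planes, and a 2D footprint is the
natural support for the downstream ring mask.

**Median filter.** A square window of side 2r+1 with reflected borders,
default r = 2. The filter exists to suppress shot noise before
thresholding; it necessarily erodes convex corners (the capsule's
rounded tips), so on *noiseless* data the correct setting is r = 0,
where the recovered mask is pixel-exact. All noisy-data defaults use
r = 2.

**Threshold.** Three forms are accepted: an absolute intensity, a
quantile of the filtered projection, and the default robust background
model — median + k·1.4826·MAD of the filtered projection with k = 10
(falling back to IQR/1.349 when the MAD is zero, which happens for
integer-concentrated noise). The robust default was chosen over a fixed
quantile because a quantile marks a fixed fraction of pixels as signal
regardless of content: it can never return an empty mask on a blank
field, and on noisy fields it sits inside the background distribution,
letting boundary pixels whose median-filter windows straddle the object
edge join the mask and bias the C/P ratio (about −8% in our Poisson
benchmark, versus under 3% with the robust rule). k = 10 robust SDs is
deliberately conservative: the filtered background of a max-projected
Poisson field is extremely tight, so the margin costs no sensitivity,
while comfortably clearing the top order statistics of the background
that appear in windows adjacent to real objects. Both alternative forms
remain available for users who calibrate per dataset, which is how the
original confocal workflows were run.

**Shape tests.** A component is a cilium only if *all* tests pass:

| test | default | direction | rationale |
| --- | --- | --- | --- |
| area | 20–500 px | range | excludes specks and large debris |
| eccentricity | ≥ 0.85 | min | cilia are elongated rods |
| solidity | ≥ 0.8 | min | excludes concave/fragmented debris |
| mean intensity | ≥ 0 | min | user-set brightness floor |
| length (max Feret) | 10–120 px | range | physical cilium scale at ~0.1 µm/px |
| border | excluded | flag | a truncated ring mask would bias C/P |

Eccentricity comes from the ellipse with matching normalized second
central moments, with each pixel contributing its unit square (the
+1/12 variance term). This keeps the invariants exact at the edge
cases: a single pixel has eccentricity 0, and a perfectly collinear
segment stays strictly below 1.

Solidity is area divided by the *rasterized* hull area — the number of
lattice pixel centers inside or on the convex hull of the component's
pixel centers. The continuous hull-polygon area of pixel centers is the
wrong normalizer for small discrete objects (a straight line has
polygon area zero; an L-tromino's triangle holds only half a pixel),
and the rasterized count is the discrete analogue that keeps solidity
in (0, 1] with value 1 for convex and collinear sets.

Length is the maximum pairwise distance between pixel centers (max
Feret diameter), computed exactly; for components above 400 px the
pairwise search is restricted to convex-hull vertices, which attain the
maximum.

Connectivity defaults to 8 so that thin diagonal rods remain single
components. Labels are assigned in raster-scan order, making repeated
runs identical.

## C/P quantification

The probe channel is never filtered — filtering is a mask-building
device for the marker channel only. For each cilium, per-plane means
are taken over the raw probe voxels inside the cilium footprint and
inside the plasma-membrane ring (dilation of the footprint by a disk of
radius 5 px, minus the footprint; the ring is clipped at image borders
and is disjoint from the mask by construction). The final value
normalizes the brightest ciliary plane by the brightest ring plane —
the two argmaxima taken independently, ties resolved to the lowest
plane index — either by division (default; all figures-style ratios)
or subtraction (kept as a first-class mode). Measuring each plane
independently avoids diluting the ciliary signal with out-of-focus
planes.

The 5 px ring radius corresponds to a ~0.5 µm annulus at typical
confocal sampling (0.1 µm/px): wide enough to average membrane speckle,
narrow enough to stay local. Division-mode values are invariant under
global rescaling of the probe channel; subtraction-mode values scale
with it.

Nuclei counting (for ciliation frequency = cilia/nuclei) is a plain
Otsu threshold on the max-projected nuclei channel followed by
small-component removal; touching nuclei merge under 8-connectivity,
a documented limitation acceptable at the densities simulated here.

## Synthetic imaging fields

A cilium is rendered as a 2D capsule (rectangle with semicircular caps,
total extent = length) at a given orientation, extruded over
z_center ± 1 planes of the marker channel. The probe channel is a
uniform "plasma membrane" sheet with each capsule footprint overwritten
by its ciliary probe level, identical in every plane, so the plane-max
normalization has an exact closed-form truth: C/P = probe level /
membrane level. Default distractors are a disk (defeats the
eccentricity test) and an open C-shape (defeats solidity), both at
cilium-like brightness. Noise is Poisson (rates = clean image) or
additive Gaussian clipped at zero; a fixed seed fixes every voxel.

What the generator does *not* emulate — and therefore what passing
tests do not establish about real data: optics (PSF blur, spectral
bleed-through, axial anisotropy), a traced cell outline instead of the
uniform membrane sheet, autofluorescence gradients, and touching or
crossing cilia. The uniform sheet is deliberate: it gives the ring mask
an exact truth value, which is what makes recovery testable.

Default study conditions: 256×256×5 stacks, background 5 a.u.,
membrane 100 a.u., marker 500 a.u., probe levels spanning C/P ratios
0.5–4, 20 Poisson replicates for accuracy estimates. Under those
conditions the mean |relative C/P error| is ~3% (the residual bias is
cap erosion by the median filter leaking bright pixels into the ring).

## Screen simulation and scoring

The generator models the sorting experiment directly: each guide's
cells carry reporter ~ Normal(effect, 1) in SD units (effect 0 for null
and non-targeting guides); the pool-wide sorting cutoff is solved so
the mixture's selected mass equals the sorted fraction (bottom 10% by
default); a guide's selection probability is its tail mass beyond that
cutoff. Unsorted counts are multinomial at uniform baseline
frequencies, sorted counts multinomial with probabilities ∝ baseline ×
selection probability — the simplest model with exact expectations;
Gamma jitter of the baseline (negative-binomial-like overdispersion) is
available behind a knob. Default scale mirrors a realistic desk-size
screen: 500 genes × 4 guides + 200 non-targeting controls, 2×10⁶ reads
per population, planted effects of |2 SD|.

Scoring implements the screen statistic exactly as defined — the
per-gene mean of guide-level sorted/unsorted RPM ratios (pseudocount
0.5 RPM guards zeros without dominating realistic depths). For
significance the package deliberately does **not** reimplement MAGeCK's
α-RRA machinery: a permutation null (reassigning observed guide ratios
to genes, preserving guide counts) is self-contained, assumption-free,
and exactly matched to the statistic being ranked. Two-sided empirical
p-values use the standard +1 correction; BH runs over targeting genes
only, with the reserved `non-targeting` pseudo-gene scored but excluded
from the FDR family. 10,000 permutations put the attainable p floor at
~10⁻⁴, comfortably below the BH threshold for tens of true hits among
hundreds of genes.

Pathway roll-up applies the expression filter (drop genes with RPKM 0
in both RNAseq replicates; genes missing from the expression table are
treated as unexpressed and logged) and maps enrichment direction to
regulator class from the declared design: in a bottom-tail sort under
high ligand, guides enriched in the sorted bin mark lost *positive*
regulators; a top-tail/low-ligand design reverses the mapping.

## Reporting statistics

The exact Mann–Whitney path enumerates the full U null (used when
n₁+n₂ ≤ 20 and the pooled sample is tie-free; otherwise the normal
approximation with tie and continuity correction is used and flagged).
Two-sided p is 2·min(lower tail, upper tail) capped at 1, which
reproduces the familiar small-sample grid: 2/70 = 0.0286 for complete
separation at n = 4 + 4, 34/70 = 0.4857 for U = 5, 2/12870 ≈ 0.0002 at
n = 8 + 8.

The outlier filter is a univariate adaptation of the ROUT idea (robust
fit, then FDR-controlled residual testing at level Q, default 0.10):
the robust fit of a single sample is its median; the robust scale is
the 68.27th percentile of absolute residuals (the robust-SD analogue);
each point gets a t-like statistic with n−1 df; removal is a
Benjamini–Hochberg scan over the resulting p-values, which tests from
the most extreme point inward and keeps the removed set monotone in Q.
Exact replication of the commercial implementation is not claimed —
its internals (df conventions, scale corrections) are not public — and
results on heavily skewed samples reflect the symmetric-residual
assumption.

Percentiles everywhere use linear interpolation between closest ranks.
Violin summaries report mean and the 25th–75th percentile range; median
fold change is the ratio of sample medians; ΔCt = CTtarget −
CTreference with relative expression 2^−ΔCt; per-DNA normalization is a
plain quotient.

## Degenerate inputs and tie-breaks

- Quantile threshold on a constant image: warning + empty mask.
- Single-pixel component: eccentricity 0, solidity 1, length 0 (fails
  the elongation test by default, as it should).
- Identical plane-mean vectors: division C/P = 1, subtraction = 0;
  argmax ties take the lowest plane.
- Kruskal–Wallis on all-identical data: H = 0, p = 1 (the underlying
  library rejects this case; the package defines it).
- ROUT with Q = 0, or with n < 3: nothing removed / error.
- Division-mode C/P with a zero ring maximum: explicit error.

## Problem sizes

Test-suite and acceptance workloads were sized to what the statistics
need, not more: 20 Poisson replicates for imaging accuracy (standard
error of the mean error ≪ the 5% bound), 10 seeds × 10,000 permutations
for screen operating characteristics, and ≥ 100 random instances per
brute-force oracle comparison. The full suite runs in well under a
minute on one CPU.

## Known limitations

- 2D segmentation on the projection; no 3D volume, deconvolution, or
  time tracking.
- No optics simulation in the generator (see above), so absolute
  accuracy numbers describe the idealized geometry, not microscope
  data.
- Touching nuclei undercount; touching cilia would merge likewise.
- The permutation null treats guides as exchangeable across genes;
  strong per-gene guide-efficiency structure would violate it.
- MAGeCK-style robust rank aggregation is intentionally out of scope.
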