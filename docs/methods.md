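# Methods

This note documents the models, estimators and numerical choices behind
`optiregen`, what the synthetic phantoms do and do not emulate, and the
design decisions taken where the underlying assay descriptions left the
procedure open.

## Synthetic phantoms

Every analysis module is exercised against a generator that produces its
input together with machine-readable ground truth. All generators draw
from `numpy.random.default_rng(seed)` and are bit-reproducible.

**Nerve phantom.** The nerve axis is horizontal; proximal to the injury
site the intensity is `f_pre_level` (default 200, arbitrary linear
units), and distal to it the regenerated GFP signal follows a logistic
fall-off centred on the regeneration front: `f0 + (f_pre − f0) ·
σ((front_x − x)/softness)` with softness 25 μm (default). A logistic
front rather than a step reflects the graded appearance of regenerating
growth cones and gives a differentiable template for oracle tests.
Defaults: 1500 μm nerve, injury at 250 μm, front at 750 μm (500 μm of
regrowth), background 20, Gaussian noise σ configurable (0 by default).

**Tectum phantom.** Each coronal section carries two mirrored lateral
half-annulus bands standing for the pooled SO/SFGS layer (outer radius
80 px, thickness 12 px): the control side at `uninjured_level` (200), the
crushed side at `background + fraction · (uninjured − background)` where
the per-sector fraction profile is a function of normalized rostro-caudal
position. The default profile declines linearly from 0.8 rostral to 0.4
caudal in all sectors — a mid-recovery (≈7 dpi) pattern. A stack has 21
sections by default (the 17–24 range typical of a whole tectum).

**Silhouette phantom.** The fish is a filled ellipse (length 120 px,
aspect 4:1) at a true tilt plus per-frame Gaussian jitter. Head/tail
asymmetry is omitted, so angles live in (−90°, 90°] and positive means
blind-eye-up by convention; the day-0 / uninjured baseline default is 0°,
the post-crush regime in this assay is ≈8–12°.

**Puncta phantom.** Cells are disks (radius 8 px) placed by rejection
sampling with centre separation ≥ 2·radius + 4·spot σ, which makes
punctum-to-cell assignment unambiguous by construction; an overfull field
is rejected. Per-cell counts are Poisson (mean 3) unless forced. Puncta
are unit-amplitude Gaussians (σ 1.5 px) placed uniformly within 0.9·radius
of their parent centre with a ≥ 4σ separation between same-cell puncta so
that the spots remain individually resolvable — the regime the detector
contract specifies. Fields denser than that limit would require joint
deconvolution, which is out of scope.

**Count phantom.** Genes × samples negative-binomial counts via a
gamma–Poisson mixture with common dispersion 0.1; gene base means are
log-normal (meanlog 4, sdlog 1, natural log). A named "spiked" gene set
(default 25 genes, standing in for the cholesterol-biosynthesis pathway)
has its mean multiplied by 2^log2FC (default 2.0) in the second group
before sampling. Default 4 samples per group, matching a typical
knockdown RNA-seq arm. Library size factors are per-sample multipliers on
the mean.

What the phantoms do **not** emulate: optics (PSF, depth of field),
autofluorescence and illumination gradients, curved nerves, anatomical
asymmetry between tectal hemispheres, fish body shape beyond an ellipse,
gene–gene correlation, and batch effects. Passing tests therefore
demonstrate correctness of the measurement machinery under its stated
geometric and statistical assumptions, not robustness to every real-image
artefact.

## Nerve regeneration index

Mean intensity is averaged over the full image height in half-open 50 μm
bins `[start, start + step)` from the injury site toward the chiasm; a
trailing partial bin is dropped so all bins have equal support. `F_pre`
is the single step-wide window immediately proximal to the injury (the
assay description gives no width; one bin width matches the profile
granularity). `F₀` comes from a separate uninjured-nerve image (whole
image mean) or a precomputed scalar. The index `(F − F₀)/(F_pre − F₀)` is
not clipped to [0, 1]: under noise, clipping would bias group means
toward the interior. `front_position` summarizes a profile as the centre
of the most distal bin with index ≥ 0.5 (threshold configurable) and
returns `None` when nothing qualifies. The nerve axis is assumed
horizontal; `rectify(image, angle)` rotates by a user-supplied angle, but
automatic centreline tracing is out of scope.

## Tectal reinnervation

The uninjured hemisphere's band is segmented by Otsu thresholding; a
circle is fitted to the thresholded pixels (algebraic Kåsa initialization
refined by least squares on radial residuals — the algebraic fit alone is
biased ≈1 px along the symmetry axis of a half-annulus) and the band mask
is the thresholded foreground intersected with the annular shell
`[outer_r − thickness, outer_r]`, with `outer_r` the 99.5th percentile of
pixel distances from the fitted centre and thickness a config parameter.
The crushed-side band is constructed by reflecting that shell across the
vertical midline and restricting it to the same fold-angle support, so a
fully denervated (dark) band is still measured over the matching anatomy;
this assumes the hemispheres are mirror-symmetric about the image
midline. Crushed-side identity is metadata, never inferred from
intensity, which would bias toward the hypothesis.

Sectors: the angle from the dorsal pole (straight up) ventralward, folded
to [0°, 180°] regardless of lateral direction, split into equal thirds —
dorsal ≤ 60°, medial ≤ 120°, ventral beyond; boundary angles go to the
more dorsal sector. The assay names the three regions without defining
boundaries; equal angular thirds is the least-informative choice.

ΔF/F is crushed mean over uninjured mean (`mode="ratio"`, reaching 1 at
full recovery); `mode="delta"` gives `(crushed − uninjured)/uninjured`
for the alternative reading of the ratio. No background subtraction is
applied by default. Per fish, section values at rank r of n map to
position `r/(n−1)·100` percent of tectal length and are linearly
interpolated onto a fixed 20-point grid, adjusting for brain-size
variation. Group comparison: per sector, a two-way fixed-effects ANOVA
(group × position, with interaction) followed by Fisher's LSD — an
unadjusted t on the ANOVA mean-square error — at each position, flagging
positions with p < 0.05.

## Dorsal light response

Frames are binarized by Otsu; the largest connected component above a
minimum area is the fish; the body-axis angle is the principal-axis
orientation from second-order central moments, computed in an up-positive
frame so counter-clockwise tilts are positive, reported in (−90°, 90°].
Moments were chosen over manual angle annotation because they are
deterministic and testable; the 180° head/tail ambiguity is irrelevant to
tilt magnitude. A per-(fish, time point) mean requires ≥ 5 frames.
Recovery curves aggregate per-fish means (SEM over fish, never frames)
and are compared with a mixed two-way ANOVA (within: dpi, between:
group; no sphericity correction, noted in the result metadata) plus
Bonferroni-multiplied per-dpi pooled t contrasts. Missing (fish, dpi)
cells are an error — no imputation.

## Retinal quantification

One LoG blob detector serves two scales: cells (radius range 4–12 px by
default) and puncta (single scale at the spot σ). Cell detections closer
than one radius merge (union-find, centroid average); cells touching the
field border are excluded by default (configurable — whether border cells
were excluded in the original counting procedure is unknown, so the
choice is explicit). Each punctum goes to the nearest cell centroid
within `max_dist` (default cell radius + 2 spot σ, since RNAscope puncta
can sit over the cytoplasmic margin); ties go to the lowest cell id;
unassigned puncta are counted, so assigned + unassigned always equals the
total. Density is detections per calibrated field area. Colocalization
matches detections one-to-one greedily by increasing distance and reports
the matched fraction of the reference channel. All images are single 2-D
views; z-stack handling is out of scope.

## Enrichment statistics

**Normalization** is the median-of-ratios method: reference genes have
strictly positive counts in all samples; a sample's factor is the median
of count/geometric-mean ratios over reference genes, standardized to unit
geometric mean across samples so that normalization is idempotent.

**Differential expression** replaces a parametric negative-binomial fit
with a permutation test, deliberately: with a handful of replicates the
relabelling null requires no dispersion estimation and preserves the
downstream thresholds unchanged. The statistic is
`log2((mean₂ + 1)/(mean₁ + 1))` on normalized counts. When at most 1000
distinct label assignments exist they are enumerated and
`p = #{non-identity assignments with |stat| ≥ |observed|} / (#assignments − 1)`;
otherwise `n_perm` Monte-Carlo draws give `p = (b + 1)/(n_perm + 1)`.
The exhaustive convention excludes the identity labeling so that the test
attains its nominal size at small n: at 4 + 4 samples the achievable
two-sided p-values otherwise sit on a 2/70 grid and the test would reject
at barely half the nominal rate. The cost is slight liberality (size
≈ 0.057 at α = 0.05 for n = 4/group), which the calibration tests bound.
Note the granularity consequence: at n = 4/group the smallest achievable
p is 1/69, so BH FDR < 0.05 over thousands of genes is only reachable
with ≥ 6 replicates per group or Monte-Carlo nulls. Gene lists use strict
thresholds: up = log₂FC > 1 and FDR < 0.05 (both strict), down
symmetric.

**GSEA** ranks genes by signal-to-noise `(μ₂ − μ₁)/(σ₁ + σ₂)` on
log₂(normalized + 1), each σ floored at max(0.2·|μ|, 1e−8) — the usual
stabilization for small replicate counts; a plain mean-difference metric
is available. The enrichment score is the extremum of the weighted
Kolmogorov–Smirnov running sum (hit increments ∝ |score|^weight
normalized over the set, miss decrements 1/(N − m)); weight defaults to 1
(the classic weighted statistic). Ties in the ranking break by gene id
for determinism. The null permutes sample labels and recomputes the
ranking metric ("phenotype permutation"); when fewer distinct labelings
than `n_perm` exist, all of them (minus the observed) are enumerated.
NES = ES / mean(|permutation ES| of the same sign); p is the same-sign
permutation tail with the (b+1)/(n+1) correction; FDR is the
permutation-NES tail ratio (pooled null vs. observed), capped at 1 and
monotonized step-up so a more extreme NES never has a larger FDR. Gene
sets are intersected with the universe and filtered to [5, 2000] members
before analysis. Display thresholds follow the study design: FDR < 0.05
by default, < 0.25 for low-powered comparisons.

**Intersection.** The three-way "common genes" filter takes |fold
change| > 1.5 in all three comparisons, strict. "1.5" is interpreted on
the linear signed-fold scale (|log₂FC| > log₂ 1.5 ≈ 0.585) with a
`scale="log2"` switch for the alternative reading — the two cannot be
distinguished from the assay description alone.

**ORA.** Upper-tail hypergeometric `P(X ≥ k)` for an n-gene list hitting
k of an m-gene set in an N-gene universe, enrichment ratio
`(k/n)/(m/N)`, BH across sets. **ΔΔCt**: technical replicates are
averaged per (sample, gene); ΔCt = Cq_target − Cq_reference,
ΔΔCt = ΔCt − mean ΔCt of the control group, fold = 2^(−ΔΔCt).

## Statistical battery

Normality is the one-sample KS test against a normal with estimated mean
and SD using the Lilliefors-corrected p-value (the naive KS p with
estimated parameters is far too conservative to be useful as a
pre-test). Equality of variances is Brown–Forsythe (median-centred
Levene). The t-test is pooled-variance two-tailed. One-way ANOVA uses
pairwise pooled t post hocs with Bonferroni multiplication capped at 1.
Two-way ANOVA is fixed-effects with interaction (type-II sums of
squares); Fisher's LSD builds unadjusted t statistics on the ANOVA MSE;
a single observation per cell is rejected as degenerate. The
repeated-measures analysis is a mixed ANOVA on complete cases with
Bonferroni per-level contrasts and no sphericity correction. Degenerate
inputs (constant samples, < 3 observations, incomplete subjects) raise
errors rather than returning misleading numbers.

## Problem sizes and calibration checks

The test suite calibrates every battery test and the DE permutation test
under null simulations (2000 replicates each; 2000 genes × 4 + 4 samples
for DE), verifies the GSEA spike ranking over 20 replicates of a
1000-gene universe with 20 null decoy sets of 25 genes drawn from the
non-spiked complement, and checks all closed-form oracles exactly. These
sizes give Monte-Carlo standard errors comfortably inside the asserted
tolerances while keeping a full run in a few minutes.

## Known limitations

- The tectum segmentation assumes mirror-symmetric hemispheres and a
  roughly circular band; strongly oblique sections violate both.
- The tilt estimator needs a single, thresholdable fish; occlusions,
  reflections and multi-fish scenes are out of scope.
- The DE permutation test is slightly liberal at very small n (see
  above) and, like all relabelling tests, loses FDR resolution when few
  distinct labelings exist.
- GSEA NES saturates at small sample sizes because partially aligned
  relabelings retain true signal, inflating the per-set null; rankings
  remain stable but NES magnitudes are not comparable across designs.
- ΔΔCt assumes perfect (2-fold per cycle) amplification efficiency for
  both target and reference.
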