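# Methods

## Problem and scope

`octaquant` quantifies en-face OCTA angiograms of the optic nerve head
(ONH) and compares cohorts of eyes with arteritic (AAION) and
non-arteritic (NAION) anterior ischemic optic neuropathy against their
contralateral eyes and healthy controls. The pipeline computes two
image parameters per vascular plexus (radial peripapillary capillaries
RPC, superficial SCP, deep DCP, choriocapillaris CC):

* **Vessel density (VD)** — fraction of vessel pixels after
  mean-threshold binarization;
* **Vessel tortuosity (VT)** — mean arc/chord ratio of the branches of
  the skeletonized vascular network, organized by Strahler stream
  ordering rooted toward the optic disc.

Both are also computed per disc-centered quadrant
(superior/inferior/nasal/temporal) for the RPC and SCP layers, where
they feed a quadrant sub-analysis and a concordance analysis against
Humphrey visual-field defects. Device-side processing (plexus
segmentation, quality index, RNFL extraction from structural OCT) is
out of scope: those arrive as numbers in the manifest and eye tables.

## Image metrics

**Binarization.** The threshold is the arithmetic mean intensity of the
analyzed area; a pixel is vessel iff intensity ≥ threshold. The
inclusive rule keeps boundary behavior deterministic (a constant image
becomes all-vessel, not empty). Intensities are normalized by the
input dtype maximum, not per-image min–max, so the mean threshold keeps
one meaning across a cohort. VD is vessel pixels / total pixels of the
analyzed area; the alternative reading "white / black" was rejected
because clinically reported VD values (≈ 0.28–0.55) are area fractions
and the ratio reading would exceed 1 near half coverage.

**Skeleton graph.** The binary map is thinned (Zhang–Suen, via
scikit-image) to an 8-connected, one-pixel skeleton; thinning preserves
the 8-connected component count. Skeleton pixels with one neighbor are
endpoints, with ≥ 3 neighbors junction pixels; adjacent junction pixels
are merged into one junction node because thinning leaves 2-pixel (and
at dense crossings larger) junction clusters. Branches are the maximal
node-free pixel paths between nodes; an isolated cycle receives one
artificial node at its topmost-leftmost pixel. Non-thin input is
rejected by a fixed-point test: pixels that a second thinning pass
would remove *and* that lie in a solid 2×2 block indicate genuine
thickness (cosmetic corner pixels of hand-drawn loops are tolerated).

**Roots and Strahler orders.** ONH vessels radiate from the disc, so
each connected component is rooted at its endpoint nearest the
operator-supplied disc center (ties to the smaller (row, col);
components without endpoints root at their artificial loop node or, for
junction-only shapes, the smallest node pixel). Capillary networks
contain loops, so before ordering, each cycle is broken at its shortest
branch (maximum spanning forest under path length; among equal lengths
the branch with the smaller terminal pixel is removed). On the
resulting tree, leaf branches have order 1 and a parent takes the
maximum child order, plus one when at least two children attain it;
removed branches keep order 1 and stay eligible for tortuosity.

**Branch tortuosity.** Each branch scores arc length / chord length
(≥ 1; exactly 1 for straight vessels). Two length fields are kept:

* `path_length_px` — chain-code sum (1 per orthogonal, √2 per diagonal
  step), the conventional raw measure;
* `arc_length_px` — length of the moving-average-smoothed pixel path
  (window 5, endpoints pinned), which is what tortuosity uses.

The smoothed estimator is used because the chain-code sum overestimates
smooth-curve length in an orientation-dependent way (up to ≈ 8 % at
22.5°, ≈ 5.5 % averaged over orientations), which would bias every
curved branch; the smoothed polyline is exact on axis-aligned and
diagonal straight segments, within ≈ 0.2 % on a radius-100 px
semicircle, and within 10⁻⁵ of quadrature arc length on a rasterized
sine. Loops (zero chord) are flagged degenerate and excluded.

**Aggregation.** Image- or quadrant-level VT is the unweighted mean of
branch tortuosities over branches whose midpoint lies in the mask and
whose chord is at least `min_chord_px` (default 3 px — shorter chords
are dominated by quantization). A length-weighted mean is available by
flag; the unweighted mean is canonical because one aggregation rule
must be fixed for reproducibility. A region with no eligible branch is
reported as NaN, never silently 0.

**Quadrants.** The standard clinical RNFL convention: the two ±45°
diagonals through the disc center split the grid into S/I/N/T 90°
sectors. Pixels exactly on a diagonal go to the vertical sector; the
disc-center pixel counts as superior. In upright fundus orientation the
nasal sector is image-right for OD and image-left for OS, overridable
per manifest because vendor export orientations differ. An optional
circular disc-exclusion mask (radius in mm) is available and off by
default; whether the source analysis excluded the disc is unknown.

**Visual-field mapping.** Ocular optics invert the retinal projection,
so superior field maps to inferior retina and temporal field to nasal
retina. With quadrants named anatomically the map is
laterality-independent and involutory; all concordance statistics
compare flags in retinal space.

## Known limitation: the absolute VT scale

Clinically reported VT values for healthy eyes (≈ 7–8.4) are far above
any arc/chord ratio of real capillaries (≈ 1.05–1.3); they come from a
proprietary analysis script whose exact formula is not public and
cannot be reconstructed. This package implements the literal geometric
definition (skeleton path vs Euclidean distance). Consequently the
clinical VT magnitudes are treated purely as cohort-level distribution
parameters in the synthetic tier and are never used as image-level
ground truth; image-tier validation compares measured VT against the
generator's analytic arc/chord ratios instead.

## Synthetic data

Two deliberately separate tiers, because of the VT-scale issue above.

**Image tier.** Vascular trees grown from roots on a circle around the
grid center: each branch is a straight segment perturbed by a
perpendicular sine (amplitude 4 px, wavelength 60 px by default) with
an integer number of half-periods so branches connect continuously;
lengths are Normal(45, 10) px, branching depth 3, rasterized at 3 px
width. Defaults target a vessel fraction of 0.35, roughly what
peripapillary angiograms occupy. The generator records each branch's
analytic arc and chord lengths, giving exact ground truth for VD and
VT recovery tests. Rendering assigns vessels intensity 1.0 over a 0.2
background, adds Gaussian speckle (SD 0.05) and optional blur, and
clips to [0, 1]. What this tier does **not** emulate: OCT speckle
statistics, projection artifacts, vessel caliber variation, disc edema;
passing tests therefore show metric correctness on clean geometry, not
robustness to device artifacts.

**Cohort tier.** Per-eye records for the five groups at n = 15/group,
drawn from the published summary distributions: group-level VD/VT
Normal(mean, SD) (VD truncated to [0, 1]; printed SDs are floored at
0.005 because a rounded "0.00" cannot be literal). Diseased eyes get
1 affected retinal quadrant (NAION) or 1–2 with equal probability
(AAION) — involvement is reported as more extensive in AAION.
Quadrant metrics follow a hierarchical model: an eye-level stratum mean
drawn from the affected/unaffected stratum distribution, plus
independent within-eye quadrant noise (SD 0.02 for VD; the stratum SD
for VT). The hierarchy matters: the published ± SDs describe
between-eye spread of stratum means, and drawing quadrants i.i.d. from
them would shrink per-eye means below the published spread and distort
every downstream test. The within-eye SDs were fixed once, by
simulation, so that the 2-SD normative classifier retains high
specificity on unaffected quadrants. The defect structure encodes the
study's signature: VD is reduced **focally** (unaffected quadrants draw
from near-normal distributions) while VT is reduced **globally**
(unaffected quadrants draw from already-reduced distributions).
VF-defect flags are the affected set mapped to field space with each
flag flipped with probability 1 − 0.95; the 0.95 concordance default
places the pooled Kendall tau between VF defects and VD impairment
near the reported ≈ 0.85 (verified by simulation, not assumed).
RNFL quadrant values use a focal model (unaffected ≈ 105 ± 10 µm,
affected 65/75 ± 12 µm for AAION/NAION) since per-quadrant RNFL
distributions were not published; global RNFL is drawn separately from
the published global distributions.

## Cohort statistics

* **Omnibus:** classical one-way ANOVA (F = MSB/MSW, df (k−1, N−k)).
* **Pairwise battery:** the seven clinically reported contrasts per
  metric, Bonferroni-adjusted with m = 7. The per-pair test defaults
  to Welch's t because group SDs differ several-fold; the SPSS-style
  pooled-MSW post hoc (df = N − k) is available as `method="pooled"`.
* **Normative limits:** control mean − 2 SD per quadrant-level metric
  and quadrant (k = 2 is the conventional normative cut and is
  configurable); a value is impaired iff strictly below the limit.
* **Quadrant sub-analysis:** strata are the affected / unaffected
  visual-field quadrants (mapped to retina); the unit of analysis is
  the per-eye stratum mean, avoiding pseudo-replication of quadrants
  within an eye; Welch t over the eight comparison rows, Bonferroni
  m = 8.
* **Concordance:** per diseased eye and quadrant, the retina-mapped VF
  flag is paired with the impairment flag; pairs are pooled across eyes
  (the per-eye-tau-averaged alternative is noted but not default), and
  Kendall tau-b is reported for RNFL, VD(RPC) and VT(RPC). Tau-b
  because binary indicators are tie-heavy. When a flag vector has zero
  variance (e.g. VT impaired everywhere) tau is reported as NaN rather
  than a fabricated value.

## Reproduction behavior and a known red result

With the published group parameters at n = 15/group, simulation
reproduces: all disease-vs-control and disease-vs-contralateral
contrasts significant; contralateral-vs-control non-significant; the
quadrant-table dissociation (unaffected-quadrant VT significant vs
controls in every run, unaffected-quadrant VD predominantly
non-significant); and
pooled tau(VF, VD) ≈ 0.77–0.80 with tau(VF, VT) far lower. One
published contrast does not reproduce at high power: AAION vs NAION for
VT SCP (3.81 ± 0.38 vs 4.27 ± 0.42) has a Welch-t noncentrality of
only ≈ 3.1 at n = 15, so Bonferroni-corrected significance at p < 0.01
occurs in only ≈ 30–40 % of simulated cohorts (≈ 55 % with the pooled
post hoc). No test choice at these printed means/SDs can make that
contrast near-certain; the corresponding acceptance test is left
failing by design rather than weakened.

## Problem sizes and numerics

Default validation sizes: 256² px phantoms, 20 seeds for VD recovery,
10 for VT recovery, 100 random trees for Strahler, 500 null cohorts for
type-I calibration, 100 cohorts for pattern reproduction, 50 for
concordance — chosen to give stable Monte-Carlo estimates at
single-core desk scale. All randomness flows through
`numpy.random.default_rng` seeds; fixed seed ⇒ byte-identical outputs
end-to-end. Degenerate inputs (empty masks, empty skeletons, zero
chords, zero-variance samples) raise explicit errors rather than
returning sentinel numbers.
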