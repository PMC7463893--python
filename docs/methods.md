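# Methods

This note documents the analysis model, the synthetic-data model standing in
for the unavailable microscopy data, the numerical conventions, and the
limits of what the validation shows.

## The voxel-cube analysis

The pipeline quantifies marker expression in 3-D cultures too dense for
instance segmentation.  Its unit of analysis is the *voxel cube*: a
non-overlapping 32 × 32 × 16-voxel block (x, y, z), tiled from the volume
origin in half-open intervals, with trailing margins that do not fit a whole
cube dropped so every cube has the same 16 384-voxel denominator.

**Foreground.**  All quantification is gated on a DAPI-derived mask.  The
DAPI channel is smoothed with an anisotropic Gaussian, σ = (4, 4, 0) pixels
in (x, y, z).  σ_z = 0 is deliberate and literal: smoothing is plane-wise,
no intensity crosses z before thresholding, matching the strong z-anisotropy
of 1-µm-step confocal stacks.  The wide in-plane sigma dilates the mask into
the perinuclear cytoplasm, where membrane (CEA), matrix (Coll4) and
metabolic markers actually reside.  One global Otsu threshold is computed
over the whole smoothed volume (256 histogram bins spanning min–max);
voxels *at or above* the threshold are foreground (ties are foreground, so
tests can be exact).  Background subtraction follows segmentation: for every
channel (DAPI included) the median intensity of mask-false voxels is
subtracted, clipped at zero.  The median is used because residual foreground
contamination of the background sample is expected; subtraction after
thresholding follows the order in which the steps are described for the
original workflow, and the threshold is recorded in the mask object for
audit.

**Cube statistics.**  A cube is included only when strictly more than 50%
of its voxels are foreground; a cube at exactly 8192/16384 is excluded, and
the boundary is tested exactly.  For included cubes, each channel's mean is
taken over foreground voxels only — background voxels inside an included
cube never contribute.  Cubes of the (by default five) cavities of a
condition are pooled with per-record provenance.

**Discrimination.**  The reference threshold is the CEA value bounding 95%
of fibroblast mono-culture cubes.  It is computed as a nearest-rank-above
quantile — the ⌈q·n⌉-th order statistic of the cube CEA means — because the
definition is a *coverage* statement: the cutoff must be an observed value
with at least q of the cubes at or below it.  Realized coverage is
therefore ≥ q by construction and equals q when q·n is integral and values
are distinct.  Classification is `> cutoff → putative_cancer`,
`≤ cutoff → putative_fibroblast`; a cube exactly at the cutoff is
*contained* and lands on the fibroblast side.  Every classified table is
reported with its compartment sizes: a quantile threshold near the top of
the fibroblast distribution is intrinsically skewed toward the brighter
population, and that skew must stay visible.

**Volumetric summary.**  The per-µm³ path sums a background-subtracted
channel over all foreground voxels and divides by their physical volume
(n·dz·dy·dx).  The foreground volume, not the imaged volume, is the
denominator: empty cavity space would otherwise dilute the ratio.  This
path has no cube partition and no inclusion rule, which makes it free of
the discrimination skew — it is the control analysis used when the cube
split is suspect.

**Colocalization.**  Thresholded Pearson correlation with Costes
randomization.  Automatic thresholds: candidate T_a values descend from
max(a) in 256 levels; T_b follows the orthogonal (total-least-squares)
regression of b on a; the scan stops at the first pair whose
*below*-threshold correlation is ≤ 0 or undefined.  The observed statistic
is Pearson's R over voxels with a ≥ T_a or b ≥ T_b.  Significance:
channel a is shuffled in 3 × 3-pixel in-plane blocks ("PSF-sized"; z-planes
are never mixed, since the PSF scale is a single in-plane figure), with
ragged edge blocks permuted within their own shape groups so each plane's
histogram is conserved exactly; R is recomputed against the observed
thresholds for each shuffle.  The add-one rule
p = (1 + #{R_rand ≥ R_obs}) / (1 + n) keeps p strictly positive; with the
classical 10 randomizations the smallest attainable p is 1/11, and a larger
n is a config knob.

**2-D ROIs.**  Monolayer images are split by intensity only: Otsu on
smoothed DAPI (σ = 2 px, a declared free parameter) gives the cell area;
Otsu on CEA within the cell area gives the cancer islets (a flat CEA
channel gives an empty cancer compartment, not an error); the fibroblast
compartment is the cell area minus the islets dilated by 2 px (guard band
against edge bleed).  The human analyst's morphological criteria (islet vs
spindle shape) are *not* formalized — a documented simplification.
Compartment means are background-subtracted (median outside the cell area);
an empty compartment is a labeled missing value, never a silent zero.  SEM
is across replicate images, not pixels.

## The synthetic-stack generator

No image data are published for this assay, so the generator is the test
bed; its defaults define the conditions every validation runs under.  All
intensity levels are stand-ins — plausible for antibody-stained dense
cultures, but not measured from real specimens — and are configuration, not
constants.

* **Populations.**  Cancer-like: near-round nuclei, mean semi-axis 3.5 µm,
  DAPI 300 ± 45, CEA 200 ± 30, Coll4 20 ± 5.  Fibroblast-like: elongated
  nuclei (axis ratio 2.3 ± 0.3), mean semi-axis 4.5 µm, DAPI 100 ± 20
  (≈ 3× DAPI contrast), CEA 50 ± 10, Coll4 80 ± 12 (≈ 4× contrasts).  DAPI
  is nuclear; all other markers fill a 2.5-µm perinuclear halo.
* **Geometry.**  Cells occupy a dense cylindrical cell mass (radius 0.44 of
  the XY extent) surrounded by empty cleared medium, emulating a microcavity
  culture inside its imaged field.  Nuclei are placed by rejection sampling
  with collisions tested on a 0.85-scaled core, so they pack to touching —
  the regime in which instance segmentation genuinely fails.  Reference
  packing densities are 8.5 × 10⁻⁴ nuclei/voxel (cancer) and 4.2 × 10⁻⁴
  (fibroblast); mono-cultures use the full density of one population,
  co-cultures half of each, mirroring equal-count co-seeding.
* **Mixing.**  In co-cultures the fibroblasts occupy compact circular
  clusters interspersed in the cancer colony (`interspersed`), or fewer,
  tighter, denser islets (`islets`, the spheroid-like regime).  Cluster area
  is allocated by packing-normalized share so each population keeps its
  mono-culture local density — otherwise co-culture fibroblast cubes would
  be systematically brighter than the mono-culture cubes that define the
  reference line, which would be an artifact of the generator, not a
  property of the method.
* **Image formation.**  Clean volume → narrow Gaussian PSF surrogate
  (σ = (1, 1, 1.5) px in x, y, z) mixed with a wide scattered-light
  component (25% of the signal through σ = (6, 6, 3) px): dense cleared
  specimens show substantial out-of-focus light, and without it a dense
  cell mass cannot reach the >50%-foreground inclusion anywhere.  Then a
  constant background offset (10), Poisson shot noise (scaling 1 photon per
  intensity unit) and Gaussian read noise (σ = 2), clipped at zero.
* **Ground truth.**  A label volume (background / cancer / fibroblast over
  nuclei + halos), a nucleus-only mask, and nucleus centers.  Same seed ⇒
  bit-identical stacks; per-cavity seeds derive from one master seed via
  `SeedSequence`.

**What the generator does not emulate:** real PSF structure (only Gaussian
surrogates), spectral bleed-through, photobleaching and depth-dependent
attenuation, nuclear texture, cell shapes beyond ellipsoid + halo, and any
true biological intensity distribution.  Passing tests therefore demonstrate
that the *pipeline* recovers what the generator encodes — contrasts,
orderings, coverage — not that the biology of real cultures would be
recovered with these numbers.

## Validation panels and problem sizes

Stacks are desk-scale stand-ins for 1024 × 1024-px acquisitions: default
cavities are 192 × 192 × 32 voxels (a 6 × 6 × 2 cube grid), mono-culture
reference panels 256 × 256 × 32 (5 cavities, ≥ 200 included cubes), and
co-culture classification panels 512 × 512 × 32 with a single contiguous
fibroblast zone (radius 160 px).  The wider classification crops are a
fidelity choice, not a convenience: at 192–256 px the fibroblast-zone
*boundary* cubes (genuinely mixed, ambiguous by construction) outnumber
interior cubes several-fold more than they would at acquisition scale, and
boundary-cube accuracy measures the scale-down, not the classifier.

The contrast sweep (CEA contrast 2×/4×/8×, fibroblast CEA level varied)
holds the deployed reference line — computed from the default-contrast
mono-culture panel — fixed.  Recomputing the reference at every contrast
would make accuracy contrast-independent, because a quantile threshold
adapts to whatever population it is computed on; with the reference fixed,
the sweep measures the classifier's sensitivity to the separation it
actually relies on.

The volumetric ordering panel encodes the reported autophagy biology:
fibroblast marker staining doubles in co-culture (40 → 80) with cancer
cells contributing at an intermediate level (60), so the co-culture per-µm³
value must exceed the fibroblast mono-culture value.  The tracker/TMRM
panel co-places the TMRM-like channel with the cancer population's tracker
halos only, so r(tracker_cancer, TMRM) must exceed r(tracker_fibroblast,
TMRM) for every seed.

## Numerical conventions

* Axis order is fixed to (Z, Y, X, C) internally; 0-based indices, half-open
  intervals everywhere.  Cube shape arguments are (x, y, z) to match the
  method's "32, 32, 16" convention and are transposed internally.
* Otsu: 256 bins over min–max; the returned threshold is the interior bin
  *edge* maximizing between-class variance; when several edges tie exactly
  (an empty gap between two separated classes makes the variance flat), the
  middle edge of the maximal plateau is returned — deterministic and
  centered between modes.  Constant input raises a degenerate-histogram
  error; callers that want an all-background fallback must say so
  explicitly.
* Comparisons at thresholds: foreground is ≥ the Otsu threshold; cube
  inclusion is > the foreground fraction; cancer-side classification is >
  the CEA cutoff.  Each boundary is tested at the exact tie.
* Voxel-size metadata: OME header wins over the caller's argument; absence
  of both is a logged warning and 1 µm isotropic, because only the per-µm³
  path needs physical units.
* Missing SEM (single replicate) is NaN/None, never 0.

## Known limitations

* The discrimination split inherits the documented skew toward the
  CEA-bright population; compartment sizes are always emitted so it stays
  visible, but no correction is attempted.
* With plane-wise smoothing, the polar z-planes of an *isolated* nucleus
  carry almost no in-plane mass and fall below the global threshold; in
  dense stacks neighboring cells fill the gap and nucleus-voxel recall is
  0.97–0.99 at default conditions.
* Costes thresholds assume an approximately linear b-vs-a relation; with
  strongly nonlinear coupling the descending scan still terminates but the
  thresholds lose their interpretation.
* The 2-D ROI split formalizes only the intensity criteria; cultures whose
  populations differ mainly in morphology will not be separated.
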