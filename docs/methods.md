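# Methods

## Scope and model

carposcan quantifies radial pigmentation patterns in single-fruit
cross-section images and carries the derived trait through to genetic
analysis. The chain is: segmentation → annular CIELAB a\* histograms →
PCA trait → genotype × year aggregation → REML/BLUP → haplotype tests.
A synthetic image generator with known genetic ground truth closes the
loop for validation. Everything outside this chain (QTL mapping proper,
haploblock construction, omics) is out of scope; the BLUP table is the
hand-off point.

## Segmentation and radial geometry

Images are reduced to gray with ITU-R BT.709 luma weights and split by
Otsu's threshold. Foreground polarity is decided by the image border:
the class occupying less than half of the border pixels is taken as
fruit, which handles both light-on-dark and dark-on-light setups without
configuration. Holes (carpel cavities, specular highlights) are filled
before keeping the largest 8-connected component, because they must not
fragment the mask. Failure modes are explicit errors: no component of at
least `min_area` (default 500 px) pixels, or a component touching all
four borders.

The normalized radial coordinate divides each pixel's distance from the
area centroid by the boundary distance along its ray (`radius_mode =
"ray"`, default). Boundary distances are sampled by marching outward in
0.5 px steps along `n_rays` = 720 discrete directions and interpolating
linearly (and periodically) between directions — deterministic and
resolution-independent. A `scalar` mode divides by the equivalent radius
√(area/π) instead, mirroring a plain region-properties implementation;
`ray` is the default because it honors size-invariance for non-circular
fruit. A mask whose centroid is not itself a mask pixel (non-star-shaped
segmentation) raises an error directing the user to inspect the
segmentation rather than silently producing nonsense radii.

Skin pixels at r ≈ 1 are included by default; `peel_erode_frac` strips
an outer fraction of the radius and rescales r when peel exclusion is
wanted.

## Color features

Rings are inner 30–55 %, medium 55–75 %, outer 75–100 % of the radius;
the carpel zone below 30 % is excluded. Ring intervals are half-open
[lo, hi) with the outer ring closed above, so boundary pixels whose
discretized r slightly exceeds 1 still belong to the outer ring and the
three rings plus carpel zone exactly partition the mask.

a\* histograms use 10 equal bins on [0, 60]; values outside the range
are clipped into the end bins rather than dropped, so each ring's
frequencies are normalized over all of its pixels and always sum to 1.
Normalization is per ring by default (`normalize = "global"` normalizes
the concatenated 30 bins jointly). The mean/SD a\* descriptors are
computed on unclipped a\* over the union of the three rings — the same
pixels the histograms see. Conversion to CIELAB is the standard sRGB
(D65) transform via scikit-image; the test suite pins it against an
independently coded closed-form oracle.

## Trait derivation

PCA is fit on fruit-level rows pooled across years, mean-centered but
not variance-scaled: all 30 features are frequencies on one common
scale, and scaling would inflate near-empty bins. Components follow a
deterministic sign convention (largest-magnitude loading positive).
Axis naming is data-driven: intensity = argmax |r| with mean a\*,
pattern = argmax |r| with SD a\* among the remaining components, with
the pattern component re-oriented so higher scores mean higher a\*
dispersion. PC2 is the documented expectation for the pattern axis on
real data, but the selection is not hard-coded — on synthetic
populations the pattern axis typically lands on PC3, with PC2 absorbing
residual curvature of the intensity response (see below). If both
argmaxes coincide the code raises "axes not separable" instead of
guessing.

Genotype × year phenotypes are plain means of the available fruit
scores per cell (count recorded). For the redness filter, the
per-genotype mean a\* is taken over all of its fruit rows across years —
the most stable level — and the filter retains genotypes with mean
a\* strictly greater than 10 *and* the focal marker present, emitting an
audit row (with reason) for every exclusion, including "no marker data".

## Mixed model

The phenotype model is y = Xβ + Zu + e with year as categorical fixed
effect (first year = reference) and genotype i.i.d. random; no
genotype × year interaction is fitted because tree and genotype effects
are confounded in the motivating design. Variance components are
estimated by REML with the likelihood profiled to a bounded 1-D search
over log λ, λ = σ²g/σ²r (search window e^±16, `scipy`
bounded Brent). Because genotype is the only grouping factor,
H = I + λZZᵀ inverts analytically through per-genotype sums (Woodbury),
so each likelihood evaluation is O(n) and fits are exact at any
population size. The λ = 0 boundary is evaluated explicitly; if it wins,
σ²g is set to 0 and flagged in the convergence record. BLUPs are
u_i = λ s_i/(1 + λ n_i) with s_i the genotype sum of H⁻¹-weighted
residuals; with an intercept in X they sum to zero identically.
Balanced designs reproduce the closed-form ANOVA estimator and the
shrinkage formula σ²g/(σ²g + σ²r/n) to 1e-6 (tested), and unbalanced
fits match R's lme4 on a frozen fixture. h² = σ²g/(σ²g + σ²r) on the
per-observation scale of the fitted table, exactly the intra-class
correlation formula; the degenerate all-equal-data case yields
σ²g = 0 and h² = 0, while h² with both components zero is an error when
requested directly.

Haplotype effects on BLUPs are tested for two groupings — canonical
diplotype (sorted haplotype pair) and presence/absence of a focal
haplotype — by one-way ANOVA and Tukey–Kramer HSD. The Tukey adjusted
p-values use the studentized-range distribution directly (scipy), which
lets degenerate inputs (zero within-group variance) be handled exactly:
equal means give F = 0, p = 1; separated means with zero variance give
p = 0. The implementation is cross-checked against statsmodels'
`pairwise_tukeyhsd` in the tests. Groups with fewer than 2 members are
dropped from testing (with a warning) but kept in the descriptives.
Letters come from the insert-and-absorb algorithm, guaranteeing that two
groups share a letter iff their adjusted p ≥ α (= 0.05 throughout).

## Synthetic data

`render_fruit` draws a roughly circular fruit (boundary = radius × (1 +
irregularity × smooth low-order harmonic perturbation)) on a dark
background, a reserved light-brown carpel zone below r = 0.30, and flesh
whose a\* follows a logistic fading profile a_white + depth ·
logistic((r − ρ)/w) plus Gaussian pixel noise — the simplest smooth
monotone transition consistent with white-inside/red-outside fading.
L\* and b\* are held fixed so a\* is the only controlled color axis,
matching the pipeline's exclusive use of a\*. They are fixed at
L\* = 60, b\* = 15: at this lightness the entire working a\* range
[−15, 60] lies inside the sRGB gamut, so rendering is invertible (the
often-natural choice L\* = 75 clips every a\* above ~37, which would
corrupt the outer flesh at the default a_red = 40). Gamut clipping is
counted per image by round-tripping the written pixels back to Lab.

`simulate_population` draws the latent value of fruit k of genotype i in
year j as g_i + year_j + e_ijk (g ~ N(0, σ²g), e ~ N(0, σ²r); defaults
σ²g = 0.56, σ²r = 0.44, year effects (0, 0.3, −0.3)) and maps it
affinely onto the fading boundary ρ (default) or onto depth, clipping to
the valid range and counting clips. An independent per-genotype
intensity shift (Gaussian, sd `intensity_sd`) moves a_white and a_red
jointly, emulating overall-redness differences between genotypes — the
second, non-genetic factor of real populations. All draws come from
counter-keyed substreams of the scenario seed (per genotype, per fruit,
per image), so enlarging a population never reshuffles previously
generated images.

### Calibration of the default scenario

The default factor scales are deliberately in the small-perturbation
regime: intensity shift sd 3 a\* units, latent-to-ρ slope 0.035 (so the
fading boundary spans roughly ±0.1 of the radius across a population),
and within-flesh pixel noise sd 3 a\* units with transition width
w = 0.05. Two considerations fix these values. First, realism of the
measurement: photographed flesh has broad within-tissue a\* dispersion,
and a noise sd of ~half the 6-unit bin width makes bin occupancies
respond smoothly to profile changes, as they do in real images. Second,
identifiability of the construct: when factor excursions are large
relative to the bin width, the histogram response becomes strongly
nonlinear (a level shift sliding two sharp peaks across fixed bin edges
is a sawtooth in bin-mass space), the nonlinear variance spreads over
many principal components, and no single axis tracks either descriptor —
a property of coarse fixed-bin histograms worth knowing when applying
the method to populations with very large mean-a\* ranges. At the
default scales the intensity axis correlates with mean a\* at |r| ≈
0.96–0.98 and the pattern axis with SD a\* at r ≈ 0.73–0.94 across
seeds, and the full image → BLUP chain recovers true genetic values at
r ≈ 0.84 for 100 genotypes × 3 years × 4 fruits.

### What the simulator does not emulate

Lighting gradients and shadows, peel/skin texture, color-chart
calibration error, non-elliptic lobed fruit outlines, bruises and
vascular structures, and any L\*/b\* variation. Passing tests therefore
demonstrate correctness of the measurement and statistical chain under
controlled conditions, not robustness to photographic artifacts — real
deployments should keep acquisition standardized.

## Numerical choices and problem sizes

Histogram bins are half-open with the last bin closed; ties at interior
edges go up. The REML search is deterministic; PCA uses full SVD with a
fixed sign convention, so every pipeline output is byte-reproducible
from the config seed (CSV floats are written at 6 significant digits).
Test and validation runs use desk-scale populations — 200 fruits for
axis recovery, 1 200 images (100 genotypes × 3 years × 4 fruits,
radius ~60 px) for end-to-end recovery, 50 replicates of 256 genotypes
× 3 years for h² calibration — sizes at which the checked quantities
are statistically stable while a full run of everything stays in the
tens of seconds on one core.

## Known limitations

- The radial model assumes a star-shaped fruit section; heavily lobed
  or cut-damaged sections are rejected rather than approximated.
- Fixed bins on [0, 60] saturate for a\* outside that range (clipped
  into end bins); populations with extreme chroma would need a wider
  range in the config.
- The two-component mixed model cannot separate genotype from tree or
  location effects; h² is repeatability across years under the stated
  confounding.
- Descriptors are limited to mean and SD of a\*; no hue, texture, or
  L\*/b\* descriptors are implemented.
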