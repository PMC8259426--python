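# Methods

`wingvar` implements a landmark-based geometric-morphometric analysis of
how an environmental stressor (a sublethal insecticide exposure) shifts
trait means and inflates the layered variance structure of insect wings:
phenotypic plasticity (treatment effects on means), environmental
canalisation (among-individual variance within genotype), genetic
canalisation (among-family variance), and developmental stability
(fluctuating asymmetry, FA). The experimental design it assumes is a
split full-sib-family design: each family contributes insects to a
control and a treated group, every insect has a left and a right wing,
and each wing is digitised twice so that measurement error can be
separated from FA.

## Geometry

A wing is a configuration of k = 10 two-dimensional type-I landmarks.
Size is centroid size, CS = sqrt(sum_i ||x_i − x̄||²). Shape is extracted
by a generalised full Procrustes fit: each configuration is centred,
scaled to unit CS, and iteratively rotated (rotations only) to the
running consensus, which is re-estimated as the normalised mean until its
change falls below 1e-10 (maximum 100 iterations; convergence is reached
in < 10 on data at this scale). Left wings are mirrored about the
vertical axis *before* the fit, driven by the side label in the metadata
— free per-configuration reflection is never allowed, because it would
silently absorb directional asymmetry. All specimens, sides, replicates
and treatments enter one joint fit so that coordinates are comparable
across every stratum of the analysis.

Because GPA is defined only up to a common rotation, the consensus
orientation is standardised: its major principal axis is rotated onto the
x-axis with the sign fixed so that landmark 1 has non-negative x. This
makes outputs reproducible across runs and input orders.

Aligned configurations are orthogonally projected to the tangent plane at
the consensus by removing the components along the four similarity
directions (the consensus itself for scale, its 90°-rotated copy for
rotation, and the two translations), giving 2k-dimensional tangent
vectors of rank 2k − 4 = 16. Shape PCA is the eigendecomposition of the
tangent covariance matrix; the first 16 PC scores span the full shape
space and serve as the multivariate response.

## Mean models

Wing size is analysed with an ANOVA on specimen-level CS (the mean of the
four wing measurements, avoiding pseudo-replication), shape with a
MANCOVA on the 16 PC scores using Pillai's trace and the standard F
approximation. Both use sequential (Type I) sums of squares in the fixed
order treatment, family, treatment × family (CS entering last as the
covariate in the shape model). The design is unbalanced, so the order
matters; it is part of the contract and deliberately places the
treatment main effect first. Size ANOVAs can be run per sex or pooled;
shape models pool sexes. No multiple-testing correction is applied.

A canonical variate analysis with family × treatment as the grouping
factor solves the generalised eigenproblem of the between-group-means
covariance against the pooled within-group covariance; scores are scaled
to unit within-group variance. A rank-deficient within matrix triggers an
automatic projection onto its leading principal components (logged).
Reaction norms are reported numerically: per-family control mean, treated
mean and difference, plus the variance of the differences across families
as a parallelism summary (zero when all norms are parallel; inflated by
genetic variation in plasticity).

## Asymmetry decomposition and FA10

For every family × treatment cell, a two-factor crossed ANOVA with
effects individual, side and individual × side is computed, the two
digitisation replicates forming the error stratum: a regular ANOVA for
CS, a Procrustes ANOVA for shape (sums of squares pooled over tangent
coordinates, degrees of freedom multiplied by 16). Side is treated as
fixed and individual as random (side is tested over the interaction, the
interaction over the error). The among-individual mean square estimates
individual variation; the measurement-error-corrected FA index is

    FA10 = (MS_interaction − MS_error) / 2.

Negative FA10 values (interaction MS below error MS) are reported as-is
with a flag, never truncated at zero — truncation would bias the
cross-family rank correlations downstream. Like mean squares are compared
between treatments per family with a two-sided F test,
p = 2·min(P(F ≥ f), P(F ≤ f)), since no direction is pre-specified per
family. Genetic variation is the among-family mean square of a one-way
(Procrustes) ANOVA within each treatment; the treated/control ratio of
family MS is tested with (families − 1) degrees of freedom per group
(× 16 for shape). With 14 families this gives df = (13, 13) for size and
(208, 208) for shape; an alternative convention not adopted here counts
14 × 16 = 224.

Under the generator's bilateral model (below), the balanced-design
expectations are E[MS_error] = σ²_ME, E[MS_int] = σ²_ME + 4σ²_FA and
E[MS_ind] = σ²_ME + 4σ²_I per coordinate, so FA10 is an unbiased
estimator of 2σ²_FA — half the variance of the R − L difference net of
measurement error. The factor arises because the FA deviation enters the
two sides with opposite signs (exact antisymmetry), which makes the
side-sum constraint of the restricted two-way model hold exactly; the
test suite verifies these expectations against 200 simulated families.

## Covariance-matrix comparison

Three families of shape covariance matrices are built from the joint
tangent coordinates: *individual* (covariance of specimen mean shapes
within family × treatment — environmental canalisation), *FA* (covariance
of per-specimen signed asymmetry vectors, (R − L)/2 of replicate-averaged
sides, centred on the cell mean so directional asymmetry drops out —
developmental stability), and *genetic* (covariance of family mean shapes
within treatment — genetic canalisation). With 14 families and two
treatments this yields 28 + 28 + 2 = 58 matrices. The FA matrices are not
corrected for measurement error: the MS-subtraction that defines FA10 has
no direct analogue for a full covariance matrix, an acknowledged upward
bias of the FA matrices' diagonal.

Matrices are compared by Pearson correlation over their unique elements
*including the diagonal* (variances carry information too). Correlations
are tested by permutation against a null of complete dissimilarity:
landmark labels of one matrix are permuted, moving x/y coordinate pairs
jointly because the two coordinates of a landmark are not independent;
the one-tailed p-value is (1 + #{r_perm ≥ r_obs})/(1 + n_perm) with 999
permutations by default and a mandatory seed. This test requires the
landmark-block structure, so pairwise correlations and permutation tests
run on the full 2k-coordinate tangent basis. The ordination, in contrast,
needs all matrices on a common basis of rank no larger than the genetic
matrices support (14 families ⇒ rank ≤ 13), so every matrix entering the
PCO is rebuilt on the first 14 principal components of the pooled data.
Both bases are exposed; the per-run choice is a config switch.

The matrix-to-matrix distance is 1 − r². Principal coordinates analysis
is classical Torgerson–Gower scaling: double-centre −½·J·(D∘D)·J,
eigendecompose, and scale the eigenvectors of positive eigenvalues by
their square roots. Negative eigenvalues — expected, since 1 − r² is not
Euclidean — are reported, never silently dropped, together with the
correlation between input and embedded distances as a goodness-of-fit
diagnostic. Note that element-wise matrix correlation is invariant under
a simultaneous relabeling of landmarks but *not* under a rotation of the
basis, so correlations on the coordinate and reduced bases are related
but not identical; the suite demonstrates both facts.

## Rank concordance

Per-family variability estimates (among-individual MS, FA10) are compared
with the tie-corrected Kendall tau-b: across treatments (do the most
variable/asymmetric families under control conditions stay so when
treated?) and between individual variation and FA within each treatment
(are canalisation and developmental stability coupled?). That is eight
analyses: {IV, FA} × {size, shape} across treatments plus IV-vs-FA within
each treatment for both traits. P-values are two-sided, by exact
enumeration for n ≤ 10 without ties and the normal approximation
otherwise. At n = 14 families the asymptotic p is adequate away from
|tau| = 1; the suite bounds the exact-vs-asymptotic gap by enumeration.

## Synthetic data generator

No raw landmark data are distributable, so the generator is a first-class
module that emulates the study conditions. The latent shape of insect i
in family f under treatment t is

    template + m_G(t)·g_f + t·(Δ_shape + gxe_f) + e_i + s·(da + fa_i)

with s = +1 (right) / −1 (left) and independent isotropic Gaussian
landmark displacements per layer — the simplest exchangeable model
consistent with untyped "variation"; anisotropic layers are a config
extension. Each digitised replicate adds isotropic measurement noise,
then a random similarity nuisance transform (translation, rotation, and a
pixel-scale jitter recorded as the TPS SCALE factor, playing the role of
the reference scale photographed with each wing). Left wings are written
mirrored, as a camera sees them; reflecting them back is the reader/GPA's
job. Each wing is "digitised" twice; every insect has both sides.

Defaults define the study-scale conditions and are chosen once:

| parameter | default | meaning / rationale |
|---|---|---|
| n_families | 14 | study design |
| n_per_cell | 4–20 | insects per family × sex × treatment (study range) |
| size_baseline | 7 (mm) | adult wing CS scale |
| treatment_size_effect | +0.7 | ≈10% larger treated wings |
| σ_G, σ_GxT, σ_I, σ_FA, σ_ME | 0.008, 0.004, 0.010, 0.004, 0.002 | per-coordinate SDs in unit-CS shape units; ordered genetic > individual > FA > ME as typical for wing landmarks |
| Δ_shape | 0.012 × lateral dilatation | treated wings widen laterally |
| da_vector | 0.003 × distal field | small directional asymmetry |
| variance multipliers | ×2 on σ_I, σ_FA, σ_G (treated) | the stressed-group inflation under study |
| family_scale_sd | 0.5 (lognormal) | per-family FA/IV scale heterogeneity, shared across treatments, so family ranks persist (the regime in which cross-treatment tau is detectable at n = 14) |
| iv_inflation_sd | 0.03 | treated-only individual variation along the dilatation direction (below) |

The same σ values act as coefficients of variation of centroid size
(scaled by `size_baseline`); `size_noise_factor = 0` switches size
variability off, which isolates the shape layers for the
expected-mean-square oracles. Sexes are generated but exchangeable by
default (an optional mean-size offset exists); an optional linear
size→shape allometry coefficient defaults to 0 so the layers stay
orthogonal for recovery tests. A per-treatment survival fraction can thin
cohorts binomially; there is no dose–mortality model.

The structured inflation deserves a note. Per-family covariance matrices
on the 14-dimensional basis are estimated from only ~15–35 specimens, so
their element-wise sampling noise is of order σ²/√n. A treated-group
direction shared across families is detectable by matrix correlation and
PCO only when its variance is a substantial fraction of the isotropic
layer; 0.03 (rank-1 variance 9e-4 against an isotropic treated total of
20·0.02² = 8e-3) produces a clear and reproducible clustering of
individual-variation matrices by treatment while FA matrices — whose
treated inflation is purely isotropic, and correlation is insensitive to
overall scale — stay unstructured. This mirrors the qualitative contrast
the analysis is designed to detect.

What the generator does *not* emulate: landmark-specific error
heterogeneity, digitiser drift or bias, allometric curvature, antisymmetry,
non-Gaussian FA, correlated x/y noise within a landmark, or selection of
survivors by size. Passing recovery tests therefore show that the
pipeline recovers the layered Gaussian structure it assumes — not that
real wings satisfy those assumptions.

## Numerical choices

- GPA tolerance 1e-10 on the consensus change, 100 iterations maximum;
  non-convergence raises with the iteration trace.
- Sequential SSCP increments are computed from cumulative least-squares
  fits; effect degrees of freedom are rank increments, so rank-deficient
  blocks are handled consistently.
- Singular residual SSCP in the MANCOVA raises with a pointer to
  dimension reduction; a rank-deficient within-group matrix in the CVA is
  projected out automatically and logged.
- Permutation p-values use the add-one correction, making them valid
  (never anti-conservative) at any n_perm.
- Two-sided F p-values are 2·min(upper, lower) capped at 1; zero
  denominators are flagged (p = 0 with an infinite F, or NaN for 0/0).
- PCO eigenvalues below 1e-12 of the spectral radius are treated as zero.

## Problem sizes in the test suite

The suite runs the full pipeline at the 14-family study scale (~650
insects, ~2600 wing images) in a few seconds. Expected-mean-square
oracles use 200 balanced families; type-I-error calibrations use 2000
null replicates per statistic, wide enough that the accepted band
[0.03, 0.07] sits ±4 Monte-Carlo SEs from the true 0.05; recovery and
ordination contrasts use 20–100 independent seeds. The all-pairs
permutation stage of the pipeline defaults to 199 permutations per pair
(1653 pairs); the standalone test function defaults to 999.

## Known limitations

- Family is a fixed classification, as in the ANOVA framework used; no
  REML/mixed-model refit, no heritability estimation.
- FA covariance matrices include measurement error (see above).
- The 1 − r² distance treats positively and negatively correlated
  matrices alike at |r|; PCO eigenvalue sums can therefore be dominated
  by sampling noise when matrices are near-independent.
- No sliding semilandmarks, 3D data, or missing-landmark estimation;
  TPS records must be complete.
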