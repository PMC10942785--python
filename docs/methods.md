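# Methods

This note documents the models implemented in `crossneuro`, the choices made
where the design was genuinely open, what the synthetic-data generator does
and does not emulate, and the package's known limitations. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Volumetric sex effects

For each region the package fits, by ordinary least squares,

    z(vol) = β₀ + β₁·male + β₂·(age − age̅) + β₃·TTV + β₄·Q + ε

where `male` is the F=0/M=1 indicator, `Q` is the Euler number (human, a
surface-reconstruction quality index) or a background-strain indicator
(mouse), and `z()` z-scores the volume across included subjects. β₁ is the
*standardized sex effect size*, in SD units, positive = male-larger. Only
the outcome is standardized; covariates enter in native units (TTV and Euler
are mean-centered, which changes nothing but the intercept and the
conditioning of the solve). Dummy coding and sign convention are recorded in
every output's metadata because downstream congruence scores depend on them.

Global outcomes (TTV itself, total gray/white matter) drop the TTV
covariate. The `without_ttv` covariate set drops it for regional fits too;
with a male TTV advantage this shifts every regional β₁ male-ward, which is
the expected behavior, not a bug. FDR correction (Benjamini–Hochberg,
q < 0.05) is applied across the regions of one species for one covariate
set; families are never pooled across species or covariate sets.
Zero-variance regions produce flagged rows with NaN statistics rather than
aborting the fit.

Quality filtering removes human subjects with Euler number strictly below
−200 (more negative = worse reconstruction); −200 itself is retained. Mouse
rows always pass through.

## Dispersion differences

Volumes are residualized per region on the nuisance covariates (never sex),
then each region gets a two-group Levene-type test between the sexes. The
default centering is the group median (Brown–Forsythe), the conventional
robust choice; mean-centering is available because the literature is often
silent on which variant was used, and the choice is logged in the output.
The direction call (male- vs female-more-variable) compares the groups' mean
absolute deviations and is reported regardless of significance, with
significance tiered at p < 0.05 (uncorrected) and q < 0.05.

## Harmonization (ComBat)

Multi-cohort mouse volumes are harmonized with parametric empirical-Bayes
ComBat: per region, standardize retaining covariate effects (sex and age by
default) in the grand mean; estimate per-batch location (γ) and scale (δ²)
effects; shrink them toward cross-region priors (normal for γ,
moment-matched inverse-gamma for δ²) via the standard iterative update
(tolerance 1e-4, max 100 iterations); remove the shrunken effects and
restore the covariate structure. Harmonization runs strictly *within*
background strain; batches may not span strains, and strain remains a
downstream covariate. A strain with a single batch is returned untouched.
The implementation is validated in the test suite against a frozen output of
Bioconductor's `sva::ComBat` on a mixed-batch fixture (agreement ≈ 1e-7).

Two properties of EB shrinkage are worth knowing. First, when a planted
batch shift is *uniform* across regions, the cross-region prior variance is
tiny, shrinkage toward the prior is strong, and the removed effect is the
prior mean — the per-region residual after harmonization is then a fraction
of the per-batch sampling noise, O(1/√n_b). Second, ComBat is not exactly
idempotent: the inverse-gamma prior always keeps a share of each batch's
scale estimate (half of it when batch variances differ only by noise), so a
second pass still moves values by roughly 1% of an SD. The tests assert the
attainable operational property — a second pass changes values by far less
than the first and by under 0.02 SD — rather than exact idempotence, which
no parametric-EB implementation satisfies.

## Homologous regions and congruence

The packaged registry lists 60 region instances (28 bilateral pairs + 4
midline) with their atlas components per species, a cortical/non-cortical
compartment label, and an expression-availability flag (false only for the
bilateral medial amygdalar nucleus and medial preoptic area → 56
expression-bearing instances). The compartment split is registry *data*, not
code, because the allocortical assignments (subiculum, entorhinal, piriform)
are debatable; editing the TSV changes the subgroup analyses without
touching code. Reported subgroup correlations should be read with that
sensitivity in mind.

Cross-species congruence of sex effects is the percentage-bend correlation
(Wilcox) between the species' β₁ vectors. For each variable the bend scale ω
is the m-th order statistic of |x − median|, m = floor((1−β_pb)·n + 0.5)
with bend constant β_pb = 0.2 by default (the reference implementation's
default; exposed as a parameter). Deviations are standardized by ω,
winsorized through ψ(u) = max(−1, min(1, u)) around the percentage-bend
location, and the normalized cross-product gives r; p-values use the t
transform with n−2 df. |r| = 1 returns p = 0 exactly. Ties in the order
statistic resolve by sorted position, deterministically.

Per region, the anatomical sex-effect similarity score is the product of the
two species' β₁ (SD² units). Quadrant classification follows the beta signs;
an exact zero is reported as `unbiased` rather than silently assigned.
Influence diagnostics use Cook's distance from the simple regression, with
the 4/n rule of thumb for flagging.

## Expression pipeline

The order is fixed: aggregate unit-level expression to regions (human:
component-volume-weighted mean over atlas samples; mouse: unweighted mean
over voxels) → reflect hemispheres (a bilateral region missing on one side
receives its homotopic counterpart's profile; regions missing on both sides
are excluded with a report) → intersect to the one-to-one homologous gene
set, re-indexing both matrices to the shared symbols → z-score each gene
across regions → per-region Pearson correlation across genes.

Z-scoring after the intersection guarantees that genes dropped for zero
regional variance disappear from both species; dropping them (rather than
setting z = 0) avoids asymmetric deflation of the correlations. A region
present in only one species after reflection is excluded from similarity
with a report.

## Resampling nulls

Gene-subset analyses (presets: 91 X-linked, 34 hormone-signaling, of which
11 androgen and 23 estrogen/progesterone) are calibrated against a null of
anatomy–transcription correlations recomputed over random gene subsets of
matched size, drawn without replacement from the shared pool with a single
seeded RNG stream (default 10,000 draws). The observed subset correlation is
compared to the null with an add-one empirical p-value,
p = (1 + #{draws ≥ obs}) / (1 + n_draws), two-sided by doubling the smaller
tail; the add-one correction keeps p strictly positive where a raw
proportion could return 0. The subset correlation itself (not its difference
from the all-gene value) is the tested statistic; the difference variant is
available to callers by building the null on that contrast.

## Synthetic-data generator

The generator exists so every estimator can be tested against known truth.
Volumes arise from a unit-SD latent model — covariate effects (β_TTV = 0.5,
β_age = −0.1 by default), a per-region sex effect, deterministic per-batch
offsets, and Gaussian noise whose male SD can be scaled by a variance
ratio — mapped affinely to positive mm³ per region. Ages are uniform in
range; TTV is Gaussian with a configurable male−female gap in SD units;
human Euler numbers are integers in the observed [−136, −16] range with an
optional outlier fraction below −200 to exercise the QC filter. Batch
membership is assigned deterministically and consumes no random numbers, so
zero batch shifts reproduce a single-batch run bit-for-bit.

Because the analysis defines the standardized effect as an OLS coefficient
on z-scored volumes, a naive generator that plants β on the latent scale
would see it attenuated by the volume's marginal SD (which grows with β and
the covariate effects). The generator therefore solves the self-consistency
σ_y² = V_rest / (1 − β²p(1−p)) and plants β·σ_y, so the requested β is
exactly what the fit recovers in expectation. The planted β refers to the
*batch-free* data; fits on unharmonized batch-contaminated data are
correspondingly attenuated, which is what harmonization recovery tests
measure.

Default cohort sizes mirror the study conditions: 597 F / 496 M humans
(pre-QC) with a 1.28 SD male TTV shift, ages 22–36 y; 213 F / 216 M mice
over 18 cohorts in 2 background strains with no TTV shift, postnatal days
56–90. The published per-cohort mouse table sums to one fewer male than its
own printed totals; the packaged design adds one male to the largest
C57BL6N cohort to restore the totals. Residual variances and covariate
effect magnitudes are not reported quantities; the defaults are
order-of-magnitude choices and are flagged as such here.

Expression pairs are drawn per region as mouse = ρ_r·human + √(1−ρ_r²)·noise
over iid standard-normal gene vectors, so ρ_r is the intended cross-species
correlation *before* z-scoring. Z-scoring across R regions attenuates the
recovered similarity by roughly ρ/(R−1) — negligible at the 56-region
geometry, visible at toy sizes — so recovery assertions hold at the analysis
geometry.

What the generator does **not** emulate: family/twin structure, spatial
covariance between regions, non-Gaussian volume distributions, scanner
drift within cohort, regional co-expression structure (genes are
independent), or donor effects in expression data. Passing tests therefore
demonstrate estimator correctness under the assumed model, not robustness
to those real-data complications.

## Monte-Carlo scales and numerical choices

Acceptance-level checks run at the scales the guarantees are stated for:
200 replicate cohorts of 200/sex for effect recovery; 2000 simulated null
regions for type-I calibration of both the t-test and the Levene test; 200
replicates of 2835 genes × 56 regions for similarity recovery; 1000
replicates at 500 null draws for permutation-p uniformity (the production
default remains 10,000 draws). Module-level tests use smaller versions of
the same constructions. Fixed seeds make every stochastic test
deterministic; pipeline stage outputs are pure functions of config + seed,
verified by hashing outputs across reruns.

Degenerate inputs fail loudly: collinear designs, single-sex tables,
constant vectors in the robust correlation, singleton batches, batches
spanning strains, empty gene intersections. Zero-variance regions and genes
are the exception — they are flagged/dropped with reports, because they are
expected in real parcellations.

## Limitations

The package consumes regional volume tables and expression matrices; it does
not perform image processing, atlas registration, or expression
preprocessing, and it takes the homology registry as given. Gene subsets are
consumed as plain lists. Mixed-effects models for family structure and
spatially constrained region permutations are out of scope. The cortical
subgroup correlation is sensitive to the debatable compartment assignment of
allocortical regions (see above) and should not be over-interpreted.
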