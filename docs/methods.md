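# Methods

## Synthetic dyad cohorts (`synthio`)

The simulator emulates a three-group birthweight cohort with paired maternal
and cord plasma metabolomes.  The log intensity of metabolite *j* in dyad *i*
and compartment *c* is

    log x_ijc = b_j + e_j(g_i) + λ u_ij + ε_ijc

with metabolite baselines b_j ~ N(9, 1) (so raw abundances are log-normal,
median ≈ 8 × 10³ counts), a latent u_ij ~ N(0, 1) shared by the two
compartments of a dyad, and independent residuals ε ~ N(0, σ²) per
compartment.  The loading λ = σ·√(ρ/(1−ρ)) makes the maternal–cord Pearson
correlation of log intensities exactly ρ (`transfer_rho`); the matching
Spearman correlation is slightly smaller (≈ (6/π)·asin(ρ/2)), a ~0.02 gap at
ρ = 0.7 that recovery checks must absorb.

Planted classes and their log-scale effects e_j(g), with group ordinal
(SGA, AGA, LGA) = (0, 1, 2):

| class | SGA | AGA | LGA |
|---|---|---|---|
| `U_up` / `U_down` | ±δ_u | 0 | ±δ_u |
| `line_up` / `line_down` | ∓δ_line | 0 | ±δ_line |
| `null` | 0 | 0 | 0 |

Because group variances are equal, the ratio of arithmetic group means of the
raw (exponentiated) values converges to exp(effect), so δ = ln 2 plants
two-fold fold changes directly.  Effects are identical in both compartments
by default; `discordant_fraction` flips the cord effect of a random subset to
exercise the classifier's discordance branch, and `line_by_birthweight`
indexes line effects by standardized birthweight instead of the group
ordinal.  Missingness is MCAR at `missing_rate` (default 0 — the analysis
chain makes no attempt to model informative missingness).  Defaults: groups
16/28/23; 30 metabolites per planted class + 200 nulls split round-robin over
positive/negative ionization modes; δ_u = δ_line = ln 2; σ = 0.4; ρ = 0.5.

Phenotypes are drawn per group — Gaussian for continuous panels, Bernoulli
for parity/sex/GDM — from the cohort demographics table (16/28/23 design).
Panels reported only in supplementary material (HbA1c, HDL-C, LDL-C, FFA,
HCY) use typical third-trimester values chosen once (e.g. HbA1c 5.3 ± 0.4 %,
HDL-C 2.0 ± 0.4 mmol/L with the LGA deficit, HCY 6 ± 1.5 µmol/L).  The LGA
adiponectin SD is kept as printed (393.2 ng/mL) even though it is likely a
typo in the source table; it is never used in an assertion.  Gaussian draws
of high-CV panels (cord insulin/leptin) can produce negative values — they
are left untruncated so the group tests stay calibrated.  Phenotypes are
independent of the metabolome unless `pheno_links` plants a linear link
(slope × standardized phenotype added to a metabolite's log intensity),
which is how association recovery is exercised.

All randomness flows from one integer seed through named `SeedSequence`
streams (phenotypes / metabolome / missingness), so outputs are reproducible
and `generate_phenotypes` alone reproduces the table embedded in
`generate_cohort`.

## Preprocessing (`prep`)

Z-score normalization is column-wise with the sample SD (denominator n − 1,
the usual chemometrics convention).  Constant or all-missing columns are
dropped with a warning (the transform is undefined).  Normalization is
within-compartment; fold changes are always computed on raw intensities and
Z-scores serve only the heatmap/meta-analysis ordering.  Mode merging
concatenates features with `pos:`/`neg:` prefixes and never deduplicates
across modes.  Imputation offers `half-min` (half the metabolite's minimum
observed value, a limit-of-detection surrogate) or `none`
(pairwise-complete downstream).

## Multivariate models (`mva`)

PLS2 (multi-group overview) and O-PLS (two-class) are fitted by NIPALS with
convergence tolerance 1e−10 on the score vector, max 500 iterations,
deterministic initialization (the dummy column of maximal variance), and a
fixed sign convention (largest-magnitude x-loading positive), so refits are
bit-for-bit identical.  O-PLS removes `n_orth` (default 1) class-orthogonal
components — w_o ∝ p − (wᵀp)w — before the single predictive component;
predictive and orthogonal scores are exactly orthogonal by construction.
Scaling options are `uv` (unit variance, the default, recomputed inside
every fit so cross-validation rescales per training fold), `pareto` (√SD)
and `none` (centering only).

VIP uses the predictive component(s) only (`variant="pred"`), the
convention for O-PLS feature ranking; `variant="total"` folds in orthogonal
weights weighted by the X sum of squares each captures.  Both satisfy
mean(VIP²) = 1 exactly.

Cross-validation uses stratified venetian-blind folds driven by one global
counter across classes, which balances fold sizes and degenerates to exact
leave-one-out at k = n.  Q² = 1 − PRESS/SSY with out-of-fold predictions
from fully refit models (scaling included).  Q² may be negative; VIP
selection proceeds regardless, since two-class models at n ≈ 44 with
thousands of features are routinely non-predictive yet still rank variables
usefully.  A permutation helper re-runs CV under label permutations; on null
data the permuted Q² mean is at or below zero.

## Shape discovery (`shapes`)

DM selection is the strict inequality VIP > threshold (default 1.0), so a
single-variable model (VIP ≡ 1) selects nothing.  The four comparison sets
are intersected with full 15-region Venn accounting.  Fold changes are
ratios of arithmetic group means of raw intensity (`method="geometric"`
available); a zero denominator or < 2 observed values flags the metabolite
rather than silently dropping it.  Classification is per compartment by the
sign pattern of (FC_SGA − 1, FC_LGA − 1); any FC exactly 1 is `none` (the
strict rules leave the boundary undefined), and the final label requires
maternal/cord agreement (`concordance="maternal"` relaxes this for
sensitivity analysis).  The rule is total: all 81 sign patterns of the two
compartment pairs map to exactly one label.

The pipeline models log-transformed intensities (`log_transform=True`):
abundances are log-normal, and modelling on the log scale with per-model UV
scaling is what gives the chain its power at the default effect sizes.
Fold-change computation and Z-score exports are unaffected.

## Associations (`assoc`)

Model 1 is Spearman's ρ with average ranks and the two-sided t
approximation.  Model 2 rank-transforms the metabolite, the clinical
variable **and** every numeric covariate, dummy-codes categorical covariates,
residualizes the two rank vectors on the covariate design by least squares,
and correlates the residuals; p uses df = n − 2 − k.  Ranking the covariates
makes the adjustment fully nonparametric — a variable identical to a
covariate partials to exactly 0 — and matches the usual partial-Spearman
definition.  Collinear covariate columns are rank-reduced with a warning; a
variable lying numerically in the covariate span returns r = 0, p = 1 rather
than amplifying floating-point noise.  Two covariate presets ship: `table`
(maternal age, parity, GDM, gestational age, fetal sex — the default) and
`methods` (the same without GDM); the source material is internally
inconsistent about GDM, so neither is privileged as correct.  Records are
complete-case with the n used reported; no multiple-testing correction is
applied (per-test α = 0.05 two-sided), with an optional BH-FDR column.

## Cohort statistics (`cohorts`)

One-way ANOVA comes from `scipy.stats.f_oneway` for raw data and from
reconstructed sums of squares for printed summaries (SS_between from means
and group sizes; SS_within = Σ(nᵢ−1)sdᵢ²).  Inputs rounded to printed
precision can shift p values in the third decimal, so summary-based checks
compare at two decimals.  The Fisher–Freeman–Halton r×c test enumerates all
tables with the observed margins by recursion over row compositions,
accumulating log-factorial probabilities (no overflow at any n), and sums
the probabilities ≤ the observed table's with relative tie tolerance 1e−12 —
on 2×2 tables this reproduces the classical two-sided Fisher p exactly.
Enumeration is capped (default 10⁷ candidate tables); beyond it a seeded
Monte-Carlo mode samples tables row-by-row from multivariate hypergeometric
draws, which is exactly the margin-conditional null.  `summarize_cohort`
formats means/SDs and percentages to one decimal and p to two decimals with
a "< 0.001" floor.

## Pipeline (`pipeline`, `cli`)

`run_pipeline` executes simulate/load → prep → four OPLS-DA comparisons →
VIP selection → Venn intersection → fold-change classification →
maternal–cord and clinical correlations → demographics table, writing CSV/
JSON outputs and a manifest (config hash, seed, versions, per-stage counts,
per-model R²X/R²Y/Q²/selection counts).  One root seed is split
deterministically into per-stage streams, so output trees are byte-identical
given config + seed.  Caching is whole-run: a manifest matching the current
config digest and seed short-circuits the run with an "up-to-date" log line
(per-stage caching was judged machinery without analytical payoff).  Exit
codes: 0 success, 2 validation error, 3 stage failure.

## Problem sizes and what the tests show

Recovery checks run the full chain on 10 cohorts at the default design
(67 dyads, 320 metabolites, δ = ln 2, σ = 0.4, ρ = 0.5): planted-shape
sensitivity ≥ 0.8 with ≤ 5 % of nulls mislabelled; transfer correlation
ρ = 0.7 recovered within ±0.08; type-I error of both correlation models
inside the binomial 95 % band of 5 % at 1000 null metabolites; mean Q² over
100 label permutations of 24×40 noise ≤ 0.  Oracle-equivalence checks use
small matrices (≤ 20×50) and exact-rational Fisher enumeration at N ≤ 30.
These sizes were chosen as the smallest at which the statistics are stable.

## Limitations

The simulator plants clean multiplicative effects with homoscedastic
log-normal noise, MCAR missingness and no batch/drift structure, no
correlation between metabolites beyond the dyad latent, and no
retention-time/m-z information — passing recovery tests demonstrates the
chain's statistical machinery, not robustness to instrument artefacts,
annotation errors or informative missingness in real acquisitions.  Venn
counts and shape totals from real studies depend on cohort-specific effect
and noise distributions and are not reproduced by design.  Commercial chemometrics software is
ambiguous about whether "R²" denotes R²X or R²Y for discriminant models, so
both are exported and no single value is labelled "R²".
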