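# Methods notes

This note records the models implemented in `mtbrain`, the assumptions they
make, the defaults and why they were chosen, and the numerical decisions a
maintainer would otherwise have to reverse-engineer.

## Copy-number estimation (`copynumber`)

The estimator is the coverage ratio `mtDNAcn = 2 · cov_mt / cov_nuc` with
medians of *per-base* depth. Medians are computed directly on run-length
(bedGraph) intervals via a weighted median, which is exact and avoids
expanding chromosome-length arrays; the tie convention for even counts is
the mean of the two central order statistics (configurable to
`lower` for integer-median emulation). Autosomal positions inside the
ambiguity mask are excluded; the mitochondrial contig is never masked.
Zero-usable-position failures distinguish "all masked" from "empty track"
because the two have different upstream causes.

Raw values are comparable only within one extraction protocol. For
modeling, values are natural-log transformed and then z-standardized within
each batch (region × extraction-kit label). Log-before-z is the only
well-defined order — z-scores are negative for half the samples, so the
reverse composition is undefined — and the z uses the population SD
(ddof 0) so that re-standardizing an already-normalized batch is the
identity. Batches with fewer than two samples or zero log-variance are
rejected by name.

Coordinates follow the field's conventions: BED/bedGraph files are 0-based
half-open; everything in memory is 1-based inclusive; conversion happens
only in `io`.

## Heteroplasmy calling (`heteroplasmy`)

Candidate generation is a pure counting operation: every non-reference
allele with at least `min_alt_reads` (default 3) supporting reads at a
position with depth ≥ `min_depth` (default 50) becomes a candidate with
allele fraction AF = alt/depth. The depth floor makes an AF of 0.03
estimable at all (3/0.03 = 100 ≥ 50 keeps the floor conservative); both
knobs are exposed.

Classification uses the closed interval `0.03 ≤ AF ≤ 0.90` for
heteroplasmy, `AF > 0.90` for homoplasmic-like and `AF < 0.03` for noise.
The thresholds are alternative-allele fractions; at sites with AF > 0.5
the alternative is the major allele, and the convention is documented
rather than switched, because burden counting treats the site identically
either way. Boundary inclusivity is a convention choice; it is pinned by
tests.

The circular genome is handled by the shifted-reference strategy: a second
pileup against a reference rotated by 8,000 bp yields clean calls across
the linearization junction. The merge takes shifted-alignment calls for
the control region (16024–16569 wrapping to 1–576) and standard-alignment
calls elsewhere, mapping shifted coordinate `s` to
`((s + shift − 1) mod 16569) + 1`. The junction window equals the control
region because that is where the artificial origin sits; the property
guaranteed by tests is stronger: calling on *any* rotation of a pileup
returns the same original-coordinate variant set.

Artifact filters re-implement the *roles* of the usual external tools:

- **NUMT filter** — a polymorphic nuclear insertion of mitochondrial
  sequence contributes reads proportional to nuclear depth, so variants
  with alt reads ≤ k·cov_nuc (k = 2, i.e. up to two nuclear copies) are
  flagged. k is configurable; 2 covers a heterozygous diploid insertion.
- **Contamination filter** — variants with AF not exceeding the supplied
  sample contamination level (a surrogate for a haplogroup-based
  contamination estimate, which requires real haplotypes) are flagged.

Flags are independent predicates; burden (the count of unflagged calls in
the AF band) is therefore invariant to filter order. Indels are carried as
aggregate `ins`/`del` pileup alleles, left-aligned and under 50 bp by
construction of the input format; no realignment is attempted.

Gene-level enrichment treats positions as uniform under the null: a
feature of length L_g receives Binomial(n, L_g/16569) of n heteroplasmies,
tested on the upper tail with Bonferroni adjustment across features. The
binomial tail is discrete, hence conservative; the calibration test checks
super-uniformity (P(p ≤ α) ≤ α) rather than a two-sided KS statistic,
which a discrete p-value cannot pass. The built-in feature map has an
exact control region and canonical gene *starts* as block boundaries —
adequate for synthetic positions, not a curated annotation.

## Deconvolution (`deconvolution`)

The Digital Sorting Algorithm premise: for genes exclusive to cell type t,
bulk signal is proportional to the type's proportion. The per-type signal
is the *median* expression over the type's markers (robust to single
aberrant markers), after dropping markers with cross-sample mean < 2 CPM.
Scale factors g ≥ 0 are the non-negative least-squares solution of
`Oᵀ g = 1` (each sample's proportions should sum to one in expectation),
proportions are `g_t · O[t, i]`, clipped to [0, 1] and renormalized per
sample. The NNLS solve is convex with a unique minimum when O has full row
rank, so the estimate is deterministic. The two-stage solution (scales,
then renormalization) preserves DSA's linear structure and is robust to
noise; a full quadratic program over all proportions simultaneously was
rejected as it couples samples without improving the noiseless identity.
TMM normalization and technical-covariate residualization of real RNA-seq
are upstream of this module; synthetic expression is generated directly on
the normalized CPM scale.

## Proteomic scores (`proteomics`)

Each score is the per-sample median of z-standardized member proteins
(standardize first, then median; population SD). Standardization makes
scores invariant to affine rescaling of any single protein column, and the
median gives a breakdown point of one half against corrupted members.
Subunits and assembly factors are weighted equally within a complex —
nothing in the data motivates differential weights. Panels are allowed to
be partial (mass spectrometry rarely detects everything): missing proteins
are dropped with a warning, with a floor of 3 present members.

## Association stack (`association`, `network`)

**Standardization.** Continuous variables (float-typed or more than ten
distinct integer values) are z-scored so coefficients are in SD units;
dosages and stage codes stay on their natural scale, which is what makes
"SD per allele dosage" effect sizes directly readable.

**Linear association.** Single predictors are tested by the F-test of the
full vs covariate-only model (multi-level categoricals jointly), with
partial R² as the SSE ratio of nested models. Per-term t-tests are used in
the joint multivariable model. Rank-deficient designs are rejected with the
collinear columns named.

**Quasi-Poisson.** Point estimates are the Poisson MLE (IRLS, log link);
the dispersion φ (Pearson χ²/df) only scales the SEs, a fact asserted by a
test on overdispersed data. Wald t-tests with φ-scaled SEs mirror R's
`summary.glm` for the quasipoisson family; an analysis-of-deviance F-test
on (dev_reduced − dev_full)/(q·φ) is also provided, covering the
likelihood-ratio-flavored alternative. Age effects are reported as
100·(e^β − 1) percent per year.

**Meta-analysis.** DerSimonian–Laird with τ² truncated at zero is the
default, matching the classical behavior of the R meta-analysis packages;
the truncation matters (statsmodels' `combine_effects` does not truncate
and produces a different pooled SE on the same inputs). With τ² = 0 the
result collapses to the fixed-effect inverse-variance estimate, and the
pooled estimate always lies within the range of the study estimates; both
are tested. An iterative REML estimator of τ² is available behind
`method="reml"`.

**Mediation.** Both path models are OLS; `n_sim` (default 1000) parameter
vectors are drawn from each fit's asymptotic normal, and per draw
ACME = a·b, ADE = c′, total = ACME + ADE (an identity in the linear case,
holding exactly for the point estimates too) and proportion = ACME/total.
Intervals are 2.5/97.5 percentiles. The proportion is a ratio with the
total effect in the denominator: when the total's interval spans zero the
proportion is flagged unstable and its interval reported as (−∞, ∞). For
the same reason, aggregating the proportion across simulation replicates
pools ACME and total first and then takes the ratio — the mean of
per-replicate ratios is noisy and can be badly behaved near small totals.
A categorical treatment such as an allele dosage is treated as numeric,
matching per-dosage effect reporting.

**SNP panel.** Per-region OLS on the unstandardized dosage with
z-standardized outcome, pooled by random effects, with Bonferroni
adjustment over the panel size (default 81). Ancestry principal components
enter as ordinary covariates; computing them from genotypes is out of
scope.

**Networks.** Variables are optionally Gaussianized by the truncated-ECDF
nonparanormal transform (Winsorization at δ_n = 1/(4·n^{1/4}·√(π·log n)),
then the normal quantile, each column rescaled to unit SD) — monotone in
the input and therefore invariant to monotone re-expressions, which is the
point for count-valued burden variables. The graphical lasso (coordinate
descent, on the correlation matrix; non-PD inputs get a 1e-4 ridge jitter
then re-normalization) is solved over a 30-point log-spaced λ grid from
λ_max = max|off-diagonal correlation| down to λ_max/100, and λ is chosen by
EBIC = −2ℓ + E·log n + 4γ·E·log p with γ = 0.5. One numerical choice
deserves emphasis: the likelihood entering the EBIC is computed on the
*unpenalized restricted MLE* for each candidate support (classical
covariance selection by cyclic modified regressions), not on the shrunken
glasso estimate. Scoring the penalized estimate lets the likelihood gain
from un-shrinking strong true edges masquerade as evidence for extra
edges, and the chain-graph recovery test fails under it; refit-scoring
selects the true support. The reported precision matrix remains the
penalized glasso solution at the selected λ (so the p = 2 analytic
soft-threshold identity holds for it), with the refit used only for
selection. Bootstrap stability is plain case resampling with per-edge
inclusion frequencies; degenerate resamples (e.g. a constant column) are
skipped and frequencies renormalized over successful refits.

## Synthetic cohorts (`synthetic`)

The generator emulates the *statistical structure* the analysis assumes,
not the biology: its purpose is that every estimator upstream has a truth
table to be checked against.

- **Cohort marginals.** Region presets fix n, age mean/SD (e.g. DLPFC
  n = 454, age 89.3 ± 6.6 years), male fraction, and mean heteroplasmy
  burden (cortical regions ≈ 2.6–2.8, cerebellum 1.0). Two cohorts emulate
  right-censored ages via 5-year stratum midpoints with an open top
  interval above 95 (97.5 assigned).
- **Pathologies.** Ten variables share a Gaussian copula with a fixed
  positive-semidefinite correlation matrix (validated, rejected with the
  offending eigenvalue otherwise); ordinal stages are thresholded at the
  normal quantiles of configured stage prevalences, and the two
  quantitative burdens are emitted on the sqrt-%-area scale with means/SDs
  back-solved so the raw-scale mean/SD match the targets (tau 7.4 ± 8.1,
  amyloid 4.6 ± 4.4).
- **Copy number.** A standardized latent combines tau (−0.30 SD/SD),
  neuronal proportion (+0.30), APOE paths (a = 0.5 per dosage onto the
  AD-pathology latents, b = −0.32, c′ = −0.204 — chosen so the total
  per-dosage effect is −0.364 with 44% of it indirect), an optional SNP
  effect, and Gaussian noise; raw copies are
  2000·exp(0.25·z), a realistic brain-tissue scale for a WGS coverage
  ratio.
- **Heteroplasmies.** Counts are Poisson with log-linear age dependence
  (default rate ln(1.016) per year, i.e. +1.6%/yr, with the configured
  mean burden holding at the cohort mean age), positions put 60% of mass
  on the control region, allele fractions are Beta(1.2, 8) truncated to
  (0.03, 0.90) — a right-skewed shape consistent with clonal-expansion
  intuition; no empirical AF distribution was available to fit, so this is
  a modeling choice. Planted homoplasmies (AF 0.995), NUMT artifacts
  (alt reads ~ Poisson(1.5·cov_nuc), i.e. scaling with *nuclear* depth)
  and optional low-AF contaminants exercise every filter; alt counts are
  Binomial(depth, AF).
- **Coverage.** Toy contigs (two 10-kb autosomes, the 16,569-bp MT)
  suffice because coverage medians are scale-free in contig length.
  Depths are negative binomial around the targets (size 100, mild
  overdispersion — at heavier dispersion the NB median visibly departs
  from its mean and would bias the estimator check); `coverage_noise = 0`
  produces constant integer depths for exactness tests. MT depth targets
  `mtDNAcn_true · cov_nuc / 2` so the estimator inverts the formula.
  Because emitted depths are integers, exact recovery holds when the
  latent is constant (quantization is below 0.1% otherwise).
- **Expression / proteomics.** Five cell types with exclusive marker genes
  (87/88/59/90/86 markers), sample profiles are proportion-weighted
  signatures with log-normal noise; glial proportions are a Dirichlet
  split of 1 − neuronal. Protein abundances are driven by a latent
  mitochondrial content that loads on the component of neuronal proportion
  orthogonal to the copy-number latent — so content and mtDNAcn decouple
  while both correlate with neuronal proportion — with complex I–V latents
  sharing the content factor (mutual score correlations > 0.8) and
  mtDNA-encoded proteins receiving a weak (0.15) copy-number loading.

What the generator does **not** emulate: read-level errors, alignment
artifacts, GC bias, real reference sequence content (the pseudo-reference
fixes positions and bases deterministically, nothing else), linked
genotypes/haplogroups, longitudinal cognition, or batch effects beyond a
label. Passing tests therefore demonstrate estimator correctness under the
assumed generative structure, not robustness to real-data pathologies.

Determinism: every generator takes a `numpy.random.Generator`; equal seeds
give byte-identical CSV/TSV emissions (enforced by rounding at emission).

## Problem sizes

The test suite and the acceptance script run desk-scale configurations
chosen to keep full runs in minutes while leaving Monte-Carlo error well
inside the assertion margins: cohorts of 4–454 samples, pileups for ≤ 30
samples at a time, 2,000-replicate type-I-error calibration at n = 25,
25-panel family-wise-error simulation, 40–100 replicate recovery runs for
the age-rate, mediation and SNP targets, and bootstrap stability at
B = 40–100 in tests (the default B = 1000 remains the analysis setting).

## Known limitations

- The caller consumes allele-count pileups, not BAMs; producing pileups
  from alignments (e.g. with samtools) is deliberately outside the tested
  core.
- The NUMT and contamination filters are coverage/AF heuristics standing
  in for haplotype-aware tools; they share those tools' blindness to NUMTs
  at unusually high nuclear copy number.
- DSA requires strictly exclusive, expressed markers; violation of
  exclusivity is rejected rather than modeled.
- EBIC-glasso support recovery is demonstrated at n ≫ p; in the n ≈ p
  regime the estimator warns and results should be read through the
  bootstrap frequencies.
- The enrichment test assumes positional exchangeability under the null
  and a fixed feature map; it is a sanity screen, not a substitute for a
  mutational-signature model.
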