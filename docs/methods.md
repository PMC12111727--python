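# Methods

This note documents the statistical model behind `mrmediate`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that matter for
reproducing results.

## Causal model and estimators

The package implements two-sample summary-data Mendelian randomization.
For an exposure X and outcome Y, each instrument SNP j contributes a
Wald ratio r_j = β_out,j / β_exp,j with first-order delta-method
standard error se_out,j / |β_exp,j| (exposure-side noise is ignored in
the SE, the standard first-order choice; a second-order correction is out
of scope).  The IVW estimate is the 1/se²-weighted mean of the ratios,
equivalent to a weighted no-intercept regression of outcome on exposure
effects.  Because the analyst rarely knows in advance whether per-SNP
effects are homogeneous, the default inference is **multiplicative random
effects**: the fixed-effect SE is scaled by √max(1, Q/df), where Q is
Cochran's statistic.  Fixed-effect mode is selectable
(`ivw(h, mode="fixed")`).  IVW p-values use a two-sided normal reference;
MR-Egger uses a t reference with n−2 df, and its coefficient SEs are the
unscaled weighted-least-squares SEs multiplied by max(1, residual SD) —
the convention of mainstream two-sample MR software, which inflates but
never deflates uncertainty relative to the exact-fit case.

The MR-PRESSO-style outlier test is reconstructed from its published
logic and declared normative for this package: observed statistic
RSS = Σ w_j (β_out,j − b₋ⱼ β_exp,j)² with w_j = 1/se_out,j² and b₋ⱼ the
leave-one-out IVW slope; null distribution from parametric draws of both
β_out* and β_exp* around their fitted/observed values; global p as the
fraction of simulated RSS at or above the observed; per-SNP empirical
p-values Bonferroni-multiplied by the SNP count; outliers (adjusted
p < α) removed and IVW recomputed.  `n_sim` (default 1000), α and the
seed are all explicit arguments, and results are bit-reproducible under a
fixed seed.  A caveat documented by the planted-outlier test: the
leave-one-out slopes of non-outlier SNPs are themselves contaminated by a
gross outlier, so the per-SNP test is reliable for clearly separated
outliers but can approach its α level for neighbours of an extreme one.

Instrument selection is significance (strict p < 1e-5), greedy LD
clumping (keep the smallest-p remaining SNP, drop same-chromosome SNPs
within ±10,000 kb center-to-center with r² ≥ 0.001; ties broken by rsid
so the result is independent of input row order), then strict F > 10
with F = β²/SE².  SNPs absent from the LD reference are treated as
uncorrelated with a logged warning, since reference panels never cover
every variant; an empty LD matrix therefore means "no pruning beyond
significance and strength".

Harmonization flips the outcome effect sign when the allele pair is
swapped, always drops palindromic (A/T, C/G) variants in strict mode
(no frequency-based disambiguation — allele frequency is optional in the
data model), and drops-and-counts pairs matching in neither orientation
rather than strand-complementing them; both counters are carried on the
harmonized set so any future policy change is observable.

## Colocalization

Per-SNP evidence is the Wakefield approximate Bayes factor
log ABF = ½·ln(V/(V+W)) + ½·z²·W/(V+W) with V = se², W = prior_sd².
Default effect-prior SDs are 0.20 for quantitative traits and 0.15 for
binary (log-odds) traits, the conventional choices; per-SNP priors
p1 = p2 = 1e-4 and p12 = 1e-5.  The five-hypothesis posterior assumes at
most one causal variant per trait; H3 sums ABF products over ordered
distinct SNP pairs, computed as a log-difference of logsumexp terms and
floored at −∞ when numerically non-positive (single-SNP regions report
PPH3 = 0).  All mixture arithmetic is in log space.  Regions default to
±500 kb around the exposure's smallest-p variant; the window is a
prominent configuration knob because regional versus genome-wide overlap
materially changes the posterior.  PPH4 > 0.75 is the conventional
evidence threshold; in the screening cascade, candidates below it are
retained with a `not_established` label rather than removed, because a
sub-threshold PPH4 cannot rule out a causal relationship.

## Screening cascade

Gates, in order: forward MR (keep P_IVW < α = 0.05, raw not
FDR-adjusted at this first gate); reverse MR with roles swapped (exclude
reverse P_IVW < α, strict inequality, so a reverse p of exactly 0.05 is
retained); per-exposure mediator families with bidirectional
exposure ↔ mediator gating; Benjamini–Hochberg FDR (step-up, via
statsmodels) within each family with adjusted p < 0.05; colocalization
labelling; and the mediated proportion 100·(β1·β2)/β, reported as a
signed percentage to three decimals (negative = mediated path opposing
the total effect).  Exposures or mediators left with fewer than
`min_snps = 2` instruments are excluded with an explicit reason — a
single-SNP exposure cannot support heterogeneity or pleiotropy
diagnostics — and Egger/Q are reported as absent below their own df
guards (3 and 2 SNPs).  A pair whose Egger intercept is significant is
flagged, PRESSO-corrected and re-tested, not silently dropped: published
screens of this design retain pairs with nominally significant pleiotropy
when the corrected estimate stands, so flagging keeps both behaviours
observable.  Every gate logs its exclusions; the pipeline manifest
records configuration, seed and per-gate counts, and report tables are
byte-identical across re-runs with the same seed (the manifest timestamp,
written only by the CLI, is the one deliberately non-reproducible field).

## Synthetic-data generator

`simulate_mediation_scenario` draws a panel of SNPs with MAF ~ U(0.05,
0.5) on a block-diagonal AR(1) LD fabric (blocks of 10, ρ = 0.5).  Joint
effect vectors implement the DAG X → R → Y with a direct X → Y path:
R's joint effects are γ + β1·α and Y's are (direct + β1β2)·α + β2·γ + δ,
with α, γ, δ planted at the centers of disjoint LD blocks.  Marginal
effects are the LD matrix times the joint effects; observed betas add
independent N(0, se²) noise per trait (disjoint cohorts, the two-sample
assumption), with se = s/√(2n·maf·(1−maf)), s = 1 for quantitative
traits and s = 1/√(φ(1−φ)) for the binary outcome with case fraction
φ = 0.2 — a liability-style approximation of the log-odds SE in a
case-control GWAS.  The total-effect identity
total = direct + β1·β2 holds by construction for every scenario.

Defaults are sized for desk-scale replication: 500 SNPs, 20 instruments
each for X and R, 5 for Y, n = 50,000 per cohort, under a second per
replicate.  Instrument magnitudes are drawn from U(0.15, 0.25) with
random signs — strong, cis-pQTL-like instruments (F in the hundreds),
chosen so that ratio-denominator noise contributes negligible bias to
the recovered mediated proportion at the default cohort sizes.  The
mediator is simulated directly as one quantitative trait (a log-ratio of
two protein levels collapses to a single Gaussian variable); decoy
mediators have their own instruments but no X → decoy path and no effect
on Y, providing specificity targets.  The default effect triple
(β1 = −0.084, β2 = 0.159, direct = −0.1296, hence total ≈ −0.143)
mirrors a protective exposure whose mediated path acts with the total
effect.

What the generator does **not** emulate: individual-level genotypes,
population structure or relatedness, sample overlap between cohorts,
winner's-curse selection of instruments from the same data, strand
errors, INDELs/multi-allelics, and genuine horizontal pleiotropy unless
planted.  Passing tests therefore demonstrate correctness of the
estimators and the cascade under the stated sampling model, not
robustness to those real-data pathologies.

`simulate_coloc_scenario` builds a 200-SNP region (AR(1), ρ = 0.8,
blocks of 50) with one causal variant at marginal |z| = 8 shared by both
traits (`shared`) or one per trait in different blocks (`distinct`).
`simulate_null_screen_panel` gives each of many exposures its own
uncorrelated SNPs with strong instruments and a binary outcome of pure
noise, for type-I-error calibration of the forward screen; the observed
pass rate (≈ 0.03–0.04 at α = 0.05) is mildly conservative because the
multiplicative-random-effects SE never shrinks below the fixed-effect
SE.

## Numerical conventions and edge cases

- 95% intervals use the hard-coded multiplier 1.96.
- P-values from simulated z-scores are floored at 1e-300 to stay within
  the (0, 1] domain of the data model.
- Summary-statistics text serialization: betas/SEs/frequencies at 10
  significant digits, p-values in scientific notation, missing optionals
  as `NA`; write∘read∘write is byte-idempotent.
- Clumping tie-breaks: (pval, rsid) lexicographic, making selection
  deterministic and order-invariant.
- A zero exposure beta among instruments is an error (undefined Wald
  ratio) rather than a silent drop.
- Zero total effect makes the mediated proportion undefined; it is
  reported as absent and flagged, never as ±inf.
- Posterior vectors are renormalized after the log-sum-exp softmax and
  validated to sum to 1 within 1e-9.

## Problem sizes used in the test and acceptance runs

Oracle-equivalence checks run on ≤ 12-SNP instances against exhaustive
enumeration or brute-force re-implementations.  Calibration uses 200
null exposures (1000 in the acceptance script, for a tighter binomial
estimate) and 200 PRESSO null replicates at 500 simulations each.
Parameter recovery uses 100 scenario seeds at the default scenario size.
These sizes were chosen as the smallest that give stable Monte-Carlo
estimates for the properties being checked.

## Known limitations

- No weighted-median, mode-based, Steiger-filtering or multivariable MR
  estimators; β2 is the univariable mediator → outcome estimate, so
  mediator-exposure feedback beyond the bidirectional gate is not
  modelled.
- No standard error or confidence interval for the mediated proportion
  (a delta-method or bootstrap CI is a natural extension).
- Colocalization assumes a single causal variant per trait per region;
  no SuSiE-style extension, no conditional analysis.
- LD is an input; the package never computes it from genotypes.
- The PRESSO per-SNP test's leave-one-out contamination (above) is
  inherent to the single-pass formulation.
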