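# Methods

## Scope and model

`mrmediation` implements two-sample Mendelian randomization (MR) from GWAS
summary statistics, together with a two-step (network) MR mediation
decomposition. The causal diagram has an exposure X (e.g. childhood
adiposity), a mediator M (a metabolite, or a pubertal-timing trait), and an
outcome Y (pubertal stage, or an adult disease on the log-odds scale):

```
        A           B
   X ------> M ------> Y
    \_________________/
            C'
```

Per-variant associations are treated as given (beta, SE) pairs from three
non-overlapping GWAS. The package's estimators consume only these summary
quantities.

## Instrument selection

Candidate instruments for a trait are filtered in a fixed order, each stage
recorded in a provenance ledger so the counts reconcile exactly with the
input size:

1. genome-wide significance, p < 5e-8 (strict inequality);
2. greedy LD clumping at r² = 0.001 within a 10,000 kb window. Clumping
   consumes a user-supplied LD correlation matrix; without one, variants
   are treated as independent. The window constraint applies only when a
   `pos` column is present;
3. per-variant strength, F = (beta/se)² > 10 (strict). The per-variant
   (beta/se)² form is the standard summary-data approximation; its
   expectation is 1 + n·R²/(1−R²) for a variant explaining R² of a
   standardized trait;
4. allele harmonization against the outcome GWAS (below);
5. a per-variant directionality filter retaining variants that explain
   more variance in the exposure than in the outcome.

### Harmonization

Outcome effects are aligned to the exposure's effect allele: swapped
alleles flip the outcome beta and frequency, strand-complemented records
are complemented then aligned, and irreconcilable allele pairs are dropped
with a recorded reason rather than raised. Palindromic variants (A/T, C/G)
cannot be oriented from allele labels; they are oriented by effect-allele
frequency agreement and dropped when either frequency is missing or either
study's minor-allele frequency is ≥ 0.42 (too close to 0.5 to call). The
result is invariant to wholesale reorientation of the outcome file.

### Variance explained from p and n

Where a per-variant r² is needed (directionality), it is recovered from the
association p-value and sample size by inverting the 1-df regression F
test, computed through the t quantile (which stays finite for p as small as
1e-300, where the incomplete-beta inverse overflows).

## Estimators

* **Wald ratio** — beta_outcome/beta_exposure; first-order SE
  se_outcome/|beta_exposure| by default, with a second-order option adding
  the exposure-uncertainty term. The second-order term matters only when
  the ratio and the exposure SE are large relative to the outcome SE.
* **IVW** (main estimator) — inverse-variance-weighted mean of Wald ratios,
  algebraically a weighted least-squares fit of outcome on exposure betas
  through the origin with weights 1/se_outcome². The default
  *multiplicative random-effects* model inflates the fixed-effect SE by
  √(Q/(k−1)) whenever that exceeds 1 and never deflates it; p-values are
  normal. A single instrument degrades to its Wald ratio.
* **MR-Egger** — the same weighted regression with an intercept, after
  reflecting instruments so all exposure betas are non-negative (without a
  fixed orientation the intercept is meaningless). The intercept estimates
  the average directional pleiotropy, the slope the adjusted causal effect;
  both SEs carry the multiplicative overdispersion factor max(1, √(Q/(k−2)))
  and are tested against t with k−2 df.
* **Weighted median** — weighted median of Wald ratios (linear
  interpolation at cumulative standardized weight 0.5); consistent when
  valid instruments carry a majority of weight. SE by seeded parametric
  bootstrap (default 1,000 draws) redrawing both betas at their reported
  SEs.
* **Cochran's Q** — heterogeneity of ratios about the pooled estimate,
  chi-square with k−1 df. With first-order weights Q is exactly
  chi-square-distributed only when the exposure betas are noise-free or the
  causal effect is null; under a non-null effect the neglected
  exposure-side variance inflates it slightly.

## Sensitivity suite

* **MR-PRESSO.** The global test ranks the observed weighted residual sum
  of squares about leave-one-out fitted values within a parametric null:
  each simulation redraws every instrument's exposure and outcome effects
  from normals centred on the observed exposure beta and its leave-one-out
  prediction, then recomputes the statistic (add-one p-value, so the
  smallest attainable p is 1/(n_sim+1)). The outlier test ranks each
  variant's weighted squared residual in its own simulated distribution,
  flagging variants below a Bonferroni-corrected 0.05. The distortion test
  compares the percent change between all-instrument and outlier-free IVW
  estimates against a null built by deleting equally many randomly chosen
  non-outlying instruments. All three are seeded and reproducible; the
  corrected estimate is exactly `ivw()` on the outlier-free set.
* **Steiger directionality.** Instrument-set r² per trait is the sum of
  per-variant r² from the p/n transform; the direction is "true" when the
  instruments explain more variance in the exposure. The p-value uses a
  two-independent-sample Fisher-z comparison at the mean per-study sample
  sizes — an approximation that treats the two GWAS as independent, which
  is exactly the two-sample setting. For binary outcomes the transform is
  applied on the log-odds scale (an approximation, documented here).
* **Leave-one-out.** One IVW estimate per excluded variant. An exclusion is
  flagged when it changes the sign, leaves the all-instrument 95% CI, or
  when the reduced-set CI excludes the all-instrument estimate — the last
  rule matters because random-effects inflation widens the full CI exactly
  when one variant dominates heterogeneity.

## Mediation

The indirect effect is the product of the two step estimates (exposure →
mediator times mediator → outcome, each from univariable MR — the two-step
design; multivariable MR is out of scope). The direct effect is defined as
total − indirect, so the decomposition is exact by construction. Percent
mediated is 100·indirect/total.

Two interval engines are provided:

* **delta** (default): SE = √(a²σ_b² + b²σ_a²), symmetric normal interval.
  An exact-variance option adds σ_a²σ_b². When both point estimates are
  exactly zero the first-order variance collapses and the interval
  degenerates to a point.
* **product**: quantiles of the product of two independent normals by
  seeded Monte Carlo (default 10⁶ draws), asymmetric in general; the
  p-value is twice the smaller tail beyond zero. The two engines converge
  as the relative SEs shrink. Published mediation intervals in this
  literature are often visibly asymmetric, which indicates a
  product-distribution engine even where the text says "delta"; both are
  therefore exposed.

Multiple testing across MR associations uses Benjamini–Hochberg
(`statsmodels` step-up). In the pipeline, a mediation triple is evaluated
only when both step estimates stay significant at FDR < 0.05 within their
family; families default to one per exposure and are configurable, since
family structure is a study-design decision.

### Step-2 instrument hygiene

When instrumenting the mediator, variants that are genome-wide significant
for the exposure are excluded before selection. Such variants reach the
mediator GWAS through the exposure and affect the outcome through exposure
paths other than the mediator, so keeping them biases the mediator→outcome
step toward (A·B + C′)/A. With the exclusion, the step-2 instrument set is
dominated by mediator-specific variants, as the two-step design assumes.

## Synthetic data generator

The generator emulates the summary statistics of three non-overlapping
GWAS over a shared variant panel, directly at the summary level: for
variant j with effect-allele frequency f_j and sample size n, the reported
SE is the large-sample value 1/√(2 f_j (1−f_j) n) for a standardized
trait, the reported beta is the true marginal effect plus centred normal
noise at exactly that SE, and p-values are two-sided normal. True marginal
effects follow the diagram: γ_j on the exposure, γ_j·A on the mediator,
γ_j·(A·B + C′) + α_j on the outcome. Horizontal pleiotropy α_j is present
for a configurable fraction of instruments, drawn N(mean, sd) and applied
relative to the *exposure-increasing* allele — allele labels are
arbitrary, so a fixed-sign offset on the labelled allele would cancel
under Egger's orientation and "directional" would be meaningless.
Optionally, additional mediator-specific variants carry effects δ_j on the
mediator and δ_j·B on the outcome and none on the exposure; these are what
make an unconfounded mediator→outcome step estimable, mirroring real
mediator GWAS that contribute their own loci. LD is block-diagonal
exchangeable; true effects attach to one index variant per block and are
tagged at r·γ by the rest, which is sufficient structure for clumping to
be meaningful.

Defaults describe a well-powered study: 50 instruments, MAF uniform on
(0.05, 0.5), per-allele effects N(0, 0.05²) (mean F ≈ 60 at n = 50,000,
comfortably past the F > 10 convention), GWAS of 50,000 per trait, causal
chain A = 0.3, B = 0.2, C′ = 0.1 (total 0.16), no pleiotropy, no LD.

What the generator does **not** emulate: individual-level genotypes,
sample overlap between the GWAS, population stratification, liability-scale
binary traits (binary outcomes are log-odds betas with the user's SE
scale), allele-frequency differences between studies, and genomic
positions. Tests passing on this generator therefore validate the
estimators and the pipeline logic under clean two-sample assumptions, not
robustness to those real-data complications.

## Simulation studies shipped with the tests

Problem sizes are chosen to give stable Monte-Carlo answers at desk scale:
calibration uses 1,000 replicates of the default study (coverage and
type-I error bands ±2% and ±1.5%); Q-uniformity is checked under the null
configuration, where first-order weights are exact (see above); the
pleiotropy diagnostics use 200 replicates (Egger intercept recovery) and
50 replicates of 20 instruments with two planted 10-SE outliers
(MR-PRESSO); parameter recovery uses 200 replicates of the default study
plus 50 mediator-specific variants.

Two experimental-design choices deserve note. First, estimator-calibration
checks harmonize the generator's instruments directly rather than
re-screening them at p < 5e-8: screening on the same betas that enter the
Wald denominators induces winner's-curse weak-instrument bias, which is a
property of the screening step, not of the estimator under test (the full
screening pipeline is exercised separately). Second, the Egger-intercept
recovery study withholds the Steiger directionality filter, which
preferentially deletes strongly pleiotropic instruments and would censor
the quantity being estimated.

## Known limitations

* Ratio-based IVW carries a finite-sample attenuation of roughly 1/F̄ per
  step (≈1.5–3% at the generator's defaults); products of two steps
  compound it. This is the textbook weak-instrument dilution of two-sample
  MR, visible in the recovery studies as a small systematic shortfall of
  the recovered indirect effect.
* No multivariable MR, mode-based estimators, CAUSE-style methods, radial
  MR, or I²GX diagnostics.
* No reference-panel LD computation, proxy-variant lookup, or liftover;
  LD must be supplied (or simulated).
* The Steiger p-value's Fisher-z approximation uses mean sample sizes;
  per-variant heterogeneous n is summarized, not modelled.
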