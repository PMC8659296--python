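# Methods

This package re-implements, as tested reusable code, the quantitative
workflow of a study of ecdysone-driven antimicrobial-peptide (AMP)
expression at *Drosophila melanogaster* pupariation and its effect on
bacterial persistence through metamorphosis. Four strands of analysis are
covered; each is exercisable end to end on synthetic data with known ground
truth.

## Relative qPCR quantification and factorial contrasts

Expression is quantified by the ddCT method: for each biological sample
(a pool of five individuals) and target gene, technical CT replicates are
averaged; dCT = CT(target) − CT(*rpl32*), the housekeeping reference;
ddCT subtracts the mean dCT of the calibrator cell (control genotype at the
mid-L3 larval stage); fold-change = 2^−ddCT. By construction the calibrator
cell has geometric-mean fold-change 1.

Fold-changes are analysed on the natural-log scale with an ordinary
least-squares fit of the full Genotype × Stage × Gene factorial (a
Gaussian-family identity-link GLM; implemented via statsmodels OLS). The
choice of log base only rescales estimates — p-values and letter groupings
are invariant. Pairwise comparisons of estimated marginal (cell) means are
formed within conditioning families (e.g. L3 vs P0 within each genotype, or
between genotypes at P0), with standard errors from the pooled residual
variance, Tukey adjustment per family via the studentized-range
distribution, and a compact letter display at the chosen alpha (cells
sharing a letter are not significantly different). Technical replicates are
aggregated by arithmetic mean before the model; no efficiency-corrected
(Pfaffl) model and no mixed effects — samples are treated as independent.

## CFU quantification and load categories

Each pupa or pharate adult is macerated in 300 µL of medium of which 50 µL
are plated, so one colony represents 6 CFU per individual (the
`dilution_factor`, default 6). Per-pupa loads are reported in five
log-decade classes: [0, 10], (10, 10²], (10², 10³], (10³, 10⁴], (10⁴, ∞).
Bins are upper-inclusive so every load maps to exactly one class; a load of
exactly 10 counts as cleared ("0–10").

## Zero-inflated negative binomial regression

Per-individual counts y with stage s ∈ {0 = P0, 1 = pharate adult} follow a
two-part mixture: a logistic component for structural zeros,
logit π = γ₀ + γ₁ s (zero — an individual without culturable bacteria — is
the event of interest), and an NB2 negative binomial for counts,
log μ = β₀ + β₁ s with Var(y) = μ + μ²/θ and a stage-shared dispersion θ.
Positive β₁ means loads rise across metamorphosis.

The fit maximises the exact mixture log-likelihood over (β, γ, log θ).
Numerical choices:

* the zero branch log(π + (1−π)·NB(0)) uses log-sum-exp stabilisation; an
  independent naive evaluation is kept as a test oracle;
* analytic gradient; L-BFGS-B followed by a damped-Newton polish with a
  central-difference Hessian (step 1e-5·(1+|x|));
* starting values: the closed-form two-group Poisson fit for β, empirical
  per-stage zero-fraction logits for γ, log θ = 0;
* convergence: max-abs gradient ≤ 1e-6 (KKT-reduced at clamped
  coordinates). When the polish stalls — relative log-likelihood change
  below 1e-10 at double precision, which happens on ill-conditioned subsets
  with very few positive counts — the fit is accepted if the gradient norm
  is below √tolerance (1e-3). A genuinely stalled optimiser returns
  `converged=False` rather than raising;
* clamps: perfect separation of the zero indicator within a stage drives
  |γ| to a bound of 15 (π within 3·10⁻⁷ of 0 or 1); barely-identified
  dispersion drives |log θ| to a bound of 10. Both are flagged `boundary`
  and treated as boundary maxima, not failures;
* standard errors, used for diagnostics only, come from the inverse
  observed information (numerical Hessian).

Degenerate inputs — a stage absent, all counts zero, no zeros at all, or a
stage with no positive count — raise a distinct error: they cannot identify
the model. The last condition (per-stage positives) extends the obvious
degeneracy list because with no carriers in a stage the count-component
stage coefficient runs to −∞; treating such subsets as degenerate (and, in
the resampling engine, redrawing them) keeps the coefficient distribution
interpretable.

Correctness is established three ways: a naive-formula likelihood oracle, a
dense grid search on a small fixed dataset, and coefficient agreement with
an independent ZINB implementation (statsmodels) on simulated data.

## Resampling engine

For one genotype × bacterium dataset spanning both stages, each of 4000
cycles draws 60 rows without replacement (rows are replaced between
cycles), fits the ZINB, and stores the two stage coefficients (β₁, γ₁).
Subsampling is simple random, unstratified — the closest literal reading of
drawing "subsets of 60 entries" — with an explicit repair rule: degenerate
subsets and non-converged fits are redrawn from a fresh substream, counted,
and capped at 50× the cycle count. Substreams are derived counter-style
from (seed, cycle, attempt), so redraws never shift later cycles and
results are bit-reproducible for a given seed. Subsets are returned as
sorted index sets so floating-point summation order cannot perturb the fit.

The coefficient distributions are summarised by median, quartiles,
0.05/0.95 quantiles (linear interpolation with plotting position
(k−1)/(n−1), so the 0.05 quantile of 1..100 is 5.95) and a one-sample
Wilcoxon signed-rank test of central tendency against zero. The Wilcoxon
uses the normal approximation with tie correction and continuity correction
(exact enumeration is irrelevant at n = 4000); zeros are dropped before
ranking; the effect size is r = |z|/√n, which approaches the one-sided
ceiling √(3(n+1)/(2(2n+1))) ≈ 0.866 when every coefficient has the same
sign. With the continuity correction, r sits ~1e-7 below that closed form
rather than exactly on it — within the rounding of any printed value.

## Motif scanning

A JASPAR-format position frequency matrix becomes a log-odds PWM in bits:
per cell, log2[(count + pseudocount·bg)/(total + pseudocount)/bg], with a
configurable background (default uniform 0.25) and pseudocount (default
0.1). The null distribution of the score of a random background L-mer is
computed exactly, up to discretization, by dynamic programming over integer
score grids (1000 bins across the attainable range — p-value error far
below the 1e-4 filter); windows are scored on the same integer grid, so
window p-values and the DP are mutually consistent, and an exhaustive
enumeration oracle checks the DP for short motifs. A scan reports every
window on either strand (reverse strand scored against the reverse
complement) with p < threshold; windows containing N are skipped; no
multiple-testing correction over windows is applied — the published filter
is a raw p < 1e-4.

## Synthetic data

The generators define the study conditions the tests exercise:

* **CFU counts** — the ZINB forward model via the gamma–Poisson mixture,
  100 individuals per stage per genotype × bacterium (the plating design's
  sample size). The control-like default (P0: π = 0.83, μ = 800, θ = 0.3;
  pharate: π = 0.93, μ = 80, θ = 0.3) puts most individuals in the cleared
  0–10 class with a heavy tail above 10³ CFU and a carrier mean falling an
  order of magnitude across metamorphosis (β₁ = log 0.1 ≈ −2.3); the
  EcRDN-like condition mirrors the stages so loads rise. Counts are
  generated directly on the per-pupa scale (the scale the regression
  models), so the 6× plate scaling is exercised separately by the CFU
  module. Within-gut ecological dynamics are not modelled; individuals are
  i.i.d. draws.
* **CT tables** — CT = baseline − (log2 effect) + Gaussian replicate noise
  (default sd 0.2 CT units, 2 technical replicates, 5 biological samples
  per cell); the reference gene is untouched by effects, so a planted +3
  log2 effect inverts downstream to a fold-change of exactly 8 at zero
  noise. Real qPCR features not emulated: amplification-efficiency
  differences between genes, plate effects, and censoring at the cycle
  ceiling.
* **Promoters** — i.i.d. background sequence with the motif consensus
  written at chosen non-overlapping positions, returned with the ground
  truth.

All generators draw from one counter-based RNG stream per dataset, keyed by
(seed, dataset label), so the order in which datasets are produced is
irrelevant.

Two packaged fixtures are synthetic stand-ins, labelled as such: a
developmental RPKM table for 20 AMP transcripts whose pupariation peak is
dominated by drs, drsl2 and drsl5 (the three jointly 95% of the P0 total,
drs + drsl2 70%, all other AMPs two to three orders of magnitude lower),
and an AT-rich 10-column binding-motif count matrix standing in for an
ecdysone-response transcription factor's JASPAR record. Because both are
constructed, analyses over them demonstrate the pipeline's arithmetic, not
biological measurements.

## Known limitations and open choices

* Whether the original subsets were stratified by stage, and whether failed
  fits were redrawn or dropped, is not documented; the unstratified draw
  with a logged redraw rule is this package's choice. Under the default
  control-like conditions the redraw fraction stays below 20%.
* The "slope" summarised in coefficient plots is mapped to the
  count-component stage coefficient β₁ (sign convention: positive = more
  bacteria at the pharate stage); γ₁ is retained and reported alongside.
* The ZINB stage coefficient is noticeably biased at the study's own sample
  size: with ~100 individuals per stage but only ~7–17 positive carriers
  under the default zero-inflation, the package's simulation experiment
  (500 replicates, reported by `scripts/acceptance.py` as
  `zinb_beta1_bias_n100`) measures a mean bias near −0.2 on a true β₁ of
  −2.3, driven by the concavity of the log link at small carrier counts. An
  independent reference implementation shows the same or larger bias, so
  this is a property of the estimator under these conditions, not of this
  implementation. Sign-level conclusions are unaffected.
* Exact reproduction of published contrast p-values is not attempted: the
  multiplicity adjustment behind the original marginal-means output is not
  stated, and Tukey (the package default of that environment) is assumed.
* Whether the original Wilcoxon used a continuity correction is unstated;
  printed effect sizes (0.865 vs 0.866) differ by less than the
  correction's effect, so the choice here (with correction) is noted rather
  than claimed as theirs.

## Problem sizes

The default test suite runs the full 4000-cycle resampling for the two
headline conditions and 500-replicate bias and agreement experiments;
`scripts/acceptance.py` repeats them from scratch in about a minute on one
CPU. Analysis drivers accept `--n-iterations` to scale the resampling.
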