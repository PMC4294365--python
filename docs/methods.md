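# Methods

This note documents the statistical procedures the package implements, the
generative model behind the synthetic cohorts, the numerical choices, and
what the shipped tests do and do not demonstrate.

## Copy-number calling

Input is a table of probe-level states (one of loss / neutral / gain per
probe per patient), the representation produced upstream by aCGH
segmentation; this package deliberately does not re-derive states from
intensities. Calling proceeds in three steps:

1. **Collapse.** Maximal runs of probes sharing a non-neutral state within
   one chromosome become regions. Coordinates are 0-based half-open; a
   region spans `[first probe, last probe + 1)` because probe target
   extents are unknown — the conservative (shortest defensible) span.
2. **Filter.** Regions supported by a single probe are removed first; then
   regions wholly inside an assembly gap (centromere/telomere) are dropped
   and regions partially overlapping a gap are trimmed to exclude the
   overlap, never extended. A region bisected by a gap keeps both flanks,
   each re-snapped to the probe grid with its probe count recomputed, and
   the single-probe filter is re-applied to the flanks. (The ordering —
   filter, trim, re-filter — is a package choice; trimming before or after
   the first filter only differs for single-probe fragments that the final
   re-filter removes anyway.)
3. **Intersect.** A gene is called gain (loss) when ≥ 1 bp of a gain
   (loss) region overlaps its merged annotation interval. If both states
   overlap one gene, the larger total overlap wins; an exact tie is called
   neutral with a logged warning — deterministic and conservative.

## Percent genome aberration

Raw PGA is 100 × (summed region lengths) / (summed chromosome sizes), with
the denominator taken from the provided chromosome-size table so toy
genomes are exact. The per-gene *adjusted* PGA excludes the gene's
chromosome from both numerator and denominator: a gene genuinely coupled
to instability must show the association genome-wide, not through the
aberration that produced its own call. On the default 22-chromosome
genome, raw and adjusted PGA correlate at r > 0.95.

Association tests: Mann-Whitney U (exact enumeration when the pooled
sample is ≤ 20 without ties, otherwise normal approximation with tie and
continuity correction; an all-tied comparison returns p = 1) and Welch's
unequal-variance t-test — both are reported because neither is privileged
in practice. "Altered" defaults to gain-or-loss; a gain-only flag exists
for sensitivity analyses. The covariate-adjusted model is OLS of adjusted
PGA on the alteration indicator plus the three dichotomized clinical
covariates.

## Survival analysis

Follow-up is censored administratively at 5 years; the primary outcome is
time to biochemical recurrence. Clinical covariates enter dichotomized:
PSA < 10 vs ≥ 10 ng/mL, T1 vs T2–T3, Gleason ≤ 6 vs ≥ 7. The gain-vs-
neutral contrast for a focal gene excludes loss carriers by default
(poolable via a flag).

The Cox model is fit by Newton-Raphson on the partial likelihood with
analytic gradient and Hessian, covariates centered for stability,
convergence at gradient sup-norm < 1e-8, and step-halving on any
likelihood decrease. Efron's tie correction is the default; Breslow is
available by flag (the two coincide on the generator's continuous event
times). Standard errors come from the inverse observed information; Wald
95% CIs are exp(β ± 1.96·SE). A coefficient escaping |β| > 15 is treated
as monotone likelihood (separation): the fit is returned flagged, with a
warning rather than an exception. Proportionality is checked per covariate
by the Pearson correlation of Schoenfeld residuals with event time.
Absolute 5-year risks use the Breslow baseline cumulative hazard.

Added-value metrics compare the clinical-only Cox model with the
clinical + marker model on the same patients. Patients are *determinate*
if they either relapse by 5 years or are followed event-free to 5 years;
patients censored earlier are excluded, and the excluded counts are
reported so the exclusion is auditable. The c-statistic is the fraction of
(event, event-free) pairs ranked correctly (ties 0.5) — equivalent to the
Mann-Whitney U scaled to [0,1] and invariant under monotone transforms of
the score. NRI is the category-free (continuous) variant, since no risk
categories are defined for this disease setting; IDI is the difference in
mean predicted risk between events and non-events, new model minus old.

## Co-segregation screening

Each gene pair yields a 2×2 table of altered/neutral patients and two
one-sided Fisher exact tests: `greater` for co-occurrence, `less` for
mutual exclusivity. Bonferroni correction multiplies by the number of
tested pairs (15 for the six DDR genes), separately per side; the
significance threshold applied to the corrected p is configurable and
defaults to 0.001. The pooled matrix is treated as exchangeable — cohort
of origin is not a stratification factor.

## Expression

NanoString-style normalization runs positive-control lane scaling →
negative-control background subtraction (mean by default, mean + 2 SD by
flag) → housekeeping geometric-mean content scaling, in that fixed vendor-
conventional order, with the expected 6/8/3 control-probe layout enforced.
The cell-line analysis regresses SF₃Gy on normalized abundance by OLS and
reports r², the two-sided slope p and n; the default exclusion list drops
PrEC, whose clonogenic measurement is a 2 Gy surrogate. Median-stratified
survival sends ties to the low stratum and delegates to the survival
module.

## The synthetic cohort generator

The generator is the package's study bed: it emulates the *statistical
structure* the analysis assumes, not the biophysics of aCGH.

**Genome.** 22 autosomes of 1 Mb, probes every 20 kb, telomeric gaps of
10 kb at both ends and a 40 kb centromere per chromosome. Genes are 100 kb
(5 probes); the six DDR genes sit on distinct chromosomes so per-gene
chromosome exclusion is meaningful, using the real chromosome where that
assignment is unique (NBN chr8, MRE11A chr11, RAD50 chr5, ATR chr3).

**Gene events.** Per gene, each patient independently draws gain / loss /
neutral at configured prevalences. Default gain/loss prevalences follow
the radiotherapy cohort the scenarios emulate: NBN 14.4%/0.7% (15.1%
altered), ATR 8.6%, PRKDC 7.9%, ATM 5.8% total alteration, RAD50 and
MRE11A below 5%, with splits favouring gains. Probes over the gene body
(plus a uniform random flank up to 40 kb on each side when altered) are
set to the planted state, so every planted event spans ≥ 2 probes, never
touches a gap, and the probe→region→gene pipeline reproduces the planted
truth exactly — the property the calling tests assert.

**Background instability.** Aberrant segments arrive as a per-chromosome
Poisson process (default rate 5×10⁻⁷ per bp) with exponential lengths
(mean 100 kb) and a fair gain/loss coin, giving a mean PGA near 5% —
a realistic magnitude for localized prostate tumours. DDR-altered patients
receive a rate increment calibrated so their expected *realized* PGA
(after probe quantization, the single-probe filter and gap/gene masking)
rises by `pga_shift` = 5 percentage points: for exponential lengths of
mean L on a grid of spacing s the expected retained span per segment is
L·e^(−s/L), and the masked genome fraction is known, so the increment has
a closed form up to chromosome-edge effects of a few percent.

**Covariates and outcomes.** Clinical indicators are independent Bernoulli
draws at the radiotherapy-cohort mix (PSA ≥ 10: 33.8%, T2–T3: 64.0%,
GS ≥ 7: 75.5%); raw PSA/T/Gleason values are synthesized consistently with
their indicator. Event times are exponential with rate
λ₀·exp(Σβx) — the simplest model satisfying the proportional-hazards
assumption the Cox analysis presumes. Censoring is administrative: accrual
uniform over a 6-year window read against a fixed analysis date, so censor
times are U(4, 10) years and ≈ 17% of patients censor before the 5-year
horizon. The true accrual pattern of the emulated cohorts is unpublished;
this censoring model is a stand-in, not an inference.

**Shipped scenarios.**

| scenario | calibration |
|---|---|
| `igrt_default` | prevalences + covariate mix above; multivariable log-hazards ln 3.28 (NBN gain), ln 2.93 (PSA), ln 0.91 (T2–T3), ln 0.89 (GS ≥ 7); λ₀ = −ln(0.85)/5 |
| `km_calibrated` | two-group exponential hazards pinned to 5-year relapse-free rates 77% (NBN neutral) and 46% (NBN gain) |
| `cox_calibrated` | the multivariable log-hazards of `igrt_default` at n = 50,000 for parameter recovery |
| `cox_univariate` | single planted log-hazard ln 3.35 on NBN gain |

**Expression.** Endogenous counts are linear in SF₃Gy on the normalized
scale, wrapped in lane factors, a 30-count background and optional
negative-binomial noise. Defaults are integer-exact at zero dispersion so
the noise-free r² = 1 invariant holds exactly. The five-line panel (PrEC,
LNCaP, 22RV1, PC-3, DU-145) carries SF₃Gy values of 0.30/0.20/0.40/0.55/
0.70 — a plausible radiosensitivity ordering, not measured data.

**What passing tests show.** Recovery of planted prevalences, hazard
ratios, survival rates and instability shifts demonstrates that the
*analysis chain is correct and internally calibrated*. It does not
validate the biology: real aCGH data have correlated probe noise,
segmentation errors, tumour heterogeneity and non-exponential hazards,
none of which the generator models, and the real-cohort effect sizes used
to calibrate scenarios are taken as givens, not re-estimated.

## Problem sizes and determinism

Calibration studies use n = 20,000 (Kaplan-Meier, probe-pipeline
prevalence; ~3 binomial-SD bands) and n = 50,000 (Cox recovery to ±5%),
sizes at which Monte-Carlo error sits comfortably inside the stated
tolerances; the instability association runs at the pooled cohort size
n = 293. All randomness flows from a single integer seed through
`numpy.random.SeedSequence` fan-out, so every stage is independently
re-runnable and full runs are byte-reproducible.

## Known limitations

* Probe grids are regular and shared across patients; irregular platforms
  work for collapsing/intersection but the trimming step assumes one grid
  per chromosome.
* The Schoenfeld check is a residual-vs-time Pearson correlation, not the
  full scaled-residual score test; it is a screen, not a proof of
  proportionality.
* NRI/IDI standard errors are not computed (the emulated analysis reported
  point estimates only).
* Competing risks, time-varying covariates and tumour multifocality are
  out of scope.
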