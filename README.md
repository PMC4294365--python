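# ddrcna

Copy-number alteration (CNA) calling, genomic-instability metrics and
censored survival-biomarker evaluation for the DNA-damage-response (DDR)
sensor genes — *MRE11A*, *RAD50*, *NBN* (the MRN complex) and *ATM*, *ATR*,
*PRKDC* (the PI3K-like kinases) — in localized prostate cancer.

## The problem

Clinical prognostic factors (pre-treatment PSA, T-category, Gleason score)
leave wide outcome heterogeneity after image-guided radiotherapy (IGRT) or
radical prostatectomy. Because radiotherapy kills tumour cells through DNA
double-strand breaks, copy-number gains or losses in the genes that *sense*
DNA damage are plausible treatment-specific biomarkers. This package
implements the full analysis chain needed to evaluate that hypothesis, for
anyone working with probe-level aCGH-style copy-number states and censored
biochemical-recurrence follow-up:

1. **Gene-level CNA calling** (`ddrcna.calls`) — probe states in
   {loss, neutral, gain} are collapsed into contiguous same-state regions;
   regions with a single supporting probe are removed; regions inside
   centromere/telomere gaps are dropped and regions straddling a gap are
   trimmed conservatively (shortened, never elongated); surviving regions
   are intersected with a merged gene annotation (≥1 bp of overlap calls
   the gene; larger overlap wins when both states touch a gene).
2. **Percent genome aberration** (`ddrcna.instability`) —
   PGA = 100·(aberrant bp)/(genome bp), plus a per-gene *adjusted* PGA that
   excludes the gene's own chromosome from numerator and denominator so a
   gene–instability association cannot be a mechanical artifact of its own
   locus. Associations by Mann-Whitney U, Welch t, and OLS adjusting for
   the clinical covariates.
3. **Co-segregation screening** (`ddrcna.cooccurrence`) — Fisher's exact
   test on every gene pair, one-sided in both directions (co-occurrence /
   mutual exclusivity), Bonferroni-corrected per side by the number of
   pairs.
4. **Survival biomarker evaluation** (`ddrcna.survival`) — follow-up
   censored at 5 years; Kaplan-Meier with Greenwood errors; two-group
   log-rank; Cox proportional hazards
   (h(t|x) = h₀(t)·exp(βᵀx), Efron or Breslow ties, Newton-Raphson on the
   partial likelihood, Schoenfeld-residual PH diagnostics); added-value
   metrics for a marker on top of the clinical model: the
   censoring-aware c-statistic, continuous net reclassification
   improvement (NRI) and integrated discrimination improvement (IDI), with
   5-year risks from the Breslow baseline hazard.
5. **Expression analyses** (`ddrcna.expression`) — NanoString-style
   normalization (positive-control lane scaling → negative-control
   background subtraction → housekeeping content scaling), CNA–mRNA Welch
   t-tests, median-stratified survival, and OLS of clonogenic surviving
   fraction after 3 Gy (SF₃Gy) on normalized abundance.
6. **Synthetic cohorts** (`ddrcna.simulate`) — a first-class generator
   that plants gene prevalences, a PGA shift in DDR-altered patients,
   proportional-hazards recurrence with configured hazard ratios, and
   control-probe structure, on a 22-chromosome toy genome. No external
   data are required anywhere.

## Worked example

Run the whole pipeline on a 500-patient synthetic radiotherapy-style
cohort (probe tracks → gene calls → PGA → pair screening → survival →
expression → report):

```bash
cna all --outdir run/ --scenario igrt_default --n 500 --seed 17
cat run/summary.txt
```

```
ddrcna v0.1.0 — scenario igrt_default, seed 17

Gene alteration frequencies (% of patients):
   MRE11A: gain 0.6%  loss 1.4%  any 2.0%
    RAD50: gain 0.4%  loss 1.4%  any 1.8%
      NBN: gain 12.6%  loss 0.4%  any 13.0%
      ATM: gain 3.0%  loss 2.0%  any 5.0%
      ATR: gain 3.8%  loss 3.8%  any 7.6%
    PRKDC: gain 5.4%  loss 4.6%  any 10.0%

5-year bRFR by NBN gain: 0=0.817, 1=0.616  (log-rank p=9.2e-05)
  univariate NBN_gain: HR=2.42 (1.53-3.82), p=0.000153
  multivariate NBN_gain: HR=2.78 (1.75-4.41), p=1.49e-05
  multivariate gs_ge7: HR=0.60 (0.40-0.91), p=0.0161
  multivariate psa_ge10: HR=2.78 (1.88-4.11), p=3.24e-07
  multivariate t2_t3: HR=1.12 (0.73-1.70), p=0.608
  c-statistic 0.648 -> 0.679; NRI=0.260, IDI=0.035
```

Reading it: *NBN* gain was planted at 14.4% prevalence (here 12.6% of 500
patients drew it); carriers show a lower 5-year biochemical relapse-free
rate (61.6% vs 81.7%) and an independent multivariate hazard ratio of 2.78
after adjusting for PSA ≥ 10 ng/mL, T2–T3 and Gleason ≥ 7 — at n=500 these
sample estimates scatter around the planted hazard ratios (3.28 for NBN
gain, 2.93 for PSA). Adding the marker moves the c-statistic from 0.648 to
0.679 with a continuous NRI of 0.26.

Each stage is also callable on its own (`cna simulate`, `cna call`,
`cna pga`, `cna cooccur`, `cna survive`, `cna express`, `cna report`) and
reads/writes plain-text files (SEG-like TSV, BED, CSV, JSON), so real
probe-level calls can be substituted for the simulated ones.

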