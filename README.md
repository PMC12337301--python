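# epiclock

Epigenetic clock construction and aging-rate analysis for pooled
whole-genome bisulfite sequencing (WGBS), built around a two-treatment
longitudinal design: insect cohorts (e.g. *Nasonia*-style jewel wasps, with a
functional DNA methylation system and a ~30-day adult lifespan) sampled at
several adult ages, with one treatment — larval diapause — that extends
lifespan and slows the rate of epigenetic aging.

The package is for researchers who have per-CpG methylated/unmethylated read
counts (Bismark-style coverage files) from replicated pooled libraries plus
per-individual survival records, and who want to go from counts to biology:

1. **Spike-in calibration** — the apparent methylation of an unmethylated
   lambda spike-in estimates the bisulfite non-conversion error rate *e*.
2. **Methylation-status calling** — each CpG is tested against the null that
   all its methylated reads are non-conversion noise (one-sided binomial test
   at rate *e*, Benjamini–Hochberg across sites), defining the analysis
   universe.
3. **Age-related differential methylation** — per-site binomial GLMs with a
   logit link, methylation ~ age (days), 1-df likelihood-ratio tests with a
   quasi-binomial dispersion adjustment for pooled libraries, BH-corrected.
4. **Clock fitting** — candidate CpGs are filtered by Pearson correlation
   with age in control libraries (|r| ≥ 0.3, p ≤ 0.05), then an elastic net
   (mixing parameter α = 0.5, strength λ chosen by repeated 10-fold
   cross-validation minimising RMSE) yields a sparse panel of clock CpGs and
   an age predictor: predicted age = β₀ + Σᵢ βᵢ·mᵢ where mᵢ is the
   methylation proportion at panel CpG i.
5. **Aging-rate statistics** — OLS of predicted epigenetic age on
   chronological day × treatment: per-group slopes, the interaction test,
   estimated-marginal-mean contrasts at chosen days, percent slowdown
   (1 − s₂/s₁) × 100, and the day at which the group trajectories converge.
6. **Survival** — Kaplan–Meier medians with Greenwood/log-log CIs, a Cox
   proportional-hazards treatment effect (Efron ties), and the hazard
   translation β = −ln(HR)/Δ that converts a treatment hazard ratio acting
   through a Δ-day epigenetic-age difference into a per-day hazard increment.

A synthetic-data generator (`epiclock.synthetic`) emulates the full study
design — 2 treatments × 5 timepoints (days 6–30) × 4 replicate pools of 10,
beta-binomial overdispersion, negative-binomial coverage, a 1% unmethylated
spike-in, and planted clock CpGs whose drift rate and emergence offset differ
by treatment — so every stage can be validated against known ground truth.

## Worked example

One command generates a synthetic study (with the inputs written as real
coverage/CSV files), runs the full pipeline and writes every table:

```bash
epiclock demo --out demo_run --seed 1
cat demo_run/results/report.txt
```

which prints:

```
epiclock run report
===================

funnel: 1000 sites -> 1000 methylated -> 49 age-DML -> 49 filtered -> 38 panel
clock: lambda=0.017034 panel=38 control CV R2=0.983 RMSE=1.12 d
       transfer R2=0.723 RMSE=4.46 d
trajectory: control slope=0.98046 treatment slope=0.67548 slowdown=31.1% convergence day=7.35
survival: HR=0.328 medians={'control': 23.0, 'diapause': 85.0}
          median extension=269.6%
          implied hazard increase per epigenetic day=17.5%
```

Reading the numbers: of 1,000 simulated CpGs all are called methylated (the
simulation plants no unmethylated sites), 49 show significant age-related
differential methylation, 49 survive the control-sample correlation filter,
and the elastic net keeps 38 in the final panel.  The clock explains 98.3% of
chronological-age variance in held-out control pools (RMSE 1.12 d) and
transfers to the diapause pools (R² 0.72).  The diapause group's epigenetic
aging rate is 31.1% slower than the control rate (the generator plants a rate
ratio of 0.708, i.e. a true slowdown of 29.2%), and diapause reduces the
mortality hazard (HR 0.33; the generator plants 0.35).

The same stages are available as individual commands (`epiclock import`,
`call-methylated`, `dml`, `fit`, `predict`, `trajectory`, `survival`,
`hazard-translate`, `run`) and as plain library functions.

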