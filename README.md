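# sirscan — geographic analysis of screening-cohort cancer incidence

`sirscan` implements, as a tested and reproducible pipeline, the statistical
workflow used to ask whether thyroid-cancer incidence observed in a large
multi-round ultrasound screening programme shows geographic structure: spatial
clusters of elevated risk, a general clustering tendency, or an association
with municipality-level radiation dose. It is aimed at epidemiologists and
biostatisticians who want to run (or stress-test) this class of analysis on
their own screening data, and it ships a synthetic-cohort generator with known
ground truth so every stage is testable without access to confidential
individual-level data.

## The statistical pipeline

1. **Person-period expansion.** Each subject `j` contributes one
   *pseudo-observation* per attended follow-up round `t ∈ {2, 3}` (stopping
   after a first diagnosis), with diagnosis indicator `y_jt` and the elapsed
   time `d_jt` since the most recent prior examination. BMI values outside
   [5, 50] kg/m² are treated as database recording errors and replaced from
   another attended round, or the subject is excluded.
2. **Discrete-time survival model.** The `y_jt` are Bernoulli with

   ```
   log(−log(1 − λ_jt)) = log d_jt + α + Σ_k β_k x_jtk
   ```

   a binomial GLM with complementary log-log link and offset `log d_jt`
   (a constant-hazard exponential survival model in person-years), with
   covariates sex (0 = men, 1 = women), log(age), log(BMI) and a third-round
   dummy; `exp(β_k)` is a hazard ratio.
3. **Standardized incidence ratios.** Expected counts are
   `e_i = Σ_{j∈S_i} Σ_t λ̂_jt` and `SIR_i = o_i / e_i` per region `i`.
4. **Flexibly shaped spatial scan.** All connected zones `Z` (size ≤ K,
   grown inside each region's K-nearest-neighbour set) are scored with the
   Poisson likelihood ratio comparing risk inside vs outside; the maximising
   zone is the *most likely cluster*, and its p-value comes from Monte Carlo
   replicates that redistribute the case total in proportion to the `e_i`.
5. **Clustering tendency (MEET).** Tango's C-index
   `C(s) = Σ_ij exp(−4(d_ij/s)²)(r_i − p_i)(r_j − p_j)` is profiled over
   spatial scales `s` = 5…100 km, and the minimum per-scale Monte Carlo
   p-value is multiplicity-adjusted with the same replicate set
   (maximized excess events test).
6. **Dose-group Poisson regression.** Per-region scenario doses are collapsed
   to a representative value (median; min/max as sensitivity), regions are
   grouped at <2.0 / 2.0–4.9 / 5.0–9.9 / ≥10.0 mGy, and
   `o_i ~ Poisson(r_i e_i)` with `ln r_i = Σ_k β_k z_ki` (no intercept,
   offset `log e_i`) gives each group's relative risk, an AIC comparison
   against the homogeneous-risk null, and an ordinal trend test. The same
   group dummies can enter the individual-level survival model as a
   sensitivity analysis.

## Worked example

The numbered drivers under `analysis/` run the whole study on a synthetic
cohort (59 regions, 252,502 subjects, homogeneous risk):

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_build_person_periods.py
python analysis/03_fit_survival_sir.py
python analysis/04_spatial_clustering.py --seed 1
python analysis/05_dose_response.py --seed 1
```

With `--seed 1` this prints, in turn (abbreviated):

```
simulated 252502 subjects in 59 regions: 691518 examination records, 85 diagnosed cases
BMI cleaning: 6915 records replaced, 8 subjects excluded
subgroups: D12=241901 D23=186514 D13=10593 analysed=252494
pseudo-observations: 439008 records, 85 cases

   term     coef     se      hr   hr_lo   hr_hi      p
    sex   0.1654 0.2177  1.1799  0.7701  1.8077 0.4474
log_age   2.7970 0.3897 16.3951  7.6376 35.1941 0.0000
log_bmi   0.5320 0.6222  1.7023  0.5028  5.7635 0.3926
 round3  -0.5700 0.2239  0.5655  0.3646  0.8771 0.0109

most likely cluster: 7 regions [0, 13, 29, 41, 48, 55, 56]
  observed 27, expected 14.37, relative risk 1.88, Monte Carlo p = 0.335 (R = 999)
MEET: minimum per-scale p = 0.244 at 10 km; adjusted p = 0.419

      group  n_regions  observed  expected    rr  rr_lo  rr_hi     p
     lowest         12      10.0    13.155 0.760  0.409  1.413 0.386
 middle-low         26      29.0    34.010 0.853  0.593  1.227 0.391
middle-high         15      39.0    28.958 1.347  0.984  1.843 0.063
    highest          6       7.0     8.877 0.789  0.376  1.654 0.530
AIC fitted 166.32 vs null 163.49 (delta +2.83); trend p = 0.240
```

Read: the fitted hazard ratios are consistent with the generator's true
values (age and BMI raise the hazard, the third round lowers it); because the
simulated risk surface is homogeneous, the best-scoring spatial cluster is
not significant (p = 0.335), MEET finds no clustering tendency (adjusted
p = 0.419), the dose-group model does not improve on the null by AIC
(Δ = +2.8), and the trend is flat. The individual-level sensitivity model
reproduces the ecological relative risks nearly exactly (e.g. 1.77 vs
1.35/0.76 = 1.77 for the middle-high group relative to the lowest).

The same stages are available as a library (`import sirscan`), as one
orchestrated run (`sirscan run-all --seed 1 --out results`), or as per-stage
CLI subcommands (`sirscan simulate | build | fit | sir | flexscan | meet |
dose`).

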