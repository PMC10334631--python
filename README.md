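# mwascreen

**Medication-wide association screening (MWAS/DWAS) of longitudinal claims
data for cancer prognosis.**

Hypothesis-free pharmacoepidemiology asks, for *every* prescribed drug at
once: is starting this medication associated with a patient's subsequent
survival?  `mwascreen` implements the full screening pipeline for a
colorectal-cancer prognosis setting on insurance-claims tables:

1. **Cohort construction** — cancer cases are patients with a qualifying
   diagnosis code (C18–C20) *and* treatment evidence (colonoscopy,
   operation, chemotherapy or radiotherapy); time zero t₀ is the first
   treatment date; a 2-year washout removes non-incident cases; follow-up
   runs to death or the administrative end of coverage.  The combination of
   treatments received is kept as a 6-level staging proxy.
2. **Past-1-year incident-user exposure** — prescriptions are mapped to ATC
   levels 2 and 4 (anticancer drugs excluded).  For each patient × drug
   pair: any use in [t₀−1.5 y, t₀−1 y) ⇒ *prevalent user* (excluded from
   that drug's model); otherwise use in [t₀−1 y, t₀) ⇒ *incident user*;
   otherwise *nonuser*.  Defining exposure wholly before the t₀ landmark
   removes immortal-time bias by construction.
3. **Two-stage screen** — the cohort is split 1:1 into discovery and
   validation sets.  Per drug *d* and outcome (all-cause and
   cancer-specific mortality), a Cox proportional-hazards model

   λ(t | X) = λ₀(t) · exp(β_d · user_d + γᵀ·(sex, age band, treatment
   category, Charlson category))

   is fit in the discovery set; within each outcome × ATC-level family the
   Benjamini–Hochberg step-up procedure controls the FDR at q = 0.05.
   Discovery signals are refit in the validation set and count as
   *validated* when p < 0.05 with a direction-consistent hazard ratio.
4. **Reporting** — volcano tables/plots (x = log₂ HR, y = −log₁₀
   FDR-adjusted p), a signal summary and a machine-readable manifest.

Because real national claims databases are access-restricted, the package
ships a **synthetic claims generator** (`mwascreen.synthetic_claims`) that
emulates the cohort structure of such a study — covariate margins, per-drug
never/prevalent/incident prescription histories, cause-specific Weibull
survival with *planted* drug effects — so that every stage of the pipeline
can be verified against known ground truth.

The per-drug Cox fits use a compiled Newton solver for the partial
likelihood (Efron or Breslow ties) written for the many-refits workload of
a drug-wide screen; it is cross-validated against `lifelines` and
`statsmodels` in the test suite.

## Worked example

Run the shipped demo scenario (n = 2,618 patients, 20 drugs, four planted
effects echoing a two-protective/two-detrimental signal structure):

```python
from mwascreen.synthetic_claims import default_config, simulate_analysis_frame
from mwascreen.screening import ScreenConfig, split_cohort, run_two_stage_screen

cfg = default_config()
cohort, matrices, truth = simulate_analysis_frame(cfg, levels=(2, 4))
cohort = split_cohort(cohort, ratio=0.5, seed=3)
report = run_two_stage_screen(cohort, matrices, ScreenConfig(split_seed=3))

res = report.results
sl = res[(res.level == 4) & (res.outcome == "all_cause") & (res.stage == "discovery")]
print(sl.sort_values("p_raw").head(6).round(4).to_string(index=False))
```

prints (abridged to the leading columns):

```
 drug  n_users  n_nonusers     hr  ci_low  ci_high  p_raw  p_fdr_adjusted  validated
A02AA      134        1121 2.1540  1.6408   2.8276 0.0000          0.0000       True
G03DA       77        1195 2.2150  1.5930   3.0798 0.0000          0.0000       True
N07AA      107        1142 0.5437  0.3624   0.8158 0.0032          0.0217       True
N01AH       73        1201 0.5154  0.3211   0.8272 0.0060          0.0302      False
A01AK       93        1147 1.5251  1.0904   2.1331 0.0137          0.0547      False
B01AC      141        1067 1.3162  0.9900   1.7500 0.0587          0.1956      False
```

Reading the table: among 1,309 discovery patients, 134 incident users of
magnesium compounds (A02AA, planted log-HR +0.7) show an adjusted hazard
ratio of 2.15 (95% CI 1.64–2.83); its FDR-adjusted p is far below 0.05, and
the association replicates in the validation set (`validated=True`).
Anticholinesterases (N07AA, planted log-HR −0.8) appear protective with
HR 0.54.  The null drug aspirin (B01AC) stays non-significant.  The
planted detrimental drugs validate for both outcomes; the protective
signals split across outcomes at this sample size:

```
validated (level 4): A02AA, G03DA, N07AA (all-cause);
                     A02AA, G03DA, N01AH (cancer-specific)
```

The same pipeline is available from a shell:

```bash
mwascreen simulate --out data/ --seed 7
mwascreen build-cohort --bundle data/ --cci data/covariates.csv --out cohort.csv
mwascreen exposure --bundle data/ --cohort cohort.csv --level 4 --out exposure_L4.csv
mwascreen screen --cohort cohort.csv --exposure 4 exposure_L4.csv --seed 7 --out results.csv
mwascreen report --results results.csv --out figs/
```

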