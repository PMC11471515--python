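# mrmediate

Two-sample Mendelian randomization (MR) screening and mediation analysis
over GWAS summary statistics, built for questions of the form: *does a blood
metabolite causally affect venous thromboembolism (VTE) risk, and is part of
that effect carried by an inflammatory cytokine such as PDGF-BB?*

It is aimed at statistical geneticists and epidemiologists who work with
summary-level GWAS exports (metabolite panels, cytokine panels, case-control
endpoints) and want a tested, deterministic, scriptable pipeline instead of
ad-hoc notebook code.

## What it computes

Using genetic variants as instrumental variables, with per-SNP exposure
effects γ_j and outcome effects Γ_j (log-odds for case-control outcomes):

* **Instrument construction** — p-value selection (default p < 1e-5),
  greedy LD clumping (r² ≤ 0.001 within 10,000 kb), palindromic-SNP
  exclusion at intermediate allele frequency, confounder-SNP exclusion
  lists, per-SNP R² = 2·MAF(1−MAF)·(β/SD)² and F = (N−2)·R²/(1−R²) with an
  F ≥ 10 filter, and allele harmonization across traits.
* **Five estimators** — inverse-variance-weighted (IVW, with multiplicative
  random effects when Cochran's Q > df), MR-Egger, weighted median, and
  weighted/simple mode, all reported as β, SE, p, OR = exp(β) with 95% CI.
* **Diagnostics** — Cochran's Q, MR-PRESSO (global, outlier and distortion
  tests), leave-one-out; exposures losing significance after outlier
  correction are dropped from downstream tables.
* **Multiple testing** — Benjamini-Hochberg FDR per outcome with
  significant (adjusted p < 0.05) / suggestive (raw p < 0.05 only) tiers.
* **Mediation** — two-step MR gate (all three legs p < 0.05), multivariable
  MR for direct effects, and the product-of-coefficients mediated effect
  β_EMO = β_EM·β′_MO with delta-method SE
  √(β′_MO²·SE_EM² + β_EM²·SE′_MO²) and mediated proportion β_EMO/β_EO.
* **Synthetic data** — a seeded generator of exposure/mediator/outcome
  summary statistics under a known structural model, including emulation of
  instrument selection (and hence winner's curse), for fully offline
  testing and calibration.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

Reproduce the arithmetic of a published mediation pathway — glycocholate →
PDGF-BB → VTE, where the exposure→mediator effect is β_EM = −0.097
(SE 0.036), the MVMR-adjusted mediator→outcome effect is β′_MO = 0.089
(95% CI 0.041–0.136), and the total effect is β_EO = −0.059:

```python
from mrmediate import mediation_effect, se_from_ci

res = mediation_effect(
    beta_em=-0.097, se_em=0.036,
    beta_prime_mo=0.089, se_prime_mo=se_from_ci(0.041, 0.136),
    beta_eo=-0.059,
)
print(f"mediated effect {res.beta_emo:.3f} "
      f"(95% CI {res.ci_low:.3f}, {res.ci_high:.3f}), "
      f"proportion {res.proportion_pct:.1f}%")
```

prints

```
mediated effect -0.009 (95% CI -0.016, -0.001), proportion 14.6%
```

i.e. about 15% of glycocholate's protective effect on VTE is carried through
lowered PDGF-BB, and the mediated-effect CI excludes zero.

An end-to-end run on synthetic cohorts:

```bash
mr-mediate simulate --seed 1 --theta-direct 0.08 --out results/sim
mr-mediate screen --config config.yaml --seed 2 --out results/screen
```

where `config.yaml` points `exposure_files`/`outcome_files` at the simulated
TSVs. The same stages are available as library calls (`run_screen`,
`run_mediation`, `run_reverse`) and as narrative drivers under `analysis/`
(01 simulate → 02 screen → 03 mediation → 04 calibration), each writing its
tables under `results/`.

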