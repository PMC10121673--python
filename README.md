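# scarsig

Mutational-signature analysis for predicting durable immunotherapy benefit
in advanced non-small cell lung cancer (NSCLC).

Response to immune checkpoint inhibition in advanced NSCLC is hard to
predict from pre-treatment information. Tumor mutational burden (TMB)
pools all coding mutations regardless of origin; mutational signatures
instead partition the mutation spectrum by the mutagenic process that
produced it — tobacco smoke (SBS4), thiopurine exposure (SBS87), APOBEC
activity, and so on. `scarsig` implements the full analysis pipeline that
turns somatic variant calls into a durable-benefit prediction:

1. **Spectrum extraction** — single-base substitutions are classified into
   the 96 trinucleotide channels (pyrimidine-strand convention) to form a
   sample × channel count matrix **X**.
2. **Fixed-catalog refitting** — given a catalog **H** ∈ ℝ₊^{p×n} of
   signature profiles (rows sum to 1), per-sample activities
   **W** ∈ ℝ₊^{m×p} minimise ‖X − WH‖² subject to W ≥ 0, solved by cyclic
   coordinate descent (tolerance 10⁻⁶, at most 10⁴ sweeps). Activities and
   TMB are reported per megabase (default exome size 47.9 Mb), rounded to
   two decimals.
3. **Univariate screening** — per-signature two-sided Kolmogorov–Smirnov
   tests between durable-benefit strata, Benjamini–Hochberg corrected
   (q ≤ 0.05); Kendall τ-b for signature–gene correlation; Fisher exact
   enrichment; a logistic check for gene–TMB confounding.
4. **Classification** — a naive Bayes classifier whose per-class feature
   model is a zero-inflated exponential: P(x|c) = π_c at x = 0 and
   (1 − π_c)·λ_c·e^{−λ_c x} for x > 0. The decision threshold is 0.438,
   the estimated population prevalence of durable benefit. Discovery-style
   results use leave-one-out cross-validation.
5. **Evaluation** — ROC AUC, average precision, sensitivity/specificity
   with 1000-iteration bootstrap CIs, paired/unpaired permutation tests,
   calibration, and decision-curve analysis (net benefit
   TP/n − (FP/n)·p_t/(1 − p_t) plus its untreated-side counterpart).
6. **Survival** — Kaplan–Meier curves and medians, Cox proportional
   hazards for the predicted grouping (Breslow ties, Newton–Raphson on
   the partial likelihood), and a regression-coefficient test comparing
   hazard ratios across cohorts.

Durable benefit (DB) is progression-free survival (PFS) ≥ 26 weeks; a
patient censored before 26 weeks is labelled *unknown* and enters only
the survival analysis. The label is always derived from (PFS, event),
never read from a file.

Because the cohorts this kind of analysis is run on are access-restricted
clinical datasets, the package ships a first-class synthetic-cohort
generator (`scarsig.synthetic`) that reproduces the statistical structure
the pipeline assumes: zero-inflated exponential signature activities with
two informative signatures, Poisson mutation catalogs X ~ Poisson(WH),
variant files whose trinucleotide contexts realise the spectrum exactly,
and censored exponential PFS with a class-dependent hazard.

## Worked example

```python
import scarsig as ss
from scarsig.synthetic import SimulationConfig, simulate_cohort
from scarsig.refit import refit

# Published worked examples: the discovery confusion counts
# (36 DB / 57 non-DB labelled patients, 8 FP, 16 FN) ...
print(ss.confusion_metrics(tp=20, fp=8, tn=49, fn=16))
# {'sensitivity': 0.56, 'specificity': 0.86, 'accuracy': 0.74, 'f1': 0.63}

# ... and the cross-cohort hazard-ratio comparison from printed intervals.
print(round(ss.compare_hazard_ratios((0.40, 0.23, 0.68),
                                     (0.24, 0.10, 0.55)), 2))
# 0.32   (the two cohorts' hazard ratios are statistically compatible)

# Synthetic cohort at the default study conditions (m=101 patients).
cohort = simulate_cohort(SimulationConfig(seed=1))
attribution = refit(cohort.spectrum, cohort.catalog, coverage_mb=47.9)
print(attribution.per_mb[["SBS4", "SBS87"]].head(3))
#        SBS4  SBS87
# P0000  2.02   3.42
# P0001  0.31   0.37
# P0002  0.57   1.24

# Leave-one-out cross-validated prediction and the PFS hazard ratio
# between predicted groups.
preds = ss.loocv(attribution.per_mb[["SBS4", "SBS87"]],
                 cohort.cohort["db_label"].to_numpy())
group = (preds["predicted"] == "yes").astype(int).to_numpy()
fit = ss.cox_binary(cohort.cohort["pfs_weeks"], cohort.cohort["event"], group)
print(f"hazard ratio {fit.hazard_ratio:.2f} "
      f"[{fit.ci_bounds[0]:.2f}, {fit.ci_bounds[1]:.2f}], p = {fit.p:.3f}")
# hazard ratio 0.57 [0.33, 0.98], p = 0.041
```

The per-Mb attributions are mutation counts attributed to each signature
divided by covered megabases; the hazard ratio below 1 means patients the
classifier flags as beneficiaries progress more slowly.

A command-line interface mirrors the library
(`scarsig simulate | spectrum | refit | screen | classify | evaluate |
survival | dca`, with global `--seed` and `--config`); run
`scarsig --help` for details.

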