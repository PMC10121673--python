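# Methods

## Problem setting

Advanced NSCLC patients treated with immune checkpoint inhibitors are
labelled by durable benefit (DB): progression-free survival of at least
half a year, taken as exactly 26 weeks since PFS is recorded in weeks.
Censoring before 26 weeks makes the label *unknown*; such patients are
excluded from classification metrics but retained in survival analyses.
The pipeline asks whether signature-resolved mutation burden — rather
than total mutational burden — identifies the beneficiaries.

## Spectrum extraction

Single-base substitutions are classified by the pyrimidine-strand
substitution type (C>A, C>G, C>T, T>A, T>C, T>G) and both flanking bases,
giving 96 channels. Records whose reference base is a purine are
reverse-complemented (alleles and flanks) before labelling. Variants with
an N in the context or at a contig edge are skipped and counted in the
log; a VCF REF allele that disagrees with the reference FASTA is an
error, not a skip, because it indicates mismatched inputs. Only records
flagged nonsynonymous are counted: the burden of interest is
amino-acid-changing mutations. Doublet, indel and copy-number spectra
(DBS-78, ID-83, CN-48) are consumed as precomputed matrices; native
extraction is out of scope.

## Fixed-catalog refitting

With the catalog **H** fixed, the least-squares problem
min‖X − WH‖², W ≥ 0 decouples across samples into independent
non-negative least-squares fits — the per-sample solution is identical to
a joint multiplicative/coordinate update on W, but simpler and directly
testable. Each row is solved by cyclic coordinate descent with the exact
single-coordinate minimiser w_s ← max(0, w_s − g_s/(HHᵀ)_ss); the
objective is non-increasing by construction and asserted per sweep.
Convergence: relative objective decrease < 10⁻⁶ over a sweep, at most
10⁴ sweeps. Initialisation is the clipped unconstrained least-squares
projection max(0, xHᵀ(HHᵀ)⁻¹); the problem is convex, so initialisation
affects speed only. The test suite checks the optimum against SciPy's
active-set NNLS solver as an independent oracle.

Attributions and TMB are normalised per megabase of covered sequence
(default 47.9 Mb, the exome size used when per-sample coverage is
unknown; a per-sample coverage Series is accepted) and rounded
half-away-from-zero to two decimals — matching the convention of printed
values such as 0.91 Mb⁻¹. Rounding uses decimal arithmetic on the
shortest float repr so that, e.g., 0.625 → 0.63.

Signatures flagged as sequencing artefacts, and signatures whose
attribution variance is exactly zero within either DB stratum of the
discovery labels, are excluded before modelling; each stratum needs at
least two samples for the variance to be defined.

A variant's **responsibility** vector splits its channel's reconstructed
intensity over signatures: r_s = W_is·H_sk / Σ_t W_it·H_tk. A signature
with r_s ≥ 0.5 is *dominant*; an exact tie at 0.5 reports both (the ≥ is
inclusive). A channel with zero reconstructed intensity leaves the
variant unattributed. The dominance wording in the source material is
ambiguous ("accounts for ≥ 50 % of the signature's mutations"); the
standard responsibility reading — the signature carries at least half of
the variant's attribution mass — is implemented.

## Univariate screening

Signature–outcome differences use the two-sided two-sample
Kolmogorov–Smirnov test (exact p by enumeration for tie-free pooled
samples of ≤ 12 observations, asymptotic otherwise; both regimes agree
where the method is used). Multiplicity is controlled per test battery
with Benjamini–Hochberg (one family across the signatures of a channel
system, one across a gene panel), significance at q ≤ 0.05.
Signature–gene correlation uses Kendall τ-b with tie-corrected variance
and a normal-approximation p (adequate at cohort sizes near 100);
non-mutated genes are excluded before correction since their correlation
is trivially zero. Enrichment of tumor-suppressor/oncogene annotations
uses Fisher's exact test. Confounding of TMB by a gene is assessed by
fitting logistic models of DB on TMB with and without the gene indicator
(maximum likelihood via IRLS) and flagging a > 10 % change in the TMB
coefficient; perfect separation is reported as non-converged.

Elementary tests are delegated to SciPy/statsmodels behind the module
surface; B–H is implemented directly and cross-checked against both the
statsmodels implementation and the classic step-up rule in tests.

## Zero-inflated exponential naive Bayes

Signature attributions are semicontinuous: a point mass at zero (the
mutational process is absent) plus a right-skewed positive part. Each
feature is modelled per class as a mixture of a zero mass π and an
exponential density with rate λ on x > 0. Estimates: π̂ = (n₀+1)/(n+2)
(add-one smoothing keeps every likelihood strictly positive, so
log-space products never degenerate); λ̂ = n₊/Σx₊, with fallback
λ̂ = 1/max(observed feature value) when a class has no positive value
(whole-column maximum keeps the rate finite and on the data's scale, 1.0
if the column is all zero). Class priors are the empirical frequencies;
the external DB prevalence (43.8 %) enters only as the decision
threshold on the posterior, inclusive at equality. Posteriors are
computed in log space and normalised with logsumexp. Default features
are the rounded per-Mb SBS4 and SBS87 attributions.

Discovery-style evaluation uses leave-one-out cross-validation; samples
with unknown labels are scored by the full-data model and enter only the
PFS analysis. A training fold reduced to a single class falls back to a
priors-only model and is logged.

## Evaluation

Point estimates carry 95 % percentile bootstrap intervals
(1000 resamples; resamples with a single class, on which rank metrics
are undefined, are redrawn), reported as (a, −b, +c) for the a^{+c}_{−b}
convention. Paired model comparisons permute the two models' scores per
sample with probability ½; unpaired comparisons permute cohort
membership; both use the (1 + hits)/(R + 1) two-sided estimate with
R = 10⁴ by default (p resolution 10⁻⁴). Decision curves are evaluated on
a 0.01–0.99 grid (step 0.01): treated-side net benefit
TP/n − (FP/n)·p_t/(1−p_t), untreated-side TN/n − (FN/n)·(1−p_t)/p_t,
combined = sum, integrated by the trapezoid rule over the clinically
discussed 0.3–0.6 threshold band; the median/IQR of the integrated
combined net benefit are taken over cohort bootstrap resamples (taking
them over the threshold grid instead is possible but the bootstrap
reading is the default). Calibration uses equal-width bins with empty
bins omitted.

## Survival analysis

Kaplan–Meier estimation is delegated to lifelines; the median is
inf{t : S(t) ≤ 0.5}, reported as missing when never reached. The Cox fit
for the binary predicted-benefit indicator is implemented directly:
Breslow tie handling, Newton–Raphson on the partial likelihood to
|Δβ| < 10⁻⁸, standard error from the observed information, 95 % CI
exp(β ± 1.96·SE). Breslow is the simplest consistent tie rule, and the
synthetic cohorts are almost surely tie-free, making the choice
immaterial there; tests cross-check against lifelines (Efron) on
tie-free data and against a dense grid search of the partial likelihood.
A group with no observed events gives a monotone likelihood and is
flagged with no estimate. Two independent hazard ratios are compared on
the log scale with a Wald z test; when a fit arrives as a printed
interval, its SE is reconstructed as (ln upper − ln lower)/(2·1.96) —
this reconstruction reproduces the published cross-cohort p ≈ 0.32,
which also validates the 1.96 assumption. Proportionality is checked by
correlating scaled Schoenfeld residuals with event time (Pearson,
two-sided); the exact trend-test recipe is a design choice, as is the
time axis (untransformed event times).

## Synthetic cohorts

The generator is the testing ground for every downstream stage, since
the real cohorts are restricted. It emulates:

* **Activities** — per class, W_is is zero with probability π₀ and
  exponential otherwise. Defaults: two informative signatures (named
  SBS4/SBS87 after the processes they emulate) with π₀ = 0.25 and mean
  150 counts in the benefit class versus π₀ = 0.70 and mean 40 counts
  otherwise (≈ 3.1 vs 0.8 Mb⁻¹ after 47.9 Mb normalisation, the scale of
  reported smoking-signature attributions); ten exchangeable background
  signatures with π₀ = 0.4, mean 60. Benefit prevalence 0.44.
* **Catalog** — sparse Dirichlet profiles (concentration 0.1) over the
  96 channels, a synthetic stand-in for a reference catalog (which is
  not redistributed with the package).
* **Spectra** — X ~ Poisson(WH), with a noiseless mode returning WH
  exactly for oracle tests.
* **Variants** — an i.i.d.-uniform reference sequence and per-sample
  VCFs whose trinucleotide contexts realise X exactly, so spectrum
  re-extraction is an exact round trip. Sites are unique per sample;
  `required_reference_length` sizes the reference from the largest
  per-context demand (each of the 32 contexts occupies ~1/32 of the
  sequence counting both strands) with a 4× safety factor.
* **PFS** — exponential event times; the no-benefit class has median
  11 weeks and the benefit-class hazard is scaled by the configured true
  hazard ratio (0.4). Censoring: each subject is independently censored
  with probability equal to the censoring rate (default 0.1), at a time
  uniform on (0, event time) — this realises the stated expected
  censoring fraction exactly. The DB label is re-derived from
  (PFS, event), so label noise near the 26-week cutoff arises naturally.

What the generator does **not** emulate: realistic genome composition
and mutation hotspots, clonal structure and purity, inter-signature
correlation beyond class membership, and the tight coupling between
features and realised outcome present in real cohorts. The last point
matters for interpretation: because PFS is linked to the features only
through the latent benefit class, the derived labels are a noisy version
of that class (with exponential PFS, a benefit-class patient clears the
26-week cutoff only ~52 % of the time). Screening and classification
against derived labels are therefore attenuated relative to the same
analysis against the class labels — at the default m=101, the screen
finds no significant signature against derived labels while finding
exactly SBS4/SBS87 against the class labels. Power and recovery tests
accordingly condition on the class labels where they probe a single
stage, and on derived labels where they probe the full pipeline; passing
tests demonstrate correctness of the machinery under the stated model,
not clinical performance on real data.

## Problem sizes and numerical choices

Simulation-based tests use: m=400 patients × 20 signatures × 50
replicates for screening power; n=500/class × 100 seeded runs for
classifier parameter recovery (recovery is assessed per parameter
estimate — the joint event that all four rate estimates land within 10 %
has probability bounded near 0.90 at this sample size, since each
estimate's relative standard error is 1/√n₊ ≈ 0.05); m=300 × 100
replicates for Cox CI coverage; ~10⁴ mutations/sample × 4 samples for
the generative round trip. These sizes keep every Monte-Carlo bound at
least ~2σ from its threshold under the stated conditions. All
randomness flows through numpy Generators seeded explicitly; generators
are bitwise-reproducible under a fixed seed. Matrix round trips through
TSV preserve 12 significant digits. All label joins (channels,
signatures, samples) are by name, never by position.

## Known limitations

* Only SBS-96 spectra are extracted natively; other channel systems are
  consumed as matrices.
* The Cox module handles a single binary covariate (the predicted
  grouping), not multivariable adjustment.
* The logistic confounding check reports coefficient changes without
  causal interpretation.
* The decision-curve median/IQR convention (bootstrap resamples) is one
  of two defensible readings; the grid alternative is available via the
  returned curve object.
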