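# Methods

## Signature construction

A combination regimen is represented by the set of its cytotoxic
component drugs screened on a cell-line panel (`CombinationSpec`). The
combination-sensitivity vector is the **unweighted sum** of the
components' −log₁₀(GI50) vectors — no z-scoring or reweighting before
summation, so a drug with a wide GI50 dynamic range contributes more
than one with a narrow range (for CHOP this means vincristine and
doxorubicin dominate; cyclophosphamide, an inactive prodrug in vitro,
contributes little). A cell line enters the sum only if it has a
measurement for **every** component drug; fewer than three complete
lines is an error because a Pearson correlation over them is
meaningless. Whether intersection should happen per drug or across all
drugs is genuinely open; complete-case across all components is the
choice here because it keeps the summed vector a true per-line sum.

Feature selection is plain Pearson correlation of each probe's log2
expression with the summed vector, pairwise-complete per probe, with
the per-probe n recorded. Selection keeps probes with `r > threshold`
**strictly** (default 0.25, so a tie at exactly 0.25 is excluded), and
only on the positive side: the model is that high expression marks
sensitivity, and negatively correlated probes are treated as carrying
no predictive signal. Zero-variance probes have undefined r and are
marked excluded. Two-sided probe p-values use the t transform
`t = r√((n−2)/(1−r²))` with n−2 degrees of freedom; they are reported
but play no role in selection. Entries are sorted by probe id so the
procedure is bitwise deterministic.

The packaged 20-probe CHOP signature carries, per probe, its published
correlations with single-drug sensitivity (vincristine, doxorubicin,
cyclophosphamide) and with clinical remission. The correlation against
the summed combination vector was never published, so the file's
`selection_correlation` column stores the strongest single-component
correlation as a documented stand-in; nothing downstream consumes these
values — scoring uses the feature list with equal weights only.

## Patient scoring

`Prediction score = mean(signature probes)` on the log2 scale, each
probe equally weighted. Probes missing from a sample (absent row or NA
cell) are dropped from the mean with a warning — the equal-weight mean
degrades gracefully — and a sample with no signature probe at all is an
error.

Raw scores are mapped to 0–100 by min–max over the normalization
population: `s' = 100·(s − min)/(max − min)`. Min–max is the most
literal reading of a "linear transformation onto 0–100"; percentile
anchoring was considered and rejected as a stronger assumption. A
population with no score spread is an error rather than a silent
constant. The normalization population is, by default, the patients of
the same treatment arm scored with that arm's signature
(`norm_population="arm"`); a pooled-cohort mode exists behind a flag.
Samples scored outside the fitted population may fall outside [0, 100]
and are deliberately not clipped.

`Combination score = Prediction − w·IPI` with `w = 25`, giving the IPI
term a range of 125 over IPI 0–5, commensurate with the 0–100
prediction scale; range [−125, 100]. The call boundary is **score ≥
cutoff → sensitive** (cutoff default 50): the boundary itself had to go
somewhere, the sensitive side was chosen, and the convention is tested.

The subtype score is `mean(GCB probes) − mean(ABC probes)`, positive
meaning GCB-like. A quantile-normalize-then-log2 utility is provided
for raw intensity matrices; it is a generic quantile method, not RMA,
and pipeline inputs are otherwise assumed pre-normalized.

## Validation statistics

* **Rank-sum** (responders vs non-responders, responders hypothesized
  higher): exact enumeration when the pooled sample is ≤ 20 with no
  ties, otherwise the normal approximation with tie and continuity
  corrections. A fully tied input returns p = 1.
* **Response correlation**: Pearson r between score and the ordinal
  coding CR=5, CRu=4, PR=3, SD=2, PD=1, dead-before-evaluation=0
  (equal spacing — the true category spacing is unknowable, and equal
  spacing is the convention here), one-sided p via the t transform.
  Unevaluable patients are always excluded; dead-before-evaluation
  patients are included as non-responders by default with an exclusion
  flag (`include_dead=False`) for the sensitivity analysis that treats
  toxicity deaths separately. Responder definition defaults to CR+CRu
  with a CR-only mode.
* **Survival**: Kaplan–Meier product-limit curves (lifelines); median =
  earliest time with S ≤ 0.5, "not reached" reported as infinity;
  median CIs by the log−log (exponential-Greenwood) construction at a
  configurable level, default 90%. Log-rank is the standard 1-df
  two-group statistic (k-group extension available).
* **ROC/AUC** over all distinct thresholds; AUC equals the normalized
  Mann–Whitney concordance with half credit for ties (asserted against
  the U statistic in the tests).
* **Multivariate remission model**: logistic regression fit by maximum
  likelihood, `remission ~ A·Prediction + B·IPI (+ C·GCB/ABC)`. The
  link is a design choice — the remission outcome is binary and the
  published coefficient magnitudes are compatible with a logit scale.
  One-sided Wald p-values test the hypothesized directions A > 0,
  B < 0, C > 0. A covariate without variation is dropped and reported
  inestimable. Complete separation (detected by non-convergence,
  exploding coefficients or non-finite standard errors) triggers a
  small-ridge IRLS refit (α = 0.01, intercept unpenalized) with an
  explicit flag; the ridge fallback is hand-rolled because penalized
  fits with Wald covariances are not otherwise available.
* **Summary table** (3 endpoints × 4 methods): remission row by
  one-sided rank-sum on each score (IPI entered negated, low IPI being
  favorable); OS/PFS rows by two-group log-rank at each method's
  cutoff — prediction at 50, IPI at ≥ 3 (the standard high-risk split,
  configurable), combined and subtype scores at their natural zero.
  Degenerate splits yield NaN cells rather than errors. No
  multiple-testing correction is applied across cells.

## Relapse analysis

Per-regimen scores are normalized 0–100 **across the relapse cohort
being analyzed** (the normalization population for relapse is otherwise
unspecified, and the relapse cohort is the only coherent context when
primary and relapse biopsies are scored against many regimens). A
patient's relapse score is the mean over the regimens actually
received, order-invariant. The sensitive/resistant cutoff is chosen
either by maximizing the two-group log-rank chi-square over midpoints
of sorted unique scores subject to a minimum group size (default 3,
guarding against degenerate splits in ~13-patient cohorts; ties break
toward the cutoff nearest the median score), or — `fixed_n` mode — to
yield an exact number of predicted-sensitive patients. Optimized
cutoffs set `data_optimized=True` on their result: the selection is on
the outcome, so the accompanying p-value is descriptive, never a test.
Regimen recommendations rank all panel signatures per patient,
descending score, alphabetical on ties. Biopsy concordance reports the
paired Pearson correlation (undefined for a single pair or zero
variance) plus counts above/below the diagonal.

## Synthetic data

The generators are pure functions of (params, seed); default seed
20150218.

**Cell-line screen** (`PanelSimParams`): 60 cell lines × 1756 features,
20 planted. Latent sensitivity `s ~ N(0,1)` per line; per-drug
−log₁₀(GI50) = β·s + N(0, drug_noise_sd²) shifted to a micromolar
scale, with β = 0.6 (vincristine), 0.6 (doxorubicin), 0.1
(cyclophosphamide) mirroring the observed dominance pattern; planted
features = baseline 7 + γ·s + N(0, noise_sd²) in log2 units, γ = 0.8,
noise_sd = 1.0. The per-drug assay noise (drug_noise_sd = 0.5) is kept
below the expression noise so the three-drug summed vector carries
about one unit of noise on the combination scale; the implied
planted-feature/combination correlation is ≈ 0.52, putting single-probe
recall at n = 60 near 0.99 while null probes pass the 0.25 threshold at
the analytic t-tail rate ≈ 0.027.

**Patient cohort** (`CohortSimParams`): 116 patients; IPI multinomial
at frequencies 10/28/37/18/16/7; treatment arms 95:21. The ordinal
response latent is `u = a1·s − a2·IPI + N(0,1)` with a1 = a2 = 0.5 —
calibrated once so the normalized-score/ordinal-response correlation
sits near the observed ≈ 0.24 at this cohort size, then frozen.
Category thresholds are computed analytically as quantiles of the
normal-mixture CDF of `u` at the study frequencies (CR 57, CRu 42,
PR 5, SD 0, PD 2, dead 5 of 111 evaluable); a 5/116 unevaluable
fraction is drawn independently. Planted sensitivity features reuse the
screen generator's identifiers so screen-built signatures score cohorts
end to end; 10 GCB and 8 ABC features load ±0.8 on an independent
subtype latent. Survival is exponential: death hazard
`(ln2/12000)·exp(0.25·IPI + 1.2·nonresponder − 0.3·g)` per day
(dead-before-evaluation patients get a 60-day median), progression
hazard `(ln2/15000)·exp(0.2·IPI + 1.5·nonresponder)`, censoring uniform
on 600–2400 days. These constants were calibrated once against the
study margins (≈19% deaths, ≈12% relapses, median observation ≈1270
days) and frozen. Relapse patients receive 1–2 regimens from the
second-line pool.

**Relapse pairs** (`RelapseSimParams`): 13 patients; per-regimen latent
sensitivities share a common component (ρ = 0.5); relapse expression =
primary + independent N(0, drift_sd²) per feature with drift_sd = 1 —
pure measurement/sampling drift, symmetric about the diagonal, with no
systematic resistance shift. Post-relapse survival is exponential with
median 600·exp(0.9·z̄) days, z̄ the mean latent sensitivity to the
regimens received, censored at 2000 days. The regimen panel returned
with the simulation lists each regimen's planted probes with their
population selection correlation as nominal entries.

What the generators do **not** emulate: probe-level array artifacts,
batch effects, FFPE degradation, tumor-cell-content dilution,
non-Gaussian heavy tails, correlated null features, or biological
drift between diagnosis and relapse. Passing tests therefore
demonstrate correctness of the pipeline's statistics and its behavior
under the assumed generative structure — not clinical performance on
real cohorts.

## Problem sizes used in the automated checks

The repeated-simulation checks use 50 screens (recall/null-rate), 1000
null replicates per type-I suite (groups of 20/20 for the rank-sum test,
30/30 exponential for log-rank, n = 100 for the response correlation),
100 cohorts of n = 400 for Wald-coverage of the logistic model, and
15–20 cohort/relapse seeds for the power-ordering and median-ordering
checks. These sizes give binomial bands tight enough to be meaningful
(3 SE on a 5% rate at 1000 replicates is ±2.1 points) while keeping the
default suite quick.

## Known limitations

* The optimized relapse cutoff's log-rank p is biased by selection;
  the package flags it but cannot correct it (a permutation-calibrated
  version would need far more patients than the intended ~13).
* Equal-weight scoring is the method; no attempt is made to learn
  feature weights, and the package deliberately offers no option to.
* The min–max normalization ties a patient's score to the cohort it was
  normalized in; scores are not transferable across cohorts without
  renormalization.
* With ~12 non-responders per 116-patient cohort, AUC and rank-sum
  outcomes on a single simulated cohort are noisy; seed-averaged checks
  are the meaningful ones.
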