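# mirsense

MicroRNA-based chemosensitivity prediction for diffuse large B-cell
lymphoma (DLBCL) combination regimens.

## The problem

More than 80% of DLBCL patients respond to first-line R-CHOP, but
relapse patients face a poor prognosis and a wide menu of second-line
regimens with no biomarker to choose between them. `mirsense`
implements a cell-line-derived predictor of treatment sensitivity that
can be read out from the microRNA expression of an archival (FFPE)
tumor biopsy:

1. **Signature construction** (in vitro). For a combination regimen
   with component drugs *d₁…d_k* screened on a cell-line panel, the
   combination sensitivity of cell line *c* is the unweighted sum of
   −log₁₀ GI50 values, `s_c = Σ_d (−log₁₀ GI50_{d,c})`. Each microRNA
   probe's baseline expression is Pearson-correlated with `s`, and
   probes with `r > 0.25` (strictly; positive side only) form the
   regimen's response signature. The packaged 20-probe CHOP signature
   built this way from the NCI60 screen ships with the library
   (`mirsense.chop_signature()`).
2. **Patient scoring.** `Prediction score = mean(signature probes)` —
   every probe gets equal weight — then a min–max linear transform onto
   0–100 across the scored cohort (per treatment arm by default).
   `Combination score = Prediction score − 25 × IPI`, which makes the
   International Prognostic Index term's range (125) commensurate with
   the prediction scale (100). A patient is called *sensitive* when the
   score is at or above the cutoff (default 50).
3. **Validation.** One-sided Wilcoxon rank-sum of scores between
   responders (CR+CRu) and non-responders, Pearson correlation with the
   ordinal response scale (CR > CRu > PR > SD > PD > dead-before-
   evaluation), Kaplan–Meier / log-rank survival at the cutoff, ROC/AUC
   comparison of prediction, IPI and combined scores, and a
   multivariate logistic remission model
   `remission ~ A·Prediction + B·IPI (+ C·GCB/ABC)`.
4. **Relapse regimen selection.** Relapse patients are scored against a
   panel of second/third-line regimen signatures (mean over the
   regimens actually received, normalized across the relapse cohort),
   split at an optimized cutoff, compared by survival, and given a
   ranked list of alternative regimens. Because an optimized cutoff is
   chosen on the outcome, the result carries an explicit
   `data_optimized` flag marking its p-values as descriptive.

A fully parameterized synthetic-data module (`mirsense.simulate`)
generates cell-line screens, patient cohorts and matched
primary/relapse biopsy pairs with planted ground truth, reproducing the
study cohort's margins (116 patients; IPI distribution 10/28/37/18/16/7;
response categories CR 57, CRu 42, PR 5, PD 2, dead 5, unevaluable 5;
≈19% deaths; 13 relapses), so the whole pipeline can be exercised and
calibrated end to end.

## Worked example

```python
import numpy as np
from mirsense import (CombinationSpec, build_signature, score_cohort,
                      response_correlation, wilcoxon_one_sided, roc_auc)
from mirsense.simulate import (PanelSimParams, CohortSimParams,
                               simulate_cell_line_panel, simulate_patient_cohort)
from mirsense.validation import ResponseCoding

# in-vitro screen -> CHOP signature
panel, cell_expr, truth = simulate_cell_line_panel(PanelSimParams(seed=20150218))
spec = CombinationSpec("CHOP", ("vincristine", "doxorubicin", "cyclophosphamide"))
signature = build_signature(panel, cell_expr, spec)

# clinical cohort -> scores -> validation
expr, records, _ = simulate_patient_cohort(CohortSimParams(seed=20150218))
scores = score_cohort(expr, records,
                      {t: signature for t in {r.treatment for r in records}})
cc, p = response_correlation(np.array(scores.normalized_scores),
                             [r.response for r in records])
```

Output of the full script (printed values):

```
selected 56 probes (recall of planted set: 20/20)
score vs ordinal response: cc = 0.36, one-sided p = 0.0001
combined score: responders vs non-responders one-sided p = 0.0020, AUC = 0.79
```

Reading: the Pearson selection recovered all 20 planted sensitivity
biomarkers (the extra probes are threshold-level false positives,
expected at the analytic null rate P(r > 0.25 | n = 60) ≈ 0.027 of the
1736 null features); the prediction score tracks the ordinal clinical
response, and combining it with the IPI separates responders from
non-responders with an AUC near 0.8 on this synthetic cohort.

The same pipeline is available from the shell:

```sh
mirsense simulate panel --seed 1 --out panel/
mirsense build-signature --gi50 panel/gi50.tsv --expr panel/cell_expression.tsv \
    --drugs vincristine,doxorubicin,cyclophosphamide --name CHOP --out chop.sig.tsv
mirsense score --expr patients.tsv --signature chop.sig.tsv \
    --clinical clinical.csv --out scores.csv
mirsense validate --scores scores.csv --clinical clinical.csv --out report/
mirsense relapse --expr relapse.tsv --clinical clinical.csv \
    --panel-dir signatures/ --out relapse_report/
```

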