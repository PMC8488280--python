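# pairsig

Normalization-free gene-pair survival signatures for multi-cohort
transcriptomics.

## The problem

Expression-based prognostic signatures rarely survive a platform change:
absolute intensities from different microarrays and RNA-seq are not
comparable, and cross-cohort normalization is fragile. `pairsig` implements
the *relative expression ordering* approach: every feature is a binary
within-sample comparison of two genes,

```
s(g1, g2 | x) = 0  if x[g1] > x[g2],  else 1   (ties score 1)
```

so each feature is invariant under any strictly increasing transform of a
sample's values — exactly the class of monotone distortions that platform
effects induce. A signature is a Cox linear predictor over pair indicators

```
index(x) = Σ_k  w_k · s(g1_k, g2_k | x)
```

with a risk cutoff θ (index > θ ⇒ high risk). The package provides:

* the full training pipeline — pair enumeration, cross-cohort constancy
  filtering, per-pair log-rank screening (p < 0.05), LASSO-penalized Cox
  with 10-fold cross-validation at the 1-SE penalty, unpenalized refit, and
  a time-dependent-ROC (Youden) risk cutoff;
* self-implemented survival statistics: Kaplan–Meier, log-rank (scalar and
  vectorized screen), Cox PH (Breslow/Efron ties), LASSO-Cox path + CV,
  nearest-neighbor time-dependent ROC, Harrell's C with a jackknife
  comparison of correlated C statistics, and restricted mean survival time;
* the published 10-pair autophagy gene-pair index (ATGPI) for early-stage
  lung adenocarcinoma as a frozen scorer (15 genes, cutoff 1.35), plus the
  published clinical composite
  `ACPI = 0.6657·ATGPI + 0.4445·stage + 0.0199·age` (stage coded I=1, II=2;
  cutoff 1.31);
* a synthetic multi-platform cohort generator with known ground truth
  (Weibull proportional hazards driven by planted pair indicators plus
  age/stage effects, per-cohort monotone platform distortions, right
  censoring) so every pipeline stage is testable without any download.

## Worked example

```python
import pairsig as ps

# simulate four platform-distorted cohorts with five true prognostic pairs
cfg = ps.SimulationConfig(seed=1, gamma_age=0.0, gamma_stage=0.0)
cohorts, truth = ps.simulate_cohorts(cfg)
print(f"{cohorts.n_samples} samples, censoring {ps.censoring_rate(cohorts):.3f}")

model = ps.train_signature(cohorts, ps.TrainConfig(seed=1))
meta = model.metadata
print(f"{meta['n_candidate_pairs']} -> {meta['n_informative_pairs']} -> "
      f"{meta['n_screened_pairs']} -> {meta['n_selected_pairs']} pairs")
recovered = {p.label for p in model.pairs} & set(truth.betas)
print(f"recovered {len(recovered)}/5 true pairs, cutoff {model.cutoff:.3f}")

heldout, _ = ps.simulate_cohorts(ps.SimulationConfig(seed=99, gamma_age=0.0,
                                                     gamma_stage=0.0))
report = ps.evaluate_signature(model, heldout)
risk = report.cox_table.query("variable == 'risk' and model == 'univariate'")
print(f"high-vs-low HR {float(risk['HR'].iloc[0]):.2f}, "
      f"log-rank p {report.logrank.p_value:.2e}, C-index {report.c_index:.3f}")
```

prints (exactly, for these seeds):

```
800 samples, censoring 0.676
435 -> 409 -> 69 -> 7 pairs
recovered 5/5 true pairs, cutoff 0.472
high-vs-low HR 4.74, log-rank p 6.65e-32, C-index 0.727
```

The 435 candidate pairs over 30 genes shrink to 409 after removing pairs
constant within any cohort, 69 survive the log-rank screen, and the LASSO at
λ_1SE keeps 7 — including all 5 planted pairs. On an untouched cohort the
trained index separates risk groups with a hazard ratio of 4.7, and its
concordance of 0.73 reflects the strong planted effects.

Scoring with the frozen published model needs only a 15-gene expression
frame:

```python
from pairsig import signature as sig
model = sig.published_atgpi()        # 10 pairs, 15 genes, cutoff 1.35
scores = sig.score_atgpi(expr_df, model)
risk = sig.classify_risk(scores.to_numpy(), model.cutoff)
```

A command-line interface wraps the same library:

```bash
pairsig simulate --out data/ --seed 7
pairsig train --expression data/C1.tsv --expression data/C2.tsv \
    --expression data/C3.tsv --expression data/C4.tsv \
    --clinical data/clinical.csv --out model.json --acpi-out acpi.json
pairsig score --expression data/C1.tsv --model model.json --out scores.tsv
pairsig evaluate --expression data/C1.tsv --clinical data/clinical.csv \
    --model model.json --acpi acpi.json --out report/ --no-plots
```

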