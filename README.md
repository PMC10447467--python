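# tmesurv

Multi-task deep learning of the tumor microenvironment and survival from CT,
with a complete downstream clinical-statistics toolkit, exercisable
end-to-end on seeded synthetic phantom cohorts.

## What this is for

The tumor microenvironment (TME) of gastric cancer — its immune
infiltration and stromal content — predicts prognosis and treatment
response, but assessing it requires tissue. This package implements a
biology-guided imaging alternative: a single convolutional model that reads
a preoperative CT and *jointly* (i) classifies the tumor into one of four
IHC-defined TME classes and (ii) outputs a scalar survival risk, the
deep-learning survival score (DLS). The two tasks share representations and
the predicted TME probabilities feed the survival head, so outcome
prediction is guided by the biology.

The TME ground truth comes from two scores:

* **IS_GC** (immune axis) = 0.149·CD3_IM + 0.021·CD3_CT + 0.044·CD8_IM
  + 0.096·CD45RO_CT − 0.173·CD66b_IM (cell densities per field; IM =
  invasive margin, CT = center of tumor);
* **POSTN** (stromal axis) = mean over five fields of stain intensity
  (0–3) × stain extent (0–4).

Both are dichotomized at their training-cohort medians; the quadrants give
class 1 (immune-high/stroma-low) … class 4 (immune-low/stroma-high).

The model trains with the joint loss

    L = L_CE(Y, Ŷ)  +  L_Cox(ĥ),
    L_Cox = − Σ_{i: E_i=1} [ ĥ_i − log Σ_{j: T_j ≥ T_i} exp(ĥ_j) ],

cross-entropy for the TME classes plus the negative Cox log partial
likelihood over the batch (Breslow ties), after gated-attention pooling of
the five slice features:

    A = softmax( w₃( tanh(w₁f + b₁) ⊙ sigmoid(w₂f + b₂) ) + b₃ ),  M = A·f.

Around the model sit the analyses a clinical study needs: Kaplan–Meier and
log-rank, Cox regression (uni/multivariable, Breslow), time-dependent ROC,
DeLong AUC comparison, Harrell's C, IPCW Brier/IBS and .632+
prediction-error curves, continuous NRI, calibration curves, χ² variable
importance, an integrated imaging+clinical model with 8 frozen risk strata,
propensity-matched per-class chemotherapy effects with interaction tests,
and a CPS × TME decision tree for immunotherapy response.

No patient data ship with the package. A first-class synthetic module
generates phantom cohorts — textured CT lesions whose heterogeneity rises
with TME class, IHC panels consistent with the score quadrants,
proportional-hazards outcomes, class-dependent chemotherapy effects and
class+CPS-dependent immunotherapy response — so every stage is testable and
reproducible from one seed. The network runs on a small numpy autodiff
engine written for this package (float64 throughout; gradients are
finite-difference checked in the test suite).

## Worked example

```python
import numpy as np
from tmesurv.synthetic import GeneratorConfig, generate_cohort
from tmesurv import evaluate as ev, treatment as tr

cfg = GeneratorConfig(n_subjects=600, seed=7)
cohort = generate_cohort(cfg, write_images=False)

stat, p = ev.log_rank_test(cohort["time"], cohort["event"], cohort["true_class"])
print(f"log-rank across TME classes: chi2 = {stat:.1f}, p = {p:.3g}")

class1 = cohort[cohort["true_class"] == 1].reset_index(drop=True)
scores = tr.fit_propensity(class1)
match = tr.match_1to1_nearest(class1, scores, seed=7)
matched = class1.iloc[match.matched_indices].reset_index(drop=True)
eff = tr.stratum_treatment_effect(matched)
print(f"class-1 chemotherapy HR = {eff['hr']:.3f} "
      f"({eff['ci'][0]:.3f}-{eff['ci'][1]:.3f}), p = {eff['p']:.2g}")

cohort["predicted_class"] = cohort["true_class"]  # oracle imaging model
tree = tr.fit_response_tree(cohort["predicted_class"], cohort["cps_category"],
                            cohort["response"], seed=7)
rep = tr.response_report(cohort, tree)
print(f"ORR by class: {rep['orr_by_class']['mean'].round(3).tolist()}")
print(f"AUC  CPS only: {rep['auc_cps']:.3f}  TME only: {rep['auc_tme']:.3f}  "
      f"composite: {rep['auc_composite']:.3f}")
```

Output:

```
log-rank across TME classes: chi2 = 475.2, p = 1.14e-102
class-1 chemotherapy HR = 0.381 (0.220-0.657), p = 0.00053
ORR by class: [0.745, 0.547, 0.196, 0.176]
AUC  CPS only: 0.607  TME only: 0.767  composite: 0.798
```

Reading it: the four generated TME classes carry sharply distinct
disease-free survival (the log-rank test); within predicted class 1,
propensity-matched patients who received chemotherapy did markedly better
(hazard ratio 0.38, the generator's class-1 benefit of 0.258 lies inside
the CI); objective response to anti-PD-1 therapy falls from ~75% in class 1
to ~18% in class 4, and combining TME class with the PD-L1 CPS category in
a shallow decision tree beats either biomarker alone.

## Command line

```bash
tmesurv run-all --out run --seed 20230823          # simulate → … → response
tmesurv simulate --out run --seed 1                # one stage at a time
tmesurv evaluate --config myrun.yaml
```

Each run writes a `manifest.json` with the configuration hash and per-stage
output hashes; deterministic stages reproduce their hashes on re-run.

## Layout

```
src/tmesurv/
  synthetic.py    phantom cohorts: images, IHC, outcomes, treatment, response
  preprocess.py   resampling, HU windowing, tumor-centered slice stacks
  tme.py          IS_GC / POSTN scoring and TME class assignment
  autodiff.py     minimal reverse-mode engine (float64 numpy)
  network.py      backbones, gated attention, heads, joint CE+Cox loss, training
  evaluate.py     KM, Cox, ROC(t), DeLong, C, NRI, Brier/IBS, .632+, calibration
  treatment.py    propensity matching, stratum HRs, CPS bins, response CART
  pipeline.py     stage orchestration + manifest;  cli.py: `tmesurv` entry point
docs/methods.md   model assumptions, generator design, numerical choices
```

See `docs/methods.md` for the full methods note, including what the
synthetic cohorts do and do not establish about real imaging data.
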