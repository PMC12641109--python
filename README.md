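# gliofuse

Predicting MGMT promoter methylation status in glioblastoma from
multiparametric MRI (mpMRI) deep features.

MGMT promoter methylation is a key molecular marker in glioblastoma — it
predicts response to temozolomide chemotherapy — but determining it requires
tissue. `gliofuse` implements a non-invasive imaging pipeline for
radiogenomics researchers: tumor regions of co-registered T1, post-contrast
T1 (T1wCE), T2 and FLAIR volumes are converted to 150-frame videos,
off-the-shelf video networks supply 400 deep features per modality, and a
five-branch attention-fusion classifier — with a fifth branch for the
voxelwise T1wCE − T1 contrast-enhancement ("delta") image — produces
P(methylated) together with interpretable per-modality attention weights.

The core model is a Siamese multi-branch network. One shared encoder
f<sub>θ</sub>: ℝ⁴⁰⁰ → ℝ⁶⁴ embeds every branch; additive self-attention

&nbsp;&nbsp;s<sub>b</sub> = u·tanh(W e<sub>b</sub> + c) + γ β<sub>b</sub>,&nbsp;&nbsp;α = softmax(s),&nbsp;&nbsp;fused = Σ<sub>b</sub> α<sub>b</sub> e<sub>b</sub>

yields nonnegative per-subject modality weights summing to 1, and a linear
head with a sigmoid gives the methylation probability. Absent modalities are
handled at inference by masking their attention scores to −∞ (exactly a
renormalization of the remaining weights). The package also ships the full
evaluation apparatus: repeated stratified 5-fold cross-validation with
mean ± SEM, Wilcoxon rank-sum model comparisons, decision-curve analysis
(net benefit TP/n − (FP/n)·t/(1−t)), modality and delta-branch ablations,
an MLP baseline (400→100→32→1, dropout 0.4), and Lin's concordance
correlation coefficient for cross-extractor feature reproducibility —
plus synthetic generators (ellipsoid-tumor phantoms and Gaussian feature
cohorts with a closed-form Bayes AUC of Φ(Δ/√2)) so the entire pipeline is
testable without downloading imaging data or pre-trained weights.

See `docs/methods.md` for the model, its assumptions and the design
decisions.

## Worked example

Train the fusion model on a synthetic 585-subject cohort whose only signal
is a Mahalanobis separation of Δ = 1.5 on the T1wCE branch (Bayes-optimal
AUC = Φ(1.5/√2) = 0.856):

```python
import numpy as np
from gliofuse import (AttentionFusionClassifier, FeatureCohortConfig,
                      bayes_auc, generate_feature_cohort, make_split_plan,
                      run_cross_validation)

cohort = generate_feature_cohort(FeatureCohortConfig(
    n_subjects=585, effect_size=(0, 0, 0, 1.5, 0), seed=101))
plan = make_split_plan(cohort, k=5, repetitions=4, seed=11)
report = run_cross_validation(cohort, AttentionFusionClassifier(), plan)

print(f"mean AUC {report.mean['auc']:.3f} (SEM {report.sem['auc']:.3f}) "
      f"over {len(report.folds)} folds; Bayes bound {bayes_auc(1.5):.3f}")
print("mean attention per branch:",
      np.round(report.mean_attention.mean(axis=0), 3))
```

Output:

```
mean AUC 0.800 (SEM 0.010) over 20 folds; Bayes bound 0.856
mean attention per branch: [0.07  0.01  0.183 0.661 0.076]
```

The model recovers most of the analytically attainable discrimination (the
remaining gap is the finite-sample cost of estimating which features carry
signal), and its attention weights put the largest mean weight on the
informative branch — T1wCE, the fourth entry — in all 20 folds. The same `report` carries
per-fold precision/recall/accuracy and feeds the decision-curve, Wilcoxon
and ablation utilities.

A command-line interface mirrors the pipeline stages:

```bash
gliofuse synth phantom --seed 1 --out phantom/          # NIfTI phantom subject
gliofuse preprocess --t1 ... --t1ce ... --t2 ... --flair ... --mask ... --out clips/
gliofuse extract --clips-dir clips/ --extractor stub --out features.csv
gliofuse cv --features features.csv --model fusion --reps 4 --k 5 --seed 0 --out report.json
gliofuse ablate modalities --features features.csv --out ablation.csv
```

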