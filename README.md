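# latemix

Late-integration machine learning for predicting 1-sd classes of
cardiovascular risk factors from multi-omic data.

`latemix` is for biostatisticians and epidemiologists who want to compare
dimension-reduction and classification strategies for continuous risk
factors — systolic/diastolic blood pressure and echocardiographic markers of
left-ventricular diastolic dysfunction (E/e' ratio, E/A ratio, LAVI) —
measured alongside transcriptomic, metabolomic and DNA-methylation blocks.
Because cohort data of this kind are access-restricted, the package ships a
latent-factor synthetic cohort generator with the same statistical skeleton
(block widths, omic–target correlation, (0,1) beta values, ~15/70/15 class
imbalance, a shifted external cohort), so the entire pipeline is runnable
and testable out of the box.

## The method

Each participant is assigned, per risk factor, to one of three **1-sd
classes**: below (−1), within (0) or above (+1) one training standard
deviation of the training mean. Per continuous omic block, a
**semi-supervised denoising autoencoder (SSAE)** — encoder p → bottleneck l,
symmetric decoder, and a one-layer-perceptron head on the bottleneck that
predicts the age/sex/BMI-adjusted targets — is trained with the bi-output
loss

```
L(X, X', Y, Y') = α·MSE(X, X') + (1 − α)·MSE(Y, Y'),   α ∈ [0, 1]
```

on Gaussian-corrupted inputs; `α = 1` gives the unsupervised control
(USAE), trained to the same reconstruction MSE for a like-for-like
comparison. Variable importance through the encoder and head uses Olden's
Connection-Weights product `RI = W₁W₂H₁H₂` (signs preserved). Six classifier
families (random forest, linear/RBF SVM, LDA, GBM, 1-hidden-layer MLP)
predict 1-sd classes from each encoded subspace plus covariates with
stratified 5-fold CV; their per-omic class probabilities are fused through a
**Cross-omics Discovery Tensor** (all 3³ = 27 cross-view probability
products) feeding a **View Correlation Discovery Network** (27 → 9 → 3,
softmax). Model quality is macro-F1 — the unweighted mean of the three class
F1 scores, with a prevalence-proportional random baseline of exactly 1/3.
Finally, pre-trained SSAE encoders can be **transferred** to hypertension
prediction (SBP > 140 or DBP > 90 mmHg) in an external cohort, fine-tuning
only new layers, against an identically shaped from-scratch clone, compared
by AUC across fine-tuning fractions.

All neural components are implemented in NumPy with explicit
backpropagation; standard steps (classifiers, scaling, OLS, CV) use
scikit-learn.

## Worked example

```python
import numpy as np
from latemix import RunConfig, SimConfig, run_full

config = RunConfig(
    sim=SimConfig(n_samples=600, block_sizes=(80, 30, 12), seed=7,
                  signal_density=(0.4, 0.5, 0.6),
                  target_noise_sd=np.array([4.0, 3.0, 0.3, 0.12, 2.0])),
    targets=("sbp",), families=("lda", "random_forest"),
    ae={"transcriptomic": {"p": 20, "l": 6, "corruption_sd": 0.01,
                           "min_epochs": 6, "stop_window": 6, "scaling": "minmax"},
        "metabolomic": {"p": 12, "l": 4, "corruption_sd": 0.1,
                        "min_epochs": 6, "stop_window": 6, "scaling": "zscore"}},
    max_epochs=40, vcdn_epochs=120, seed=1)
bundle = run_full(config)
table = bundle["eval"]
print(table[table.encoder != "usae"][
    ["target", "omics", "classifier", "f1_low", "f1_mid", "f1_high", "macro_f1"]
].to_string(index=False, float_format=lambda v: f"{v:.2f}"))
```

prints

```
target          omics    classifier  f1_low  f1_mid  f1_high  macro_f1
   sbp transcriptomic           lda    0.00    0.76     0.19      0.32
   sbp transcriptomic random_forest    0.00    0.77     0.20      0.32
   sbp    metabolomic           lda    0.09    0.75     0.29      0.38
   sbp    metabolomic random_forest    0.10    0.78     0.14      0.34
   sbp     epigenetic           lda    0.48    0.76     0.38      0.54
   sbp     epigenetic random_forest    0.25    0.77     0.25      0.42
   sbp    multi-omics           lda    0.36    0.77     0.30      0.48
   sbp    multi-omics random_forest    0.24    0.77     0.34      0.45
```

Each row is the held-out test performance of one classifier on one encoded
omic (or the VCDN fusion): per-class F1 for the low/mid/high 1-sd classes
and their macro average (naive baseline 0.33). Here the feature-selected
methylation block and the fused predictions clearly beat chance while the
small, briefly trained transcriptomic autoencoder lags — the kind of
contrast the pipeline is built to expose. The bundle also reports the
SSAE-vs-USAE comparison (`bundle["ssae_vs_usae"]`, here 75% of cases at
least as good) and the variance in raw SBP explained by the fused test
probabilities:

```
p_high                     0.276
p_high+p_low               0.348
p_high+p_low+covariates    0.358
```

i.e. the predicted probability of the high class alone explains 27.6% of
test-sample SBP variation, rising to 35.8% with the low-class probability
and the clinical covariates.

A thin CLI covers the two most common entry points:
`latemix simulate out_dir/` and `latemix run-all --seed 1 --out reports/`.

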