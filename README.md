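# mfdl — multimodal functional deep learning for multiomics data

`mfdl` predicts phenotypes from several omics modalities at once — e.g. the
SNPs of a gene region plus expression levels — for study sizes where a plain
deep network overfits (hundreds of samples, hundreds of markers). It is aimed
at statistical geneticists and methodologists who want a transparent,
NumPy-level reference implementation of functional neural networks with
exact gradients, plus the baselines and simulation machinery to benchmark
them.

## The model

Each modality k with marker values g_ki at positions rescaled to [0, 1] is
represented as an *omics variant function*, a Dirac comb
G_ki(t) = Σ_j g_kij δ(t − t_kj). A functional neural subnet maps it to a
low-dimensional embedding:

    Z_ki^(1)(t) = σ( X_ki α_k + ∫ G_ki(s) β_k^(1)(t, s) ds )          (input layer)
    Z_ki^(d)(t) = σ( α_k0^(d)(t) + ∫ Z_ki^(d−1)(s) β_k^(d)(t, s) ds )  (hidden layers)
    Z_ki^(D_k)  = f( α_k0^(D_k) + ∫ Z_ki^(D_k−1)(s) β_k^(D_k)(s) ds )  (output layer)

with the weight surfaces and bias functions expanded in fixed B-spline bases,
β(t, s) = Σ_ℓ Σ_j w_ℓj η_ℓ(s) η_j(t). Because G is a Dirac comb, the input
integral collapses exactly to a marker sum — no quadrature error — and the
B-spline expansion shares information across markers in linkage
disequilibrium. The per-modality embeddings are concatenated into a shared
representation Z_wide = [Z_1^(D_1) Z_2^(D_2)] and a dense feedforward head
maps it to the phenotype (scalar or vector). Scalar or low-dimensional
modalities skip the functional machinery: their subnets reduce to ordinary
dense layers, and an all-dense configuration is exactly a plain deep network.

Training minimizes the ridge-regularized loss
J̃(W, b) = (1/n) Σ_i ‖y_i − ŷ_i‖² + (λ/2)‖W‖₂² (biases unpenalized) by
full-batch gradient descent with ADADELTA step sizes; gradients are the exact
reverse-mode derivatives of the discretized forward pass. λ is selected from
{0.1, 0.3, 1, 3, 10} by validation.

Included baselines: the functional linear model (FLM, closed-form ridge on
the same Dirac designs), a plain feedforward network on concatenated raw
columns, and FNN-3HL (one functional network with three hidden layers on all
inputs forced onto a single axis). Metrics: MSE, MAE, and the
Robert–Escoufier RV coefficient (multivariate squared correlation).

The synthetic-data module generates genotypes with a rare-skewed MAF
spectrum and AR(1) linkage disequilibrium via latent-Gaussian haplotype
thresholding, Gaussian expression data, and phenotypes under linear,
interaction (Int_i = c⟨f₁, f₂⟩), and trigonometric nonlinear transformations.

## Worked example

```bash
python examples/02_fit_mfdl.py
```

generates an interaction G-G dataset (two genotype modalities, 100 markers
each, 200 samples, noise variance 0.3), trains the default two-subnet model
on a 160-sample split and prints:

```
trained 10000 epochs; final J~ = 45.43
MFDL  train MSE    20.37  test MSE    24.48  test MAE   2.61  test RV 0.965
FLM   train MSE   160.70  test MSE   140.61  test MAE   8.85  test RV 0.669
```

The phenotype contains a product interaction between the two regions; the
linear model can only absorb its linear projection (test MSE 140.6, RV 0.67),
while the multimodal network recovers most of it through the shared
representation (test MSE 24.5, RV 0.97). The other examples cover dataset
generation and export (`01`, `04`) and replicated studies (`03`).

A thin CLI wraps the same functions:

```bash
mfdl simulate --relationship interaction --omics-config G-G --seed 1 --out data/
mfdl fit --vcf data/modality1.vcf --vcf data/modality2.vcf \
         --phenotype data/phenotype.tsv --model-out model.json
mfdl study --config study.yaml --out results/
```

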