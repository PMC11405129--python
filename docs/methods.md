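# Methods

## Model

A modality with positional structure (SNPs of a region, markers of a gene)
enters as an omics variant function: marker values g_ij at base-pair
positions min–max rescaled to [0, 1] (a single marker sits at t = 0.5 by
convention; duplicate positions are a hard error rather than silently
jittered). Treating the sample's profile as the Dirac comb
G_i(t) = Σ_j g_ij δ(t − t_j) makes every integral against a smooth function
collapse to a finite marker sum, so the first-layer design
Φ[i, ℓ] = Σ_j g_ij η_ℓ(t_j) is computed exactly, never by quadrature.

Functional layers parameterize their weight surfaces by tensor-product
B-spline expansions, β(t, s) = Σ_ℓ Σ_j w_ℓj η_ℓ(s) η_j(t), and bias
functions by α₀(t) = Σ_j b_j η_j(t). Following the printed forward
equations, the input layer carries a covariate term X α and no functional
bias; hidden layers carry the functional bias. Hidden functions are sampled
on a uniform grid and the s-integrals of deeper layers use composite
trapezoid weights. The output layer integrates the last hidden function
against per-unit weight functions and applies the identity link. Embeddings
are concatenated in configuration order into the shared representation and a
dense tanh head produces the phenotype; vector phenotypes are handled by the
head's output width. A modality declared dense bypasses all of this with
plain affine layers — with every modality dense the model is exactly a
feedforward network, which the tests exploit as an independent check.

## Bases and quadrature

Clamped uniform-knot B-splines of order 5 (degree 4; "fifth order" is read
as polynomial order, the FDA convention) with 7 basis functions per
functional dimension are the default; order 1 yields indicator bases and
order 2 hat functions, used in tests. Clamping makes evaluation at both
endpoints well defined, and the family is a partition of unity, which tests
verify to 1e-10. The quadrature grid has 50 uniform points with trapezoid
weights: O(h²), exact for constants and linears, and adequate because every
integrand is a low-order spline combination. One measured subtlety: trapezoid
on a full period of sin(2πt) is exact to roundoff (the Euler–Maclaurin
boundary terms cancel), so convergence-order checks use the half-period sine;
and agreement between a 101-point and a 10001-point grid on order-5 spline
columns is limited by the edge-spline boundary-slope term to ~1.3e-4, not
machine precision.

## Training

The objective is J̃(W, b) = (1/n) Σ ‖y_i − ŷ_i‖² + (λ/2)‖W‖₂², with biases
excluded from the penalty. Gradients are exact reverse-mode derivatives of
the discretized forward pass — basis evaluations and quadrature weights are
constants — so the quantity differentiated is precisely the quantity
minimized; finite-difference agreement to 1e-4 relative error across every
layer type is part of the test suite. Updates are full-batch ADADELTA
(ρ = 0.95, ε = 1e-6), stopping when the relative J̃ change stays below 1e-6
for 50 consecutive epochs or at the epoch cap. A plain fixed-step gradient
descent mode exists for convergence-sensitive reference computations in the
tests, where ADADELTA's slow terminal phase would dominate the error.

λ is chosen from {0.1, 0.3, 1, 3, 10} by a single 75/25 validation split of
the training data (3-fold cross-validation is available for real-data-style
runs); ties break toward the stronger penalty. Two empirical properties of
the raw-scale phenotypes are worth knowing. First, with var(y) in the
10²–10³ range the grid's larger values (λ ≥ 1) drive ADADELTA into a
zero-weight basin whose predictor is constant, so validation effectively
always selects λ = 0.1; this is a property of the stated conditions, not a
tuning choice. Second, a constant predictor has undefined RV, which the
metric reports as an explicit error; the study runner records such a
replicate as a method failure and continues.

## Architecture defaults

Nothing in the model fixes the subnet depth, embedding width or head width;
they are configuration. The defaults used by the study runner — embedding
width 4 per modality, no interior functional hidden layer (functional input
layer + functional output layer per subnet), one 8-unit tanh hidden layer in
the head — are sized to the standard n = 200 / 160-train regime: systematic
sweeps showed that doubling the widths (embedding 8, head 16) or adding a
hidden functional layer inflates test error by factors of 2–4 through
overfitting while leaving training error low. Deeper and wider
configurations remain one `SubnetConfig`/`HeadConfig` away and are exercised
by the unit tests.

## Linear limit

With identity activations and no interior functional layers the network
computes Φ W₁ G W₂ W_head + const, a reparameterized functional linear
model. The correspondence of objectives is exact only as λ → 0: at larger λ
the network's penalty applies to each factor matrix, which is a different
(nuclear-norm-like) regularizer than ridge on the composite coefficients,
and empirically admits a zero-collapse local optimum at λ ≥ 0.1 under plain
gradient descent. The equivalence check therefore runs both models at a
matched small penalty (λ = 1e-3), where the converged network objective
lands within 5% of the closed-form ridge optimum.

## Synthetic data

Genotypes: each marker draws a MAF from a piecewise log-uniform law on
(4.5e-4, 0.5) with bin masses placing ≈34.8% below 0.001, ≈69.1% below 0.01
and ≈80% below 0.03 — the rare-skewed spectrum of a 30-kb sequencing
segment. Haplotypes are latent AR(1) Gaussian vectors (default ρ = 0.9,
emulating strong local LD) thresholded at each marker's MAF quantile;
genotype = sum of two independent haplotypes; positions are drawn uniformly
in a 30-kb region, sorted, and rescaled. This reproduces marginal
frequencies and local correlation but not coalescent genealogy, recombination
hotspots or population structure — so passing studies demonstrate behaviour
under realistic sparsity and LD, not on any particular real region. A VCF
import path supplies real genotypes when available.

Expression: i.i.d. N(0, 0.5) entries (diagonal covariance).

Phenotypes: y = f₁ + f₂ (+ Int) + ε with ε ~ N(0, σ²), σ² ∈ {0.3, 0.45,
0.6}. The linear effect is f_k = a_k Φ_B C_k with Φ_B the Dirac design in
the order-5 B-spline basis, a_k ~ U(−3, 3) per replicate, and C_k a fixed
N(0, 1) coefficient matrix drawn once per replicate (J×d for functional,
p₂×d for raw-column modalities). The nonlinear effect is the trigonometric
transformation Σ_l c_l [Σ_j g_ij^{e_l} cos(a_l t_j + d_l^{(1)})]
sin(a_l s + d_l^{(2)}) C_k with fixed triples (a_l) = (c_l) = (2/3, −2, 2),
e = (1/3, 3/2, 3), phases U(−π, π) per replicate; for scalar phenotypes it
is evaluated at s = 0.5 (the simplest reading; integrating over s is a
one-line alternative), for vector phenotypes on a uniform s-grid with a
scalar C_k. Fractional powers of a signed continuous modality are undefined;
the generator extends them oddly (sign(g)|g|^e) behind an explicit
`signed_powers` flag that the scenario assembler enables only for expression
inputs. The interaction is Int = c·f₁∘f₂ elementwise with c = 1 by default
(the scale is a free constant of the design; c is configurable). The
decomposition y = f₁ + f₂ (+ Int) + ε is stored exactly and tested
elementwise.

## Study protocol and problem sizes

A study cell is: generate a 200-sample dataset (seed = base_seed +
replicate_id), split 160/40, select λ per method on the training portion,
refit, and record train/test MSE, MAE and RV; medians and IQRs aggregate
over replicates. The package's desk-scale defaults are 20 replicates, a
10 000-epoch cap for final fits and a 1 000-epoch schedule for the λ search
(the penalty ranking stabilizes long before convergence); the 200-replicate
protocol sits behind `--full`. Under these conditions the interaction G-G
scenario shows the expected ordering — multimodal network median test MSE
≈22 vs ≈55 for the FLM at noise 0.3, with the MFDL median non-decreasing
across noise 0.3 → 0.45 → 0.6. In the G-E cells with a scalar expression
modality the product interaction is largely linearly explainable (one factor
is a scalar Gaussian), and the closed-form FLM remains the best method there
— a useful reminder that the multimodal advantage is identifiable only when
both modalities carry high-dimensional structure.

## Numerical choices and limitations

Parameters initialize Glorot-uniform from a stored seed; identical seeds
give bit-identical models, histories and study CSVs (tested byte-for-byte).
Model serialization is JSON with base64 arrays and round-trips exactly.
Duplicate marker positions, out-of-domain basis evaluations, shape
mismatches, multi-allelic VCF records and missing genotypes (without the
impute flag) are hard errors. Known limitations: full-batch training only
(no minibatching or GPU); the trapezoid/uniform-grid discretization is fixed
rather than adaptive; the LD simulator is a marginal/correlation emulation,
not a population-genetic simulator; and functional (curve-valued) phenotypes
are out of scope — vector phenotypes are treated coordinate-wise by the
dense head.
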