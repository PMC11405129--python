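"""Fit the multimodal functional network to one simulated dataset.

Generates an interaction G-G scenario, splits 160/40, trains the default
two-subnet architecture with the ridge-regularized loss and ADADELTA, and
reports train/test MSE, MAE and RV next to the closed-form functional linear
model on the same split.
"""

import numpy as np

from mfdl import (
    FitSchedule,
    LossSpec,
    ScenarioSpec,
    TrainingData,
    build_model,
    fit,
    fit_flm,
    mae,
    make_dataset,
    mse,
    predict_flm,
    rv_coefficient,
)
from mfdl.experiments import default_mfdl_configs
from mfdl.training import _subset_modalities

ds = make_dataset(ScenarioSpec(relationship="interaction", omics_config="G-G",
                               noise_var=0.3), seed=1)
rng = np.random.default_rng(1)
perm = rng.permutation(ds.n_samples)
tr, te = perm[:160], perm[160:]
mods_tr = _subset_modalities(ds.modalities, tr)
mods_te = _subset_modalities(ds.modalities, te)
y_tr, y_te = ds.y[tr], ds.y[te]

subnets, head = default_mfdl_configs(mods_tr, phenotype_dim=1)
model = build_model(subnets, head, seed=1)
model, history = fit(model, TrainingData(modalities=mods_tr, y=y_tr),
                     LossSpec(lambda_penalty=0.1), FitSchedule(max_epochs=10_000))
print(f"trained {len(history)} epochs; final J~ = {history['J_tilde'].iloc[-1]:.2f}")

flm = fit_flm(mods_tr, None, y_tr, ridge_lambda=0.1)
for name, pred_tr, pred_te in [
    ("MFDL", model.forward(mods_tr), model.forward(mods_te)),
    ("FLM ", predict_flm(flm, mods_tr), predict_flm(flm, mods_te)),
]:
    print(f"{name}  train MSE {mse(y_tr, pred_tr):8.2f}  "
          f"test MSE {mse(y_te, pred_te):8.2f}  "
          f"test MAE {mae(y_te, pred_te):6.2f}  "
          f"test RV {rv_coefficient(y_te, pred_te):.3f}")
print("\nA lower test MSE / higher RV for MFDL reflects the interaction "
      "between the two genotype regions, which a linear model cannot absorb.")
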