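"""Replicated simulation studies and data ingestion.

A study is a grid of scenarios (relationship x omics configuration x
phenotype dimension x noise variance) evaluated over seeded replicates.
Each replicate generates a fresh dataset, splits it into a training and a
testing portion, selects the ridge penalty per method on the training
portion, refits, and records train/test MSE, MAE and RV.  Replicate seeds
are ``base_seed + replicate_id`` so a study is resumable and parallelizable
by replicate, and every output is byte-reproducible from the configuration.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .baselines import (
    concat_raw,
    fit_flm,
    fit_nn,
    fit_fnn3hl,
    predict_flm,
)
from .functional import OmicsVariantFunction, build_variant_function
from .metrics import evaluate
from .model import HeadConfig, SubnetConfig, build_model
from .simdata import ScenarioSpec, make_dataset
from .training import (
    FitSchedule,
    LossSpec,
    TrainingData,
    fit,
    select_lambda,
    _subset_modalities,
)

__all__ = ["StudyConfig", "StudySummary", "run_replicate", "run_study",
           "load_genotypes_vcf", "default_mfdl_configs"]

log = logging.getLogger("mfdl")

DEFAULT_LAMBDA_GRID = (0.1, 0.3, 1.0, 3.0, 10.0)
ALL_METHODS = ("MFDL", "FLM", "NN", "FNN-3HL")


@dataclass
class StudyConfig:
    """Scale and protocol of a replicated simulation study."""

    scenarios: list = field(default_factory=lambda: [ScenarioSpec()])
    n_replicates: int = 20
    n_train: int = 160
    n_test: int = 40
    methods: tuple = ("MFDL", "FLM")
    lambda_grid: tuple = DEFAULT_LAMBDA_GRID
    max_epochs: int = 10_000
    selection_max_epochs: int | None = None  # shorter schedule for the lambda search
    base_seed: int = 0

    def __post_init__(self):
        if not self.methods:
            raise ValueError("methods must be nonempty")
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}")
        for s in self.scenarios:
            if self.n_train + self.n_test != s.n_samples:
                raise ValueError(
                    f"n_train + n_test ({self.n_train + self.n_test}) must equal "
                    f"scenario n_samples ({s.n_samples})")

    def schedule(self) -> FitSchedule:
        return FitSchedule(max_epochs=self.max_epochs)

    def selection_schedule(self) -> FitSchedule:
        n = self.selection_max_epochs
        return FitSchedule(max_epochs=max(500, self.max_epochs // 10) if n is None else n)


@dataclass
class StudySummary:
    """Raw per-replicate results and their per-scenario aggregates."""

    raw: pd.DataFrame
    summary: pd.DataFrame
    failures: list


def default_mfdl_configs(modalities, phenotype_dim: int, n_covariates: int = 0,
                         embedding_width: int = 4,
                         n_hidden_functional_layers: int = 0,
                         head_widths: tuple = (8,)):
    """Default MFDL architecture for a list of modality inputs.

    Functional subnets (B-spline order 5, 7 basis functions; functional
    input and output layers, optionally deeper) for positional modalities; a
    small dense subnet for scalar/matrix modalities; one tanh hidden layer in
    the head.  Widths and depth are deliberately small: at the standard
    n = 200 sample size larger embeddings, heads and extra functional layers
    overfit the 160-sample training split.
    """
    subnets = []
    for m in modalities:
        if isinstance(m, OmicsVariantFunction):
            subnets.append(SubnetConfig(
                modality_kind="functional", n_covariates=n_covariates,
                embedding_width=embedding_width,
                n_hidden_functional_layers=n_hidden_functional_layers))
        else:
            p = np.asarray(m).shape[1]
            subnets.append(SubnetConfig(modality_kind="dense", n_features=p,
                                        dense_widths=(4,),
                                        embedding_width=embedding_width))
    head = HeadConfig(hidden_widths=head_widths, output_dim=phenotype_dim)
    return subnets, head


def _fit_method(method: str, train: TrainingData, lambda_grid, schedule: FitSchedule,
                seed: int, phenotype_dim: int,
                selection_schedule: FitSchedule | None = None):
    """Select lambda on the training portion, refit, return a predictor.

    The lambda search may use a shorter schedule than the final refit; the
    penalty ranking stabilizes well before full convergence.
    """
    sel = selection_schedule or schedule
    if method == "FLM":
        # closed form: score every lambda on a held-out quarter of the training set
        rng = np.random.default_rng(seed)
        n = train.y.shape[0]
        perm = rng.permutation(n)
        n_val = max(1, n // 4)
        va, tr = perm[:n_val], perm[n_val:]
        best = None
        for lam in lambda_grid:
            m = fit_flm(_subset_modalities(train.modalities, tr), None, train.y[tr],
                        ridge_lambda=lam)
            pred = predict_flm(m, _subset_modalities(train.modalities, va))
            err = float(np.mean(np.sum((train.y[va] - pred) ** 2, axis=1)))
            if best is None or err <= best[0] + 1e-15:
                best = (err, lam)
        model = fit_flm(train.modalities, None, train.y, ridge_lambda=best[1])
        return lambda mods: predict_flm(model, mods), best[1]

    if method == "MFDL":
        subnets, head = default_mfdl_configs(train.modalities, phenotype_dim)

        def factory(s):
            return build_model(subnets, head, seed=s)

        lam, _ = select_lambda(factory, train, lambda_grid, seed=seed, schedule=sel)
        model = factory(seed)
        fit(model, train, LossSpec(lam), schedule)
        return model.predict, lam

    if method == "NN":
        X = concat_raw(train.modalities)

        def nn_val_mse(lam):
            rng = np.random.default_rng(seed)
            perm = rng.permutation(X.shape[0])
            n_val = max(1, X.shape[0] // 4)
            va, tr = perm[:n_val], perm[n_val:]
            m, _ = fit_nn(X[tr], train.y[tr], ridge_lambda=lam, schedule=sel,
                          seed=seed)
            pred = m.forward([X[va]])
            return float(np.mean(np.sum((train.y[va] - pred) ** 2, axis=1)))

        errs = [(nn_val_mse(lam), lam) for lam in lambda_grid]
        best = min(e for e, _ in errs)
        lam = max(l for e, l in errs if e <= best + 1e-15)
        model, _ = fit_nn(X, train.y, ridge_lambda=lam, schedule=schedule, seed=seed)
        return (lambda mods: model.forward([concat_raw(mods)])), lam

    if method == "FNN-3HL":
        def f3_val_mse(lam):
            rng = np.random.default_rng(seed)
            n = train.y.shape[0]
            perm = rng.permutation(n)
            n_val = max(1, n // 4)
            va, tr = perm[:n_val], perm[n_val:]
            m, _ = fit_fnn3hl(_subset_modalities(train.modalities, tr), train.y[tr],
                              ridge_lambda=lam, schedule=sel, seed=seed)
            pred = m.forward(_subset_modalities(train.modalities, va))
            return float(np.mean(np.sum((train.y[va] - pred) ** 2, axis=1)))

        errs = [(f3_val_mse(lam), lam) for lam in lambda_grid]
        best = min(e for e, _ in errs)
        lam = max(l for e, l in errs if e <= best + 1e-15)
        model, _ = fit_fnn3hl(train.modalities, train.y, ridge_lambda=lam,
                              schedule=schedule, seed=seed)
        return model.predict, lam

    raise ValueError(f"unknown method {method!r}")


def run_replicate(spec: ScenarioSpec, study: StudyConfig, replicate_id: int):
    """One seeded replicate: generate, split, select lambda, fit, evaluate.

    Returns (results, failures): EvalResult rows for every method and split,
    and (method, message) pairs for methods that failed.
    """
    seed = study.base_seed + replicate_id
    ds = make_dataset(spec, seed=seed)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ds.n_samples)
    tr, te = perm[:study.n_train], perm[study.n_train:study.n_train + study.n_test]
    train = TrainingData(modalities=_subset_modalities(ds.modalities, tr), y=ds.y[tr])
    test_mods = _subset_modalities(ds.modalities, te)
    y_test = ds.y[te]
    results, failures = [], []
    for method in study.methods:
        t0 = time.perf_counter()
        try:
            predictor, lam = _fit_method(method, train, study.lambda_grid,
                                         study.schedule(), seed, spec.phenotype_dim,
                                         selection_schedule=study.selection_schedule())
            for split, mods, y in (("train", train.modalities, train.y),
                                   ("test", test_mods, y_test)):
                results.append(evaluate(method, split, y, predictor(mods),
                                        replicate_id=replicate_id, seed=seed))
            log.info("replicate %d %s: lambda=%g (%.1fs)", replicate_id, method,
                     lam, time.perf_counter() - t0)
        except Exception as exc:  # record and continue with remaining methods
            failures.append((method, f"replicate {replicate_id}: {exc}"))
            log.warning("replicate %d %s FAILED: %s", replicate_id, method, exc)
    return results, failures


def run_study(study: StudyConfig, outdir: str | None = None) -> StudySummary:
    """Run every scenario x replicate, aggregate medians/IQRs, optionally write files."""
    if outdir:
        os.makedirs(outdir, exist_ok=True)
    all_rows, failures = [], []
    for s_idx, spec in enumerate(study.scenarios):
        label = (f"{spec.relationship}/{spec.omics_config}/"
                 f"d{spec.phenotype_dim}/noise{spec.noise_var:g}")
        for rep in range(study.n_replicates):
            res, fails = run_replicate(spec, study, rep)
            for r in res:
                row = {"scenario": label, "scenario_index": s_idx}
                row.update(r.__dict__)
                all_rows.append(row)
            failures.extend((label, m, msg) for m, msg in fails)
            if outdir:  # flush partial results
                pd.DataFrame(all_rows).to_csv(
                    os.path.join(outdir, "results_raw.csv"), index=False)
    raw = pd.DataFrame(all_rows)
    if raw.empty:
        summary = pd.DataFrame()
    else:
        g = raw.groupby(["scenario", "method", "split"], sort=True)
        summary = g.agg(
            median_mse=("mse", "median"),
            iqr_mse=("mse", lambda x: float(np.subtract(*np.percentile(x, [75, 25])))),
            median_mae=("mae", "median"),
            median_rv=("rv", "median"),
            iqr_rv=("rv", lambda x: float(np.subtract(*np.percentile(x, [75, 25])))),
            n_replicates=("replicate_id", "nunique"),
        ).reset_index()
    if outdir:
        os.makedirs(outdir, exist_ok=True)
        raw.to_csv(os.path.join(outdir, "results_raw.csv"), index=False)
        summary.to_csv(os.path.join(outdir, "results_summary.csv"), index=False)
        with open(os.path.join(outdir, "study.json"), "w") as fh:
            json.dump({"config": {**asdict(study),
                                  "scenarios": [asdict(s) for s in study.scenarios]},
                       "failures": failures}, fh, indent=1, default=str)
    return StudySummary(raw=raw, summary=summary, failures=failures)


# ---------------------------------------------------------------------------
# VCF ingestion
# ---------------------------------------------------------------------------

def load_genotypes_vcf(path, mean_impute: bool = False,
                       modality_id: str = "genotype") -> OmicsVariantFunction:
    """Read biallelic GT dosages from a VCF region into a variant function.

    Dosage is the count of alternate alleles per sample.  Multi-allelic
    records are rejected (listing CHROM:POS); missing genotypes are an error
    unless ``mean_impute`` is set.
    """
    from cyvcf2 import VCF

    cols, positions, multi = [], [], []
    vcf = VCF(str(path))
    for var in vcf:
        if len(var.ALT) != 1:
            multi.append(f"{var.CHROM}:{var.POS}")
            continue
        dos = np.array([a + b if (a >= 0 and b >= 0) else np.nan
                        for a, b, *_ in var.genotypes], dtype=float)
        if np.isnan(dos).any():
            if not mean_impute:
                raise ValueError(
                    f"missing genotypes at {var.CHROM}:{var.POS}; "
                    "pass mean_impute=True to fill with the site mean")
            dos = np.where(np.isnan(dos), np.nanmean(dos), dos)
        cols.append(dos)
        positions.append(var.POS)
    if multi:
        raise ValueError(f"multi-allelic sites not supported: {', '.join(multi)}")
    if not cols:
        raise ValueError(f"no biallelic records found in {path}")
    values = np.column_stack(cols)
    return build_variant_function(values, positions, modality_id=modality_id)
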