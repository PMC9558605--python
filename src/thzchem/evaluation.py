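"""Evaluation design: grouped k-fold CV, RMSEC/RMSEP, pipeline runs and
comparative analyses.

The cross-validation mirrors the calibration study's design: replicate spectra
of ternary mixtures are divided into k folds *by sample* (all replicates of a
sample stay together, otherwise near-duplicate spectra leak across the split),
while unitary and binary mixtures are pinned to every training set — they are
the extrema that bound the interpolation of ternary compositions.

A pipeline is (normalization | Mie baseline removal, dimensionality reduction,
prediction model); every stage has an explicit bypass.  Each fold fits every
stage on the training block only.  The headline metric is the *pooled* RMSE
over all held-out residuals (per-fold values are also reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import models as mdl
from . import preprocessing as prep
from .mie_baseline import (
    MieParams,
    ValidMask,
    mie_extinction_efficiency,
    remove_baseline,
    valid_frequency_mask,
)
from .spectra_io import SpectraDataset

__all__ = [
    "ALWAYS_TRAIN",
    "FoldAssignment",
    "PipelineSpec",
    "EvalResult",
    "assign_folds",
    "rmse",
    "run_pipeline",
    "grid_search",
    "preprocessing_effect",
    "linearity_comparison",
]

ALWAYS_TRAIN = -1

BASELINE_MODES = ("none", "multifactor", "single_factor", "multifactor_concat")


@dataclass(frozen=True)
class FoldAssignment:
    k: int
    fold_of_sample: dict  # sample_id -> fold index (0..k-1) or ALWAYS_TRAIN

    def test_indices(self, dataset: SpectraDataset, fold: int) -> np.ndarray:
        return np.array([
            i for i, r in enumerate(dataset.records)
            if self.fold_of_sample[r.sample_id] == fold
        ], dtype=int)

    def train_indices(self, dataset: SpectraDataset, fold: int) -> np.ndarray:
        return np.array([
            i for i, r in enumerate(dataset.records)
            if self.fold_of_sample[r.sample_id] != fold
        ], dtype=int)


def assign_folds(dataset: SpectraDataset, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Deal ternary samples into k folds; pin unitary/binary samples to training.

    Samples (not spectra) are shuffled with ``seed`` and dealt round-robin, so
    fold sizes differ by at most one sample and all replicates of a sample
    share its assignment.
    """
    order_of = {}
    for rec in dataset.records:
        order_of[rec.sample_id] = rec.mixture_order
    ternary = [sid for sid, order in order_of.items() if order == 3]
    if k < 2 or k > len(ternary):
        raise ValueError(f"k={k} out of range for {len(ternary)} ternary samples")
    rng = np.random.default_rng(seed)
    shuffled = list(np.array(ternary, dtype=object)[rng.permutation(len(ternary))])
    fold_of = {sid: ALWAYS_TRAIN for sid, order in order_of.items() if order <= 2}
    for i, sid in enumerate(shuffled):
        fold_of[sid] = i % k
    return FoldAssignment(k=k, fold_of_sample=fold_of)


def rmse(predicted: np.ndarray, actual: np.ndarray) -> float:
    """Root-mean-square error pooled over all records and all three analytes."""
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape:
        raise ValueError("shape mismatch between predicted and actual")
    if predicted.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((predicted - actual) ** 2)))


@dataclass(frozen=True)
class PipelineSpec:
    """One (normalization, baseline, reduction, model) combination."""

    normalizer: str = "none"            # zscore | minmax | mie | none
    baseline_mode: str = "none"         # none | multifactor | single_factor | multifactor_concat
    reducer: prep.ReducerSpec = field(default_factory=prep.ReducerSpec)
    model: mdl.ModelSpec = field(default_factory=lambda: mdl.preset("plsr-table2"))
    mie_params: MieParams = field(default_factory=MieParams)
    seed: int = 0

    def __post_init__(self):
        if self.baseline_mode not in BASELINE_MODES:
            raise ValueError(f"unknown baseline mode {self.baseline_mode!r}")
        if self.normalizer == "mie" and self.baseline_mode == "none":
            object.__setattr__(self, "baseline_mode", "multifactor")
        if self.normalizer not in ("mie", *prep.NORMALIZER_METHODS):
            raise ValueError(f"unknown normalizer {self.normalizer!r}")
        if self.baseline_mode != "none" and self.normalizer != "mie":
            raise ValueError("baseline modes require normalizer='mie'")
        if self.reducer.concat_xi and self.baseline_mode != "multifactor_concat":
            raise ValueError("concat_xi needs baseline mode multifactor_concat")

    @property
    def name(self) -> str:
        norm = self.normalizer if self.normalizer != "mie" else f"mie:{self.baseline_mode}"
        red = "none" if self.reducer.method == "none" else (
            f"{self.reducer.method}({self.reducer.n_components})"
        )
        return f"{norm}/{red}/{self.model.family}"


@dataclass(frozen=True)
class EvalResult:
    spec: PipelineSpec
    fold_rmsec: np.ndarray
    fold_rmsep: np.ndarray
    fold_test_sizes: np.ndarray
    pooled_rmsec: float
    pooled_rmsep: float
    per_analyte_rmsep: np.ndarray
    seed: int
    error: str | None = None

    def to_row(self) -> dict:
        return {
            "spec": self.spec.name,
            "pooled_rmsec": self.pooled_rmsec,
            "pooled_rmsep": self.pooled_rmsep,
            "mean_fold_rmsep": float(np.mean(self.fold_rmsep)),
            **{f"rmsep_analyte{j}": v for j, v in enumerate(self.per_analyte_rmsep)},
            "seed": self.seed,
        }


def _fit_fold(spec: PipelineSpec, train_ds, test_ds):
    """Fit every stage on the training block; transform both blocks."""
    xi_train = xi_test = None
    if spec.normalizer == "mie":
        mask = valid_frequency_mask(train_ds.grid)
        qext = mie_extinction_efficiency(spec.mie_params, train_ds.grid)
        mode = spec.baseline_mode
        train_ds, test_ds, fit = remove_baseline(
            train_ds, test_ds, spec.mie_params, mask, mode=mode,
            method="closed_form", qext=qext,
        )
        if mode == "multifactor_concat":
            xi_train, xi_test = fit["train"], fit["apply"]
        Xtr, Xte = train_ds.absorbance_matrix(), test_ds.absorbance_matrix()
    else:
        Xtr, Xte = train_ds.absorbance_matrix(), test_ds.absorbance_matrix()
        norm = prep.fit_normalizer(Xtr, spec.normalizer)
        Xtr, Xte = prep.apply_normalizer(norm, Xtr), prep.apply_normalizer(norm, Xte)

    reducer_spec = replace(spec.reducer, seed=spec.seed)
    red = prep.fit_reducer(Xtr, reducer_spec)
    Xtr = prep.apply_reducer(red, Xtr, xi_train)
    Xte = prep.apply_reducer(red, Xte, xi_test)

    model_spec = replace(spec.model, seed=spec.seed)
    model = mdl.train(model_spec, Xtr, train_ds.composition_matrix())
    return model, Xtr, Xte


def run_pipeline(
    spec: PipelineSpec, dataset: SpectraDataset, folds: FoldAssignment
) -> EvalResult:
    """Evaluate one pipeline under the grouped CV design.

    Per fold: fit normalizer/baseline/reducer/model on training spectra only,
    predict the training block (RMSEC) and the held-out block (RMSEP).  Pooled
    metrics are RMSEs over all pooled residuals, not averages of fold RMSEs.
    """
    fold_rmsec, fold_rmsep, sizes = [], [], []
    resid_c, resid_p = [], []
    for fold in range(folds.k):
        tr_idx = folds.train_indices(dataset, fold)
        te_idx = folds.test_indices(dataset, fold)
        train_ds, test_ds = dataset.subset(tr_idx), dataset.subset(te_idx)
        try:
            model, Xtr, Xte = _fit_fold(spec, train_ds, test_ds)
            pred_tr = mdl.predict(model, Xtr)
            pred_te = mdl.predict(model, Xte)
        except Exception as exc:
            raise RuntimeError(
                f"pipeline {spec.name} failed in fold {fold}: {exc}"
            ) from exc
        Ytr, Yte = train_ds.composition_matrix(), test_ds.composition_matrix()
        fold_rmsec.append(rmse(pred_tr, Ytr))
        fold_rmsep.append(rmse(pred_te, Yte))
        sizes.append(len(te_idx))
        resid_c.append(pred_tr - Ytr)
        resid_p.append(pred_te - Yte)

    rc = np.vstack(resid_c)
    rp = np.vstack(resid_p)
    return EvalResult(
        spec=spec,
        fold_rmsec=np.array(fold_rmsec),
        fold_rmsep=np.array(fold_rmsep),
        fold_test_sizes=np.array(sizes),
        pooled_rmsec=float(np.sqrt(np.mean(rc**2))),
        pooled_rmsep=float(np.sqrt(np.mean(rp**2))),
        per_analyte_rmsep=np.sqrt(np.mean(rp**2, axis=0)),
        seed=spec.seed,
    )


def grid_search(
    grid: list[PipelineSpec], dataset: SpectraDataset, folds: FoldAssignment
) -> list[EvalResult]:
    """Evaluate every spec; rank by pooled RMSEP, ties by RMSEC then spec name.

    Individual spec failures are recorded as error results (infinite RMSE),
    sorted last, never fatal.
    """
    if not grid:
        raise ValueError("empty pipeline grid")
    results = []
    for spec in grid:
        try:
            results.append(run_pipeline(spec, dataset, folds))
        except Exception as exc:
            results.append(EvalResult(
                spec=spec, fold_rmsec=np.array([]), fold_rmsep=np.array([]),
                fold_test_sizes=np.array([]), pooled_rmsec=np.inf,
                pooled_rmsep=np.inf, per_analyte_rmsep=np.full(3, np.inf),
                seed=spec.seed, error=str(exc),
            ))
    return sorted(results, key=lambda r: (r.pooled_rmsep, r.pooled_rmsec, r.spec.name))


# --- preprocessing-effect analysis -----------------------------------------


def _pair_key(spec: PipelineSpec, stage: str):
    """Identity of a spec with one stage blanked out (the matching key)."""
    if stage == "normalizer":
        return ("N", spec.reducer.method, spec.reducer.n_components,
                spec.model.family, spec.model.mlp_activation, spec.seed)
    return ("R", spec.normalizer, spec.baseline_mode,
            spec.model.family, spec.model.mlp_activation, spec.seed)


def preprocessing_effect(results: list[EvalResult]) -> dict:
    """Mean change in RMSEP per (technique, model family) over matched pairs.

    For each result using a normalization (or reduction) technique, the RMSEP
    of the configuration identical except for that stage bypassed is
    subtracted: delta = RMSEP_with - RMSEP_without, so negative means the
    technique helped.  Cells without matched pairs are absent, never zero;
    pair counts are reported.
    """
    by_key_none: dict = {}
    for r in results:
        if r.error:
            continue
        if r.spec.normalizer == "none":
            by_key_none.setdefault(("norm", _pair_key(r.spec, "normalizer")), r)
        if r.spec.reducer.method == "none":
            by_key_none.setdefault(("red", _pair_key(r.spec, "reducer")), r)

    cells: dict = {}
    for r in results:
        if r.error:
            continue
        probes = []
        if r.spec.normalizer != "none":
            tech = (r.spec.normalizer if r.spec.normalizer != "mie"
                    else "mie_baseline_removal")
            probes.append(("norm", tech, _pair_key(r.spec, "normalizer")))
        if r.spec.reducer.method != "none":
            probes.append(("red", r.spec.reducer.method, _pair_key(r.spec, "reducer")))
        for kind, tech, key in probes:
            base = by_key_none.get((kind, key))
            if base is None:
                continue
            cell = cells.setdefault((tech, r.spec.model.family), [])
            cell.append(r.pooled_rmsep - base.pooled_rmsep)

    return {
        key: {"mean_delta": float(np.mean(deltas)), "n_pairs": len(deltas)}
        for key, deltas in cells.items()
    }


def linearity_comparison(
    dataset: SpectraDataset, folds: FoldAssignment, seeds=(0, 1, 2, 3, 4)
) -> list[dict]:
    """Linear vs nonlinear MLP with no preprocessing, paired over seeds.

    For each seed the tanh-activation and identity-activation single-hidden-
    layer MLPs are run on identical folds; the paired pooled RMSEPs and their
    percentage difference probe whether the spectra→composition map is linear.
    """
    if not seeds:
        raise ValueError("need at least one seed")
    rows = []
    for seed in seeds:
        res = {}
        for name in ("mlp-tanh", "mlp-linear"):
            spec = PipelineSpec(model=mdl.preset(name, seed=seed), seed=seed)
            res[name] = run_pipeline(spec, dataset, folds)
        tanh, lin = res["mlp-tanh"].pooled_rmsep, res["mlp-linear"].pooled_rmsep
        rows.append({
            "seed": seed,
            "rmsep_tanh": tanh,
            "rmsep_identity": lin,
            "delta": tanh - lin,
            "pct_difference": 100.0 * (tanh - lin) / lin if lin else np.nan,
        })
    return rows
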