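"""Grouped CV design, pipeline runner, effect analysis, linearity table."""

import numpy as np
import pytest

import thzchem as tc
from thzchem import evaluation as ev
from thzchem import models as mdl
from thzchem.preprocessing import ReducerSpec
from conftest import clean_config


@pytest.fixture(scope="module")
def clean_ds():
    return tc.simulate_dataset(config=clean_config())


@pytest.fixture(scope="module")
def folds(clean_ds):
    return ev.assign_folds(clean_ds, k=5, seed=0)


class TestAssignFolds:
    def test_fold_sizes_match_design(self, clean_ds, folds):
        """Five folds of 60 test spectra; 420 training incl. all order<=2."""
        for f in range(5):
            te = folds.test_indices(clean_ds, f)
            tr = folds.train_indices(clean_ds, f)
            assert len(te) == 60 and len(tr) == 420
            orders = [clean_ds.records[i].mixture_order for i in te]
            assert all(o == 3 for o in orders)

    def test_fold_partition_conservation(self, clean_ds, folds):
        ternary = [i for i, r in enumerate(clean_ds.records) if r.mixture_order == 3]
        seen = np.concatenate([folds.test_indices(clean_ds, f) for f in range(5)])
        assert sorted(seen) == sorted(ternary)
        for f in range(5):
            tr_ids = {clean_ds.records[i].sample_id
                      for i in folds.train_indices(clean_ds, f)}
            low = {r.sample_id for r in clean_ds.records if r.mixture_order <= 2}
            assert low <= tr_ids

    def test_replicates_stay_together(self, clean_ds, folds):
        # fold of a record is a function of sample_id only
        by_sample = {}
        for f in range(5):
            for i in folds.test_indices(clean_ds, f):
                sid = clean_ds.records[i].sample_id
                by_sample.setdefault(sid, set()).add(f)
        assert all(len(v) == 1 for v in by_sample.values())

    def test_leave_one_sample_out(self):
        comps = [tc.Composition(0.2 + 0.05 * i, 0.5 - 0.03 * i, 0.3 - 0.02 * i)
                 for i in range(4)]
        ds = tc.simulate_dataset(compositions=comps,
                                 config=clean_config(replicates=3),
                                 grid=tc.default_grid(0.3, 3.0, 0.05))
        folds = ev.assign_folds(ds, k=4, seed=0)
        for f in range(4):
            assert len(folds.test_indices(ds, f)) == 3

    def test_different_seeds_same_size_multiset(self, clean_ds):
        f1 = ev.assign_folds(clean_ds, 5, seed=1)
        f2 = ev.assign_folds(clean_ds, 5, seed=2)
        sizes = lambda fa: sorted(len(fa.test_indices(clean_ds, f)) for f in range(5))
        assert sizes(f1) == sizes(f2)
        assert f1.fold_of_sample != f2.fold_of_sample

    def test_k_out_of_range(self, clean_ds):
        with pytest.raises(ValueError):
            ev.assign_folds(clean_ds, k=1)
        with pytest.raises(ValueError):
            ev.assign_folds(clean_ds, k=51)


class TestRmse:
    def test_hand_arithmetic(self):
        pred = np.array([[0.5, 0.3, 0.2]])
        act = np.array([[0.4, 0.4, 0.2]])
        assert ev.rmse(pred, act) == pytest.approx(np.sqrt(0.02 / 3), abs=1e-9)

    def test_perfect_and_constant_residual(self, rng):
        Y = rng.dirichlet(np.ones(3), size=10)
        assert ev.rmse(Y, Y) == 0.0
        assert ev.rmse(Y + 0.07, Y) == pytest.approx(0.07)
        assert ev.rmse(Y - 0.03, Y) == pytest.approx(0.03)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ev.rmse(np.empty((0, 3)), np.empty((0, 3)))


class TestRunPipeline:
    def test_noiseless_linear_plsr(self, clean_ds, folds):
        res = ev.run_pipeline(
            ev.PipelineSpec(model=mdl.preset("plsr-table2")), clean_ds, folds)
        assert res.pooled_rmsep <= 1e-3
        assert res.pooled_rmsec <= 1e-3

    def test_bypass_equivalence(self, clean_ds, folds):
        """Explicit no-op stages equal the raw-feature path."""
        a = ev.run_pipeline(ev.PipelineSpec(
            normalizer="none", reducer=ReducerSpec(method="none"),
            model=mdl.preset("plsr-table2")), clean_ds, folds)
        b = ev.run_pipeline(ev.PipelineSpec(
            model=mdl.preset("plsr-table2")), clean_ds, folds)
        assert a.pooled_rmsep == b.pooled_rmsep
        assert np.array_equal(a.fold_rmsep, b.fold_rmsep)

    def test_pooled_rmse_identity(self, clean_ds, folds, default_dataset):
        res = ev.run_pipeline(
            ev.PipelineSpec(model=mdl.preset("plsr-table2")),
            default_dataset, ev.assign_folds(default_dataset, 5, seed=0))
        n_total = res.fold_test_sizes.sum()
        lhs = res.pooled_rmsep**2 * n_total
        rhs = np.sum(res.fold_rmsep**2 * res.fold_test_sizes)
        assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_determinism(self, default_dataset):
        folds = ev.assign_folds(default_dataset, 5, seed=3)
        spec = ev.PipelineSpec(normalizer="minmax",
                               reducer=ReducerSpec(method="pca", n_components=10),
                               model=mdl.preset("plsr-table2", seed=3), seed=3)
        r1 = ev.run_pipeline(spec, default_dataset, folds)
        r2 = ev.run_pipeline(spec, default_dataset, folds)
        assert r1.pooled_rmsep == r2.pooled_rmsep
        assert np.array_equal(r1.fold_rmsep, r2.fold_rmsep)

    def test_monotone_noise_response(self):
        """More measurement noise cannot improve the reference pipeline."""
        rmseps = []
        for noise in (0.0, 0.01, 0.05):
            pooled = []
            for seed in range(3):
                ds = tc.simulate_dataset(config=clean_config(noise_sd=noise, seed=seed))
                folds = ev.assign_folds(ds, 5, seed=seed)
                res = ev.run_pipeline(
                    ev.PipelineSpec(model=mdl.preset("plsr-table2", seed=seed),
                                    seed=seed), ds, folds)
                pooled.append(res.pooled_rmsep)
            rmseps.append(np.mean(pooled))
        assert rmseps[0] <= rmseps[1] <= rmseps[2]

    def test_stage_failure_names_fold_and_stage(self, clean_ds, folds):
        bad = ev.PipelineSpec(
            normalizer="zscore",  # zscore makes entries negative -> NMF must fail
            reducer=ReducerSpec(method="nmf", n_components=3),
            model=mdl.preset("plsr-table2"))
        with pytest.raises(RuntimeError, match="fold 0"):
            ev.run_pipeline(bad, clean_ds, folds)


class TestGridSearch:
    def test_singleton_grid(self, clean_ds, folds):
        spec = ev.PipelineSpec(model=mdl.preset("plsr-table2"))
        results = ev.grid_search([spec], clean_ds, folds)
        single = ev.run_pipeline(spec, clean_ds, folds)
        assert len(results) == 1
        assert results[0].pooled_rmsep == single.pooled_rmsep

    def test_cartesian_count_and_order_invariance(self, default_dataset):
        folds = ev.assign_folds(default_dataset, 5, seed=0)
        grid = [
            ev.PipelineSpec(normalizer=n, reducer=r, model=mdl.preset("plsr-table2"))
            for n in ("none", "minmax")
            for r in (ReducerSpec(method="none"),
                      ReducerSpec(method="pca", n_components=5))
        ]
        res_fwd = ev.grid_search(grid, default_dataset, folds)
        res_rev = ev.grid_search(grid[::-1], default_dataset, folds)
        assert len(res_fwd) == 4
        assert [r.spec.name for r in res_fwd] == [r.spec.name for r in res_rev]
        assert len({id(r.spec) for r in res_fwd}) == 4

    def test_individual_failures_recorded_not_fatal(self, clean_ds, folds):
        grid = [
            ev.PipelineSpec(model=mdl.preset("plsr-table2")),
            ev.PipelineSpec(normalizer="zscore",
                            reducer=ReducerSpec(method="nmf", n_components=3),
                            model=mdl.preset("plsr-table2")),
        ]
        results = ev.grid_search(grid, clean_ds, folds)
        assert results[0].error is None
        assert results[-1].error is not None
        assert np.isinf(results[-1].pooled_rmsep)


class TestPreprocessingEffect:
    def _result(self, spec, rmsep):
        return ev.EvalResult(
            spec=spec, fold_rmsec=np.zeros(5), fold_rmsep=np.zeros(5),
            fold_test_sizes=np.full(5, 60), pooled_rmsec=rmsep,
            pooled_rmsep=rmsep, per_analyte_rmsep=np.full(3, rmsep), seed=0)

    def test_single_pair_delta(self):
        base = ev.PipelineSpec(model=mdl.preset("plsr-table2"))
        with_norm = ev.PipelineSpec(normalizer="minmax",
                                    model=mdl.preset("plsr-table2"))
        report = ev.preprocessing_effect(
            [self._result(base, 0.05), self._result(with_norm, 0.03)])
        cell = report[("minmax", "plsr")]
        assert cell["mean_delta"] == pytest.approx(-0.02)
        assert cell["n_pairs"] == 1

    def test_equal_rmseps_zero_delta(self):
        base = ev.PipelineSpec(model=mdl.preset("plsr-table2"))
        probe = ev.PipelineSpec(normalizer="zscore", model=mdl.preset("plsr-table2"))
        report = ev.preprocessing_effect(
            [self._result(base, 0.04), self._result(probe, 0.04)])
        assert report[("zscore", "plsr")]["mean_delta"] == 0.0

    def test_unmatched_cells_absent(self):
        probe = ev.PipelineSpec(normalizer="zscore", model=mdl.preset("plsr-table2"))
        report = ev.preprocessing_effect([self._result(probe, 0.04)])
        assert report == {}

    def test_minmax_noop_on_unit_interval_data(self, default_dataset):
        """On data already spanning [0,1] per feature min-max changes nothing
        except an affine map PLSR is invariant to; delta is solver noise."""
        X = default_dataset.absorbance_matrix()
        lo, rngs = X.min(axis=0), X.max(axis=0) - X.min(axis=0)
        X01 = (X - lo) / np.where(rngs > 0, rngs, 1.0)
        ds01 = default_dataset.with_absorbance(X01)
        folds = ev.assign_folds(ds01, 5, seed=0)
        base = ev.run_pipeline(ev.PipelineSpec(model=mdl.preset("plsr-table2")),
                               ds01, folds)
        norm = ev.run_pipeline(ev.PipelineSpec(normalizer="minmax",
                                               model=mdl.preset("plsr-table2")),
                               ds01, folds)
        report = ev.preprocessing_effect([base, norm])
        assert abs(report[("minmax", "plsr")]["mean_delta"]) <= 1e-4


class TestLinearityComparison:
    def test_table_shape(self, clean_ds, folds):
        rows = ev.linearity_comparison(clean_ds, folds, seeds=(0,))
        assert len(rows) == 1
        row = rows[0]
        assert {"seed", "rmsep_tanh", "rmsep_identity", "delta",
                "pct_difference"} <= set(row)

    def test_rejects_empty_seeds(self, clean_ds, folds):
        with pytest.raises(ValueError):
            ev.linearity_comparison(clean_ds, folds, seeds=())
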