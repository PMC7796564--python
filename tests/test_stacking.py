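"""Super Learner: meta-feature construction, the five combiners, nested
evaluation, and the paired model comparison."""

import numpy as np
import pandas as pd
import pytest

import dilearn as dl
from dilearn.cv import BlockSpec, make_folds
from dilearn.filters import FilterSpec
from dilearn.models import ModelSpec
from dilearn.stacking import (
    CombinerModel,
    MetaFeatureMatrix,
    build_meta,
    compare_models,
    fit_combiner,
    nested_evaluate,
    predict_combined,
    rank_bases,
)


def meta_from(values: dict, y, auc_table=None):
    frame = pd.DataFrame(values)
    if auc_table is None:
        auc_table = pd.DataFrame(
            {c: [dl.auc(frame[c], y)] for c in frame.columns}
        )
    return MetaFeatureMatrix(values=frame, auc_table=auc_table)


class TestBuildMeta:
    def test_one_column_per_base(self, tiny_aligned, fast_model):
        blocks, chem, y = tiny_aligned
        bases = {
            ds.block_id: [
                BlockSpec(ds.block_id, ds.data, FilterSpec(method="info1d", top_n=20)),
                BlockSpec("chem", chem.data, FilterSpec(method="welch", top_n=10)),
            ]
            for ds in blocks
        }
        plan = make_folds(np.asarray(y.index), y.to_numpy(), 4, stratified=True, seed=0, repeats=2)
        meta = build_meta(bases, y, plan, fast_model)
        assert meta.values.shape == (len(y), 2)
        assert list(meta.values.columns) == [b.block_id for b in blocks]
        assert ((meta.values.to_numpy() >= 0) & (meta.values.to_numpy() <= 1)).all()
        assert meta.auc_table.shape == (2, 2)  # repeats x bases


class TestRankBases:
    def test_perfect_column_first_and_ties_by_id(self):
        y = np.array([1, 1, 0, 0, 1, 0])
        auc_table = pd.DataFrame({"zed": [0.6, 0.6], "alpha": [0.6, 0.6], "best": [1.0, 1.0]})
        meta = meta_from({"zed": y, "alpha": y, "best": y}, y, auc_table)
        ranked = rank_bases(meta)
        assert list(ranked["base_id"]) == ["best", "alpha", "zed"]
        assert ranked["mean_internal_auc"].iloc[0] == 1.0


class TestCombiners:
    y = np.array([1, 1, 1, 0, 0, 0, 1, 0])

    def _meta(self, seed=0):
        rng = np.random.default_rng(seed)
        cols = {
            "good": np.clip(self.y * 0.8 + rng.normal(0, 0.1, 8), 0, 1),
            "noise1": rng.random(8),
            "noise2": rng.random(8),
        }
        auc_table = pd.DataFrame({c: [dl.auc(v, self.y)] for c, v in cols.items()})
        return meta_from(cols, self.y, auc_table)

    def test_best_single_stores_argmax(self):
        model = fit_combiner(self._meta(), self.y, "best_single")
        assert model.selected == ["good"]
        preds = predict_combined(model, self._meta().values)
        assert np.allclose(preds, self._meta().values["good"])

    def test_mean_all_on_identical_columns_is_identity(self):
        col = np.linspace(0, 1, 8)
        meta = meta_from({"a": col, "b": col, "c": col}, self.y)
        model = fit_combiner(meta, self.y, "mean_all")
        assert np.allclose(predict_combined(model, meta.values), col)

    def test_mean_top5_arithmetic(self):
        model = CombinerModel(kind="mean_top5", columns=list("abcde"),
                              selected=list("abcde"))
        row = pd.DataFrame([[0.9, 0.8, 0.7, 0.6, 0.5]], columns=list("abcde"))
        assert predict_combined(model, row)[0] == pytest.approx(0.7)

    def test_mean_top5_selects_min_five(self):
        meta = self._meta()
        model = fit_combiner(meta, self.y, "mean_top5")
        assert len(model.selected) == 3  # min(5, B)

    def test_mean_top5_permutation_invariant(self):
        rng = np.random.default_rng(3)
        cols = {c: rng.random(8) for c in "abcde"}
        model = CombinerModel(kind="mean_top5", columns=list("abcde"), selected=list("abcde"))
        frame = pd.DataFrame(cols)
        base = predict_combined(model, frame)
        model2 = CombinerModel(kind="mean_top5", columns=list("abcde"),
                               selected=["d", "b", "e", "a", "c"])
        assert np.allclose(base, predict_combined(model2, frame))

    def test_nn_linear_weights_favor_discriminating_column(self):
        model = fit_combiner(self._meta(), self.y, "nn_linear")
        w = pd.Series(model.weights, index=model.columns)
        assert w.sum() == pytest.approx(1.0)
        assert (w >= 0).all()
        assert w["good"] == w.max()

    def test_nn_linear_dot_product(self):
        model = CombinerModel(kind="nn_linear", columns=["a", "b", "c"],
                              weights=np.array([0.5, 0.5, 0.0]))
        frame = pd.DataFrame([[0.2, 0.6, 0.9]], columns=["a", "b", "c"])
        assert predict_combined(model, frame)[0] == pytest.approx(0.4)

    def test_nn_linear_monotone_in_each_base(self):
        model = fit_combiner(self._meta(), self.y, "nn_linear")
        base = pd.DataFrame([[0.3, 0.3, 0.3]], columns=model.columns)
        p0 = predict_combined(model, base)[0]
        for c in model.columns:
            bumped = base.copy()
            bumped[c] += 0.2
            assert predict_combined(model, bumped)[0] >= p0 - 1e-12

    def test_nn_linear_degenerate_uniform_fallback(self):
        # anti-discriminating columns: LDA direction entirely negative
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        rng = np.random.default_rng(1)
        cols = {
            "anti1": np.clip((1 - y) * 0.8 + rng.normal(0, 0.05, 8), 0, 1),
            "anti2": np.clip((1 - y) * 0.7 + rng.normal(0, 0.05, 8), 0, 1),
        }
        meta = meta_from(cols, y)
        with pytest.warns(UserWarning):
            model = fit_combiner(meta, y, "nn_linear")
        assert np.allclose(model.weights, 0.5)

    def test_rf_stacker_predicts_probabilities(self):
        meta = self._meta()
        model = fit_combiner(meta, self.y, "rf_stacker", ModelSpec(n_trees=30, seed=0))
        p = predict_combined(model, meta.values)
        assert ((p >= 0) & (p <= 1)).all()

    def test_missing_column_rejected(self):
        model = fit_combiner(self._meta(), self.y, "mean_all")
        with pytest.raises(ValueError):
            predict_combined(model, self._meta().values[["good", "noise1"]])

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            fit_combiner(self._meta(), self.y, "median")


class TestCompareModels:
    def test_identical_vectors(self):
        t, p = compare_models([0.7, 0.8, 0.75], [0.7, 0.8, 0.75])
        assert t == 0.0 and p == 1.0

    def test_constant_nonzero_difference_degenerate(self):
        with pytest.warns(UserWarning):
            t, p = compare_models([0.71, 0.81], [0.70, 0.80])
        assert p == 1.0

    def test_consistent_improvement_detected(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            b = 0.7 + rng.normal(0, 0.02, 20)
            a = b + rng.normal(0.03, 0.01, 20)
            t, p = compare_models(a, b)
            if p < 0.01 and t > 0:
                hits += 1
        assert hits >= 9


class TestNestedEvaluate:
    def test_single_base_combiners_degenerate_to_identity(self, tiny_aligned, fast_model):
        blocks, chem, y = tiny_aligned
        rep = nested_evaluate(
            {blocks[0].block_id: blocks[0].data}, chem.data, y,
            kinds=("best_single", "mean_all", "mean_top5", "nn_linear"),
            external_k=3, external_repeats=2, internal_k=3, internal_repeats=1,
            expr_filter=FilterSpec(method="info1d", top_n=20),
            chem_filter=FilterSpec(method="welch", top_n=10),
            model_spec=fast_model, seed=0,
        )
        for kind in ("mean_all", "mean_top5", "nn_linear"):
            assert np.allclose(rep.oof["best_single"], rep.oof[kind])

    def test_report_shapes_and_determinism(self, tiny_aligned, fast_model):
        blocks, chem, y = tiny_aligned
        kwargs = dict(
            kinds=("mean_top5", "rf_stacker"),
            external_k=3, external_repeats=2, internal_k=3, internal_repeats=1,
            expr_filter=FilterSpec(method="info1d", top_n=15),
            chem_filter=FilterSpec(method="welch", top_n=10),
            model_spec=fast_model, seed=4,
        )
        expr = {ds.block_id: ds.data for ds in blocks}
        a = nested_evaluate(expr, chem.data, y, **kwargs)
        b = nested_evaluate(expr, chem.data, y, **kwargs)
        assert a.external_auc["mean_top5"].shape == (2,)
        assert a.base_external_auc.shape == (2, 2)
        assert np.array_equal(a.external_auc["mean_top5"], b.external_auc["mean_top5"])
        assert np.array_equal(a.oof["rf_stacker"], b.oof["rf_stacker"])
        summary = a.summary()
        assert set(summary["combiner"]) == {"mean_top5", "rf_stacker"}

    def test_signal_bundle_external_auc_above_chance(self, tiny_aligned, fast_model):
        blocks, chem, y = tiny_aligned
        rep = nested_evaluate(
            {ds.block_id: ds.data for ds in blocks}, chem.data, y,
            kinds=("mean_top5",), external_k=4, external_repeats=2,
            internal_k=3, internal_repeats=1,
            expr_filter=FilterSpec(method="info1d", top_n=20),
            chem_filter=FilterSpec(method="welch", top_n=10),
            model_spec=ModelSpec(n_trees=60, seed=0), seed=1,
        )
        assert np.nanmean(rep.external_auc["mean_top5"]) > 0.65
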