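"""Super Learner late integration.

Base models (one per cell line, each early-integrated with molecular
descriptors) are first cross-validated *internally* on the training data;
their out-of-fold probabilities form a meta-feature matrix on which a
second-order combiner is fitted.  Five combiners are supported:

* ``best_single`` — the base model with the highest mean internal AUC;
* ``mean_all`` — unweighted mean of all base probabilities;
* ``mean_top5`` — unweighted mean of the five best bases by internal AUC;
* ``nn_linear`` — a linear combination along the pooled-covariance linear
  discriminant direction with weights clipped to be non-negative and
  normalized to sum to one;
* ``rf_stacker`` — a Random Forest on the meta-features.

Performance of the whole procedure is estimated by *nested* cross-validation:
the complete pipeline (feature selection, internal CV, combiner fitting) is
re-run on every external training set and scored on the held-out external
validation folds.  The internal (training-set) AUC of each combiner is also
recorded as the deliberately biased reference; the gap between the two is a
direct read-out of combiner overfitting.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cv import BlockSpec, FoldPlan, _assemble, _derive_seed, _select_columns, make_folds
from .filters import FilterSpec
from .metrics import auc
from .models import ModelSpec, fit_rf, predict_proba

log = logging.getLogger(__name__)

__all__ = [
    "MetaFeatureMatrix",
    "CombinerModel",
    "EvaluationReport",
    "COMBINER_KINDS",
    "build_meta",
    "rank_bases",
    "fit_combiner",
    "predict_combined",
    "nested_evaluate",
    "compare_models",
]

COMBINER_KINDS = ("best_single", "mean_all", "mean_top5", "nn_linear", "rf_stacker")


@dataclass
class MetaFeatureMatrix:
    """Internal-CV out-of-fold probabilities, compounds x base models.

    ``values`` holds probabilities averaged over internal repeats;
    ``auc_table`` records each base's AUC per internal repeat (the quantity
    base-model ranking averages).
    """

    values: pd.DataFrame
    auc_table: pd.DataFrame  # index: repeat, columns: base ids
    internal_k: int = 10
    internal_repeats: int = 5

    @property
    def base_ids(self) -> list[str]:
        return list(self.values.columns)


def build_meta(
    bases: dict[str, list[BlockSpec]],
    y,
    internal_plan: FoldPlan,
    model_spec: ModelSpec,
) -> MetaFeatureMatrix:
    """Run the internal CV for every base model and collect the out-of-fold
    probability columns (averaged over internal repeats)."""
    from .cv import cross_validated_oof

    if len(bases) < 1:
        raise ValueError("need at least one base model")
    yy = np.asarray(y).astype(int)
    cols = {}
    aucs = {}
    for base_id, blocks in bases.items():
        res = cross_validated_oof(blocks, yy, internal_plan, model_spec)
        cols[base_id] = res.oof
        aucs[base_id] = res.per_repeat_auc
    index = bases[next(iter(bases))][0].X.index
    values = pd.DataFrame(cols, index=index)
    auc_table = pd.DataFrame(aucs)
    return MetaFeatureMatrix(
        values=values,
        auc_table=auc_table,
        internal_k=internal_plan.k,
        internal_repeats=internal_plan.n_repeats,
    )


def rank_bases(meta: MetaFeatureMatrix, y=None) -> pd.DataFrame:
    """Base models ordered by decreasing mean internal AUC, ties broken by
    base id for determinism."""
    mean_auc = meta.auc_table.mean(axis=0)
    frame = pd.DataFrame({"base_id": mean_auc.index, "mean_internal_auc": mean_auc.to_numpy()})
    order = np.lexsort((frame["base_id"].to_numpy(), -frame["mean_internal_auc"].to_numpy()))
    return frame.iloc[order].reset_index(drop=True)


@dataclass
class CombinerModel:
    """A fitted second-order model over base-model probabilities."""

    kind: str
    columns: list[str]
    selected: list[str] = field(default_factory=list)  # best_single / mean_top5
    weights: np.ndarray | None = None  # nn_linear
    forest: object | None = None  # rf_stacker
    ranking: pd.DataFrame | None = None


def fit_combiner(
    meta: MetaFeatureMatrix, y, kind: str, model_spec: ModelSpec | None = None
) -> CombinerModel:
    """Fit one of the five combiners on a meta-feature matrix."""
    if kind not in COMBINER_KINDS:
        raise ValueError(f"unknown combiner kind {kind!r}")
    yy = np.asarray(y).astype(int)
    M = meta.values.to_numpy(dtype=float)
    cols = meta.base_ids
    ranking = rank_bases(meta)
    model = CombinerModel(kind=kind, columns=cols, ranking=ranking)

    if kind == "best_single":
        model.selected = [ranking["base_id"].iloc[0]]
    elif kind == "mean_all":
        pass
    elif kind == "mean_top5":
        model.selected = list(ranking["base_id"].head(min(5, len(cols))))
    elif kind == "nn_linear":
        model.weights = _nn_lda_weights(M, yy)
    elif kind == "rf_stacker":
        spec = model_spec or ModelSpec()
        model.forest = fit_rf(M, yy, spec)
    return model


def _nn_lda_weights(M: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Linear-discriminant direction with pooled covariance, a small ridge
    against singularity, negative components clipped to zero, and the
    remainder normalized to sum to one.  An all-nonpositive direction falls
    back to uniform weights with a warning."""
    pos = M[y == 1]
    neg = M[y == 0]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("nn_linear needs at least two members per class")
    b = M.shape[1]
    diff = pos.mean(axis=0) - neg.mean(axis=0)
    sp = (
        (len(pos) - 1) * np.cov(pos, rowvar=False, ddof=1).reshape(b, b)
        + (len(neg) - 1) * np.cov(neg, rowvar=False, ddof=1).reshape(b, b)
    ) / (len(pos) + len(neg) - 2)
    ridge = 1e-6 * np.trace(sp) / b
    w = np.linalg.solve(sp + ridge * np.eye(b), diff)
    w = np.clip(w, 0.0, None)
    total = w.sum()
    if total <= 0:
        warnings.warn("LDA direction has no positive component; using uniform weights", stacklevel=2)
        return np.full(b, 1.0 / b)
    return w / total


def predict_combined(model: CombinerModel, base_probs) -> np.ndarray:
    """Apply a fitted combiner to base-model probabilities for new units."""
    if isinstance(base_probs, pd.DataFrame):
        missing = [c for c in model.columns if c not in base_probs.columns]
        if missing:
            raise ValueError(f"missing base-model columns {missing}")
        frame = base_probs[model.columns]
    else:
        arr = np.asarray(base_probs, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != len(model.columns):
            raise ValueError("base probability matrix does not match training columns")
        frame = pd.DataFrame(arr, columns=model.columns)

    if model.kind == "best_single":
        return frame[model.selected[0]].to_numpy(dtype=float)
    if model.kind == "mean_all":
        return frame.to_numpy(dtype=float).mean(axis=1)
    if model.kind == "mean_top5":
        return frame[model.selected].to_numpy(dtype=float).mean(axis=1)
    if model.kind == "nn_linear":
        return frame.to_numpy(dtype=float) @ model.weights
    if model.kind == "rf_stacker":
        return predict_proba(model.forest, frame.to_numpy(dtype=float))
    raise ValueError(f"unknown combiner kind {model.kind!r}")


@dataclass
class EvaluationReport:
    """Nested-CV evaluation of the super-learner combiners.

    ``external_auc[kind]`` is the per-external-repeat AUC of pooled nested
    predictions; ``internal_auc[kind]`` the per-repeat training-set (biased)
    AUC; ``base_external_auc`` the per-repeat external AUC of each base
    model fitted on the external training folds.
    """

    external_auc: dict[str, np.ndarray]
    internal_auc: dict[str, np.ndarray]
    base_external_auc: pd.DataFrame  # index: repeat, columns: base ids
    oof: dict[str, np.ndarray] = field(default_factory=dict)  # mean nested predictions per kind
    compound_ids: list = field(default_factory=list)
    external_k: int = 10
    external_repeats: int = 20

    def summary(self) -> pd.DataFrame:
        rows = []
        for kind in self.external_auc:
            ext = self.external_auc[kind]
            internal = self.internal_auc[kind]
            rows.append(
                {
                    "combiner": kind,
                    "internal_auc": float(np.nanmean(internal)),
                    "external_auc": float(np.nanmean(ext)),
                    "external_sd": float(np.nanstd(ext, ddof=1)) if len(ext) > 1 else np.nan,
                }
            )
        return pd.DataFrame(rows)

    def to_json(self, path=None) -> str:
        payload = {
            "external_k": self.external_k,
            "external_repeats": self.external_repeats,
            "combiners": {
                kind: {
                    "internal_auc_per_repeat": list(map(float, self.internal_auc[kind])),
                    "external_auc_per_repeat": list(map(float, self.external_auc[kind])),
                    "internal_auc_mean": float(np.nanmean(self.internal_auc[kind])),
                    "external_auc_mean": float(np.nanmean(self.external_auc[kind])),
                }
                for kind in self.external_auc
            },
            "base_external_auc_mean": {
                c: float(np.nanmean(self.base_external_auc[c]))
                for c in self.base_external_auc.columns
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            from pathlib import Path

            Path(path).write_text(text)
        return text


def nested_evaluate(
    expr_blocks: dict[str, pd.DataFrame],
    chem: pd.DataFrame,
    y: pd.Series,
    kinds=COMBINER_KINDS,
    external_k: int = 10,
    external_repeats: int = 20,
    internal_k: int = 10,
    internal_repeats: int = 5,
    expr_filter: FilterSpec | None = None,
    chem_filter: FilterSpec | None = None,
    model_spec: ModelSpec | None = None,
    seed: int = 0,
) -> EvaluationReport:
    """Nested cross-validated evaluation of the full super-learner protocol.

    For every external fold the complete pipeline — in-fold feature
    selection, internal CV of every base model, combiner fitting — runs on
    the external-training compounds only, then predicts the held-out
    compounds.  Base models are one per expression block, early-integrated
    with the descriptor block (information-gain filter for expression,
    Welch for descriptors).
    """
    expr_filter = expr_filter or FilterSpec(method="info1d", top_n=100)
    chem_filter = chem_filter or FilterSpec(method="welch", top_n=100)
    model_spec = model_spec or ModelSpec()
    for kind in kinds:
        if kind not in COMBINER_KINDS:
            raise ValueError(f"unknown combiner kind {kind!r}")

    yy = np.asarray(y).astype(int)
    n = len(yy)
    units = np.asarray(y.index if isinstance(y, pd.Series) else np.arange(n))
    base_ids = list(expr_blocks)
    chem_frame = chem.data if hasattr(chem, "data") else chem
    frames = {
        b: (X.data if hasattr(X, "data") else X) for b, X in expr_blocks.items()
    }
    for b, X in frames.items():
        if len(X) != n:
            raise ValueError(f"block {b!r} not aligned with labels")

    external_auc = {k: np.full(external_repeats, np.nan) for k in kinds}
    internal_auc = {k: np.full(external_repeats, np.nan) for k in kinds}
    base_ext = np.full((external_repeats, len(base_ids)), np.nan)
    oof_sum = {k: np.zeros(n) for k in kinds}

    for r in range(external_repeats):
        ext_plan = make_folds(
            units, yy, external_k, stratified=True, seed=_derive_seed(seed, r, 11), repeats=1
        )
        assignment = ext_plan.folds[0]
        preds = {k: np.full(n, np.nan) for k in kinds}
        base_preds = np.full((n, len(base_ids)), np.nan)
        fold_internal = {k: [] for k in kinds}

        for f in range(external_k):
            va_idx = np.flatnonzero(assignment == f)
            tr_idx = np.flatnonzero(assignment != f)
            y_tr = yy[tr_idx]
            fold_seed = _derive_seed(seed, r, f, 13)

            bases_tr = {
                b: [
                    BlockSpec(name=b, X=frames[b].iloc[tr_idx], filter=expr_filter),
                    BlockSpec(name="chem", X=chem_frame.iloc[tr_idx], filter=chem_filter),
                ]
                for b in base_ids
            }
            internal_plan = make_folds(
                units[tr_idx],
                y_tr,
                internal_k,
                stratified=True,
                seed=fold_seed,
                repeats=internal_repeats,
            )
            meta = build_meta(bases_tr, y_tr, internal_plan, model_spec)

            combiners = {k: fit_combiner(meta, y_tr, k, model_spec) for k in kinds}
            for k in kinds:
                fold_internal[k].append(auc(predict_combined(combiners[k], meta.values), y_tr))

            # base models refitted on the full external-training set
            va_probs = {}
            for bi, b in enumerate(base_ids):
                blocks = [
                    BlockSpec(name=b, X=frames[b], filter=expr_filter),
                    BlockSpec(name="chem", X=chem_frame, filter=chem_filter),
                ]
                chosen = _select_columns(blocks, tr_idx, y_tr, _derive_seed(fold_seed, bi, 3))
                rf = fit_rf(
                    _assemble(chosen, tr_idx),
                    y_tr,
                    model_spec,
                    seed_offset=_derive_seed(fold_seed, bi, 5),
                )
                p_va = predict_proba(rf, _assemble(chosen, va_idx))
                va_probs[b] = p_va
                base_preds[va_idx, bi] = p_va
            va_frame = pd.DataFrame(va_probs, index=units[va_idx])
            for k in kinds:
                preds[k][va_idx] = predict_combined(combiners[k], va_frame)

        for k in kinds:
            external_auc[k][r] = auc(preds[k], yy)
            internal_auc[k][r] = float(np.mean(fold_internal[k]))
            oof_sum[k] += preds[k]
        for bi in range(len(base_ids)):
            base_ext[r, bi] = auc(base_preds[:, bi], yy)

    return EvaluationReport(
        external_auc=external_auc,
        internal_auc=internal_auc,
        base_external_auc=pd.DataFrame(base_ext, columns=base_ids),
        oof={k: oof_sum[k] / external_repeats for k in kinds},
        compound_ids=list(units),
        external_k=external_k,
        external_repeats=external_repeats,
    )


def compare_models(auc_a, auc_b) -> tuple[float, float]:
    """Paired two-sided t-test between per-repeat AUC vectors.

    Zero variance of the differences is degenerate: identical vectors give
    (0.0, 1.0); a constant nonzero difference is reported with p = 1.0 and
    a warning, since the t statistic is undefined.
    """
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length vectors with >= 2 entries")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff, 0.0):
            return 0.0, 1.0
        warnings.warn("paired differences have zero variance; p-value undefined, reporting 1.0", stacklevel=2)
        return float(np.sign(diff.mean()) * np.inf), 1.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)
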