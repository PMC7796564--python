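"""Random-Forest base models over filtered feature blocks.

A base model is a Random Forest trained on one block's top-N features
(expression-only or descriptors-only) or on the early-integrated union of
the top-100 expression features and the top-100 molecular descriptors.  All
forests predict the probability of the positive (DILI-concern) class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .cv import BlockSpec, FoldPlan, OOFResult, cross_validated_oof
from .filters import FeatureRanking, FilterSpec

log = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "fit_rf",
    "predict_proba",
    "early_integrate",
    "restrict_features",
    "run_single_block",
    "mtry_sweep",
    "INTEGRATION_MODES",
]

INTEGRATION_MODES = ("expression_only", "expression_plus_chem", "chem_only")


@dataclass(frozen=True)
class ModelSpec:
    """Random-Forest settings.  ``mtry`` is the number of features tried per
    split; the string ``"default"`` means floor(sqrt(p)), the usual RF
    default for classification."""

    n_trees: int = 500
    mtry: int | str = "default"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if isinstance(self.mtry, int) and self.mtry < 1:
            raise ValueError("mtry must be >= 1")


def fit_rf(X, y, spec: ModelSpec, seed_offset: int = 0) -> RandomForestClassifier:
    """Fit a Random Forest predicting the positive class; reproducible from
    ``spec.seed`` (plus an optional fold-derived offset)."""
    X = np.asarray(X, dtype=float)
    yy = np.asarray(y).astype(int)
    if len(np.unique(yy)) < 2:
        raise ValueError("cannot fit a classifier on a single class")
    if spec.mtry == "default":
        max_features = "sqrt"
    else:
        max_features = min(int(spec.mtry), X.shape[1])
    clf = RandomForestClassifier(
        n_estimators=spec.n_trees,
        max_features=max_features,
        random_state=(int(spec.seed) + int(seed_offset)) % (2**31),
        n_jobs=1,
    )
    clf.fit(X, yy)
    return clf


def predict_proba(model: RandomForestClassifier, X) -> np.ndarray:
    """Probability of the positive (label 1) class for each row."""
    X = np.asarray(X, dtype=float)
    proba = model.predict_proba(X)
    classes = list(model.classes_)
    if 1 not in classes:
        return np.zeros(len(X))
    return proba[:, classes.index(1)]


def early_integrate(
    expr_top: FeatureRanking,
    chem_top: FeatureRanking,
    X_expr: pd.DataFrame,
    X_chem: pd.DataFrame,
    expr_prefix: str = "expr",
    chem_prefix: str = "chem",
) -> pd.DataFrame:
    """Column-concatenate the selected expression and descriptor features
    into one matrix with block-prefixed feature ids (duplicate names across
    blocks stay distinct)."""
    if not X_expr.index.equals(X_chem.index):
        raise ValueError("expression and descriptor blocks are not row-aligned")
    expr_ids = [f for f in expr_top.feature_ids if f in set(X_expr.columns)]
    chem_ids = [f for f in chem_top.feature_ids if f in set(X_chem.columns)]
    if len(expr_ids) < len(expr_top.feature_ids) or len(chem_ids) < len(chem_top.feature_ids):
        raise ValueError("ranking refers to features absent from its block")
    if len(expr_ids) < expr_top.n_selected:
        log.info("expression ranking shorter than requested: using all %d", len(expr_ids))
    left = X_expr[expr_ids].rename(columns={c: f"{expr_prefix}:{c}" for c in expr_ids})
    right = X_chem[chem_ids].rename(columns={c: f"{chem_prefix}:{c}" for c in chem_ids})
    return pd.concat([left, right], axis=1)


def restrict_features(dataset, feature_ids) -> "pd.DataFrame":
    """Restrict an expression block to a designated feature universe (e.g. a
    list of directly measured landmark genes), before any filtering.

    ``feature_ids`` is any iterable of ids; features absent from the block
    are ignored, but an empty intersection is an error.
    """
    frame = dataset.data if hasattr(dataset, "data") else dataset
    wanted = [c for c in frame.columns if c in set(feature_ids)]
    if not wanted:
        raise ValueError("feature universe does not intersect the block")
    if len(wanted) < len(set(feature_ids)):
        log.info("feature universe: %d of %d ids present in block", len(wanted), len(set(feature_ids)))
    return frame[wanted]


def block_specs_for_mode(
    dataset,
    chem,
    mode: str,
    expr_filter: FilterSpec,
    chem_filter: FilterSpec,
) -> list[BlockSpec]:
    """Assemble the in-fold filtered blocks for an integration mode.

    Filter routing follows the protocol: information-gain filtering for
    expression, Welch t for descriptors.
    """
    if mode not in INTEGRATION_MODES:
        raise ValueError(f"unknown integration mode {mode!r}")
    expr_frame = dataset.data if hasattr(dataset, "data") else dataset
    chem_frame = chem.data if hasattr(chem, "data") else chem
    blocks = []
    if mode in ("expression_only", "expression_plus_chem"):
        name = getattr(dataset, "block_id", "expr")
        blocks.append(BlockSpec(name=name, X=expr_frame, filter=expr_filter))
    if mode in ("chem_only", "expression_plus_chem"):
        blocks.append(BlockSpec(name="chem", X=chem_frame, filter=chem_filter))
    return blocks


def run_single_block(
    dataset,
    chem,
    y,
    plan: FoldPlan,
    mode: str = "expression_plus_chem",
    expr_filter: FilterSpec | None = None,
    chem_filter: FilterSpec | None = None,
    model_spec: ModelSpec | None = None,
) -> tuple[OOFResult, pd.DataFrame]:
    """Cross-validate one base model (a single block or its early
    integration with descriptors) and report per-repeat AUC and MCC.

    Returns the OOF result and a per-repeat metrics frame.
    """
    from .metrics import auc, mcc

    expr_filter = expr_filter or FilterSpec(method="info1d", top_n=100)
    chem_filter = chem_filter or FilterSpec(method="welch", top_n=100)
    model_spec = model_spec or ModelSpec()
    blocks = block_specs_for_mode(dataset, chem, mode, expr_filter, chem_filter)
    result = cross_validated_oof(blocks, y, plan, model_spec)
    yy = np.asarray(y).astype(int)
    records = []
    for r in range(plan.n_repeats):
        probs = result.per_repeat_oof[r]
        records.append(
            {
                "repeat": r,
                "auc": auc(probs, yy),
                "mcc": mcc((probs >= 0.5).astype(int), yy),
            }
        )
    return result, pd.DataFrame(records)


def mtry_sweep(
    blocks: list[BlockSpec],
    y,
    plan: FoldPlan,
    mtry_values=range(2, 21),
    n_trees: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validated AUC as a function of the RF ``mtry`` parameter.

    Model quality is expected to be flat in ``mtry`` except at very small
    values; this utility exists to verify that on a given dataset, after
    which the default floor(sqrt(p)) is used.
    """
    rows = []
    for m in mtry_values:
        spec = ModelSpec(n_trees=n_trees, mtry=int(m), seed=seed)
        res = cross_validated_oof(blocks, y, plan, spec)
        rows.append({"mtry": int(m), "auc": res.mean_auc})
    return pd.DataFrame(rows)
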