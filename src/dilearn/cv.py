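"""Cross-validation engine with leakage control.

Fold plans support stratification (per-fold class counts within one unit of
proportionality), grouping (all observations of one compound stay in one
fold — the "clustered" CV that removes replicate leakage), repetition with
per-repeat seeds derived from one master seed, and nesting (internal plans
built strictly from external-training units).

All feature selection happens inside the fold loop: a fold's model is
filtered and fitted on its training rows only, so out-of-fold predictions
are leakage-free by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .filters import FilterSpec, rank_features, top_n
from .metrics import auc

log = logging.getLogger(__name__)

__all__ = [
    "FoldPlan",
    "BlockSpec",
    "OOFResult",
    "make_folds",
    "cross_validated_oof",
    "fold_predictions",
    "replicate_leakage_experiment",
]

_SEED_MOD = 2**31


def _derive_seed(master: int, *indices: int) -> int:
    s = int(master) % _SEED_MOD
    for i in indices:
        s = (s * 100003 + int(i) + 1) % _SEED_MOD
    return s


@dataclass
class FoldPlan:
    """Repeated k-fold assignment of units.

    ``folds[r, i]`` is the fold (0..k-1) of unit i in repeat r.  Grouped
    plans guarantee all units of one group share a fold; stratified plans
    deal each class round-robin so per-fold class counts differ by at most
    one.
    """

    unit_ids: np.ndarray
    folds: np.ndarray  # (n_repeats, n_units) int
    k: int
    stratified: bool = False
    grouped: bool = False
    seed: int = 0

    @property
    def n_repeats(self) -> int:
        return self.folds.shape[0]

    def __post_init__(self) -> None:
        if self.folds.ndim != 2 or self.folds.shape[1] != len(self.unit_ids):
            raise ValueError("fold matrix shape does not match units")
        for r in range(self.folds.shape[0]):
            present = np.unique(self.folds[r])
            if present.min() < 0 or present.max() >= self.k:
                raise ValueError("fold indices out of range")

    def to_frame(self) -> pd.DataFrame:
        records = [
            {"unit_id": u, "repeat": r, "fold": int(self.folds[r, i])}
            for r in range(self.n_repeats)
            for i, u in enumerate(self.unit_ids)
        ]
        return pd.DataFrame(records)


def make_folds(
    units,
    labels,
    k: int,
    stratified: bool = False,
    grouped: bool = False,
    seed: int = 0,
    repeats: int = 1,
    groups=None,
) -> FoldPlan:
    """Build a repeated k-fold plan.

    ``units`` are the rows being predicted; ``groups`` (defaults to the
    units themselves) defines the clusters a grouped plan keeps together.
    Stratification uses the binary ``labels``; for grouped plans the label
    of a group must be constant across its units.  A class with fewer than
    ``k`` members triggers a fallback to plain shuffling with a warning.
    """
    unit_ids = np.asarray(units)
    y = np.asarray(labels)
    n = len(unit_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError("fewer units than folds")
    if groups is None:
        groups = unit_ids
    groups = np.asarray(groups)

    entities, entity_of_unit = np.unique(groups, return_inverse=True)
    if grouped and len(entities) < k:
        raise ValueError("fewer groups than folds in a grouped plan")
    if not grouped and len(entities) != n:
        # ungrouped plans treat every row as its own entity
        entities = np.arange(n)
        entity_of_unit = np.arange(n)

    # entity-level label for stratification
    entity_label = np.empty(len(entities), dtype=y.dtype)
    for e in range(len(entities)):
        member_labels = y[entity_of_unit == e]
        entity_label[e] = member_labels[0]
        if stratified and not (member_labels == member_labels[0]).all():
            raise ValueError("grouped stratification needs a constant label per group")

    use_strat = stratified
    if stratified:
        _, counts = np.unique(entity_label, return_counts=True)
        if counts.min() < k:
            log.warning(
                "a class has fewer than k=%d members; falling back to plain shuffling", k
            )
            use_strat = False

    all_folds = np.empty((repeats, n), dtype=int)
    for r in range(repeats):
        rng = np.random.default_rng(_derive_seed(seed, r))
        entity_fold = np.empty(len(entities), dtype=int)
        if use_strat:
            cursor = rng.integers(k)  # rotate the dealing start between classes
            for cls in np.unique(entity_label):
                members = np.flatnonzero(entity_label == cls)
                rng.shuffle(members)
                for j, e in enumerate(members):
                    entity_fold[e] = (cursor + j) % k
                cursor = (cursor + len(members)) % k
        else:
            order = rng.permutation(len(entities))
            entity_fold[order] = np.arange(len(entities)) % k
        all_folds[r] = entity_fold[entity_of_unit]
    return FoldPlan(
        unit_ids=unit_ids,
        folds=all_folds,
        k=k,
        stratified=use_strat,
        grouped=grouped,
        seed=seed,
    )


@dataclass
class BlockSpec:
    """One feature block entering a model: a row-aligned matrix and the
    filter applied to it inside every training fold (``filter=None`` uses
    all columns unfiltered, e.g. for prevalidated meta-features or a fixed
    transferred feature set)."""

    name: str
    X: pd.DataFrame
    filter: FilterSpec | None = None


@dataclass
class OOFResult:
    """Out-of-fold probabilities (mean over repeats plus the per-repeat
    matrix) and the per-repeat pooled AUC."""

    oof: np.ndarray
    per_repeat_oof: np.ndarray  # (n_repeats, n)
    per_repeat_auc: np.ndarray
    selected_features: list[list[str]] = field(default_factory=list)

    @property
    def mean_auc(self) -> float:
        vals = self.per_repeat_auc[~np.isnan(self.per_repeat_auc)]
        return float(vals.mean()) if len(vals) else float("nan")


def _select_columns(blocks: list[BlockSpec], tr_idx: np.ndarray, y_tr: np.ndarray, seed: int):
    """In-fold feature selection: rank each block on training rows only and
    keep its top-N columns, block-prefixed to stay unambiguous."""
    from dataclasses import replace as _replace

    chosen: list[tuple[BlockSpec, list[str]]] = []
    for b, block in enumerate(blocks):
        if block.filter is None:
            chosen.append((block, list(block.X.columns)))
            continue
        spec = _replace(block.filter, seed=_derive_seed(seed, b))
        ranking = rank_features(block.X.iloc[tr_idx], y_tr, spec)
        cols = list(top_n(ranking, spec.top_n).table["feature_id"])
        chosen.append((block, cols))
    return chosen


def _assemble(chosen, idx: np.ndarray) -> np.ndarray:
    parts = [block.X[cols].iloc[idx].to_numpy(dtype=float) for block, cols in chosen]
    return np.concatenate(parts, axis=1) if len(parts) > 1 else parts[0]


def fold_predictions(
    blocks: list[BlockSpec],
    y,
    assignment: np.ndarray,
    k: int,
    model_spec,
    seed: int = 0,
) -> np.ndarray:
    """Out-of-fold probability vector for one fold assignment.

    Each fold's filter and forest see training rows only; a degenerate
    single-class training fold predicts its constant class probability.
    """
    from .models import fit_rf, predict_proba

    yy = np.asarray(y).astype(int)
    n = len(yy)
    oof = np.full(n, np.nan)
    for f in range(k):
        va_idx = np.flatnonzero(assignment == f)
        tr_idx = np.flatnonzero(assignment != f)
        if len(va_idx) == 0:
            continue
        y_tr = yy[tr_idx]
        if len(np.unique(y_tr)) < 2:
            oof[va_idx] = float(y_tr[0])
            continue
        chosen = _select_columns(blocks, tr_idx, y_tr, _derive_seed(seed, f, 1))
        model = fit_rf(_assemble(chosen, tr_idx), y_tr, model_spec, seed_offset=_derive_seed(seed, f, 2))
        oof[va_idx] = predict_proba(model, _assemble(chosen, va_idx))
    return oof


def cross_validated_oof(
    blocks: list[BlockSpec],
    y,
    plan: FoldPlan,
    model_spec,
) -> OOFResult:
    """Repeated cross-validated out-of-fold probabilities with strictly
    in-fold feature selection; per-repeat AUC is computed on the pooled OOF
    vector of that repeat and the reported OOF vector is the mean over
    repeats."""
    yy = np.asarray(y).astype(int)
    n = len(yy)
    for block in blocks:
        if len(block.X) != n:
            raise ValueError(f"block {block.name!r} is not row-aligned with the labels")
    R = plan.n_repeats
    per_repeat = np.empty((R, n))
    aucs = np.full(R, np.nan)
    for r in range(R):
        per_repeat[r] = fold_predictions(
            blocks, yy, plan.folds[r], plan.k, model_spec, seed=_derive_seed(plan.seed, r, 7)
        )
        if len(np.unique(yy)) == 2:
            aucs[r] = auc(per_repeat[r], yy)
    return OOFResult(oof=per_repeat.mean(axis=0), per_repeat_oof=per_repeat, per_repeat_auc=aucs)


def replicate_leakage_experiment(
    bundle,
    k: int = 10,
    seed: int = 0,
    repeats: int = 1,
    block: str | None = None,
    filter_spec: FilterSpec | None = None,
    model_spec=None,
    scheme: int = 5,
) -> tuple[float, float]:
    """Quantify replicate leakage on a null bundle with correlated replicates.

    The same observation-level data (all dose/time rows) is cross-validated
    twice: once with every row treated as an independent unit (simple CV)
    and once grouped by compound (clustered CV).  With null labels the
    clustered AUC sits at chance while the simple AUC is inflated by the
    within-compound correlation — the selection step and the forest latch
    onto compound-level noise shared between training and validation
    replicates.

    Returns ``(simple_cv_auc, clustered_cv_auc)`` on pooled OOF predictions
    averaged over repeats.
    """
    from .io import aggregate_labels
    from .models import ModelSpec

    filter_spec = filter_spec or FilterSpec(method="info1d", top_n=100)
    model_spec = model_spec or ModelSpec()

    name = block or next(iter(bundle.expression))
    obs = bundle.expression[name]
    frame = obs.frame
    binary = aggregate_labels(bundle.labels, scheme=scheme)
    keep = frame["compound_id"].isin(binary.labels.index).to_numpy()
    frame = frame.loc[keep].reset_index(drop=True)
    y = binary.labels.loc[frame["compound_id"]].to_numpy()
    X = frame[obs.feature_ids]
    compounds = frame["compound_id"].to_numpy()
    units = np.arange(len(frame))

    spec = [BlockSpec(name=name, X=X, filter=filter_spec)]
    simple_plan = make_folds(units, y, k, stratified=True, grouped=False, seed=seed, repeats=repeats)
    grouped_plan = make_folds(
        units, y, k, stratified=True, grouped=True, seed=seed + 1, repeats=repeats, groups=compounds
    )
    simple = cross_validated_oof(spec, y, simple_plan, model_spec)
    clustered = cross_validated_oof(spec, y, grouped_plan, model_spec)
    return simple.mean_auc, clustered.mean_auc
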