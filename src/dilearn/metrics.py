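"""Evaluation utilities: AUC, MCC, AUC intervals, risk-class enrichment,
and cross-block signal transferability.

AUC is computed in the Mann-Whitney formulation (fraction of
positive-negative pairs ranked correctly, ties counted half), which is
exactly the area under the empirical ROC curve.  MCC uses the closed-form
expression on the 2x2 confusion table with the convention that any zero
factor under the square root yields 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "auc",
    "mcc",
    "auc_interval",
    "roc_points",
    "enrichment",
    "EnrichmentTable",
    "transferability",
    "TransferabilityResult",
]

DILI_CLASS_NAMES = {1: "most", 2: "less", 3: "ambiguous", 4: "no"}


def auc(scores, labels) -> float:
    """Area under the ROC curve for binary ``labels`` (1 positive, 0 negative).

    Mann-Whitney estimator: mean over all positive-negative pairs of
    ``1[s+ > s-] + 0.5 * 1[s+ == s-]``, computed via midranks in O(n log n).

    Raises
    ------
    ValueError
        If only one class is present (the AUC is undefined).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-d arrays")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(s)  # midranks handle ties -> the 0.5 pair credit
    pos_rank_sum = ranks[y == 1].sum()
    return float((pos_rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def mcc(predicted, truth) -> float:
    """Matthews correlation coefficient of binary predictions.

    ``MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))``; if any
    factor in the denominator is zero the coefficient is defined as 0.
    """
    p = np.asarray(predicted).astype(int)
    t = np.asarray(truth).astype(int)
    if p.shape != t.shape:
        raise ValueError("predicted and truth must have the same shape")
    tp = float(np.sum((p == 1) & (t == 1)))
    tn = float(np.sum((p == 0) & (t == 0)))
    fp = float(np.sum((p == 1) & (t == 0)))
    fn = float(np.sum((p == 0) & (t == 1)))
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom2 == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom2)


def auc_interval(point: float, sd: float) -> tuple[float, float]:
    """Expected AUC range on new data as ``point +- 2*sd``, clipped to [0, 1]."""
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    return (max(0.0, point - 2.0 * sd), min(1.0, point + 2.0 * sd))


def roc_points(scores, labels) -> pd.DataFrame:
    """ROC curve points as a (fpr, tpr, threshold) frame, for CSV export."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(np.asarray(labels).astype(int), np.asarray(scores, float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


@dataclass
class EnrichmentTable:
    """Per-DILI-class prevalence in predicted low- vs high-risk halves.

    ``enrichment`` for class c is prevalence_low(c) / prevalence_high(c);
    classes absent from the high-risk half carry ``infinite=True`` and a NaN
    ratio rather than a number.
    """

    table: pd.DataFrame  # index: class name; columns prevalence_low, prevalence_high, enrichment, infinite
    n_low: int = 0
    n_high: int = 0

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="dili_class")


def enrichment(probabilities: pd.Series, dili_classes: pd.Series) -> EnrichmentTable:
    """Split compounds into equally numerous low-/high-risk halves by predicted
    DILI probability and compute the enrichment of each DILI class in the
    low-risk half relative to the high-risk half.

    Compounds are sorted by increasing probability, ties broken by compound
    id so the split is stable; the low-risk half takes ``n // 2`` compounds
    (the extra compound of an odd n goes to high-risk).
    """
    if len(probabilities) < 2:
        raise ValueError("need at least two compounds")
    probs = probabilities.sort_index()
    classes = dili_classes.reindex(probs.index)
    if classes.isna().any():
        raise ValueError("every scored compound needs a four-class DILI label")
    order = np.lexsort((probs.index.to_numpy(), probs.to_numpy()))
    n = len(probs)
    n_low = n // 2
    low_ids = probs.index.to_numpy()[order[:n_low]]
    high_ids = probs.index.to_numpy()[order[n_low:]]
    rows = {}
    for code, name in DILI_CLASS_NAMES.items():
        prev_low = float((classes.loc[low_ids] == code).mean())
        prev_high = float((classes.loc[high_ids] == code).mean())
        if prev_high == 0.0:
            ratio, infinite = (np.nan, prev_low > 0)
            if prev_low == 0:
                ratio, infinite = (np.nan, False)
        else:
            ratio, infinite = (prev_low / prev_high, False)
        rows[name] = {
            "prevalence_low": prev_low,
            "prevalence_high": prev_high,
            "enrichment": ratio,
            "infinite": infinite,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    return EnrichmentTable(table=table, n_low=n_low, n_high=n - n_low)


@dataclass
class TransferabilityResult:
    """Outcome of building a model on one cell line with features chosen
    on another, plus ranking-overlap counts between the two lines."""

    source_block: str
    target_block: str
    auc: float
    overlap: dict[int, int] = field(default_factory=dict)  # N -> |top-N(source) & top-200(target)|

    def to_frame(self) -> pd.DataFrame:
        row = {"source": self.source_block, "target": self.target_block, "auc": self.auc}
        row.update({f"overlap_top{n}": c for n, c in sorted(self.overlap.items())})
        return pd.DataFrame([row])


def transferability(
    source,
    target,
    y: pd.Series,
    plan,
    n_select: int = 100,
    filter_spec=None,
    model_spec=None,
    overlap_ns: tuple[int, ...] = (10, 20, 50, 100, 200),
    overlap_pool: int = 200,
) -> TransferabilityResult:
    """Select features on the source block, cross-validate an RF on the
    target block restricted to those fixed features, and count how many of
    the source's top-N features sit in the target's own top-``overlap_pool``.

    Feature rankings for the overlap counts use the full data of each block
    (no cross-validation: the question is similarity of the rankings, not
    generalization).  The transfer AUC uses pooled out-of-fold predictions
    on the target under ``plan``; the feature set is fixed, so no in-fold
    selection takes place.
    """
    from .cv import BlockSpec, cross_validated_oof
    from .filters import FilterSpec, rank_features, top_n
    from .models import ModelSpec

    filter_spec = filter_spec or FilterSpec(method="info1d")
    model_spec = model_spec or ModelSpec()

    src_X, src_id = _block_frame(source)
    tgt_X, tgt_id = _block_frame(target)
    shared = [f for f in src_X.columns if f in set(tgt_X.columns)]
    if not shared:
        raise ValueError("source and target blocks share no feature identifiers")

    src_rank = rank_features(src_X[shared], y, filter_spec)
    tgt_rank = rank_features(tgt_X[shared], y, filter_spec)
    selected = list(top_n(src_rank, n_select).table["feature_id"])
    tgt_pool = set(top_n(tgt_rank, overlap_pool).table["feature_id"])
    overlap = {
        n: len(set(top_n(src_rank, n).table["feature_id"]) & tgt_pool) for n in overlap_ns
    }

    block = BlockSpec(name=tgt_id, X=tgt_X[selected], filter=None)
    res = cross_validated_oof([block], y, plan, model_spec)
    return TransferabilityResult(
        source_block=src_id, target_block=tgt_id, auc=auc(res.oof, y), overlap=overlap
    )


def _block_frame(block) -> tuple[pd.DataFrame, str]:
    """Accept a CompoundDataset or a bare DataFrame."""
    if hasattr(block, "data") and hasattr(block, "block_id"):
        return block.data, block.block_id
    if isinstance(block, pd.DataFrame):
        return block, "block"
    raise TypeError(f"cannot interpret {type(block)!r} as a feature block")
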