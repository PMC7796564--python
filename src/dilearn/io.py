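"""Reading/writing of observation tables, descriptor matrices and DILI label
tables, plus the two dataset-shaping steps every analysis starts with:
representative-sample selection (one row per compound) and the 4-class ->
binary label aggregation schemes.

File formats
------------
* ObservationTable: CSV/TSV with header ``compound_id, dose, time_h`` followed
  by feature columns; one row per (compound, dose, time) exposure.
* CompoundDataset / DescriptorMatrix: CSV with ``compound_id`` first column.
* LabelTable: two-column CSV ``compound_id, dili_class`` with classes coded
  1 (most), 2 (less), 3 (ambiguous), 4 (no DILI concern).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "ObservationTable",
    "CompoundDataset",
    "BinaryLabels",
    "read_observation_table",
    "write_observation_table",
    "read_compound_dataset",
    "read_label_table",
    "write_label_table",
    "select_representative",
    "aggregate_labels",
    "align_blocks",
    "AGGREGATION_SCHEMES",
]

#: Incubation-time preference: 24 h when available, then 6 h, then 48 h.
TIME_PREFERENCE = (24, 6, 48)

#: Binary aggregation schemes over the four FDA DILI-concern classes.
#: Each entry: (positive classes, negative classes); everything else excluded.
AGGREGATION_SCHEMES: dict[int, tuple[frozenset[int], frozenset[int]]] = {
    1: (frozenset({1}), frozenset({2, 3, 4})),
    2: (frozenset({1, 2}), frozenset({3, 4})),
    3: (frozenset({1, 2}), frozenset({4})),
    4: (frozenset({1, 2}), frozenset({4})),
    5: (frozenset({1, 2, 3}), frozenset({4})),
}

META_COLUMNS = ("compound_id", "dose", "time_h")


@dataclass
class ObservationTable:
    """Raw per-exposure expression records for one cell line.

    ``frame`` holds one row per (compound_id, dose, time_h) with feature
    columns after the three metadata columns.
    """

    frame: pd.DataFrame
    block_id: str = "block"

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"observation table missing columns {missing}")
        if self.frame["compound_id"].isna().any():
            raise ValueError("observation table has missing compound_id values")
        keys = self.frame[list(META_COLUMNS)]
        if keys.duplicated().any():
            raise ValueError("(compound, dose, time) keys must be unique")

    @property
    def feature_ids(self) -> list[str]:
        return [c for c in self.frame.columns if c not in META_COLUMNS]

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class CompoundDataset:
    """One row per compound for a single block; index is compound_id."""

    data: pd.DataFrame
    block_id: str = "block"

    @property
    def compound_ids(self) -> list:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def X(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="compound_id")

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class BinaryLabels:
    """Scheme-dependent binary partition of the four DILI classes.

    ``labels`` maps each non-excluded compound to 1 (DILI-concern) or 0
    (no-concern); ``excluded`` lists compounds dropped by the scheme.
    """

    labels: pd.Series
    excluded: pd.Index = field(default_factory=lambda: pd.Index([]))
    scheme: int = 5

    @property
    def n_positive(self) -> int:
        return int((self.labels == 1).sum())

    @property
    def n_negative(self) -> int:
        return int((self.labels == 0).sum())


def read_observation_table(path, block_id: str | None = None) -> ObservationTable:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    frame = pd.read_csv(path, sep=sep)
    if block_id is None:
        block_id = _stem(path)
    return ObservationTable(frame=frame, block_id=block_id)


def write_observation_table(obs: ObservationTable, path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    obs.frame.to_csv(path, sep=sep, index=False)


def read_compound_dataset(path, block_id: str | None = None) -> CompoundDataset:
    frame = pd.read_csv(path).set_index("compound_id")
    return CompoundDataset(data=frame, block_id=block_id or _stem(path))


def read_label_table(path) -> pd.Series:
    frame = pd.read_csv(path)
    if not {"compound_id", "dili_class"} <= set(frame.columns):
        raise ValueError("label table needs columns compound_id, dili_class")
    labels = frame.set_index("compound_id")["dili_class"].astype(int)
    bad = set(labels.unique()) - {1, 2, 3, 4}
    if bad:
        raise ValueError(f"unknown DILI class codes {sorted(bad)}")
    return labels


def write_label_table(labels: pd.Series, path) -> None:
    labels.rename("dili_class").to_csv(path, index_label="compound_id")


def select_representative(obs: ObservationTable) -> CompoundDataset:
    """Reduce an observation table to one row per compound.

    The incubation time is chosen by the fixed preference order 24 h > 6 h >
    48 h (the most intensive biological response is expected at the highest
    dose, and 24 h is the most common measurement); at the chosen time the
    highest available dose wins.  Rows containing missing feature values are
    deprioritized; a residual tie keeps the first row in file order with a
    warning.
    """
    if len(obs) == 0:
        raise ValueError("empty observation table")
    frame = obs.frame
    dose_numeric = pd.to_numeric(frame["dose"], errors="coerce")
    if dose_numeric.isna().any():
        log.warning(
            "block %s: non-numeric doses compared lexically", obs.block_id
        )
        dose_key = frame["dose"].astype(str)
    else:
        dose_key = dose_numeric

    time_rank = frame["time_h"].map({t: i for i, t in enumerate(TIME_PREFERENCE)})
    if time_rank.isna().any():
        bad = sorted(frame.loc[time_rank.isna(), "time_h"].unique())
        raise ValueError(f"unknown incubation times {bad}; expected {TIME_PREFERENCE}")
    feature_cols = obs.feature_ids
    has_missing = frame[feature_cols].isna().any(axis=1).astype(int)

    work = pd.DataFrame(
        {
            "compound_id": frame["compound_id"],
            "_time_rank": time_rank,
            "_dose": dose_key,
            "_missing": has_missing,
            "_order": np.arange(len(frame)),
        }
    )
    # best row: complete first, preferred time, then highest dose, then file order
    work = work.sort_values(
        ["_missing", "_time_rank", "_dose", "_order"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    ties = work.duplicated(subset=["compound_id", "_missing", "_time_rank", "_dose"], keep=False)
    if ties.any():
        dup = work.loc[ties & ~work.duplicated(subset=["compound_id"]), "compound_id"]
        for cid in dup.unique():
            log.warning("compound %s: tie at same (time, dose); keeping first row", cid)
    best = work.drop_duplicates(subset="compound_id", keep="first")

    rows = frame.loc[best["_order"].to_numpy()]
    data = rows.set_index("compound_id")[feature_cols]
    all_missing = data.columns[data.isna().all(axis=0)]
    if len(all_missing):
        log.warning(
            "block %s: dropping %d fully-missing features", obs.block_id, len(all_missing)
        )
        data = data.drop(columns=list(all_missing))
    return CompoundDataset(data=data.sort_index(), block_id=obs.block_id)


def aggregate_labels(labels: pd.Series, scheme: int) -> BinaryLabels:
    """Collapse four DILI-concern classes to a binary label under one of the
    five aggregation schemes; compounds in classes the scheme omits are
    excluded from downstream matrices."""
    if scheme not in AGGREGATION_SCHEMES:
        raise ValueError(f"unknown aggregation scheme {scheme!r}; expected 1..5")
    labels = labels.astype(int)
    bad = set(labels.unique()) - {1, 2, 3, 4}
    if bad:
        raise ValueError(f"unknown DILI class codes {sorted(bad)}")
    positive, negative = AGGREGATION_SCHEMES[scheme]
    binary = pd.Series(
        np.where(labels.isin(positive), 1, np.where(labels.isin(negative), 0, -1)),
        index=labels.index,
    )
    excluded = binary.index[binary == -1]
    return BinaryLabels(labels=binary[binary >= 0], excluded=excluded, scheme=scheme)


def align_blocks(
    datasets: list[CompoundDataset], labels: BinaryLabels
) -> tuple[list[CompoundDataset], pd.Series]:
    """Restrict every block to the common compounds carrying a non-excluded
    binary label, in one shared row order.

    Returns the aligned blocks and the matching label series.
    """
    if not datasets:
        raise ValueError("need at least one block")
    common = set(labels.labels.index)
    for ds in datasets:
        common &= set(ds.compound_ids)
    if not common:
        raise ValueError("no compound is shared by all blocks and the labels")
    order = sorted(common)
    aligned = [
        CompoundDataset(data=ds.data.loc[order], block_id=ds.block_id) for ds in datasets
    ]
    return aligned, labels.labels.loc[order]


def _stem(path) -> str:
    from pathlib import Path

    return Path(path).stem
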