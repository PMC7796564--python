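"""Synthetic multi-block data with the statistical structure the DILI
protocol assumes.

The generator emulates a study design in which a panel of cell lines (13 by
default) is exposed to a few hundred drug compounds at several doses and
incubation times, expression is recorded per exposure, every compound has a
precomputed molecular-descriptor vector, and each compound carries one of
four DILI-concern classes (most / less / ambiguous / no) with roughly a
3.3:1 concern : no-concern imbalance.

Model
-----
All features are unit-variance Gaussian noise.  For a compound ``c`` in a
binary DILI-concern super-class (classes 1-3 vs 4), each informative feature
receives a mean shift of ``d`` standard deviations.  Replicate exposures
(dose x time combinations) of one compound share a compound-level latent
vector: ``x_rep = sqrt(rho) * z_c + sqrt(1 - rho) * eps``, so any two
replicate rows of a compound correlate at ``rho`` while total variance stays
1 and the standardized class shift stays ``d``.  Dose and time have no
systematic effect of their own: they exist to exercise representative-sample
selection and the clustered-CV leakage mechanism.

A minority of expression blocks carries signal (5 of 13 by default, echoing
the handful of informative cell lines in this kind of panel), with one
"strong" block given a slightly larger shift; the descriptor block is
moderately informative.  Informative feature indices are shared across
informative expression blocks, so cross-block signal transferability is
nonzero by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CompoundDataset, ObservationTable, write_label_table, write_observation_table

__all__ = ["SyntheticConfig", "SyntheticBundle", "generate", "generate_null_with_replicates", "write_bundle"]

#: Default block names, informative panel first (the "strong" MCF7-like block leads).
CELL_LINE_NAMES = (
    "MCF7", "VCAP", "A549", "HA1E", "HCC515",
    "SKB", "A375", "ASC", "HPEG2", "HT29", "NPC", "PC3", "PHH",
)

#: Four-class DILI frequencies: most, less, ambiguous, no concern.
DEFAULT_CLASS_PROBS = (39 / 233, 90 / 233, 50 / 233, 54 / 233)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters for one synthetic bundle.

    ``effect_size`` is the standardized mean shift d of an informative
    expression feature between the binary DILI super-classes;
    ``within_compound_rho`` is the correlation between replicate rows of one
    compound.  Defaults are desk-scale: 1000 expression features per block
    and 300 descriptors stand in for the full 12328 / 1660.
    """

    n_compounds: int = 233
    class_probs: tuple[float, float, float, float] = DEFAULT_CLASS_PROBS
    n_blocks: int = 13
    p_expr: int = 1000
    p_chem: int = 300
    informative_blocks: tuple[int, ...] = (0, 1, 2, 3, 4)
    n_informative_per_block: int = 50
    effect_size: float = 0.3
    strong_block: int | None = 0
    strong_multiplier: float = 1.6
    chem_informative: int = 50
    chem_effect: float = 0.5
    replicate_doses: tuple[float, ...] = (1.0, 10.0)
    replicate_times: tuple[int, ...] = (6, 24, 48)
    within_compound_rho: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds <= 0 or self.p_expr <= 0 or self.p_chem <= 0 or self.n_blocks <= 0:
            raise ValueError("dimensions must be positive")
        probs = np.asarray(self.class_probs, dtype=float)
        if probs.shape != (4,) or (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("class_probs must be 4 nonnegative values summing to 1")
        if not set(self.informative_blocks) <= set(range(self.n_blocks)):
            raise ValueError("informative_blocks must index existing blocks")
        if self.n_informative_per_block > self.p_expr:
            raise ValueError("n_informative_per_block exceeds p_expr")
        if self.chem_informative > self.p_chem:
            raise ValueError("chem_informative exceeds p_chem")
        if not (0.0 <= self.within_compound_rho < 1.0):
            raise ValueError("within_compound_rho must lie in [0, 1)")
        if not set(self.replicate_times) <= {6, 24, 48}:
            raise ValueError("replicate_times must be a subset of {6, 24, 48}")

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_doses) * len(self.replicate_times)

    def block_names(self) -> list[str]:
        names = list(CELL_LINE_NAMES[: self.n_blocks])
        names += [f"cell{i:02d}" for i in range(len(names), self.n_blocks)]
        return names


@dataclass
class SyntheticBundle:
    """Everything one study provides: per-block observation tables, a
    descriptor matrix, the four-class label table, and which features truly
    carry signal per block."""

    expression: dict[str, ObservationTable]
    descriptors: CompoundDataset
    labels: pd.Series  # compound_id -> dili_class 1..4
    ground_truth: dict[str, set[str]]
    config: SyntheticConfig

    @property
    def compound_ids(self) -> list[str]:
        return list(self.labels.index)


def _block_effect(config: SyntheticConfig, block_index: int) -> float:
    if block_index not in config.informative_blocks:
        return 0.0
    d = config.effect_size
    if config.strong_block is not None and block_index == config.strong_block:
        d *= config.strong_multiplier
    return d


def generate(config: SyntheticConfig) -> SyntheticBundle:
    """Draw one bundle: labels from ``class_probs``, expression blocks with
    replicate structure and class shifts, and a compound-level descriptor
    block.  Reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    compounds = [f"cpd{i:04d}" for i in range(config.n_compounds)]
    dili = rng.choice([1, 2, 3, 4], size=config.n_compounds, p=config.class_probs)
    labels = pd.Series(dili, index=pd.Index(compounds, name="compound_id"), name="dili_class")
    positive = (dili != 4).astype(float)  # binary super-class: any concern vs none

    expr_ids = [f"g{i:04d}" for i in range(config.p_expr)]
    informative_idx = np.sort(
        rng.choice(config.p_expr, size=config.n_informative_per_block, replace=False)
    )
    informative_ids = {expr_ids[i] for i in informative_idx}

    rho = config.within_compound_rho
    names = config.block_names()
    expression: dict[str, ObservationTable] = {}
    ground_truth: dict[str, set[str]] = {}
    n_rep = config.n_replicates
    for b, name in enumerate(names):
        d = _block_effect(config, b)
        shift = np.zeros(config.p_expr)
        shift[informative_idx] = d
        mean = positive[:, None] * shift[None, :]  # compounds x features
        z = rng.standard_normal((config.n_compounds, config.p_expr))
        rows = []
        meta = []
        for dose in config.replicate_doses:
            for t in config.replicate_times:
                eps = rng.standard_normal((config.n_compounds, config.p_expr))
                x = mean + np.sqrt(rho) * z + np.sqrt(1.0 - rho) * eps
                rows.append(x)
                meta.append((dose, t))
        frame = pd.DataFrame(
            np.concatenate(rows, axis=0), columns=expr_ids
        )
        frame.insert(0, "time_h", np.repeat([t for _, t in meta], config.n_compounds))
        frame.insert(0, "dose", np.repeat([d_ for d_, _ in meta], config.n_compounds))
        frame.insert(0, "compound_id", np.tile(compounds, n_rep))
        expression[name] = ObservationTable(frame=frame, block_id=name)
        ground_truth[name] = set(informative_ids) if d > 0 else set()

    chem_ids = [f"d{i:04d}" for i in range(config.p_chem)]
    chem_idx = np.sort(rng.choice(config.p_chem, size=config.chem_informative, replace=False))
    chem_shift = np.zeros(config.p_chem)
    chem_shift[chem_idx] = config.chem_effect
    chem = rng.standard_normal((config.n_compounds, config.p_chem)) + positive[:, None] * chem_shift
    descriptors = CompoundDataset(
        data=pd.DataFrame(chem, index=labels.index.copy(), columns=chem_ids),
        block_id="chem",
    )
    ground_truth["chem"] = (
        {chem_ids[i] for i in chem_idx} if config.chem_effect != 0 else set()
    )

    return SyntheticBundle(
        expression=expression,
        descriptors=descriptors,
        labels=labels,
        ground_truth=ground_truth,
        config=config,
    )


def generate_null_with_replicates(config: SyntheticConfig) -> SyntheticBundle:
    """A bundle with all effect sizes forced to zero but the replicate
    correlation intact: labels carry no information about features, yet
    replicate rows of one compound are strongly correlated.  This is the
    construction that makes pooled (non-grouped) cross-validation report
    optimistic scores.

    Requires ``within_compound_rho > 0`` and at least two replicates.
    """
    if config.n_replicates < 2:
        raise ValueError("need at least 2 replicates per compound")
    if config.within_compound_rho <= 0.0:
        raise ValueError("within_compound_rho must be positive for the null-replicate design")
    null_cfg = replace(config, effect_size=0.0, chem_effect=0.0)
    return generate(null_cfg)


def write_bundle(bundle: SyntheticBundle, outdir) -> None:
    """Write one bundle as the CSV formats the readers accept, plus a
    metadata JSON recording the configuration (seed included) and the
    ground-truth informative features."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, obs in bundle.expression.items():
        write_observation_table(obs, outdir / f"expression_{name}.csv")
    bundle.descriptors.to_csv(outdir / "descriptors.csv")
    write_label_table(bundle.labels, outdir / "labels.csv")
    meta = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(bundle.config).items()
        },
        "ground_truth": {k: sorted(v) for k, v in bundle.ground_truth.items()},
    }
    (outdir / "metadata.json").write_text(json.dumps(meta, indent=2))
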