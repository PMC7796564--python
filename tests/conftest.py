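import numpy as np
import pandas as pd
import pytest

import dilearn as dl
from dilearn.models import ModelSpec


@pytest.fixture(scope="session")
def tiny_bundle():
    """Small signal-bearing bundle shared by slow-ish integration tests."""
    cfg = dl.SyntheticConfig(
        n_compounds=80,
        n_blocks=2,
        p_expr=60,
        p_chem=20,
        informative_blocks=(0,),
        n_informative_per_block=10,
        effect_size=1.0,
        chem_informative=5,
        chem_effect=1.0,
        seed=7,
    )
    return dl.generate(cfg)


@pytest.fixture(scope="session")
def tiny_aligned(tiny_bundle):
    blocks = [dl.select_representative(o) for o in tiny_bundle.expression.values()]
    binary = dl.aggregate_labels(tiny_bundle.labels, 5)
    aligned, y = dl.align_blocks(blocks + [tiny_bundle.descriptors], binary)
    return aligned[:-1], aligned[-1], y


@pytest.fixture
def fast_model():
    return ModelSpec(n_trees=30, seed=0)


def observation_frame(records, feature_values):
    """Build an observation frame from (compound, dose, time) records and a
    matching list of feature vectors."""
    rows = []
    for (cid, dose, time_h), feats in zip(records, feature_values):
        row = {"compound_id": cid, "dose": dose, "time_h": time_h}
        row.update({f"g{i}": v for i, v in enumerate(feats)})
        rows.append(row)
    return pd.DataFrame(rows)
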