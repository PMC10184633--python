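import numpy as np
import pandas as pd
import pytest

from inflamstate import (
    Condition,
    Layer,
    OmicsMatrix,
    Scale,
    SimConfig,
    TrueClass,
    default_truth_plan,
    generate_dataset,
)


@pytest.fixture(scope="session")
def small_dataset():
    """Three-layer synthetic dataset, 10 features per class, fixed seed."""
    cfg = SimConfig(n_features_per_class={c.value: 10 for c in TrueClass}, seed=7)
    plan = []
    for layer in (Layer.PHOSPHO, Layer.TRANSCRIPT, Layer.PROTEIN):
        plan.extend(default_truth_plan(cfg, layer))
    matrices, truth = generate_dataset(cfg, plan)
    return cfg, matrices, truth


@pytest.fixture
def tiny_matrix():
    """2 features x (2 conditions x 2 times x 3 replicates), hand-set values."""
    cols = [
        f"{cond}_T{t}h_R{r}"
        for cond in ("CTRL", "TNF")
        for t in (0, 24)
        for r in (1, 2, 3)
    ]
    data = pd.DataFrame(
        [np.arange(12.0), np.arange(12.0) * 2.0],
        index=["GENEA", "GENEB"],
        columns=cols,
    )
    return OmicsMatrix(layer=Layer.TRANSCRIPT, scale=Scale.VST, data=data)
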