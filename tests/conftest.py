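import numpy as np
import pandas as pd
import pytest

from chillsem import PathModel, SimulationConfig, simulate_dataset
from chillsem.expression import ExpressionMatrix, default_design

FIG9_BLOCKS = [("ABA", 10), ("ICE1", 3), ("CBF", 3), ("bZIP", 3), ("AO", 10)]
FIG9_EDGES = [("ABA", "ICE1"), ("ABA", "CBF"), ("ABA", "bZIP"),
              ("ICE1", "AO"), ("CBF", "AO"), ("bZIP", "AO"), ("ABA", "AO")]


def matrix_from_columns(columns: dict[str, np.ndarray], kind: str = "log") -> ExpressionMatrix:
    """Build a genes × samples ExpressionMatrix from per-gene value arrays."""
    n = len(next(iter(columns.values())))
    sample_ids = [f"s{i + 1}" for i in range(n)]
    values = pd.DataFrame(columns, index=sample_ids).T
    return ExpressionMatrix(values, default_design(sample_ids), kind=kind)


@pytest.fixture(scope="session")
def fig9_dataset():
    """Synthetic mediation dataset: 1 hormone, 3 TF mediators, 1 AO latent,
    7 edges, n=500, loadings 0.9."""
    cfg = SimulationConfig(
        block_spec=FIG9_BLOCKS,
        structural_edges=[("ABA", "ICE1", 0.5), ("ABA", "CBF", 0.4),
                          ("ABA", "bZIP", -0.3), ("ICE1", "AO", 0.3),
                          ("CBF", "AO", 0.25), ("bZIP", "AO", -0.2),
                          ("ABA", "AO", 0.2)],
        loadings=0.9, n_samples=500, seed=7)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def fig9_model(fig9_dataset):
    ann = fig9_dataset.annotation
    blocks = {b: [g for g, bl in zip(ann["gene"], ann["block"]) if bl == b]
              for b, _ in FIG9_BLOCKS}
    return PathModel(blocks, FIG9_EDGES)
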