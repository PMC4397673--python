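"""Shared fixtures: tiny hand-built inputs used across module tests."""

import numpy as np
import pandas as pd
import pytest

from tfnetminer.io_formats import ExpressionMatrix
from tfnetminer.network_build import IntegratedNetwork, NodeData


def make_expression(rows: dict, samples: list[str], groups: dict) -> ExpressionMatrix:
    """Build a small expression matrix from {gene: [values]}."""
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=samples, dtype=float)
    frame.index.name = "gene"
    return ExpressionMatrix(values=frame, groups=groups)


@pytest.fixture
def two_group_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples, two samples per condition, log2 scale."""
    return make_expression(
        {
            "Up1": [1.0, 1.1, 4.0, 4.1],  # ~8-fold up
            "Flat": [5.0, 5.1, 5.0, 5.1],
            "Dn1": [6.0, 6.1, 3.0, 3.1],  # ~8-fold down
        },
        samples=["a1", "a2", "b1", "b2"],
        groups={"a1": "ctl", "a2": "ctl", "b1": "trt", "b2": "trt"},
    )


@pytest.fixture
def star_network() -> IntegratedNetwork:
    """K1,4 star in the PPI layer, all nodes colored up."""
    net = IntegratedNetwork()
    for name in ["Hub", "La", "Lb", "Lc", "Ld"]:
        net.add_node(name, NodeData(color="up"))
    for leaf in ["La", "Lb", "Lc", "Ld"]:
        net.add_ppi_edge("Hub", leaf)
    return net


def random_module_zs(rng: np.random.Generator, k: int) -> np.ndarray:
    """Positive-leaning member z-values for score-identity style checks."""
    return rng.normal(1.5, 1.0, size=k)
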