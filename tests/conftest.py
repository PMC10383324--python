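import numpy as np
import pandas as pd
import pytest

from egopath import (
    AbundanceMatrix,
    ContrastVector,
    InteractionNetwork,
    SimulationScenario,
    compute_contrast,
    generate_abundances,
    generate_network,
)


def make_contrast(logfc: dict, case="UCCAO", control="SHAM") -> ContrastVector:
    """Contrast vector straight from a {protein: logfc} dict (NaN = missing)."""
    s = pd.Series(logfc, dtype=float)
    return ContrastVector(logfc=s, case_group=case, control_group=control,
                          n_used=pd.Series(10, index=s.index))


@pytest.fixture
def tiny_matrix() -> AbundanceMatrix:
    """3 proteins x 6 samples, 2 groups, hand-checkable means."""
    values = pd.DataFrame(
        {
            "S1": [10.0, 8.0, 5.0],
            "S2": [10.0, 12.0, 5.0],
            "S3": [10.0, 10.0, 5.0],
            "C1": [20.0, 30.0, 5.0],
            "C2": [20.0, 10.0, 5.0],
            "C3": [20.0, 20.0, np.nan],
        },
        index=["PA", "PB", "PC"],
    )
    groups = {"S1": "SHAM", "S2": "SHAM", "S3": "SHAM",
              "C1": "UCCAO", "C2": "UCCAO", "C3": "UCCAO"}
    return AbundanceMatrix(values=values, sample_to_group=groups,
                           control_group="SHAM")


@pytest.fixture
def path_graph() -> InteractionNetwork:
    return InteractionNetwork.from_edges([("A", "B"), ("B", "C")])


@pytest.fixture
def star_graph() -> InteractionNetwork:
    return InteractionNetwork.from_edges(
        [("HUB", f"L{i}") for i in range(5)], nodes=["ISO"])


@pytest.fixture(scope="session")
def null_scenario() -> SimulationScenario:
    """Study-design defaults, no planted effects."""
    return SimulationScenario(seed=11)


@pytest.fixture(scope="session")
def null_contrasts(null_scenario):
    net = generate_network(null_scenario)
    mat = generate_abundances(net, null_scenario)
    return net, mat, [compute_contrast(mat, g)
                      for g in ("UCCAO", "UCCAO_MF")]
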