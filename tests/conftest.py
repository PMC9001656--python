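import numpy as np
import pytest

from sludgenet import (CountMatrix, Metaweb, Phylogeny, ScenarioSpec,
                       simulate_dataset)
from sludgenet.io import SampleMetadata
import pandas as pd


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """3 ASVs x 4 samples (2 timepoints x 2 replicates)."""
    return CountMatrix(
        asv_ids=["a", "b", "c"],
        sample_ids=["s1", "s2", "s3", "s4"],
        counts=np.array([[5, 0, 2, 1], [0, 3, 0, 0], [1, 1, 1, 1]]),
        sample_map={"s1": (1, 1), "s2": (1, 2), "s3": (2, 1), "s4": (2, 2)},
    )


@pytest.fixture
def tiny_metadata() -> SampleMetadata:
    df = pd.DataFrame({
        "timepoint": [1, 1, 2, 2],
        "temperature": [20.0, 20.0, 30.0, 30.0],
        "bod_in": [300.0] * 4, "bod_out": [30.0] * 4,
        "tn_in": [60.0] * 4, "tn_out": [20.0] * 4,
        "tp_in": [9.0] * 4, "tp_out": [3.0] * 4,
    }, index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"))
    return SampleMetadata(df)


@pytest.fixture
def toy_tree(tmp_path) -> Phylogeny:
    from sludgenet import read_tree

    p = tmp_path / "toy.nwk"
    p.write_text("((A:1,B:1):1,C:2);\n")
    return read_tree(p)


def metaweb_from_edges(co=(), ex=()):
    """Build a Metaweb directly from explicit edge lists (test helper)."""
    nodes = sorted({n for e in list(co) + list(ex) for n in e})
    return Metaweb(
        nodes=nodes,
        cooccurrence={tuple(sorted(e)): 1.0 for e in co},
        coexclusion={tuple(sorted(e)): 1.0 for e in ex},
    )


@pytest.fixture(scope="session")
def seasonal_run():
    """One seasonal synthetic dataset shared across tests (seed 11)."""
    return simulate_dataset(ScenarioSpec.seasonal(), seed=11)


@pytest.fixture(scope="session")
def succession_run():
    """One succession synthetic dataset shared across tests (seed 11)."""
    return simulate_dataset(ScenarioSpec.succession(), seed=11)
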