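import numpy as np
import pandas as pd
import pytest

from solodiff import CountMatrix, GeneAnnotation, RunConfig


@pytest.fixture
def two_by_two() -> CountMatrix:
    return CountMatrix(
        pd.DataFrame(
            {"lib1": [10, 20], "lib2": [30, 40]},
            index=pd.Index(["g1", "g2"], name="gene_id"),
        )
    )


@pytest.fixture
def four_library_counts() -> CountMatrix:
    """Small deterministic four-condition matrix with an ACTB anchor."""
    rng = np.random.default_rng(123)
    genes = ["ACTB"] + [f"g{i}" for i in range(1, 30)]
    libs = ["SR_IL2minus", "SR_IL2plus", "SEN_IL2minus", "SEN_IL2plus"]
    data = rng.poisson(200.0, size=(30, 4))
    data[0] = [400, 420, 390, 410]  # anchor well expressed everywhere
    return CountMatrix(pd.DataFrame(data, index=pd.Index(genes, name="gene_id"), columns=libs))


@pytest.fixture
def annotation(four_library_counts) -> GeneAnnotation:
    rng = np.random.default_rng(7)
    lengths = rng.integers(500, 5000, size=len(four_library_counts.gene_ids))
    return GeneAnnotation(pd.Series(lengths, index=four_library_counts.gene_ids))


@pytest.fixture
def config() -> RunConfig:
    return RunConfig(seed=1)
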