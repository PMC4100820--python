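import numpy as np
import pandas as pd
import pytest

import bloodmirna as bm


@pytest.fixture(scope="session")
def study():
    """Default-scale synthetic study (5 donors x 5 lineages, 623 probes)."""
    cfg = bm.default_config(seed=1)
    matrix, truth = bm.generate_count_dataset(cfg)
    proc = bm.normalize_pipeline(matrix)
    return {"config": cfg, "matrix": matrix, "truth": truth, "proc": proc}


@pytest.fixture()
def small_matrix():
    """Tiny annotated matrix for container-level tests (noise-free)."""
    cfg = bm.SimulationConfig(
        n_donors=2,
        cell_types=("A", "B"),
        n_endogenous=8,
        n_negative=3,
        donor_sd=0.0,
        residual_sd=0.0,
        neg_sd=0.0,
        seed=3,
    )
    matrix, truth = bm.generate_count_dataset(cfg)
    return matrix, truth


def make_processed(values: pd.DataFrame, cell_types: dict[str, str]):
    """Wrap a plain values frame as a ProcessedMatrix for downstream stages."""
    samples = pd.DataFrame(
        {
            "donor": ["D1"] * len(values.columns),
            "cell_type": [cell_types[s] for s in values.columns],
        },
        index=values.columns,
    )
    return bm.ProcessedMatrix(
        values=values,
        negatives=values.iloc[:0],
        factors=pd.Series(1.0, index=values.columns),
        samples=samples,
    )
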