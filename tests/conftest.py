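import numpy as np
import pandas as pd
import pytest

from regenseq import CountMatrix, SimulationConfig, simulate_counts


@pytest.fixture(scope="session")
def toy_counts() -> CountMatrix:
    """4 genes x 4 samples, two groups, hand-checkable."""
    counts = pd.DataFrame(
        {
            "s1": [10, 0, 30, 5],
            "s2": [12, 1, 28, 6],
            "s3": [40, 2, 31, 4],
            "s4": [44, 0, 29, 5],
        },
        index=pd.Index(["g1", "g2", "g3", "g4"], name="gene_id"),
    )
    groups = pd.Series(
        ["injured", "injured", "control", "control"],
        index=["s1", "s2", "s3", "s4"],
    )
    return CountMatrix(counts=counts, groups=groups)


@pytest.fixture(scope="session")
def small_sim():
    """A 1,500-gene simulated contrast with planted DE, shared across tests."""
    cfg = SimulationConfig(n_genes=1500, seed=42)
    injured, control, truth = simulate_counts(cfg)
    return CountMatrix.concat(injured, control), truth, cfg


def brute_force_bh(pvalues: np.ndarray) -> np.ndarray:
    """Independent step-up BH for oracle comparisons."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, p[idx] * m / rank_from_top)
        adjusted[idx] = running_min
    return np.minimum(adjusted, 1.0)
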