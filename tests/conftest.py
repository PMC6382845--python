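import numpy as np
import pandas as pd
import pytest

from hscp.data import CountMatrix
from hscp.synthetic_data import SyntheticConfig, generate_truth, simulate_counts


def small_config(**overrides) -> SyntheticConfig:
    """A compact synthetic study used across tests."""
    defaults = dict(n_genes=400, seed=11)
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def small_truth():
    cfg = small_config()
    return cfg, generate_truth(cfg)


@pytest.fixture(scope="session")
def small_counts(small_truth):
    cfg, truth = small_truth
    return simulate_counts(truth, cfg)


def nb_count_matrix(
    rng: np.random.Generator,
    n_genes: int,
    reps: int,
    phi: float,
    baseline: np.ndarray | None = None,
    groups: int = 1,
) -> CountMatrix:
    """Plain NB counts (no planted structure) as a CountMatrix."""
    if baseline is None:
        baseline = 2.0 ** rng.normal(5, 2, n_genes)
    cols = {}
    sheet = []
    for g in range(groups):
        for r in range(reps):
            if phi > 0:
                lam = rng.gamma(1.0 / phi, phi * baseline)
            else:
                lam = baseline
            sid = f"t{g}_r{r}"
            cols[sid] = rng.poisson(lam)
            sheet.append({"sample_id": sid, "model": "M", "time": g, "replicate": r})
    counts = pd.DataFrame(cols, index=[f"g{i:05d}" for i in range(n_genes)])
    samples = pd.DataFrame(sheet).set_index("sample_id")
    return CountMatrix(
        counts=counts, samples=samples, lengths=pd.Series(1000.0, index=counts.index)
    )
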