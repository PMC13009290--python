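import numpy as np
import pandas as pd
import pytest

from growvar import SimConfig, compute_grm, simulate_genotypes
from growvar.records import WeightRecordSet


@pytest.fixture(scope="session")
def small_sim_config():
    """Desk-scale two-pond configuration used by several suites."""
    return SimConfig(n_fish_per_pond=(60, 60), n_sires=8, n_dams=20, n_snps=400, seed=11)


@pytest.fixture(scope="session")
def small_grm(small_sim_config):
    ped, dos = simulate_genotypes(small_sim_config, seed=11)
    return compute_grm(dos, ped["fish_id"])


@pytest.fixture()
def toy_records():
    """Ten fish exactly on W = (2 + 0.1 t)^2 plus tiny per-fish offsets."""
    ages = np.array([1.0, 55.0, 104.0, 167.0, 217.0])
    rows = []
    for i in range(10):
        lin = (2.0 + 0.02 * i) + 0.1 * ages
        for t, w in zip(ages, lin**2):
            rows.append(
                {
                    "fish_id": f"T{i:02d}",
                    "pond": "aerated",
                    "hapa": 1 + i % 4,
                    "sex": ["male", "female"][i % 2],
                    "start_weight": lin[0] ** 2,
                    "age": t,
                    "weight": w,
                }
            )
    return WeightRecordSet(pd.DataFrame(rows))


def records_from_matrix(weights: np.ndarray, ages, **cov) -> WeightRecordSet:
    """Build a WeightRecordSet from an (n_fish, n_ages) weight matrix."""
    n, T = weights.shape
    rows = []
    for i in range(n):
        for j in range(T):
            rows.append(
                {
                    "fish_id": f"F{i:04d}",
                    "pond": cov.get("pond", "aerated"),
                    "hapa": cov.get("hapa", 1),
                    "sex": cov.get("sex", "male"),
                    "start_weight": weights[i, 0],
                    "age": float(ages[j]),
                    "weight": float(weights[i, j]),
                }
            )
    return WeightRecordSet(pd.DataFrame(rows))
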