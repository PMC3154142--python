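import numpy as np
import pandas as pd
import pytest

from imprintscan import BetaMatrix, SimConfig, simulate_dataset

TRIPLOID_ONLY = {"diandric": 10, "digynic": 10}


@pytest.fixture(scope="session")
def study_sim():
    """A small full-design simulation shared by read-only tests."""
    cfg = SimConfig(
        n_background=400,
        n_maternal_dmr=10,
        n_paternal_dmr=10,
        n_tissue_specific=8,
        n_gestation_drift=6,
        seed=7,
    )
    return simulate_dataset(cfg)


@pytest.fixture()
def tiny_bm():
    """3 probes x 4 samples, hand-set values."""
    beta = pd.DataFrame(
        {
            "s1": [0.10, 0.50, 0.90],
            "s2": [0.20, 0.50, 0.80],
            "s3": [0.30, 0.55, 0.70],
            "s4": [0.40, 0.45, 0.60],
        },
        index=["cg1", "cg2", "cg3"],
    )
    return BetaMatrix(beta)


def two_group_sheet(n_a: int, n_b: int, group_a="diandric", group_b="digynic"):
    ids = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    return pd.DataFrame(
        {"sample_id": ids, "group": [group_a] * n_a + [group_b] * n_b}
    ).set_index("sample_id")


def random_bm(n_probes, sheet, rng, loc=0.0, scale=1.0):
    """Logit-normal null matrix over the samples of a sheet."""
    z = rng.normal(loc, scale, size=(n_probes, len(sheet)))
    beta = 1 / (1 + np.exp(-z))
    return BetaMatrix(
        pd.DataFrame(beta, index=[f"cg{i}" for i in range(n_probes)], columns=sheet.index)
    )
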