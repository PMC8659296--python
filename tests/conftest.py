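import numpy as np
import pandas as pd
import pytest

from pupamp.config import RunConfig
from pupamp.synthetic import (
    StageParams,
    ZinbSimSpec,
    control_like_spec,
    simulate_zinb_counts,
)


@pytest.fixture(scope="session")
def control_cfu() -> pd.DataFrame:
    """Default control-like CFU dataset (loads fall across metamorphosis)."""
    return simulate_zinb_counts(control_like_spec(), seed=1)


@pytest.fixture(scope="session")
def moderate_cfu() -> pd.DataFrame:
    """Moderately zero-inflated dataset where the ZINB is well identified."""
    spec = ZinbSimSpec(
        p0=StageParams(pi=0.3, mu=50.0, theta=1.0),
        pharate=StageParams(pi=0.5, mu=20.0, theta=1.0),
        n_per_stage=100,
        genotype="moderate",
    )
    return simulate_zinb_counts(spec, seed=11)


@pytest.fixture()
def small_config() -> RunConfig:
    return RunConfig(seed=3, subset_size=60, n_iterations=30)


def toy_cfu(counts_p0, counts_ph, genotype="toy", bacterium="Lactobacillus") -> pd.DataFrame:
    """Hand-built CFU table from explicit per-stage count lists."""
    rows = [
        {"genotype": genotype, "stage": "P0", "bacterium": bacterium, "colonies": int(c),
         "cfu_per_pupa": float(c)}
        for c in counts_p0
    ] + [
        {"genotype": genotype, "stage": "pharate", "bacterium": bacterium, "colonies": int(c),
         "cfu_per_pupa": float(c)}
        for c in counts_ph
    ]
    df = pd.DataFrame(rows)
    df["stage"] = pd.Categorical(df["stage"], categories=["P0", "pharate"], ordered=True)
    return df


@pytest.fixture(scope="session")
def toy_12row() -> pd.DataFrame:
    """Fixed 12-row dataset with zeros and positives in both stages."""
    return toy_cfu([0, 0, 12, 40, 3, 0], [0, 0, 0, 5, 1, 9])
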