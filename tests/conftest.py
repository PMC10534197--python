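import numpy as np
import pandas as pd
import pytest

import methclock as mc


@pytest.fixture
def tiny_matrix() -> mc.BetaMatrix:
    """2 probes x 3 samples, hand-checkable."""
    betas = pd.DataFrame(
        [[0.1, 0.9, 0.5], [0.4, 0.2, 0.8]],
        index=["cg00000001", "cg00000002"],
        columns=["s1", "s2", "s3"],
    )
    return mc.BetaMatrix(betas)


@pytest.fixture(scope="session")
def small_synth():
    """Small synthetic cohort reused across read-only tests."""
    cfg = mc.SyntheticConfig(
        n_samples=30, n_probes=200, n_informative=5, noise_sd=0.02, seed=7
    )
    return mc.generate(cfg)


@pytest.fixture(scope="session")
def published_clock() -> mc.ClockModel:
    return mc.load_published_clock("maui_hectors_8cpg")


def beta_frame(arr, probes=None, samples=None) -> pd.DataFrame:
    arr = np.asarray(arr, dtype=float)
    probes = probes or [f"cg{i:08d}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=probes, columns=samples)
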