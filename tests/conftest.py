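import numpy as np
import pandas as pd
import pytest

from ebcpanel.simulate import (
    EffectSpec,
    NoiseModel,
    PlatformSpec,
    make_study_design,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_platform() -> PlatformSpec:
    return PlatformSpec(n_probesets=200, n_human_mirnas=100, probes_per_set=4)


@pytest.fixture(scope="session")
def design_21_21() -> pd.DataFrame:
    return make_study_design(21, 21, seed=0)


@pytest.fixture(scope="session")
def small_dataset(small_platform, design_21_21):
    """200 probe sets, 21 vs 21, three strong planted cancer effects."""
    effects = [EffectSpec(i, 2.0, "cancer") for i in range(3)]
    return simulate_dataset(
        small_platform, design_21_21, effects, NoiseModel(), seed=11
    )


def gaussian_panel_data(
    seed: int,
    n_per_group: int = 21,
    n_features: int = 16,
    n_planted: int = 3,
    effect: float = 2.0,
):
    """Samples x features matrix with the first `n_planted` features shifted
    by `effect` standard deviations in the case group (Cohen's d = effect)."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    X = rng.normal(size=(n, n_features))
    y = np.array(["control"] * n_per_group + ["case"] * n_per_group)
    X[y == "case", :n_planted] += effect
    cols = [f"hsa-miR-{i:04d}" for i in range(n_features)]
    return pd.DataFrame(X, columns=cols), y
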