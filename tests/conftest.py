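import numpy as np
import pandas as pd
import pytest


def make_meta(n: int = 24, n_wl: int | None = None, seed: int = 0) -> pd.DataFrame:
    """Small balanced metadata table for association tests."""
    rng = np.random.default_rng(seed)
    n_wl = n // 2 if n_wl is None else n_wl
    group = np.array(["weight_loss"] * n_wl + ["no_weight_loss"] * (n - n_wl))
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:03d}" for i in range(n)],
            "sex": np.where(rng.random(n) < 0.5, "female", "male"),
            "age": rng.normal(50, 10, n).round(1),
            "baseline_bmi": rng.normal(30, 5, n).round(2),
            "group": group,
        }
    )


@pytest.fixture
def meta24() -> pd.DataFrame:
    return make_meta(24, seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
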