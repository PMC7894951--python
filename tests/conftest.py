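import numpy as np
import pandas as pd
import pytest

from gaitstage.synthetic import default_gait_profile, generate_marker_walk


def make_planted_cohort(
    shift: float,
    n_per_group: int = 60,
    n_noise: int = 4,
    labels=("HS", "HY2"),
    seed: int = 42,
) -> tuple[pd.DataFrame, list[str]]:
    """Two-group cohort with two informative features (+-shift pooled SDs in
    opposite directions) and unit-variance noise features."""
    rng = np.random.default_rng(seed)
    frames = []
    for g, label in enumerate(labels):
        d = {
            "f1": rng.normal(g * shift, 1.0, n_per_group),
            "f2": rng.normal(-g * shift, 1.0, n_per_group),
        }
        for j in range(n_noise):
            d[f"noise{j}"] = rng.normal(0.0, 1.0, n_per_group)
        df = pd.DataFrame(d)
        df["label"] = label
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    return table, ["f1", "f2"] + [f"noise{j}" for j in range(n_noise)]


@pytest.fixture(scope="session")
def clean_walk():
    """Noiseless default walking trial with ground truth."""
    profile = default_gait_profile(noise_sd=0.0)
    return generate_marker_walk(profile, seed=0)


@pytest.fixture(scope="session")
def noisy_walk():
    """Default walking trial at the 1 mm marker noise floor."""
    return generate_marker_walk(default_gait_profile(), seed=3)
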