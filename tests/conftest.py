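import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture()
def small_panel():
    """A tiny two-trait panel: one strong PREVENTED trait, one null trait."""
    from drphenome import TraitSpec, generate_trait_panel

    specs = [
        TraitSpec("prevented", "PREVENTED", d_age=1.5, d_diet_old=-1.5),
        TraitSpec("flat", "NULL"),
    ]
    return generate_trait_panel(specs, n_per_group=20, seed=11)


def balanced_factors(n_per_cell):
    age = np.repeat(["young", "old"], 2 * n_per_cell)
    diet = np.tile(np.repeat(["AL", "EOD"], n_per_cell), 2)
    return age, diet


@pytest.fixture()
def survival_frame():
    def make(times, events, diet="AL"):
        return pd.DataFrame(
            {
                "animal_id": [f"m{i}" for i in range(len(times))],
                "diet": diet,
                "time_days": np.asarray(times, dtype=float),
                "event": np.asarray(events, dtype=int),
                "cause": [None] * len(times),
                "tumor_count": [None] * len(times),
            }
        )

    return make
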