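import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import fshtri as ft

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_raw():
    """Small noisy factorial experiment with some non-informative spots."""
    design = ft.SyntheticDesign(n_clones=400, frac_noninformative=0.05, seed=42)
    return ft.generate_array_experiment(design)


@pytest.fixture
def toy_raw():
    """Hand-built 3-clone, 2-group raw set for exact-value tests."""
    arrays = ["Ctrl_1", "Ctrl_2", "Fsh_1", "Fsh_2"]
    clones = ["c1", "c2", "c3"]
    si = pd.DataFrame(
        [[8.0, 8.0, 8.0, 8.0], [4.0, 4.0, 16.0, 16.0], [2.0, 2.0, 2.0, 2.0]],
        index=clones,
        columns=arrays,
    )
    vi = pd.DataFrame(np.full((3, 4), 10.0), index=clones, columns=arrays)
    bg = pd.Series(1.0, index=arrays)
    sheet = pd.DataFrame(
        {"group": ["Ctrl", "Ctrl", "Fsh", "Fsh"], "batch": "exp1", "replicate": [1, 2, 1, 2]},
        index=pd.Index(arrays, name="array"),
    )
    return ft.RawArraySet(si, vi, bg, sheet)
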