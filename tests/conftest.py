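import numpy as np
import pandas as pd
import pytest

from karstpheno import transform
from karstpheno.synthetic_data import SimulationConfig, simulate_community


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic survey shared across the suite."""
    config = SimulationConfig(seed=11)
    community, meta, traits, truth = simulate_community(config)
    return {
        "config": config,
        "community": community,
        "meta": meta,
        "traits": traits,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def default_analysis(default_sim):
    """Percent matrix, analysis (sqrt+Hellinger) matrix and Bray-Curtis matrix."""
    percent = transform.cover_to_percent(default_sim["community"])
    analysis = transform.hellinger(transform.sqrt_transform(percent))
    bray = transform.bray_curtis(analysis)
    return {"percent": percent, "analysis": analysis, "bray": bray}


@pytest.fixture()
def small_matrix():
    rng = np.random.default_rng(7)
    data = pd.DataFrame(
        rng.poisson(3.0, size=(6, 4)).astype(float) + 0.5,
        index=[f"p{i}" for i in range(6)],
        columns=list("abcd"),
    )
    return data
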