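import numpy as np
import pandas as pd
import pytest

from glycofeed.glycoforms import GlycoformTable, normalize_abundances


@pytest.fixture
def two_species_table() -> GlycoformTable:
    """50/50 mix of fully agalactosylated and mono-galactosylated pairs."""
    raw = pd.DataFrame(
        {"G0F ⋅ G0F": [50.0], "G1F ⋅ G1F": [50.0]}, index=["s1"]
    )
    return normalize_abundances(raw)


@pytest.fixture
def random_table() -> GlycoformTable:
    """Random strictly positive 6-sample x 5-glycoform abundance table."""
    rng = np.random.default_rng(42)
    cols = ["G0 ⋅ G0", "G0F ⋅ G0F", "G0F ⋅ G1F", "G1F ⋅ G1F", "G2F ⋅ G2F"]
    raw = pd.DataFrame(
        rng.uniform(1.0, 50.0, size=(6, len(cols))),
        index=[f"s{i}" for i in range(6)], columns=cols,
    )
    meta = pd.DataFrame({
        "strategy": ["STD"] * 3 + ["STD+"] * 3,
        "phase": ["exp", "exp", "sta", "sta", "exp", "sta"],
        "replicate": [f"r{i}" for i in range(6)],
    }, index=raw.index)
    return normalize_abundances(raw, meta)
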