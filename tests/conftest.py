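import numpy as np
import pandas as pd
import pytest

from sexgeno.preproc import BoldSeries, NuisanceSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_bold(rng):
    """6x5x4 random BOLD series, full mask, TR 1 s, 64 frames."""
    data = rng.standard_normal((6, 5, 4, 64))
    mask = np.ones((6, 5, 4), dtype=bool)
    return BoldSeries(data, mask, (1.0, 1.0, 1.0), 1.0, "s01")


@pytest.fixture
def small_nuisance(rng, small_bold):
    t = small_bold.n_timepoints
    return NuisanceSet(rng.standard_normal((t, 6)), rng.standard_normal(t))


@pytest.fixture
def balanced_design():
    """2x2 design, 4 subjects per cell."""
    rows = []
    for sex in ("M", "F"):
        for geno in ("WT", "MUT"):
            for k in range(4):
                rows.append({"subject": f"{sex}{geno}{k}", "sex": sex,
                             "genotype": geno})
    return pd.DataFrame(rows)
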