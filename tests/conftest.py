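import numpy as np
import pandas as pd
import pytest

from episig import SimDesign, simulate_organoid_counts


@pytest.fixture
def paired_meta():
    """2 treatments x 4 subjects, one replicate, single cluster."""
    rows = [(f"s{t}{p}", f"t{t}", f"d{p}", "c0") for t in range(2) for p in range(4)]
    return pd.DataFrame(
        {"treatment": [r[1] for r in rows], "subject": [r[2] for r in rows],
         "cluster": [r[3] for r in rows]},
        index=pd.Index([r[0] for r in rows], name="sample"),
    )


@pytest.fixture
def small_counts(paired_meta):
    rng = np.random.default_rng(42)
    y = rng.poisson(100, size=(20, len(paired_meta)))
    return pd.DataFrame(y, index=[f"g{i}" for i in range(20)], columns=paired_meta.index)


@pytest.fixture
def organoid_sim():
    design = SimDesign(n_genes=150, frac_de=0.3, effect_size=2.0, seed=11)
    return simulate_organoid_counts(design)
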