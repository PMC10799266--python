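import warnings

import numpy as np
import pandas as pd
import pytest

from mrdose import instruments as ins
from mrdose import simulate as sim

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest linear-effect cohort shared across read-only tests."""
    cfg = sim.SimConfig(n_individuals=6000, n_variants=40, seed=42)
    return sim.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_grs(small_cohort):
    weights = [
        ins.VariantWeight(v, "A", float(w))
        for v, w in small_cohort.true_weights.items()
    ]
    return ins.build_grs(small_cohort.dosages, weights)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def make_summary_stats(bx, sx, by, sy, ids=None):
    from mrdose.linear import SummaryStats

    bx = np.asarray(bx, float)
    ids = ids or [f"v{i}" for i in range(len(bx))]
    return SummaryStats(ids, bx, np.asarray(sx, float), np.asarray(by, float), np.asarray(sy, float))
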