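import numpy as np
import pytest
from hypothesis import settings

from vigormet.preprocess import MetaboliteMatrix

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")
from vigormet.synthetic_data import MetabolomeConfig, simulate_metabolome


@pytest.fixture(scope="session")
def default_metabolome():
    """Default-size matrix (188 x 24) with a fumarate-elevation signature."""
    config = MetabolomeConfig(
        line_effects={
            "ColxC24": {"tca": 0.7, "Fumarate": 1.54, "Malate": 0.7},
            "C24xCol": {"tca": 0.7, "Fumarate": 1.33, "Malate": 0.7},
        },
        seed=11,
    )
    matrix, truth = simulate_metabolome(config)
    return config, matrix, truth


@pytest.fixture
def small_matrix():
    """Tiny hand-built matrix: 1 IS peak + 3 peaks, 2 lines x 2 reps."""
    import pandas as pd

    peaks = pd.DataFrame(
        {
            "annotation": ["IS_01", "Fumarate", "Malate", "unknown"],
            "is_internal_standard": [True, False, False, False],
        },
        index=pd.Index(["p1", "p2", "p3", "p4"], name="peak_id"),
    )
    data = pd.DataFrame(
        {
            "A.1": [100.0, 8.0, 4.0, 2.0],
            "A.2": [100.0, 8.0, 4.0, 2.0],
            "B.1": [100.0, 16.0, 4.0, 2.0],
            "B.2": [100.0, 16.0, 4.0, 2.0],
        },
        index=peaks.index,
    )
    return MetaboliteMatrix(peaks, data)


def brute_force_bh(p):
    """Independent BH step-up: explicit sort + cumulative minimum from the right."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def pooled_t_p(a, b):
    """Independent two-sided pooled-variance t-test via the t CDF."""
    from scipy.stats import t as t_dist

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = a.size, b.size
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    t_stat = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    return 2.0 * t_dist.sf(abs(t_stat), df)
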