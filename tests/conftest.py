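import numpy as np
import pytest

from chronotarget import synthdata


@pytest.fixture
def time_grid():
    """The canonical 7-point, 4 h circadian sampling grid (hours)."""
    return np.arange(0.0, 25.0, 4.0)


@pytest.fixture
def small_study():
    """A small seeded synthetic matrix with ground truth (deterministic)."""
    cfg = synthdata.SynthConfig(n_genes=60, frac_rhythmic=0.3, noise_cv=0.05,
                                n_clock_genes=5, seed=7)
    matrix, truth = synthdata.generate_temporal_matrix(cfg)
    return matrix, truth


def bh_oracle(pvals):
    """Brute-force Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        i = n - rank_from_top  # 1-based rank of this p in ascending order
        running = min(running, p[idx] * n / i)
        adj[idx] = running
    return adj
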