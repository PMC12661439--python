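import numpy as np
import pytest
from scipy import stats

from pchkit import DEFAULT_PSF, PCHistogram, SimulationConfig
from pchkit.pch import _pool, _pooled_edges


@pytest.fixture(scope="session")
def geometry():
    return DEFAULT_PSF


@pytest.fixture(scope="session")
def box_volume():
    return SimulationConfig(seed=0).box_volume


@pytest.fixture(scope="session")
def nref_to_box(box_volume, geometry):
    """Convert a mean particle number in V_ref to a mean count in the box."""

    def convert(n_ref: float) -> float:
        return n_ref * box_volume / geometry.reference_volume

    return convert


def chi_square_pvalue(histogram: PCHistogram, probabilities: np.ndarray) -> float:
    """Goodness-of-fit p-value of an observed PCH against model probabilities,
    pooling tail bins to expected >= 5."""
    n = histogram.total_bins
    k_max = max(histogram.k_max, probabilities.size - 1)
    obs = np.zeros(k_max + 1)
    obs[: histogram.frequency.size] = histogram.frequency
    exp = np.zeros(k_max + 1)
    exp[: probabilities.size] = probabilities * n
    edges = _pooled_edges(exp, 5.0)
    o, e = _pool(obs, edges), _pool(exp, edges)
    chi2 = float(((o - e) ** 2 / e).sum())
    return float(stats.chi2.sf(chi2, len(edges) - 1))
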