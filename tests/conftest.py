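import numpy as np
import pytest

from reefstab.datamodel import CommunityMatrix, MetacommunityTensor


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def random_matrix(rng, t=None, s=None, site="site") -> CommunityMatrix:
    """A random non-degenerate community matrix (lognormal abundances)."""
    t = t or int(rng.integers(5, 12))
    s = s or int(rng.integers(2, 8))
    abund = np.exp(rng.normal(1.0, 0.6, size=(t, s)))
    return CommunityMatrix(site, np.arange(2000, 2000 + t), [f"sp{j}" for j in range(s)], abund)


def random_tensor(rng, n=None, s=None, t=None) -> MetacommunityTensor:
    n = n or int(rng.integers(2, 5))
    s = s or int(rng.integers(2, 6))
    t = t or int(rng.integers(5, 12))
    abund = np.exp(rng.normal(1.0, 0.6, size=(n, s, t)))
    return MetacommunityTensor(
        "eco", [f"s{i}" for i in range(n)], [f"sp{j}" for j in range(s)],
        np.arange(2000, 2000 + t), abund
    )


@pytest.fixture
def small_survey():
    """Tiny two-site survey table with replicates, as a DataFrame."""
    import pandas as pd

    rows = []
    for site in ("a", "b"):
        for year in range(2000, 2006):
            for sp, base in (("x", 4), ("y", 2)):
                rows.append((site, year, sp, base + (year % 3), 50.0, "study1"))
    return pd.DataFrame(
        rows, columns=["site_id", "year", "species_id", "abundance", "sampled_area", "study_id"]
    )
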