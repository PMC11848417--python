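import numpy as np
import pytest

from fawtrack.core import GenotypeMatrix
from fawtrack.synth import WindSimConfig, simulate_wind_field


def make_matrix(dosages, pops=None, depths=None):
    """Build a GenotypeMatrix from a plain array; rows are samples."""
    dosages = np.asarray(dosages, dtype=float)
    n, L = dosages.shape
    samples = [f"s{i}" for i in range(n)]
    labels = dict(zip(samples, pops)) if pops is not None else {}
    return GenotypeMatrix(
        samples=samples,
        loci=[("chr1", 100 * (j + 1)) for j in range(L)],
        dosages=dosages,
        depths=depths,
        pop_labels=labels,
    )


@pytest.fixture
def two_pop_fixed_matrix():
    """Two populations fixed for opposite alleles at every locus."""
    dos = np.vstack([np.zeros((4, 20)), np.full((4, 20), 2.0)])
    return make_matrix(dos, pops=["A"] * 4 + ["B"] * 4)


@pytest.fixture
def uniform_field():
    """Uniform 10 m/s eastward wind over an all-land grid."""
    return simulate_wind_field(
        WindSimConfig(
            regime="uniform", u0=10.0, v0=0.0,
            lon_min=-5.0, lon_max=15.0, lat_min=-5.0, lat_max=5.0,
            continents=[(-5.0, 15.0, -5.0, 5.0)],
            time_start="2018-06-01T00:00", time_end="2018-06-05T00:00",
        )
    )
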