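import numpy as np
import pytest

from hrrscan.core import GenotypeMatrix, make_marker_map, make_sample_table


def build_matrix(calls, bp=None, chrom=None, breeds=None):
    """Assemble a GenotypeMatrix from a call matrix and optional coordinates."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if bp is None:
        bp = [10_000 * (j + 1) for j in range(m)]
    if chrom is None:
        chrom = ["1"] * m
    if breeds is None:
        breeds = ["breedA"] * n
    markers = make_marker_map([f"snp{j}" for j in range(m)], chrom, bp)
    samples = make_sample_table([f"ind{i}" for i in range(n)], breeds)
    return GenotypeMatrix(samples, markers, calls)


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_612)
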