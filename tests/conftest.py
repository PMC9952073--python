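import numpy as np
import pytest

from popscan.genio import GenotypeMatrix, PopulationPanel


def make_gm(dosage, pos=None, chrom=None, sample_ids=None):
    """Build a GenotypeMatrix from a dosage array with default coordinates."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_samples, n_sites = dosage.shape
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 1000
    if chrom is None:
        chrom = np.full(n_sites, "1", dtype=object)
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n_samples)]
    return GenotypeMatrix(
        sample_ids=sample_ids,
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.full(n_sites, "G", dtype=object),
        dosage=dosage,
    )


def two_pop_panel(gm):
    """Split the matrix's samples into two equal populations."""
    half = gm.n_samples // 2
    return PopulationPanel(
        {s: ("popA" if i < half else "popB") for i, s in enumerate(gm.sample_ids)}
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
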