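import numpy as np
import pytest

from flameback.assoc import GenotypeMatrix
from flameback.pigments import load_pigment_table
from flameback.synthetic_data import SimConfig


@pytest.fixture(scope="session")
def pigment_table():
    return load_pigment_table()


@pytest.fixture
def small_sim_config():
    """A small but fully structured synthetic study."""
    return SimConfig(seed=11,
                     n_per_group={"red": 15, "orange": 10, "yellow": 15},
                     n_snps=500, n_chroms=3,
                     causal_loci=[(2, 50, 0.5)],
                     cnv_loci=[(3, 40, "red", 3.0)])


def toy_matrix(gt, dp=None, gq=None, ad_alt=None, chrom=None, pos=None,
               ref=None, alt=None):
    """Build a GenotypeMatrix from a dosage-style genotype array.

    ``gt`` is (n_samples, n_sites) with entries in {0, 1, 2} or -1 (missing).
    """
    gt = np.asarray(gt)
    n, p = gt.shape
    pair = np.zeros((n, p, 2), dtype=np.int8)
    pair[:, :, 0] = gt >= 1
    pair[:, :, 1] = gt == 2
    het = gt == 1
    pair[het, 0], pair[het, 1] = 0, 1
    pair[gt < 0] = -1
    dp = np.full((n, p), 20.0) if dp is None else np.asarray(dp, dtype=float)
    gq = np.full((n, p), 40.0) if gq is None else np.asarray(gq, dtype=float)
    if ad_alt is None:
        ad_alt = np.where(gt == 2, dp, np.where(gt == 1, dp / 2, 0.0))
    ad_alt = np.asarray(ad_alt, dtype=float)
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(n)],
        chrom=np.array(["chr1"] * p if chrom is None else chrom, dtype=object),
        pos=np.arange(1, p + 1, dtype=np.int64) if pos is None else np.asarray(pos),
        ref=np.array(["A"] * p if ref is None else ref, dtype=object),
        alt=np.array(["G"] * p if alt is None else alt, dtype=object),
        gt=pair, dp=dp, gq=gq, ad_ref=dp - ad_alt, ad_alt=ad_alt,
    )
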