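import numpy as np
import pytest

from tagblock import genotypes as gt
from tagblock import syndata


@pytest.fixture(scope="session")
def small_panel():
    """A structured two-subpopulation panel shared by read-only tests."""
    cfg = syndata.SimConfig(
        seed=11,
        n_groups=2,
        group_length_cm=100.0,
        n_tl_loci=200,
        subpop_sizes=(150, 80),
        missing_rate=0.1,
        het_rate=0.01,
        fst_drift=0.2,
        admixture=0.1,
    )
    tl, snp, truth = syndata.simulate_panel(cfg)
    return cfg, tl, snp, truth


@pytest.fixture(scope="session")
def small_panel_biallelic(small_panel):
    _, tl, _, _ = small_panel
    return gt.compress_to_biallelic(tl)


def toy_matrix():
    """3 lines x 2 loci with a heterozygote and a missing call."""
    loci = [
        gt.Locus("toy_1.1", ["A", "C"], group="Mrg01", cm=5.0),
        gt.Locus("toy_2.1", ["A", "C", "G"], group="Mrg01", cm=7.5),
    ]
    calls = np.array(
        [[0, 2], [1, gt.het_code(0, 1)], [gt.MISSING, 0]], dtype=np.int32
    )
    return gt.GenotypeMatrix(["l1", "l2", "l3"], loci, calls)
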