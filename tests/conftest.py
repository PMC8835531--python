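import numpy as np
import pandas as pd
import pytest

from evomet.io import SnpCountTable, StudyDesign


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_design():
    """3 treatments x 2 replicate strata = 6 populations."""
    pops = ["A1", "A2", "C1", "C2", "S1", "S2"]
    treatments = np.array(["A", "A", "C", "C", "S", "S"], dtype=object)
    strata = np.array([1, 2, 1, 2, 1, 2])
    return StudyDesign(pops, treatments, strata)


@pytest.fixture
def toy_table(toy_design, rng):
    """3 SNPs x 6 populations; SNP 2 (index 1) is monomorphic."""
    n, p = 3, 6
    cov = rng.integers(40, 80, size=(n, p))
    alt = rng.binomial(cov, 0.4)
    alt[1] = 0  # monomorphic site
    return SnpCountTable(
        np.array(["2L", "2L", "2R"], dtype=object),
        np.array([100, 5000, 100]),
        cov - alt,
        alt,
        toy_design.populations,
    )


def random_table(rng, n_snps=50, pops=None, chroms=("2L", "2R")):
    pops = pops or [f"p{i}" for i in range(6)]
    chrom = rng.choice(chroms, size=n_snps)
    order = np.argsort(chrom, kind="stable")
    pos = np.zeros(n_snps, dtype=np.int64)
    for c in chroms:
        m = chrom == c
        pos[m] = np.sort(rng.choice(np.arange(1, 10 * n_snps), size=m.sum(), replace=False))
    cov = rng.integers(20, 120, size=(n_snps, len(pops)))
    alt = rng.binomial(cov, rng.uniform(0.1, 0.9, size=n_snps)[:, None])
    return SnpCountTable(chrom[order], pos[order], (cov - alt)[order], alt[order], pops)


@pytest.fixture
def balanced_design_10():
    """The emulated 3 x 10 layout."""
    pops, tr, st = [], [], []
    for t in "ACS":
        for k in range(1, 11):
            pops.append(f"{t}{k}")
            tr.append(t)
            st.append(k)
    return StudyDesign(pops, np.array(tr, dtype=object), np.array(st))
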