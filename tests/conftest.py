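import numpy as np
import pandas as pd
import pytest

from adnapop.eigenstrat import GenotypeTable, IND_COLUMNS, SNP_COLUMNS


def make_table(calls, chroms=None, pseudo=False, groups=None):
    """Small helper: GenotypeTable from a raw call matrix."""
    calls = np.asarray(calls, dtype=np.int8)
    n_snps, n_ind = calls.shape
    chroms = chroms if chroms is not None else [1] * n_snps
    snps = pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(n_snps)],
            "chromosome": chroms,
            "genetic_pos": np.linspace(0, 0.01 * n_snps, n_snps),
            "physical_pos": np.arange(1, n_snps + 1) * 1000,
            "ref_allele": "A",
            "alt_allele": "C",
        },
        columns=SNP_COLUMNS,
    )
    groups = groups if groups is not None else [f"ind{j}" for j in range(n_ind)]
    individuals = pd.DataFrame(
        {
            "individual_id": [f"ind{j}" for j in range(n_ind)],
            "sex": "unknown",
            "group_label": groups,
        },
        columns=IND_COLUMNS,
    )
    return GenotypeTable(snps=snps, individuals=individuals, calls=calls, pseudo_haploid=pseudo)


@pytest.fixture
def tiny_table():
    """3 SNPs x 2 individuals with one missing call."""
    return make_table([[0, 2], [2, -1], [0, 0]], pseudo=True)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
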