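import numpy as np
import pytest

import strpopkit as sp
from strpopkit.str_data import GenotypeCall, GenotypeTable, StrAllele


@pytest.fixture(scope="session")
def bahrain_freqs() -> sp.FrequencyTable:
    return sp.load_bahrain_frequencies()


@pytest.fixture(scope="session")
def bahrain_params():
    return sp.load_bahrain_forensic_params()


def make_table(locus_calls: dict[str, list[tuple]], population_label: str = "") -> GenotypeTable:
    """Build a GenotypeTable from {locus: [(a, b, *extra), ...]} allele labels."""
    loci = list(locus_calls)
    n = len(next(iter(locus_calls.values())))
    calls = []
    for i in range(n):
        row = []
        for locus in loci:
            entry = locus_calls[locus][i]
            if entry is None:
                row.append(GenotypeCall())
                continue
            alleles = [sp.parse_allele(str(x)) for x in entry]
            row.append(GenotypeCall(alleles[0], alleles[1], tuple(alleles[2:])))
        calls.append(row)
    return GenotypeTable([f"s{i+1}" for i in range(n)], loci, calls, population_label)


@pytest.fixture
def two_sample_table() -> GenotypeTable:
    # one heterozygote 8/9, one homozygote 8/8
    return make_table({"L1": [(8, 9), (8, 8)]})


@pytest.fixture(scope="session")
def hwe_cohort() -> GenotypeTable:
    """10,000 individuals at one biallelic locus, p = [0.5, 0.5], no inbreeding."""
    cfg = sp.SimulationConfig(
        n_individuals=10_000, loci={"L": np.array([0.5, 0.5])}, fis=0.0, seed=42
    )
    return sp.simulate_genotypes(cfg)
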