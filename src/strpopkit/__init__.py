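"""strpopkit: forensic STR population statistics.

Per-locus allele frequencies and forensic efficiency parameters (PIC,
PM/PD, PE, TPI, heterozygosity), Monte-Carlo exact Hardy-Weinberg and
linkage-disequilibrium testing with Bonferroni correction, and
inter-population comparison via FST / Nei distances, neighbor-joining
trees and nonmetric MDS — plus a synthetic genotype generator for
end-to-end validation.
"""

from importlib import resources

__version__ = "0.1.0"

from .str_data import (
    OL,
    AnomalyRecord,
    FrequencyTable,
    GenotypeCall,
    GenotypeTable,
    StrAllele,
    StrDataError,
    AlleleParseError,
    detect_anomalies,
    format_allele,
    parse_allele,
    read_frequency_table,
    read_genotypes,
    write_frequency_table,
    write_genotypes,
)
from .forensic_stats import (
    CombinedStats,
    LocusSummary,
    allele_frequencies,
    combined_stats,
    expected_heterozygosity,
    frequency_table,
    locus_summary,
    maf_floor,
    match_probability,
    observed_heterozygosity,
    pic,
    power_of_exclusion,
    summary_table,
    typical_paternity_index,
)
from .equilibrium_tests import (
    MultipleTestSummary,
    TestResult,
    bonferroni_threshold,
    hwe_exact_enumerate,
    hwe_exact_mc,
    ld_permutation_test,
    multiple_test_summary,
)
from .interpop_distance import (
    AlignedFrequencies,
    DistanceMatrix,
    Ordination,
    Tree,
    TreeNode,
    align_loci,
    from_newick,
    nei_distance,
    neighbor_joining,
    nmds,
    pairwise_fst,
    to_newick,
    tree_distance_matrix,
)
from .synthetic_data import (
    SimulationConfig,
    cohort_from_frequency_table,
    default_panel,
    inject_anomalies,
    sample_frequency_vector,
    simulate_genotypes,
    simulate_structured_populations,
)


def load_bahrain_frequencies() -> FrequencyTable:
    """The bundled 21-locus Bahraini allele-frequency table (543 individuals).

    Frequencies are the published 5-decimal values; allele counts 2N are
    1086 at every locus except D22S1045 (1084: six off-ladder alleles
    excluded there).
    """
    path = resources.files("strpopkit.data") / "bahrain_frequencies.csv"
    ft = read_frequency_table(str(path), population_label="Bahrain")
    ft.sample_size_2n = {locus: (1084 if locus == "D22S1045" else 1086) for locus in ft.loci}
    return ft


def load_bahrain_forensic_params():
    """The published per-locus forensic parameter panel as a DataFrame.

    Rows: PM, PD, PE, TPI, PIC, Ho, HWE; columns: the 21 autosomal loci.
    """
    import pandas as pd

    path = resources.files("strpopkit.data") / "bahrain_forensic_params.csv"
    with resources.as_file(path) as p:
        return pd.read_csv(p, index_col=0)
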