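# Methods

This note documents the statistical procedures implemented in strpopkit,
the modelling assumptions behind them, the defaults and why they were
chosen, and what the synthetic-data generator does and does not emulate.

## Data model

An STR allele is an exact integer pair (repeat units, partial bases 0–3);
`9.3` is a label, not the number 9.3, so equality and hashing never go
through floating point. Off-ladder peaks (`OL`) carry no repeat
information: they compare unequal to every named allele, sort last, and
are barred from frequency tables. A diploid call is an unordered pair;
calls with an `OL` allele or a recorded third allele are QC anomalies.
Anomalous and missing calls are excluded from every frequency, forensic
parameter and test computation at the affected locus, but counted and
reported separately — published STR panels report such records as rare
variants rather than data, and leaving them in would bias the allele
counts. One published table in the bundled data behaves exactly this way:
the D22S1045 frequencies divide by 2N = 1084, its six off-ladder alleles
having been excluded, while every other locus divides by 1086.

Frequency tables are read and written in the conventional allele-rows ×
locus-columns CSV layout at 5 decimals. Because published tables are
rounded, per-locus sums within 0.005 of 1 are accepted on read (the
default; renormalization is opt-in so published values are preserved
verbatim). Genotype files are wide CSV/TSV/XLSX with `<locus>_1/<locus>_2`
column pairs (suffixes configurable, optional `<locus>_3` third-allele
column); errors cite 1-based data rows and locus names.

## Forensic parameter panel

Formulas are the field's standard ones (see README for the display
forms): Botstein PIC; expected heterozygosity with optional 2N/(2N−1)
small-sample correction (the per-locus summary uses the unbiased form by
default); PE = h²(1 − 2hH²) and TPI = 1/(2(1−h)) from *unrounded*
observed heterozygosity — recomputing them from a rounded printed Ho can
shift the 4th decimal, and published tables are themselves computed from
full precision. TPI at h = 1 is an error, never a silent infinity.

Match probability is implemented in both conventions because published
tables are not always explicit about which they used: `observed` squares
the empirical genotype-class proportions; `expected` is the HWE value
2(Σp²)² − Σp⁴, equal to summing squared HWE genotype probabilities over
all genotypes (asserted against an explicit enumeration oracle in the
tests). The per-locus summary reports both, with PD = 1 − PM maintained
exactly for each. The minimum allele frequency 5/(2N) is reported as a
floor next to the frequencies and never substituted into frequency
vectors unless explicitly requested. Combined CMP/CPD multiply per-locus
PM across loci; the product is computed in full float precision, which is
ample for 21 factors of magnitude ≥ 10⁻³.

## Exact equilibrium tests

"Exact HWE test" here means the test conditional on allele counts
(Levene's distribution; the Monte-Carlo version of Guo & Thompson). The
statistic is the conditional probability of the genotype array itself;
re-pairings of the observed allele multiset are sampled uniformly, and
only the terms that vary across re-pairings (heterozygote count and the
genotype-cell factorials) are computed, via a log-factorial lookup table,
so 10,000 permutations of a 543-individual, 48-allele locus run in
seconds. The add-one estimator p = (1 + #{≤ obs})/(B+1) keeps p off zero;
ties are compared with a 1e-9 log-probability tolerance. The allele pool
is sorted before permutation so results are invariant to input row order.
Below a state-space bound (default: an upper bound of 5×10⁵ candidate
genotype tables) the conditional distribution is enumerated exhaustively
and the p-value is exact; the enumeration asserts that the conditional
probabilities sum to 1, which is a strong self-check of the formula.
Monomorphic loci have a single attainable configuration: p = 1, flagged
degenerate, rather than an error — a pipeline over 21 loci must return a
defined result for every locus.

The LD test needed a statistic choice, since unphased diploid data do not
give haplotypes without an EM step: we use the likelihood-ratio G on the
genotype-by-genotype contingency table with individuals as units, and
permute one locus's genotype column. Permutation preserves both margins,
so only Σ O log O varies — the implementation exploits this. Default
B = 10,000 for both tests. Bonferroni correction takes the test count m
as an explicit argument because published screens sometimes divide by a
different m (e.g. a sample size); the threshold is α/m and flags use
strict inequality p < α/m.

## Inter-population comparison

Populations are first aligned to their common loci (published panels
differ; e.g. a 21-locus study compared against 15-locus literature
tables), with per-locus allele unions zero-filled. Alignment returns a
dedicated container rather than frequency tables, because zero
frequencies are not legal table entries.

Two FST estimators are provided. Nei G_ST = Σ(H_T − H_S)/ΣH_T (H_T from
the mean frequency vector, loci combined by H_T weighting) works from
published frequency tables alone. The Weir–Cockerham variance-components
θ needs sample sizes; with only frequency tables available its
heterozygosity terms are taken at their HWE expectation 2p(1−p). The two
differ systematically for a pair of populations: G_ST between r demes
carries the (r−1)/r factor, so at Balding–Nichols divergence F its
expectation is ≈ (F/2)/(1−F/2) for r = 2, while the Weir–Cockerham
estimator (r−1 denominator in the among-deme variance) is centred on F —
parameter-recovery checks therefore use Weir–Cockerham, and G_ST is the
frequency-only default for comparing literature tables. Negative
estimates (sampling noise near FST = 0) are clamped to zero with a log
note.

Nei's standard distance D_s = −ln(J_xy/√(J_x J_y)) accumulates identity
sums over loci; D_A = 1 − mean_l Σ√(x y). Pairs with no shared alleles
anywhere have infinite D_s; these are capped at twice the largest finite
entry and flagged in the matrix metadata, keeping downstream tree/MDS
code total.

Neighbor-joining is the standard Saitou–Nei agglomeration on the Q
criterion; ties break on the lowest index pair so results are
deterministic; negative branch lengths are clamped to zero with the
deficit moved to the sibling edge, preserving the joined pair's path
length. On additive matrices the recovered tree reproduces the input
metric exactly (property-tested over random trees, and cross-checked
against dendropy's patristic distances on the Newick output). Trees are
serialized as Newick with single-quote label quoting.

NMDS is Kruskal stress-1: classical (Torgerson) scaling initialization,
isotonic (pool-adjacent-violators, via scipy) disparities, Guttman
transform updates. Ties in the dissimilarities use the primary approach
(within tied blocks, ordered by current configuration distance), which
lets exactly embeddable configurations — e.g. three equidistant points in
the plane — reach stress 0. Iteration stops when stress improves by less
than 1e-7 (default; max 500 iterations); the best configuration seen is
returned, so the reported stress history is non-increasing. RSQ is the
squared Pearson correlation between disparities and configuration
distances. Exact replication of SPSS ALSCAL stress/RSQ values is not
attempted: ALSCAL minimizes a different (s-stress) loss.

## Synthetic data

The generator emulates the sampling structure of a forensic STR
population study: N unrelated diploid individuals typed at a panel of
loci, genotypes drawn independently across loci and individuals.
Within-population inbreeding uses the standard mixture construction
(with probability f the two gene copies are identical by descent), which
realizes P(hom i) = p_i² + f p_i(1−p_i), P(het ij) = 2p_i p_j(1−f)
exactly. Multi-population structure uses Balding–Nichols: population
frequency vectors are Dirichlet(p(1−F)/F) draws centred on the ancestral
vector — chosen because it gives a single interpretable FST knob.
Anomalies are injected per (sample, locus) slot as Bernoulli events:
off-ladder substitutes one allele with `OL`; tri-allelic appends a third
allele drawn from the locus's allele pool.

Defaults mirror the study design the package ships data for: 21 loci,
N = 543, per-locus allele counts spanning 7–48, and the bundled Bahraini
frequency table can be used as the panel directly. Consanguinity makes
F_IS a parameter of interest, but no published point estimate exists for
this cohort, so F_IS defaults to 0 and is a free parameter. Reproducibility
comes from one global seed driving a per-locus (and per-population)
SeedSequence substream, so a locus's draws do not depend on panel
composition or iteration order.

A second generator, `cohort_from_frequency_table`, reconstructs a
genotype-level cohort from a published frequency table: allele counts are
recovered as round(f·2N) (drift absorbed by the most common allele) and
paired at random. Count-level statistics (frequencies, Na, PIC, expected
PM/PD) then reproduce the source table exactly; pairing-level statistics
(Ho, HWE p-values) are synthetic, and the docstring says so.

What the generator does *not* emulate: STR mutation processes,
pedigree/relatedness structure among sampled individuals, locus-specific
typing artefacts (stutter, dropout) beyond the two anomaly kinds, or
linkage between loci (all loci are simulated independently, which is also
the null of the LD test). Passing tests on synthetic data therefore
validate the estimators and tests under their stated assumptions, not
robustness to those real-data complications.

## Test problem sizes

Calibration checks use scales chosen to keep the full suite fast while
leaving comfortable statistical margins: HWE type-I calibration runs 500
replicates of N = 100 at B = 1,000 permutations (binomial 2-SE band
±0.02 around α = 0.05); p-value uniformity uses 300 replicates at
B = 400 with a Kolmogorov–Smirnov screen at α = 0.01; FST recovery runs
20 seeds of two 500-individual populations at 15 octa-allelic loci;
heterozygosity laws are checked at N = 10,000 within 3 standard errors.
Monte-Carlo-vs-enumeration agreement is asserted within 2 Monte-Carlo
standard errors at B = 20,000 on loci small enough to enumerate.

## Known limitations

- No θ-corrected (subpopulation-adjusted) match probabilities and no
  kinship likelihood ratios beyond TPI.
- No haplotype-frequency estimation or r²/D′ LD coefficients; the LD test
  reports permutation p-values only.
- Weir–Cockerham θ from frequency tables assumes HWE heterozygosities;
  with genotype data available, observed heterozygosities would be
  preferable.
- No bootstrap support on NJ trees; no plotting beyond coordinate export.
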