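"""Synthetic STR genotype cohorts with controlled population structure.

Generates diploid genotype tables with the statistical structure the
analysis modules assume, so the whole pipeline is testable end to end:

* random-mating (HWE) sampling from given allele frequencies, with an
  optional inbreeding coefficient f: with probability f an individual's
  two gene copies at a locus are identical by descent (one draw,
  homozygous), otherwise two independent draws. That realizes the
  standard inbreeding law P(hom i) = p_i^2 + f p_i (1 - p_i),
  P(het ij) = 2 p_i p_j (1 - f).
* multi-population divergence at a target fixation index F via the
  Balding-Nichols model: each population's per-locus frequency vector is
  drawn from Dirichlet(p * (1 - F) / F) centred on the ancestral vector
  p, then individuals are sampled under HWE within each population.
* off-ladder and tri-allelic anomaly injection at configured rates.

The default panel mirrors a forensic 21-locus autosomal STR study of 543
individuals, with per-locus allele counts spanning 7 to 48; when the
bundled Bahraini frequency table is used as the panel the simulated
cohort matches the study's frequency spectrum exactly.

Reproducibility: one global seed drives a per-locus substream (spawned
from a ``numpy`` SeedSequence keyed on the locus index), so a locus's
draws do not depend on how many other loci were simulated before it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .str_data import (
    OL,
    AnomalyRecord,
    FrequencyTable,
    GenotypeCall,
    GenotypeTable,
    StrAllele,
    StrDataError,
)

__all__ = [
    "SimulationConfig",
    "sample_frequency_vector",
    "default_panel",
    "simulate_genotypes",
    "simulate_structured_populations",
    "inject_anomalies",
]

# the 21 autosomal loci of the GlobalFiler panel, in kit order
GLOBALFILER_AUTOSOMAL_LOCI = [
    "D8S1179", "D21S11", "D7S820", "CSF1PO", "D3S1358", "TH01", "D13S317",
    "D16S539", "D2S1338", "D19S433", "VWA", "TPOX", "D18S51", "D5S818",
    "FGA", "D12S391", "D1S1656", "D2S441", "D10S1248", "D22S1045", "SE33",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic cohort.

    ``loci`` maps locus names to allele-frequency vectors (parallel
    ``alleles`` lists give the allele labels; integer repeat ladders are
    generated when omitted). ``fis`` is the within-population inbreeding
    coefficient, ``fst`` the Balding-Nichols divergence used when
    ``n_populations >= 2``.
    """

    n_individuals: int = 543
    loci: dict[str, np.ndarray] = field(default_factory=dict)
    alleles: dict[str, list[StrAllele]] = field(default_factory=dict)
    fis: float = 0.0
    fst: float = 0.05
    n_populations: int = 1
    off_ladder_rate: float = 0.0
    tri_allelic_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("need at least one individual")
        if not 0.0 <= self.fis <= 1.0:
            raise ValueError(f"fis must be in [0,1], got {self.fis}")
        if self.n_populations >= 2 and not 0.0 < self.fst < 1.0:
            raise ValueError(f"fst must be in (0,1), got {self.fst}")
        for locus, p in self.loci.items():
            p = np.asarray(p, dtype=float)
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"frequencies at {locus} sum to {p.sum()}, not 1")


def sample_frequency_vector(
    n_alleles: int, concentration: float = 1.0, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """A strictly positive frequency vector ~ symmetric Dirichlet(concentration)."""
    if n_alleles < 1:
        raise ValueError(f"need at least one allele, got {n_alleles}")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    if n_alleles == 1:
        return np.array([1.0])
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    while True:
        p = rng.dirichlet(np.full(n_alleles, float(concentration)))
        if (p > 0).all():  # guard against underflow zeros at tiny concentration
            return p


def default_panel(
    seed: int = 0,
    n_individuals: int = 543,
    fis: float = 0.0,
    frequencies: FrequencyTable | None = None,
) -> SimulationConfig:
    """A 21-locus study-scale configuration.

    With ``frequencies`` given (e.g. the bundled Bahraini table) the
    panel uses those loci and vectors verbatim; otherwise allele counts
    are spread over the observed forensic range 7-48 and vectors drawn
    from a Dirichlet with concentration 2 (uneven, realistic spectra).
    """
    if frequencies is not None:
        loci, alleles = {}, {}
        for locus in frequencies.loci:
            d = frequencies.locus_frequencies(locus)
            labels = sorted(d, key=StrAllele.sort_key)
            p = np.array([d[a] for a in labels], dtype=float)
            loci[locus] = p / p.sum()
            alleles[locus] = labels
        return SimulationConfig(
            n_individuals=n_individuals, loci=loci, alleles=alleles, fis=fis, seed=seed
        )
    rng = np.random.default_rng(seed)
    counts = np.linspace(7, 48, num=len(GLOBALFILER_AUTOSOMAL_LOCI)).round().astype(int)
    loci = {
        locus: sample_frequency_vector(int(k), concentration=2.0, seed=rng)
        for locus, k in zip(GLOBALFILER_AUTOSOMAL_LOCI, counts)
    }
    return SimulationConfig(
        n_individuals=n_individuals, loci=loci, fis=fis, seed=seed
    )


def _locus_alleles(cfg: SimulationConfig, locus: str, k: int) -> list[StrAllele]:
    if locus in cfg.alleles:
        labels = cfg.alleles[locus]
        if len(labels) != k:
            raise ValueError(f"allele labels/frequency length mismatch at {locus}")
        return list(labels)
    return [StrAllele(6 + i, 0) for i in range(k)]


def _locus_rng(seed: int, locus_index: int, population: int = 0) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(population, locus_index))
    return np.random.default_rng(ss)


def simulate_genotypes(
    cfg: SimulationConfig, population_label: str = "sim"
) -> GenotypeTable:
    """Simulate one population of diploid genotypes under the inbreeding model."""
    if not cfg.loci:
        raise ValueError("configuration has no loci")
    n = cfg.n_individuals
    sample_ids = [f"S{i+1:04d}" for i in range(n)]
    columns: list[list[GenotypeCall]] = []
    for j, (locus, p) in enumerate(cfg.loci.items()):
        p = np.asarray(p, dtype=float)
        labels = _locus_alleles(cfg, locus, len(p))
        rng = _locus_rng(cfg.seed, j)
        a = rng.choice(len(p), size=n, p=p)
        b = rng.choice(len(p), size=n, p=p)
        if cfg.fis > 0:
            ibd = rng.random(n) < cfg.fis
            b = np.where(ibd, a, b)
        columns.append(
            [GenotypeCall(labels[ai], labels[bi]) for ai, bi in zip(a, b)]
        )
    calls = [[columns[j][i] for j in range(len(cfg.loci))] for i in range(n)]
    gt = GenotypeTable(sample_ids, list(cfg.loci), calls, population_label)
    if cfg.off_ladder_rate > 0 or cfg.tri_allelic_rate > 0:
        gt, _log = inject_anomalies(
            gt, cfg.off_ladder_rate, cfg.tri_allelic_rate, seed=cfg.seed + 1
        )
    return gt


def simulate_structured_populations(cfg: SimulationConfig) -> list[GenotypeTable]:
    """Simulate ``n_populations`` diverged populations at target FST.

    Population frequency vectors are Balding-Nichols draws
    Dirichlet(p * (1-F)/F) around each locus's ancestral vector; each
    population is then sampled under HWE (within-population ``fis``
    still applies).
    """
    if cfg.n_populations < 2:
        raise ValueError("structured simulation needs n_populations >= 2")
    scale = (1.0 - cfg.fst) / cfg.fst
    out = []
    for pop in range(cfg.n_populations):
        loci = {}
        for j, (locus, p) in enumerate(cfg.loci.items()):
            p = np.asarray(p, dtype=float)
            rng = _locus_rng(cfg.seed, j, population=pop + 1)
            while True:
                q = rng.dirichlet(np.maximum(p * scale, 1e-12))
                if (q > 0).all():
                    break
            loci[locus] = q
        sub = replace(
            cfg, loci=loci, n_populations=1,
            seed=int(np.random.SeedSequence(cfg.seed, spawn_key=(7, pop)).generate_state(1)[0] % (2**31)),
        )
        out.append(simulate_genotypes(sub, population_label=f"pop{pop+1}"))
    return out


def cohort_from_frequency_table(
    ft: FrequencyTable, seed: int = 0
) -> GenotypeTable:
    """A synthetic cohort whose allele counts exactly match a published table.

    Per locus, each allele's count is recovered as round(frequency * 2N)
    (2N from ``ft.sample_size_2n``; rounding drift is absorbed by the
    most common allele) and the resulting allele multiset is randomly
    paired into diploid genotypes. Loci with 2N below the maximum are
    padded with missing calls. The genotype *pairings* are synthetic —
    only the allele counts, and hence the recomputed frequencies, are
    faithful to the source table.
    """
    if not ft.sample_size_2n:
        raise ValueError("frequency table carries no per-locus 2N")
    n = max(ft.sample_size_2n.values()) // 2
    rng = np.random.default_rng(seed)
    columns: list[list[GenotypeCall]] = []
    for locus in ft.loci:
        freqs = ft.locus_frequencies(locus)
        two_n = ft.sample_size_2n[locus]
        labels = sorted(freqs, key=StrAllele.sort_key)
        counts = np.array([round(freqs[a] * two_n) for a in labels], dtype=int)
        counts[counts == 0] = 1  # every printed allele was observed at least once
        counts[int(np.argmax(counts))] += two_n - int(counts.sum())
        pool = np.repeat(np.arange(len(labels)), counts)
        rng.shuffle(pool)
        col = [
            GenotypeCall(labels[pool[2 * i]], labels[pool[2 * i + 1]])
            for i in range(two_n // 2)
        ]
        col += [GenotypeCall()] * (n - two_n // 2)
        columns.append(col)
    calls = [[columns[j][i] for j in range(len(ft.loci))] for i in range(n)]
    sample_ids = [f"S{i+1:04d}" for i in range(n)]
    return GenotypeTable(sample_ids, list(ft.loci), calls,
                         ft.population_label or "reconstructed")


def inject_anomalies(
    gt: GenotypeTable,
    off_ladder_rate: float = 0.0,
    tri_allelic_rate: float = 0.0,
    seed: int = 0,
) -> tuple[GenotypeTable, list[AnomalyRecord]]:
    """Randomly place off-ladder substitutions and third alleles.

    Each (sample, locus) call independently becomes off-ladder (one
    allele replaced by OL) with ``off_ladder_rate`` and tri-allelic (one
    extra allele drawn from the locus's observed alleles) with
    ``tri_allelic_rate``. Returns the modified copy and the placement
    log; the input table is untouched.
    """
    for r in (off_ladder_rate, tri_allelic_rate):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"rate out of [0,1]: {r}")
    rng = np.random.default_rng(seed)
    log: list[AnomalyRecord] = []
    pools = {
        locus: sorted(
            {a for c in gt.locus_calls(locus) if c.is_usable for a in c.alleles()},
            key=StrAllele.sort_key,
        )
        for locus in gt.loci
    }
    new_calls = []
    for sid, row in zip(gt.sample_ids, gt.calls):
        new_row = []
        for locus, call in zip(gt.loci, row):
            if not call.is_missing:
                if off_ladder_rate and rng.random() < off_ladder_rate:
                    call = GenotypeCall(call.allele_a, OL, call.extra_alleles)
                    log.append(AnomalyRecord(sid, locus, "off_ladder", "injected"))
                if tri_allelic_rate and rng.random() < tri_allelic_rate:
                    pool = pools[locus] or [call.allele_a]
                    extra = pool[rng.integers(len(pool))]
                    call = GenotypeCall(
                        call.allele_a, call.allele_b, call.extra_alleles + (extra,)
                    )
                    log.append(AnomalyRecord(sid, locus, "tri_allelic", "injected"))
            new_row.append(call)
        new_calls.append(new_row)
    return (
        GenotypeTable(list(gt.sample_ids), list(gt.loci), new_calls, gt.population_label),
        log,
    )
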