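"""Per-locus forensic efficiency parameters for STR panels.

Implements the standard forensic panel computed for each locus of a
population sample:

* allele frequencies (off-ladder / tri-allelic calls excluded),
* the minimum-allele-frequency floor 5/(2N),
* observed and (optionally unbiased) expected heterozygosity,
* Botstein's polymorphism information content
  ``PIC = 1 - sum p_i^2 - (sum p_i^2)^2 + sum p_i^4``,
* random match probability PM — both the observed-genotype form
  (sum of squared genotype proportions) and the expected-under-HWE form
  ``2*(sum p^2)^2 - sum p^4`` — with power of discrimination PD = 1 - PM,
* power of exclusion ``PE = h^2 (1 - 2 h H^2)`` with h = Ho, H = 1 - h,
* typical paternity index ``TPI = 1 / (2 (1 - Ho))``,

and the across-locus combined match probability CMP = prod PM and
combined power of discrimination CPD = 1 - CMP.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .str_data import FrequencyTable, GenotypeTable, StrAllele, StrDataError

__all__ = [
    "LocusSummary",
    "CombinedStats",
    "allele_frequencies",
    "frequency_table",
    "maf_floor",
    "observed_heterozygosity",
    "expected_heterozygosity",
    "pic",
    "match_probability",
    "power_of_exclusion",
    "typical_paternity_index",
    "locus_summary",
    "summary_table",
    "combined_stats",
]


@dataclass(frozen=True)
class LocusSummary:
    """One locus's forensic parameter panel."""

    locus: str
    n_alleles: int
    n_usable: int           # diploid individuals entering the statistics
    maf: float              # minimum reportable allele frequency, 5/(2N)
    ho: float
    he: float
    pic: float
    pm_observed: float
    pd_observed: float
    pm_expected: float
    pd_expected: float
    pe: float
    tpi: float
    hwe_p: float | None = None


@dataclass(frozen=True)
class CombinedStats:
    cmp: float              # combined match probability, prod of per-locus PM
    cpd: float              # combined power of discrimination, 1 - CMP
    loci: tuple[str, ...]


def allele_frequencies(
    gt: GenotypeTable, locus: str
) -> tuple[dict[StrAllele, float], int]:
    """Relative allele frequencies at a locus and the effective allele count 2N.

    Only usable diploid calls contribute (missing, off-ladder and
    tri-allelic calls are excluded).
    """
    calls = gt.usable_calls(locus)
    if not calls:
        raise StrDataError(f"no usable calls at locus {locus!r}")
    counts: Counter[StrAllele] = Counter()
    for c in calls:
        counts[c.allele_a] += 1
        counts[c.allele_b] += 1
    two_n = 2 * len(calls)
    return {a: k / two_n for a, k in sorted(counts.items(), key=lambda kv: kv[0].sort_key())}, two_n


def frequency_table(gt: GenotypeTable) -> FrequencyTable:
    """Per-locus allele frequencies for the whole table."""
    freqs: dict[str, dict[StrAllele, float]] = {}
    two_n: dict[str, int] = {}
    for locus in gt.loci:
        try:
            freqs[locus], two_n[locus] = allele_frequencies(gt, locus)
        except StrDataError:
            continue
    return FrequencyTable(freqs, two_n, gt.population_label)


def maf_floor(n_individuals: int) -> float:
    """Minimum reportable allele frequency, the NRC floor 5/(2N)."""
    if n_individuals < 1:
        raise ValueError(f"need at least one individual, got {n_individuals}")
    return 5.0 / (2.0 * n_individuals)


def observed_heterozygosity(gt: GenotypeTable, locus: str) -> float:
    """Fraction of usable diploid calls that are heterozygous."""
    calls = gt.usable_calls(locus)
    if not calls:
        raise StrDataError(f"no usable calls at locus {locus!r}")
    return sum(c.is_heterozygous for c in calls) / len(calls)


def _freq_values(freqs) -> list[float]:
    if isinstance(freqs, Mapping):
        vals = list(freqs.values())
    else:
        vals = list(freqs)
    if not vals:
        raise ValueError("empty frequency vector")
    return vals


def expected_heterozygosity(freqs, two_n: int | None = None, unbiased: bool = False) -> float:
    """Expected heterozygosity ``1 - sum p^2``; unbiased form scales by 2N/(2N-1)."""
    p = _freq_values(freqs)
    he = 1.0 - sum(x * x for x in p)
    if unbiased:
        if not two_n or two_n < 2:
            raise ValueError("unbiased expected heterozygosity needs 2N >= 2")
        he *= two_n / (two_n - 1.0)
    return he


def pic(freqs) -> float:
    """Botstein polymorphism information content.

    ``PIC = 1 - sum p_i^2 - sum_{i != j} p_i^2 p_j^2
          = 1 - sum p^2 - (sum p^2)^2 + sum p^4``.
    Zero for a monomorphic locus.
    """
    p = _freq_values(freqs)
    s2 = sum(x * x for x in p)
    s4 = sum(x ** 4 for x in p)
    return 1.0 - s2 - s2 * s2 + s4


def match_probability(data, mode: str = "expected") -> float:
    """Random match probability PM (sum of squared genotype proportions).

    ``mode="observed"`` takes a :class:`GenotypeTable` locus's calls or an
    iterable of genotype counts and squares the empirical genotype
    proportions. ``mode="expected"`` takes allele frequencies and computes
    the HWE value ``sum_i (p_i^2)^2 + sum_{i<j} (2 p_i p_j)^2 =
    2 (sum p^2)^2 - sum p^4``.
    """
    if mode == "expected":
        p = _freq_values(data)
        s2 = sum(x * x for x in p)
        s4 = sum(x ** 4 for x in p)
        return 2.0 * s2 * s2 - s4
    if mode == "observed":
        counts = [c for c in data]
        if counts and not isinstance(counts[0], (int, float)):
            genotypes = Counter(
                (c.allele_a, c.allele_b) for c in counts if c.is_usable
            )
            counts = list(genotypes.values())
        if not counts:
            raise ValueError("no genotypes for observed match probability")
        n = sum(counts)
        return sum((k / n) ** 2 for k in counts)
    raise ValueError(f"unknown mode {mode!r}")


def power_of_exclusion(ho: float) -> float:
    """Power of exclusion ``PE = h^2 (1 - 2 h H^2)``, h = Ho, H = 1 - h."""
    if not 0.0 <= ho <= 1.0:
        raise ValueError(f"observed heterozygosity must be in [0,1], got {ho}")
    h = ho
    big_h = 1.0 - h
    return h * h * (1.0 - 2.0 * h * big_h * big_h)


def typical_paternity_index(ho: float) -> float:
    """Typical paternity index ``TPI = 1 / (2 (1 - Ho))``."""
    if not 0.0 <= ho < 1.0:
        raise ValueError(
            f"observed heterozygosity must be in [0,1) for TPI, got {ho}"
        )
    return 1.0 / (2.0 * (1.0 - ho))


def locus_summary(
    gt: GenotypeTable,
    locus: str,
    hwe: bool = False,
    n_permutations: int = 10_000,
    seed: int = 0,
    unbiased_he: bool = True,
) -> LocusSummary:
    """Assemble the full forensic parameter panel for one locus."""
    freqs, two_n = allele_frequencies(gt, locus)
    calls = gt.usable_calls(locus)
    n = len(calls)
    ho = observed_heterozygosity(gt, locus)
    pm_obs = match_probability(calls, mode="observed")
    pm_exp = match_probability(freqs, mode="expected")
    hwe_p = None
    if hwe:
        from .equilibrium_tests import hwe_exact_mc

        hwe_p = hwe_exact_mc(gt, locus, n_permutations=n_permutations, seed=seed).p_value
    return LocusSummary(
        locus=locus,
        n_alleles=len(freqs),
        n_usable=n,
        maf=maf_floor(n),
        ho=ho,
        he=expected_heterozygosity(freqs, two_n, unbiased=unbiased_he),
        pic=pic(freqs),
        pm_observed=pm_obs,
        pd_observed=1.0 - pm_obs,
        pm_expected=pm_exp,
        pd_expected=1.0 - pm_exp,
        pe=power_of_exclusion(ho),
        tpi=typical_paternity_index(ho) if ho < 1.0 else float("inf"),
        hwe_p=hwe_p,
    )


_SUMMARY_ROWS = [
    ("Na", "n_alleles", "{:d}"),
    ("MAF", "maf", "{:.4f}"),
    ("PM_obs", "pm_observed", "{:.4f}"),
    ("PD_obs", "pd_observed", "{:.4f}"),
    ("PM_exp", "pm_expected", "{:.4f}"),
    ("PD_exp", "pd_expected", "{:.4f}"),
    ("PE", "pe", "{:.4f}"),
    ("TPI", "tpi", "{:.4f}"),
    ("PIC", "pic", "{:.4f}"),
    ("Ho", "ho", "{:.4f}"),
    ("He", "he", "{:.4f}"),
    ("HWE", "hwe_p", "{:.4f}"),
]


def summary_table(summaries: Sequence[LocusSummary]) -> pd.DataFrame:
    """Parameters-as-rows, loci-as-columns summary frame (4-decimal export)."""
    data = {}
    for s in summaries:
        col = {}
        for row_name, attr, _fmt in _SUMMARY_ROWS:
            v = getattr(s, attr)
            if v is not None:
                col[row_name] = v
        data[s.locus] = col
    return pd.DataFrame(data).reindex([r for r, _, _ in _SUMMARY_ROWS])


def combined_stats(pm_values=None, pd_values=None, loci: Sequence[str] = ()) -> CombinedStats:
    """Combined match probability across loci: CMP = prod PM, CPD = 1 - CMP.

    Provide per-locus PM values, or equivalently PD values (PM = 1 - PD).
    """
    if (pm_values is None) == (pd_values is None):
        raise ValueError("provide exactly one of pm_values / pd_values")
    if pd_values is not None:
        pm_values = [1.0 - x for x in pd_values]
    pm_values = list(pm_values)
    if not pm_values:
        raise ValueError("need at least one locus")
    for x in pm_values:
        if not 0.0 <= x <= 1.0:
            raise ValueError(f"match probability out of [0,1]: {x}")
    cmp_ = math.prod(pm_values)
    return CombinedStats(cmp=cmp_, cpd=1.0 - cmp_, loci=tuple(loci))
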