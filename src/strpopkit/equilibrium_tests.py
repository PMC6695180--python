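"""Exact tests of Hardy-Weinberg equilibrium and linkage disequilibrium.

The HWE test is the conditional exact test for multi-allelic loci
(Levene's conditional distribution, Monte-Carlo approximated as in Guo &
Thompson): given the observed allele counts m_1..m_K at a locus, the
probability of a genotype array {n_ij} under random union of gametes is

    P({n_ij} | m) = N! * 2^h * prod_i m_i! / ((2N)! * prod_{i<=j} n_ij!)

with h the number of heterozygotes. The Monte-Carlo test repeatedly
re-pairs the 2N observed alleles into N random genotypes and counts
arrays no more probable than the observed one, with the add-one rule
p = (1 + #{P_perm <= P_obs}) / (B + 1) so p is never zero. Below a
configurable state-space bound the conditional distribution is instead
enumerated exhaustively and the p-value is exact.

The LD test works on unphased two-locus genotype counts: the statistic is
the log-likelihood-ratio G of the genotype-by-genotype contingency table,
and the null is generated by permuting one locus's genotype column across
individuals (which preserves both margins, so only the sum of O*log(O)
terms varies).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .str_data import GenotypeTable, StrAllele, StrDataError

__all__ = [
    "TestResult",
    "MultipleTestSummary",
    "hwe_exact_mc",
    "hwe_exact_enumerate",
    "ld_permutation_test",
    "bonferroni_threshold",
    "multiple_test_summary",
]

_EPS = 1e-9  # tie tolerance on log-probability statistics


@dataclass(frozen=True)
class TestResult:
    """Outcome of one exact/permutation test."""

    target: str                      # locus or "locusA|locusB"
    statistic: float                 # log conditional probability (HWE) or G (LD)
    p_value: float
    n_permutations: int              # 0 for exhaustive enumeration
    seed: int | None = None
    method: str = "monte_carlo"
    degenerate: bool = False         # monomorphic / single-configuration case
    significant_after_correction: bool | None = None


@dataclass(frozen=True)
class MultipleTestSummary:
    results: tuple[TestResult, ...]
    alpha: float
    m: int
    threshold: float
    n_significant_raw: int
    n_significant_corrected: int


def _locus_codes(gt: GenotypeTable, locus: str) -> tuple[np.ndarray, int]:
    """Usable diploid calls at a locus as an (n, 2) array of allele codes."""
    calls = gt.usable_calls(locus)
    if not calls:
        raise StrDataError(f"no usable calls at locus {locus!r}")
    alleles = sorted(
        {c.allele_a for c in calls} | {c.allele_b for c in calls},
        key=StrAllele.sort_key,
    )
    index = {a: i for i, a in enumerate(alleles)}
    codes = np.array([[index[c.allele_a], index[c.allele_b]] for c in calls])
    return codes, len(alleles)


def _pairing_statistic(a: np.ndarray, b: np.ndarray, k: int, logfact: np.ndarray) -> np.ndarray:
    """h*log(2) - sum log(n_ij!) for each row of paired allele codes.

    ``a``, ``b`` are (B, N) allele codes for the two chromosomes of each
    genotype; only the terms that vary across re-pairings of a fixed
    allele multiset are included.
    """
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    cell = lo * k + hi
    n_rows = cell.shape[0]
    offset = (np.arange(n_rows) * (k * k))[:, None]
    counts = np.bincount((cell + offset).ravel(), minlength=n_rows * k * k)
    counts = counts.reshape(n_rows, k * k)
    het = (lo != hi).sum(axis=1)
    return het * math.log(2.0) - logfact[counts].sum(axis=1)


def hwe_exact_mc(
    gt: GenotypeTable,
    locus: str,
    n_permutations: int = 10_000,
    seed: int = 0,
    method: str = "auto",
    enumeration_bound: int = 500_000,
) -> TestResult:
    """Exact test of Hardy-Weinberg proportions at one locus.

    ``method`` is ``"monte_carlo"``, ``"enumerate"`` or ``"auto"`` (use
    exhaustive enumeration when the number of distinct pairings of the
    allele multiset is below ``enumeration_bound``, Monte Carlo
    otherwise). A monomorphic locus has a single attainable configuration
    and returns p = 1 flagged degenerate.
    """
    if method not in ("auto", "monte_carlo", "enumerate"):
        raise ValueError(f"unknown method {method!r}")
    codes, k = _locus_codes(gt, locus)
    n = codes.shape[0]
    if k == 1:
        return TestResult(locus, 0.0, 1.0, 0, seed, "degenerate", True)
    if method == "enumerate" or (
        method == "auto" and _enumeration_size(codes, k) <= enumeration_bound
    ):
        return hwe_exact_enumerate(gt, locus)
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    if n < 2:
        raise StrDataError("need at least 2 usable diploid calls")

    logfact = gammaln(np.arange(n + 2, dtype=float) + 1.0)  # logfact[c] = log(c!)
    t_obs = float(_pairing_statistic(codes[:, :1].T, codes[:, 1:].T, k, logfact)[0])

    pool = np.sort(codes.ravel())  # canonical order: invariant to row permutation
    rng = np.random.default_rng(seed)
    n_le = 0
    # chunked so the (chunk, K*K) bincount workspace stays small
    chunk = max(1, min(n_permutations, 4_000_000 // (k * k)))
    done = 0
    while done < n_permutations:
        b = min(chunk, n_permutations - done)
        order = np.argsort(rng.random((b, pool.size)), axis=1)
        perm = pool[order]
        t = _pairing_statistic(perm[:, 0::2], perm[:, 1::2], k, logfact)
        n_le += int((t <= t_obs + _EPS).sum())
        done += b
    p = (1 + n_le) / (n_permutations + 1)
    return TestResult(locus, t_obs, p, n_permutations, seed, "monte_carlo")


def _enumeration_size(codes: np.ndarray, k: int) -> float:
    """Rough count of genotype tables with the observed allele counts."""
    m = np.bincount(codes.ravel(), minlength=k)
    # upper bound: product over cells of (min margin + 1), capped
    size = 1.0
    for i in range(k):
        for j in range(i, k):
            size *= min(m[i], m[j]) + 1
            if size > 1e12:
                return size
    return size


def _enumerate_tables(m: Sequence[int], k: int):
    """Yield all symmetric genotype-count tables with allele counts ``m``.

    A table is a dict {(i,j): n_ij} over i<=j with 2*n_ii + sum_{j!=i}
    n_ij = m_i.
    """
    cells = [(i, j) for i in range(k) for j in range(i, k)]

    def rec(idx: int, remaining: list[int], table: dict):
        if idx == len(cells):
            if all(r == 0 for r in remaining):
                yield dict(table)
            return
        i, j = cells[idx]
        # (i, k-1) is the last cell touching allele i; its count must close out
        last_of_row = j == k - 1
        top = remaining[i] // 2 if i == j else min(remaining[i], remaining[j])
        for n in range(top + 1):
            table[(i, j)] = n
            if i == j:
                remaining[i] -= 2 * n
            else:
                remaining[i] -= n
                remaining[j] -= n
            if not last_of_row or remaining[i] == 0:
                yield from rec(idx + 1, remaining, table)
            if i == j:
                remaining[i] += 2 * n
            else:
                remaining[i] += n
                remaining[j] += n
        del table[(i, j)]

    yield from rec(0, list(int(x) for x in m), {})


def _table_log_prob(table: dict, m: np.ndarray, n: int) -> float:
    """Log conditional probability of a genotype table given allele counts."""
    two_n = int(m.sum())
    h = sum(v for (i, j), v in table.items() if i != j)
    lp = (
        math.lgamma(n + 1)
        + h * math.log(2.0)
        + sum(math.lgamma(int(mi) + 1) for mi in m)
        - math.lgamma(two_n + 1)
        - sum(math.lgamma(v + 1) for v in table.values())
    )
    return lp


def hwe_exact_enumerate(gt: GenotypeTable, locus: str) -> TestResult:
    """Exhaustively enumerated conditional exact HWE test (small loci only).

    p = sum of conditional probabilities of all genotype tables no more
    probable than the observed one.
    """
    codes, k = _locus_codes(gt, locus)
    n = codes.shape[0]
    if k == 1:
        return TestResult(locus, 0.0, 1.0, 0, None, "degenerate", True)
    m = np.bincount(codes.ravel(), minlength=k)

    obs: dict[tuple[int, int], int] = {}
    for a, b in codes:
        key = (min(a, b), max(a, b))
        obs[key] = obs.get(key, 0) + 1
    lp_obs = _table_log_prob(obs, m, n)

    p = 0.0
    total = 0.0
    for table in _enumerate_tables(m, k):
        lp = _table_log_prob(table, m, n)
        total += math.exp(lp)
        if lp <= lp_obs + _EPS:
            p += math.exp(lp)
    if abs(total - 1.0) > 1e-8:
        raise AssertionError(f"enumeration mass {total} != 1")
    return TestResult(locus, lp_obs, min(p, 1.0), 0, None, "enumeration")


def ld_permutation_test(
    gt: GenotypeTable,
    locus_a: str,
    locus_b: str,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> TestResult:
    """Permutation test of linkage disequilibrium between two loci.

    Statistic: likelihood-ratio G on the genotype-by-genotype contingency
    table over individuals usable at both loci; null by permuting locus
    B's genotypes across individuals. If either locus shows a single
    genotype among the shared individuals the test is degenerate (p = 1).
    """
    target = f"{locus_a}|{locus_b}"
    ja, jb = gt.locus_index(locus_a), gt.locus_index(locus_b)
    pairs = [
        (row[ja], row[jb])
        for row in gt.calls
        if row[ja].is_usable and row[jb].is_usable
    ]
    if len(pairs) < 2:
        raise StrDataError(f"fewer than 2 samples usable at both {locus_a} and {locus_b}")

    def encode(calls):
        seen: dict = {}
        out = []
        for c in calls:
            key = (c.allele_a, c.allele_b)
            out.append(seen.setdefault(key, len(seen)))
        return np.array(out), len(seen)

    ga, ka = encode([p[0] for p in pairs])
    gb, kb = encode([p[1] for p in pairs])
    if ka < 2 or kb < 2:
        return TestResult(target, 0.0, 1.0, 0, seed, "degenerate", True)
    n = len(pairs)

    def olog_o(joint_counts: np.ndarray) -> np.ndarray:
        c = joint_counts.astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(c > 0, c * np.log(c), 0.0)
        return t.sum(axis=-1)

    joint = np.bincount(ga * kb + gb, minlength=ka * kb)
    ra = np.bincount(ga, minlength=ka).astype(float)
    rb = np.bincount(gb, minlength=kb).astype(float)
    margin_term = (
        (ra * np.log(ra, where=ra > 0, out=np.zeros_like(ra))).sum()
        + (rb * np.log(rb, where=rb > 0, out=np.zeros_like(rb))).sum()
        - n * math.log(n)
    )
    g_obs = 2.0 * (float(olog_o(joint[None, :])[0]) - margin_term)

    rng = np.random.default_rng(seed)
    n_ge = 0
    chunk = max(1, min(n_permutations, 4_000_000 // (ka * kb)))
    done = 0
    while done < n_permutations:
        b = min(chunk, n_permutations - done)
        order = np.argsort(rng.random((b, n)), axis=1)
        perm_gb = gb[order]
        cell = ga[None, :] * kb + perm_gb
        offset = (np.arange(b) * (ka * kb))[:, None]
        counts = np.bincount((cell + offset).ravel(), minlength=b * ka * kb)
        g_perm = 2.0 * (olog_o(counts.reshape(b, ka * kb)) - margin_term)
        n_ge += int((g_perm >= g_obs - _EPS).sum())
        done += b
    p = (1 + n_ge) / (n_permutations + 1)
    return TestResult(target, g_obs, p, n_permutations, seed, "permutation")


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-test significance threshold alpha/m."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    return alpha / m


def multiple_test_summary(
    results: Sequence[TestResult], alpha: float = 0.05, m: int | None = None
) -> MultipleTestSummary:
    """Annotate test results with Bonferroni significance flags.

    ``m`` defaults to the number of results; it is an explicit argument
    because published screens sometimes correct by another count (e.g.
    the sample size).
    """
    results = list(results)
    if m is None:
        m = len(results)
    thr = bonferroni_threshold(alpha, m)
    annotated = tuple(
        replace(r, significant_after_correction=r.p_value < thr) for r in results
    )
    return MultipleTestSummary(
        results=annotated,
        alpha=alpha,
        m=m,
        threshold=thr,
        n_significant_raw=sum(r.p_value < alpha for r in results),
        n_significant_corrected=sum(r.significant_after_correction for r in annotated),
    )
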