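"""Domain types and I/O for forensic STR genotype and allele-frequency data.

STR alleles are named by repeat count, with microvariants written as
``<repeats>.<extra bases>`` (e.g. ``9.3`` is nine full repeats plus three
bases) and peaks outside the kit's allelic ladder recorded as ``OL``.
Alleles are kept as exact integer pairs — ``9.3`` is a label, not the
number 9.3 — so equality, hashing and ordering are exact.

Genotype tables are wide delimited files (CSV/TSV/XLSX), one row per
individual and two columns per locus (``<locus>_1``/``<locus>_2`` by
default, with an optional ``<locus>_3`` for tri-allelic records).
Off-ladder and tri-allelic calls are routed into :class:`AnomalyRecord`
entries and excluded from frequency arithmetic, never dropped silently.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "StrAllele",
    "GenotypeCall",
    "GenotypeTable",
    "FrequencyTable",
    "AnomalyRecord",
    "StrDataError",
    "AlleleParseError",
    "parse_allele",
    "format_allele",
    "read_genotypes",
    "write_genotypes",
    "read_frequency_table",
    "write_frequency_table",
    "detect_anomalies",
]


class StrDataError(ValueError):
    """Malformed STR data (bad allele label, inconsistent table, ...)."""


class AlleleParseError(StrDataError):
    """An allele label could not be parsed."""


@dataclass(frozen=True, order=False)
class StrAllele:
    """An STR allele: full repeat units plus 0-3 partial-repeat bases.

    ``is_off_ladder`` marks a peak outside the allelic ladder; such
    alleles carry no repeat information, compare unequal to every named
    allele, and are excluded from frequency computations.
    """

    repeat_units: int = 0
    partial_bases: int = 0
    is_off_ladder: bool = False

    def __post_init__(self) -> None:
        if self.is_off_ladder:
            return
        if self.repeat_units < 0:
            raise StrDataError(f"negative repeat count: {self.repeat_units}")
        if self.partial_bases not in (0, 1, 2, 3):
            raise StrDataError(
                f"partial_bases must be in 0..3, got {self.partial_bases}"
            )

    def sort_key(self) -> tuple[int, int, int]:
        # off-ladder alleles sort last; they have no meaningful order
        if self.is_off_ladder:
            return (1, 0, 0)
        return (0, self.repeat_units, self.partial_bases)

    def __lt__(self, other: "StrAllele") -> bool:
        return self.sort_key() < other.sort_key()

    def __str__(self) -> str:
        return format_allele(self)


OL = StrAllele(is_off_ladder=True)


def parse_allele(text: str) -> StrAllele:
    """Parse an allele label: ``"8"``, ``"9.3"``, ``"31.2"`` or ``"OL"``.

    Raises :class:`AlleleParseError` for anything else (the partial-repeat
    digit must be a single digit 1-3; ``"9.35"`` and ``"9.0"`` are invalid
    labels).
    """
    token = str(text).strip()
    if not token:
        raise AlleleParseError("empty allele label")
    if token.upper() == "OL":
        return OL
    head, dot, tail = token.partition(".")
    try:
        units = int(head)
    except ValueError:
        raise AlleleParseError(f"malformed allele label {token!r}") from None
    if units < 0:
        raise AlleleParseError(f"negative allele label {token!r}")
    if not dot:
        return StrAllele(units, 0)
    if tail not in ("1", "2", "3"):
        raise AlleleParseError(
            f"malformed allele label {token!r}: partial-repeat part must be a single digit 1-3"
        )
    return StrAllele(units, int(tail))


def format_allele(a: StrAllele) -> str:
    """Inverse of :func:`parse_allele`; integer alleles print without a dot."""
    if a.is_off_ladder:
        return "OL"
    if a.partial_bases:
        return f"{a.repeat_units}.{a.partial_bases}"
    return str(a.repeat_units)


@dataclass(frozen=True)
class GenotypeCall:
    """An unordered diploid call; ``extra_alleles`` non-empty marks tri-allelic.

    A missing call has both alleles ``None``. The two alleles are stored
    sorted so ``(a, b)`` and ``(b, a)`` construct equal objects.
    """

    allele_a: StrAllele | None = None
    allele_b: StrAllele | None = None
    extra_alleles: tuple[StrAllele, ...] = ()

    def __post_init__(self) -> None:
        a, b = self.allele_a, self.allele_b
        if (a is None) != (b is None):
            raise StrDataError("half-missing genotype call")
        if a is not None and b is not None and b < a:
            object.__setattr__(self, "allele_a", b)
            object.__setattr__(self, "allele_b", a)
        object.__setattr__(
            self, "extra_alleles", tuple(sorted(self.extra_alleles, key=StrAllele.sort_key))
        )

    @property
    def is_missing(self) -> bool:
        return self.allele_a is None

    @property
    def is_tri_allelic(self) -> bool:
        return bool(self.extra_alleles)

    @property
    def has_off_ladder(self) -> bool:
        if self.is_missing:
            return False
        return (
            self.allele_a.is_off_ladder
            or self.allele_b.is_off_ladder
            or any(x.is_off_ladder for x in self.extra_alleles)
        )

    @property
    def is_usable(self) -> bool:
        """Usable for diploid frequency/test arithmetic."""
        return not (self.is_missing or self.is_tri_allelic or self.has_off_ladder)

    @property
    def is_heterozygous(self) -> bool:
        if not self.is_usable:
            raise StrDataError("heterozygosity undefined for anomalous/missing call")
        return self.allele_a != self.allele_b

    def alleles(self) -> tuple[StrAllele, ...]:
        if self.is_missing:
            return ()
        return (self.allele_a, self.allele_b, *self.extra_alleles)


MISSING_CALL = GenotypeCall()


@dataclass(frozen=True)
class AnomalyRecord:
    """A QC flag at (sample, locus): an off-ladder peak or a tri-allelic call."""

    sample_id: str
    locus: str
    kind: str  # "off_ladder" | "tri_allelic"
    detail: str = ""


@dataclass
class GenotypeTable:
    """Diploid STR calls for a cohort: samples x loci grid of :class:`GenotypeCall`."""

    sample_ids: list[str]
    loci: list[str]
    calls: list[list[GenotypeCall]]  # calls[i][j]: sample i, locus j
    population_label: str = ""

    def __post_init__(self) -> None:
        if len(self.sample_ids) < 1:
            raise StrDataError("genotype table needs at least one sample")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise StrDataError("duplicate sample ids")
        if len(self.calls) != len(self.sample_ids):
            raise StrDataError("calls/sample_ids length mismatch")
        for row in self.calls:
            if len(row) != len(self.loci):
                raise StrDataError("every sample needs a call slot for every locus")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise StrDataError(f"locus {locus!r} not in table") from None

    def locus_calls(self, locus: str) -> list[GenotypeCall]:
        j = self.locus_index(locus)
        return [row[j] for row in self.calls]

    def usable_calls(self, locus: str) -> list[GenotypeCall]:
        return [c for c in self.locus_calls(locus) if c.is_usable]


@dataclass
class FrequencyTable:
    """Per-locus allele relative frequencies with the allele count 2N behind them."""

    frequencies: dict[str, dict[StrAllele, float]]
    sample_size_2n: dict[str, int] = field(default_factory=dict)
    population_label: str = ""

    def __post_init__(self) -> None:
        for locus, freqs in self.frequencies.items():
            if not freqs:
                raise StrDataError(f"locus {locus!r} has no alleles")
            for a, f in freqs.items():
                if a.is_off_ladder:
                    raise StrDataError(f"off-ladder allele in frequency table at {locus}")
                if f <= 0:
                    raise StrDataError(f"non-positive frequency at {locus}/{a}")

    @property
    def loci(self) -> list[str]:
        return list(self.frequencies)

    def locus_frequencies(self, locus: str) -> dict[StrAllele, float]:
        try:
            return self.frequencies[locus]
        except KeyError:
            raise StrDataError(f"locus {locus!r} not in frequency table") from None

    def allele_counts(self) -> dict[str, int]:
        """Number of distinct alleles (Na) per locus."""
        return {locus: len(freqs) for locus, freqs in self.frequencies.items()}

    def validate_sums(self, tol: float = 1e-6) -> None:
        for locus, freqs in self.frequencies.items():
            s = sum(freqs.values())
            if abs(s - 1.0) > tol:
                raise StrDataError(f"frequencies at {locus} sum to {s:.6f}, not 1")


# ---------------------------------------------------------------------------
# genotype table I/O


def _call_from_tokens(
    tokens: Sequence[str], where: str
) -> GenotypeCall:
    alleles: list[StrAllele] = []
    for tok in tokens:
        tok = "" if tok is None else str(tok).strip()
        if tok in ("", "nan", "NA", "-"):
            continue
        try:
            alleles.append(parse_allele(tok))
        except AlleleParseError as e:
            raise StrDataError(f"{where}: {e}") from None
    if not alleles:
        return MISSING_CALL
    if len(alleles) == 1:
        # single recorded allele: treat as homozygous (standard STR convention)
        alleles = [alleles[0], alleles[0]]
    return GenotypeCall(alleles[0], alleles[1], tuple(alleles[2:]))


def read_genotypes(
    path: str | Path,
    loci: Sequence[str] | None = None,
    suffixes: tuple[str, str] = ("_1", "_2"),
    extra_suffix: str = "_3",
    sample_column: str | None = None,
    population_label: str = "",
) -> GenotypeTable:
    """Read a wide genotype file (CSV, TSV or XLSX) into a :class:`GenotypeTable`.

    The header names loci via ``<locus><suffix>`` column pairs, with an
    optional ``<locus><extra_suffix>`` column for third alleles. ``loci``,
    if given, fixes the panel and its order; columns outside it are an
    error. Errors report 1-based data row numbers.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, dtype=str)
    else:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
        df = pd.read_csv(path, sep=sep, dtype=str)

    cols = list(df.columns)
    if sample_column is None:
        sample_column = cols[0]
    s1, s2 = suffixes

    found: dict[str, dict[str, str]] = {}
    for col in cols:
        if col == sample_column:
            continue
        for suf, slot in ((s1, "a"), (s2, "b"), (extra_suffix, "x")):
            if col.endswith(suf) and len(col) > len(suf):
                found.setdefault(col[: -len(suf)], {})[slot] = col
                break
        else:
            raise StrDataError(f"column {col!r} matches no locus/suffix convention")

    for locus, slots in found.items():
        if "a" not in slots or "b" not in slots:
            raise StrDataError(f"locus {locus!r} lacks a complete {s1}/{s2} column pair")
    if loci is None:
        loci = list(found)
    else:
        unknown = set(found) - set(loci)
        if unknown:
            raise StrDataError(f"unknown locus columns: {sorted(unknown)}")
        missing = set(loci) - set(found)
        if missing:
            raise StrDataError(f"loci missing from file: {sorted(missing)}")
        loci = list(loci)

    sample_ids = [str(s) for s in df[sample_column]]
    calls: list[list[GenotypeCall]] = []
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        out_row = []
        for locus in loci:
            slots = found[locus]
            tokens = [row[slots["a"]], row[slots["b"]]]
            if "x" in slots:
                tokens.append(row[slots["x"]])
            out_row.append(_call_from_tokens(tokens, f"row {i}, locus {locus}"))
        calls.append(out_row)
    return GenotypeTable(sample_ids, loci, calls, population_label)


def write_genotypes(gt: GenotypeTable, path: str | Path,
                    suffixes: tuple[str, str] = ("_1", "_2"),
                    extra_suffix: str = "_3") -> None:
    """Write a genotype table as wide CSV (two columns per locus, third where needed)."""
    path = Path(path)
    needs_extra = {
        locus for locus in gt.loci
        if any(c.is_tri_allelic for c in gt.locus_calls(locus))
    }
    header = ["sample_id"]
    for locus in gt.loci:
        header += [locus + suffixes[0], locus + suffixes[1]]
        if locus in needs_extra:
            header.append(locus + extra_suffix)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for sid, row in zip(gt.sample_ids, gt.calls):
            out = [sid]
            for locus, call in zip(gt.loci, row):
                if call.is_missing:
                    out += ["", ""]
                else:
                    out += [format_allele(call.allele_a), format_allele(call.allele_b)]
                if locus in needs_extra:
                    out.append(
                        format_allele(call.extra_alleles[0]) if call.extra_alleles else ""
                    )
            w.writerow(out)


# ---------------------------------------------------------------------------
# frequency table I/O (Tables 1-4 layout: allele labels as rows, loci as columns)


def read_frequency_table(
    path: str | Path,
    sum_tolerance: float = 0.005,
    renormalize: bool = False,
    population_label: str = "",
) -> FrequencyTable:
    """Read a loci-by-allele frequency matrix CSV.

    Rows are allele labels, columns are loci, blank cells mean the allele
    is absent at that locus. An optional row labelled ``2N`` carries the
    per-locus allele counts. Published tables are rounded, so per-locus
    sums within ``sum_tolerance`` of 1 are accepted (and renormalized only
    if ``renormalize`` is set); sums outside it raise naming the locus.
    """
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise StrDataError("frequency table needs an allele column plus >=1 locus")
    label_col = df.columns[0]
    loci = [c for c in df.columns if c != label_col]
    freqs: dict[str, dict[StrAllele, float]] = {locus: {} for locus in loci}
    two_n: dict[str, int] = {}
    for _, row in df.iterrows():
        label = str(row[label_col]).strip()
        if label == "2N":
            for locus in loci:
                v = row[locus]
                if isinstance(v, str) and v.strip():
                    two_n[locus] = int(float(v))
            continue
        allele = parse_allele(label)
        for locus in loci:
            v = row[locus]
            if v is None or (isinstance(v, float) and pd.isna(v)):
                continue
            v = str(v).strip()
            if not v:
                continue
            f = float(v)
            if f < 0:
                raise StrDataError(f"negative frequency at {locus}/{label}")
            if f > 0:
                freqs[locus][allele] = f
    freqs = {locus: d for locus, d in freqs.items() if d}
    if not freqs:
        raise StrDataError("frequency table contains no frequencies")
    for locus, d in freqs.items():
        s = sum(d.values())
        if abs(s - 1.0) > sum_tolerance:
            raise StrDataError(
                f"frequencies at locus {locus} sum to {s:.5f}, outside tolerance {sum_tolerance}"
            )
        if renormalize:
            freqs[locus] = {a: f / s for a, f in d.items()}
    return FrequencyTable(freqs, two_n, population_label)


def write_frequency_table(ft: FrequencyTable, path: str | Path, decimals: int = 5) -> None:
    """Write a frequency table in the allele-rows x locus-columns CSV layout."""
    if not ft.frequencies:
        raise StrDataError("cannot write an empty frequency table")
    loci = ft.loci
    all_alleles = sorted(
        {a for d in ft.frequencies.values() for a in d}, key=StrAllele.sort_key
    )
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["Allele"] + loci)
        if ft.sample_size_2n:
            w.writerow(["2N"] + [ft.sample_size_2n.get(locus, "") for locus in loci])
        for a in all_alleles:
            row = [format_allele(a)]
            for locus in loci:
                f = ft.frequencies[locus].get(a)
                row.append(f"{f:.{decimals}f}" if f is not None else "")
            w.writerow(row)


def detect_anomalies(gt: GenotypeTable) -> list[AnomalyRecord]:
    """List off-ladder and tri-allelic calls, ordered by sample then locus."""
    records: list[AnomalyRecord] = []
    for sid, row in zip(gt.sample_ids, gt.calls):
        for locus, call in zip(gt.loci, row):
            if call.is_missing:
                continue
            labels = "/".join(format_allele(a) for a in call.alleles())
            if call.has_off_ladder:
                records.append(AnomalyRecord(sid, locus, "off_ladder", labels))
            if call.is_tri_allelic:
                records.append(AnomalyRecord(sid, locus, "tri_allelic", labels))
    return records
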