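"""Strain genotype tables, multilocus genotype (MLG) assignment and
per-date diversity statistics.

A strain is a diploid individual scored at a fixed, ordered set of
microsatellite loci; each locus genotype is an unordered pair of integer
fragment lengths (base pairs) or missing as a unit.  Strains with a
missing locus are excluded from MLG-based statistics: a lenient match
could create false clonal groups.
"""

from __future__ import annotations

import csv
import datetime as dt
import math
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MatingType",
    "LocusGenotype",
    "StrainRecord",
    "MlgPartition",
    "GenotypeFormatError",
    "read_genotype_table",
    "write_genotype_table",
    "assign_mlgs",
    "genotypic_richness",
    "allele_summary",
    "unbiased_heterozygosity",
    "diversity_by_date",
    "mlg_recurrence",
    "complete_strains",
]


class MatingType(str, Enum):
    """Heterothallic mating type of a strain."""

    PLUS = "MT+"
    MINUS = "MT-"
    UNKNOWN = "unknown"


class GenotypeFormatError(ValueError):
    """Raised for malformed genotype tables."""


@dataclass(frozen=True)
class LocusGenotype:
    """Unordered diploid genotype at one locus; ``alleles is None`` == missing."""

    locus: str
    alleles: tuple[int, int] | None

    def __post_init__(self) -> None:
        if self.alleles is not None:
            a, b = self.alleles
            if a <= 0 or b <= 0:
                raise ValueError(
                    f"allele lengths must be positive at locus {self.locus!r}: {self.alleles}"
                )
            if a > b:  # store order-insensitively
                object.__setattr__(self, "alleles", (b, a))

    @property
    def is_missing(self) -> bool:
        return self.alleles is None


@dataclass(frozen=True)
class StrainRecord:
    """One isolated strain with its diploid multilocus genotype."""

    strain_id: str
    sampling_date: dt.date
    genotype: tuple[LocusGenotype, ...]
    mating_type: MatingType = MatingType.UNKNOWN

    @property
    def loci(self) -> tuple[str, ...]:
        return tuple(g.locus for g in self.genotype)

    @property
    def is_complete(self) -> bool:
        return all(not g.is_missing for g in self.genotype)

    def mlg_key(self) -> tuple[tuple[int, int], ...] | None:
        """Hashable complete-genotype key, or None if any locus is missing."""
        if not self.is_complete:
            return None
        return tuple(g.alleles for g in self.genotype)  # type: ignore[misc]


@dataclass
class MlgPartition:
    """Partition of complete-genotype strains into multilocus genotypes."""

    mlg_ids: dict[str, str]
    excluded_strains: list[str] = field(default_factory=list)

    @property
    def n_mlg(self) -> int:
        return len(set(self.mlg_ids.values()))

    @property
    def n_included(self) -> int:
        return len(self.mlg_ids)

    def members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = defaultdict(list)
        for sid, mlg in self.mlg_ids.items():
            out[mlg].append(sid)
        return dict(out)


# ---------------------------------------------------------------------------
# I/O


_MT_ALIASES = {
    "+": MatingType.PLUS,
    "mt+": MatingType.PLUS,
    "plus": MatingType.PLUS,
    "mt_plus": MatingType.PLUS,
    "-": MatingType.MINUS,
    "mt-": MatingType.MINUS,
    "minus": MatingType.MINUS,
    "mt_minus": MatingType.MINUS,
    "": MatingType.UNKNOWN,
    "unknown": MatingType.UNKNOWN,
    "na": MatingType.UNKNOWN,
}


def _parse_mt(raw: str) -> MatingType:
    try:
        return _MT_ALIASES[raw.strip().lower()]
    except KeyError:
        raise GenotypeFormatError(f"unrecognised mating type value {raw!r}") from None


def _locus_columns(header: Sequence[str], reserved: set[str]) -> dict[str, list[int]]:
    """Map locus name -> column indices, preserving header order.

    Allele columns are named ``<locus>.<suffix>`` (e.g. ``PNm1.a1``); any
    column without a dot that is not reserved is rejected.
    """
    loci: dict[str, list[int]] = {}
    for i, col in enumerate(header):
        if col in reserved:
            continue
        if "." not in col:
            raise GenotypeFormatError(
                f"column {col!r} is neither metadata nor a '<locus>.<allele>' pair"
            )
        locus = col.rsplit(".", 1)[0]
        loci.setdefault(locus, []).append(i)
    for locus, cols in loci.items():
        if len(cols) != 2:
            raise GenotypeFormatError(
                f"locus {locus!r} has {len(cols)} allele column(s); expected exactly 2"
            )
    return loci


def read_genotype_table(
    path,
    *,
    id_col: str = "strain_id",
    date_col: str = "date",
    mt_col: str = "mt",
    missing_sentinels: Sequence[str] = ("0", ""),
) -> list[StrainRecord]:
    """Read a CSV genotype table (one row per strain, two columns per locus).

    Missing alleles are coded by ``missing_sentinels``; a half-missing pair
    is rejected because alleles are missing as a unit.
    """
    sentinels = set(missing_sentinels)
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and any(f.strip() for f in r)]
    rows = [r for r in rows if not r[0].lstrip().startswith("#")]
    if not rows:
        raise GenotypeFormatError(f"empty genotype table: {path}")
    header = [c.strip() for c in rows[0]]
    for required in (id_col, date_col):
        if required not in header:
            raise GenotypeFormatError(f"missing required column {required!r}")
    reserved = {id_col, date_col, mt_col}
    loci = _locus_columns(header, reserved)
    idx = {c: i for i, c in enumerate(header)}

    strains: list[StrainRecord] = []
    seen: set[str] = set()
    for row_no, row in enumerate(rows[1:], start=2):
        get = lambda col: row[idx[col]].strip() if idx[col] < len(row) else ""
        sid = get(id_col)
        if sid in seen:
            raise GenotypeFormatError(f"duplicate strain_id {sid!r} (row {row_no})")
        seen.add(sid)
        try:
            date = dt.date.fromisoformat(get(date_col))
        except ValueError:
            raise GenotypeFormatError(
                f"unparseable date {get(date_col)!r} in row {row_no} (strain {sid!r})"
            ) from None
        mt = _parse_mt(get(mt_col)) if mt_col in idx else MatingType.UNKNOWN
        genotype = []
        for locus, (c1, c2) in loci.items():
            raw = (row[c1].strip(), row[c2].strip())
            if all(v in sentinels for v in raw):
                genotype.append(LocusGenotype(locus, None))
            elif any(v in sentinels for v in raw):
                raise GenotypeFormatError(
                    f"half-missing genotype at locus {locus!r}, row {row_no}"
                )
            else:
                try:
                    pair = (int(raw[0]), int(raw[1]))
                except ValueError:
                    raise GenotypeFormatError(
                        f"non-integer allele {raw!r} at locus {locus!r}, row {row_no}"
                    ) from None
                genotype.append(LocusGenotype(locus, pair))
        strains.append(StrainRecord(sid, date, tuple(genotype), mt))
    return strains


def write_genotype_table(strains: Sequence[StrainRecord], path) -> None:
    """Inverse of :func:`read_genotype_table` (missing coded as ``0,0``)."""
    if not strains:
        raise ValueError("no strains to write")
    loci = strains[0].loci
    header = ["strain_id", "date", "mt"]
    for locus in loci:
        header += [f"{locus}.a1", f"{locus}.a2"]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for s in strains:
            if s.loci != loci:
                raise ValueError(f"inconsistent locus order for strain {s.strain_id!r}")
            row = [s.strain_id, s.sampling_date.isoformat(), s.mating_type.value]
            for g in s.genotype:
                row += ["0", "0"] if g.is_missing else [str(g.alleles[0]), str(g.alleles[1])]
            w.writerow(row)


def complete_strains(strains: Iterable[StrainRecord]) -> list[StrainRecord]:
    """Strains with a complete genotype at every locus."""
    return [s for s in strains if s.is_complete]


# ---------------------------------------------------------------------------
# MLG assignment and diversity


def assign_mlgs(strains: Sequence[StrainRecord]) -> MlgPartition:
    """Group strains with identical complete genotypes into MLGs.

    Strains with any missing locus are excluded.  Labels are assigned in
    order of first occurrence, so the partition is deterministic for a
    given input order; group membership is order-invariant.
    """
    if not strains:
        raise ValueError("cannot assign MLGs to an empty strain collection")
    loci = strains[0].loci
    key_to_label: dict[tuple, str] = {}
    mlg_ids: dict[str, str] = {}
    excluded: list[str] = []
    width = max(3, len(str(len(strains))))
    for s in strains:
        if s.loci != loci:
            raise ValueError(f"inconsistent locus order for strain {s.strain_id!r}")
        key = s.mlg_key()
        if key is None:
            excluded.append(s.strain_id)
            continue
        if key not in key_to_label:
            key_to_label[key] = f"MLG{len(key_to_label) + 1:0{width}d}"
        mlg_ids[s.strain_id] = key_to_label[key]
    return MlgPartition(mlg_ids=mlg_ids, excluded_strains=excluded)


def genotypic_richness(partition: MlgPartition, n_strains: int | None = None) -> float:
    """(MLG - 1) / (N - 1); NaN when fewer than two strains are included."""
    n = partition.n_included if n_strains is None else n_strains
    if partition.n_mlg > n:
        raise ValueError(f"n_mlg ({partition.n_mlg}) exceeds n_strains ({n})")
    if n < 2:
        return math.nan
    return (partition.n_mlg - 1) / (n - 1)


def unbiased_heterozygosity(frequencies: Sequence[float], n_individuals: int) -> float:
    """uHe = (2N / (2N - 1)) * (1 - sum p_i^2) for N genotyped diploids."""
    if n_individuals < 1:
        return math.nan
    he = 1.0 - float(np.sum(np.square(np.asarray(frequencies, dtype=float))))
    return (2 * n_individuals) / (2 * n_individuals - 1) * he


@dataclass
class LocusSummary:
    """Allele-level summary of one locus over a strain collection."""

    locus: str
    n_typed: int  # genotyped individuals
    allele_counts: dict[int, int]
    frequencies: dict[int, float]
    uhe: float  # NaN when no strain is genotyped

    @property
    def n_alleles(self) -> int:
        return len(self.allele_counts)


def allele_summary(strains: Sequence[StrainRecord]) -> dict[str, LocusSummary]:
    """Per-locus allele counts, frequencies and unbiased heterozygosity.

    Each genotyped diploid contributes two gene copies; missing genotypes
    are excluded.  A locus with zero genotyped strains is flagged with
    ``uhe = NaN`` rather than raising.
    """
    if not strains:
        raise ValueError("allele_summary requires at least one strain")
    loci = strains[0].loci
    out: dict[str, LocusSummary] = {}
    for j, locus in enumerate(loci):
        counts: Counter[int] = Counter()
        n_typed = 0
        for s in strains:
            g = s.genotype[j]
            if g.is_missing:
                continue
            n_typed += 1
            counts.update(g.alleles)
        if n_typed == 0:
            out[locus] = LocusSummary(locus, 0, {}, {}, math.nan)
            continue
        total = 2 * n_typed
        freqs = {a: c / total for a, c in sorted(counts.items())}
        uhe = unbiased_heterozygosity(list(freqs.values()), n_typed)
        out[locus] = LocusSummary(locus, n_typed, dict(sorted(counts.items())), freqs, uhe)
    return out


def diversity_by_date(strains: Sequence[StrainRecord]) -> pd.DataFrame:
    """Per-sampling-date diversity table: N, MLG, richness, per-locus counts/uHe."""
    if not strains:
        raise ValueError("no strains")
    loci = strains[0].loci
    by_date: dict[dt.date, list[StrainRecord]] = defaultdict(list)
    for s in strains:
        by_date[s.sampling_date].append(s)
    rows = []
    for date in sorted(by_date):
        group = by_date[date]
        part = assign_mlgs(group)
        row: dict[str, object] = {
            "date": date.isoformat(),
            "n_strains": len(group),
            "n_complete": part.n_included,
            "n_mlg": part.n_mlg if part.n_included else 0,
            "r_mlg": genotypic_richness(part) if part.n_included else math.nan,
        }
        summ = allele_summary(group)
        for locus in loci:
            row[f"{locus}.n_alleles"] = summ[locus].n_alleles
            row[f"{locus}.uhe"] = summ[locus].uhe
        rows.append(row)
    return pd.DataFrame(rows)


def mlg_recurrence(
    partition: MlgPartition,
    strains: Sequence[StrainRecord],
    grouping: Mapping[dt.date, Hashable] | Callable[[dt.date], Hashable] | None = None,
) -> pd.DataFrame:
    """Period x period matrix of shared MLG counts.

    Diagonal entries count the MLGs observed within a period; off-diagonal
    entries count MLGs observed in both periods.  ``grouping`` maps each
    sampling date to a period label (default: calendar year).
    """
    if grouping is None:
        to_period: Callable[[dt.date], Hashable] = lambda d: d.year
    elif callable(grouping):
        to_period = grouping
    else:
        def to_period(d: dt.date, _m=grouping) -> Hashable:
            try:
                return _m[d]
            except KeyError:
                raise ValueError(f"sampling date {d.isoformat()} has no period mapping") from None

    membership: dict[Hashable, set[str]] = defaultdict(set)
    by_id = {s.strain_id: s for s in strains}
    for sid, mlg in partition.mlg_ids.items():
        strain = by_id.get(sid)
        if strain is None:
            raise ValueError(f"strain {sid!r} in partition but not in collection")
        membership[to_period(strain.sampling_date)].add(mlg)
    periods = sorted(membership, key=str)
    n = len(periods)
    mat = np.zeros((n, n), dtype=int)
    for i, p in enumerate(periods):
        for j, q in enumerate(periods):
            mat[i, j] = len(membership[p] & membership[q])
    return pd.DataFrame(mat, index=periods, columns=periods)
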