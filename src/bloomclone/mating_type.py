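"""Mating-type assignment from the MT-marker fragment pattern and
per-date MT-ratio statistics.

MT+ is determined by the presence of a single diagnostic allele
("allele A") in the multiallelic marker region; its base-pair size is a
required configuration value with no default.
"""

from __future__ import annotations

import csv
import datetime as dt
import math
import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_core import MatingType, StrainRecord

__all__ = [
    "MtMarkerGenotype",
    "assign_mating_type",
    "read_mt_table",
    "mt_ratio",
    "mt_ratio_summary",
]


@dataclass(frozen=True)
class MtMarkerGenotype:
    """Fragment sizes observed at the MT marker region for one strain."""

    strain_id: str
    sampling_date: dt.date
    fragment_sizes: frozenset[int]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.fragment_sizes):
            raise ValueError(f"fragment sizes must be positive: {sorted(self.fragment_sizes)}")


def assign_mating_type(genotype: MtMarkerGenotype, allele_a_size: int) -> MatingType:
    """MT+ iff the configured allele-A fragment size is present."""
    sizes = genotype.fragment_sizes
    if not sizes:
        raise ValueError(f"strain {genotype.strain_id!r}: empty fragment set")
    if len(sizes) > 2:
        raise ValueError(
            f"strain {genotype.strain_id!r}: {len(sizes)} fragments at a diploid "
            "marker suggests contamination"
        )
    return MatingType.PLUS if allele_a_size in sizes else MatingType.MINUS


def read_mt_table(path) -> list[MtMarkerGenotype]:
    """CSV with columns strain_id, date, fragments (semicolon-separated sizes)."""
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row_no, row in enumerate(reader, start=2):
            sizes = frozenset(
                int(s) for s in row["fragments"].split(";") if s.strip()
            )
            out.append(
                MtMarkerGenotype(
                    strain_id=row["strain_id"].strip(),
                    sampling_date=dt.date.fromisoformat(row["date"].strip()),
                    fragment_sizes=sizes,
                )
            )
    return out


def mt_ratio(
    assignments: Iterable[tuple[dt.date, MatingType]] | Sequence[StrainRecord],
    date_from: dt.date | None = None,
    date_to: dt.date | None = None,
) -> pd.DataFrame:
    """Per-date MT+ ratio with an exact two-sided binomial test against 0.5.

    Accepts (date, MatingType) pairs or StrainRecords carrying MT labels;
    UNKNOWN assignments are ignored.  Dates outside the optional range are
    dropped; a requested range containing a date with zero assigned
    strains simply yields no row for it.
    """
    pairs: list[tuple[dt.date, MatingType]] = []
    for item in assignments:
        if isinstance(item, StrainRecord):
            pairs.append((item.sampling_date, item.mating_type))
        else:
            pairs.append(item)
    by_date: dict[dt.date, list[MatingType]] = defaultdict(list)
    for date, mt in pairs:
        if date_from is not None and date < date_from:
            continue
        if date_to is not None and date > date_to:
            continue
        if mt is not MatingType.UNKNOWN:
            by_date[date].append(mt)
    rows = []
    for date in sorted(by_date):
        mts = by_date[date]
        n_plus = sum(1 for m in mts if m is MatingType.PLUS)
        n_minus = len(mts) - n_plus
        if n_plus + n_minus == 0:
            warnings.warn(f"no assigned strains on {date.isoformat()}; skipped")
            continue
        p = stats.binomtest(n_plus, n_plus + n_minus, 0.5, alternative="two-sided").pvalue
        rows.append(
            {
                "date": date.isoformat(),
                "n_plus": n_plus,
                "n_minus": n_minus,
                "ratio_plus": n_plus / (n_plus + n_minus),
                "binomial_p": float(p),
            }
        )
    return pd.DataFrame(rows, columns=["date", "n_plus", "n_minus", "ratio_plus", "binomial_p"])


def mt_ratio_summary(per_date: pd.DataFrame, pooled: bool = False) -> dict[str, float]:
    """Mean/std of the MT+ ratio over a set of dates.

    Default is the unweighted mean of per-date ratios; ``pooled=True``
    instead pools strains across dates before taking the ratio.
    """
    if per_date.empty:
        raise ValueError("no dates to summarise")
    if pooled:
        n_plus = int(per_date["n_plus"].sum())
        n_tot = int(per_date["n_plus"].sum() + per_date["n_minus"].sum())
        return {"mean_ratio": n_plus / n_tot, "std_ratio": math.nan, "n_dates": len(per_date)}
    ratios = per_date["ratio_plus"].to_numpy(dtype=float)
    std = float(np.std(ratios, ddof=1)) if ratios.size > 1 else math.nan
    return {"mean_ratio": float(ratios.mean()), "std_ratio": std, "n_dates": len(per_date)}
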