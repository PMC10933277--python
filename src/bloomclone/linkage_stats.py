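"""Standardized index of association with a Monte-Carlo permutation test.

The statistic compares the observed variance Vd of pairwise locus-mismatch
counts against the variance Ve expected under linkage equilibrium:

    ia_s = [1 / (n_loci - 1)] * [(Vd / Ve) - 1]

A locus "differs" between two strains iff their unordered diploid allele
pairs are not identical (binary mismatch, no partial credit).  Vd is the
population variance over all strain pairs; Ve = sum_j d_j (1 - d_j) with
d_j the proportion of pairs differing at locus j.  The null distribution
is built by independently permuting each locus column across strains;
d_j, and hence Ve, are invariant under these permutations, so only Vd is
recomputed per replicate.
"""

from __future__ import annotations

import datetime as dt
import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_core import StrainRecord

__all__ = [
    "MismatchDistribution",
    "IaResult",
    "genotype_codes",
    "pairwise_mismatch",
    "index_of_association",
    "ia_by_date",
    "correlate_series",
]


@dataclass
class MismatchDistribution:
    """All pairwise mismatch counts K and per-locus difference proportions d_j."""

    counts: np.ndarray  # K per unordered pair, length C(m, 2)
    d: np.ndarray  # per-locus proportion of differing pairs
    loci: tuple[str, ...]

    @property
    def n_pairs(self) -> int:
        return self.counts.size


@dataclass
class IaResult:
    vd: float
    ve: float
    ia_s: float
    p_value: float
    n_iterations: int
    seed: int
    n_strains: int
    n_loci: int
    undefined: bool = False  # Ve == 0: every locus monomorphic in the sample


def genotype_codes(strains: Sequence[StrainRecord]) -> tuple[np.ndarray, tuple[str, ...]]:
    """Integer-code unordered diploid genotypes: (m, n_loci) array.

    Equal codes at a locus <=> identical unordered allele pairs.  All
    strains must be complete at the same locus set.
    """
    if len(strains) < 2:
        raise ValueError("at least 2 strains required")
    loci = strains[0].loci
    m = len(strains)
    codes = np.empty((m, len(loci)), dtype=np.int64)
    for j in range(len(loci)):
        mapping: dict[tuple[int, int], int] = {}
        for i, s in enumerate(strains):
            if s.loci != loci:
                raise ValueError(f"inconsistent loci for strain {s.strain_id!r}")
            g = s.genotype[j]
            if g.is_missing:
                raise ValueError(
                    f"strain {s.strain_id!r} is missing locus {loci[j]!r}; "
                    "mismatch statistics require complete genotypes"
                )
            codes[i, j] = mapping.setdefault(g.alleles, len(mapping))
    return codes, loci


def _pair_mismatch_counts(codes: np.ndarray) -> np.ndarray:
    """K over all unordered pairs, by direct enumeration."""
    m = codes.shape[0]
    iu, ju = np.triu_indices(m, k=1)
    return (codes[iu] != codes[ju]).sum(axis=1)


def _matching_pairs(column: np.ndarray) -> int:
    """Number of unordered pairs with equal code in one column."""
    counts = np.bincount(column)
    return int((counts * (counts - 1) // 2).sum())


def pairwise_mismatch(strains: Sequence[StrainRecord]) -> MismatchDistribution:
    """Mismatch counts for all C(m, 2) strain pairs plus per-locus d_j."""
    codes, loci = genotype_codes(strains)
    counts = _pair_mismatch_counts(codes)
    t = counts.size
    d = np.array([1.0 - _matching_pairs(codes[:, j]) / t for j in range(codes.shape[1])])
    return MismatchDistribution(counts=counts, d=d, loci=loci)


def _vd_decomposition(codes: np.ndarray) -> tuple[float, np.ndarray, float, float]:
    """Return (Vd, d, const, scale) where for any locus-wise permutation
    Vd_perm = const + scale * sum_{j<k} M_jk and M_jk is the number of
    pairs matching at both j and k.

    Derivation: K = sum_j I_j over pair indicators, so
    Var K = sum_j d_j(1-d_j) + 2 sum_{j<k} (P11_jk - d_j d_k) where
    P11_jk = (T - M_j - M_k + M_jk)/T is the proportion of pairs
    differing at both loci.  Under locus-wise permutation d_j, M_j are
    invariant; only M_jk varies.
    """
    m, n_loci = codes.shape
    t = m * (m - 1) // 2
    match = np.array([_matching_pairs(codes[:, j]) for j in range(n_loci)], dtype=float)
    d = 1.0 - match / t
    ve = float(np.sum(d * (1.0 - d)))
    const = ve
    for j in range(n_loci):
        for k in range(j + 1, n_loci):
            const += 2.0 * ((t - match[j] - match[k]) / t - d[j] * d[k])
    return ve, d, const, 2.0 / t


def _joint_matches(codes: np.ndarray) -> int:
    """sum_{j<k} M_jk: pairs matching at both loci of each locus pair."""
    n_loci = codes.shape[1]
    total = 0
    for j in range(n_loci):
        base = int(codes[:, j].max()) + 1
        for k in range(j + 1, n_loci):
            joint = codes[:, j] * (int(codes[:, k].max()) + 1) + codes[:, k]
            total += _matching_pairs(joint)
    return total


def index_of_association(
    strains: Sequence[StrainRecord],
    n_iterations: int = 1000,
    seed: int | None = None,
) -> IaResult:
    """Standardized index of association with a locus-permutation test.

    p = (1 + #{Vd_perm >= Vd_obs}) / (1 + n_iterations)  (add-one rule,
    so p is never exactly 0).  When every locus is monomorphic (Ve = 0)
    the result is flagged ``undefined`` instead of raising.
    """
    if seed is None:
        raise ValueError("seed is required for reproducibility")
    codes, loci = genotype_codes(strains)
    m, n_loci = codes.shape
    if n_loci < 2:
        raise ValueError("index of association requires >= 2 loci")

    ve, d, const, scale = _vd_decomposition(codes)
    vd = float(np.var(_pair_mismatch_counts(codes)))
    if ve == 0.0:
        return IaResult(vd, 0.0, math.nan, math.nan, n_iterations, seed, m, n_loci, True)

    ia_s = (1.0 / (n_loci - 1)) * (vd / ve - 1.0)

    rng = np.random.default_rng(seed)
    perm = codes.copy()
    n_ge = 0
    # permutation changes only the joint-match term of the variance
    for _ in range(n_iterations):
        for j in range(n_loci):
            rng.shuffle(perm[:, j])
        vd_perm = const + scale * _joint_matches(perm)
        if vd_perm >= vd - 1e-12:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_iterations)
    return IaResult(vd, ve, ia_s, p, n_iterations, seed, m, n_loci, False)


def ia_by_date(
    strains: Sequence[StrainRecord],
    n_iterations: int = 1000,
    seed: int = 0,
    min_strains: int = 3,
) -> pd.DataFrame:
    """Index of association per sampling date (complete genotypes only)."""
    by_date: dict[dt.date, list[StrainRecord]] = defaultdict(list)
    for s in strains:
        if s.is_complete:
            by_date[s.sampling_date].append(s)
    rows = []
    for i, date in enumerate(sorted(by_date)):
        group = by_date[date]
        if len(group) < min_strains:
            continue
        res = index_of_association(group, n_iterations=n_iterations, seed=seed + i)
        rows.append(
            {
                "date": date.isoformat(),
                "n": len(group),
                "Vd": res.vd,
                "Ve": res.ve,
                "ia_s": res.ia_s,
                "p_value": res.p_value,
                "significant_at_0.05": (not res.undefined) and res.p_value < 0.05,
                "undefined": res.undefined,
            }
        )
    return pd.DataFrame(rows)


def correlate_series(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation after dropping positions undefined in either series.

    Returns NaN when either series has zero variance.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("series must have equal length")
    keep = np.isfinite(xa) & np.isfinite(ya)
    xa, ya = xa[keep], ya[keep]
    if xa.size < 3:
        raise ValueError("need >= 3 paired defined values")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        return math.nan
    return float(stats.pearsonr(xa, ya).statistic)
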