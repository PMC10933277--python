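"""Population differentiation and ordination.

Pairwise F_ST between allele-frequency profiles (Nei-style multilocus
G_ST), classical principal coordinates analysis, percolation-threshold
networks from distance matrices, and Evanno delta-K post-processing of
externally produced clustering ln-likelihood tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree

from .genotype_core import StrainRecord

__all__ = [
    "AlleleFrequencyProfile",
    "PairwiseFstMatrix",
    "PcoaResult",
    "PercolationNetwork",
    "profile_from_strains",
    "profile_from_percentages",
    "pairwise_fst",
    "fst_matrix",
    "pcoa",
    "percolation_network",
    "evanno_delta_k",
    "best_k",
]


@dataclass
class AlleleFrequencyProfile:
    """Per-locus allele frequencies for one sample.

    ``freqs[locus][allele] -> frequency``; frequencies at each locus sum
    to 1.  ``size[locus]`` is the number of observations behind the
    estimate (gene copies or amplicons).
    """

    freqs: dict[str, dict[object, float]]
    size: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for locus, fr in self.freqs.items():
            if not fr:
                raise ValueError(f"locus {locus!r} has no alleles")
            tot = sum(fr.values())
            if any(v < 0 for v in fr.values()):
                raise ValueError(f"negative frequency at locus {locus!r}")
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"frequencies at locus {locus!r} sum to {tot}, not 1")

    @property
    def loci(self) -> list[str]:
        return list(self.freqs)


def profile_from_strains(strains: Sequence[StrainRecord]) -> AlleleFrequencyProfile:
    """Allele frequencies from diploid genotypes (2 gene copies per strain).

    Loci with zero genotyped strains are omitted with a warning.
    """
    if not strains:
        raise ValueError("no strains")
    loci = strains[0].loci
    freqs: dict[str, dict[object, float]] = {}
    size: dict[str, int] = {}
    for j, locus in enumerate(loci):
        counts: dict[int, int] = {}
        for s in strains:
            g = s.genotype[j]
            if g.is_missing:
                continue
            for a in g.alleles:
                counts[a] = counts.get(a, 0) + 1
        total = sum(counts.values())
        if total == 0:
            warnings.warn(f"locus {locus!r} has no observations; omitted")
            continue
        freqs[locus] = {a: c / total for a, c in sorted(counts.items())}
        size[locus] = total
    if not freqs:
        raise ValueError("no genotyped locus in input")
    return AlleleFrequencyProfile(freqs=freqs, size=size)


def profile_from_percentages(
    pct: Mapping[str, Mapping[object, float]],
    size: Mapping[str, int] | None = None,
) -> AlleleFrequencyProfile:
    """Rescale per-locus percentage tables (e.g. pooled amplicon output) to sum to 1."""
    freqs: dict[str, dict[object, float]] = {}
    for locus, table in pct.items():
        kept = {a: float(v) for a, v in table.items() if v > 0}
        tot = sum(kept.values())
        if tot == 0:
            warnings.warn(f"locus {locus!r} has zero total frequency; omitted")
            continue
        freqs[locus] = {a: v / tot for a, v in kept.items()}
    if not freqs:
        raise ValueError("no locus with nonzero frequencies")
    return AlleleFrequencyProfile(freqs=freqs, size=dict(size or {}))


# ---------------------------------------------------------------------------
# F_ST


def _expected_het(freq_vector: np.ndarray) -> float:
    return 1.0 - float(np.sum(freq_vector**2))


def pairwise_fst(a: AlleleFrequencyProfile, b: AlleleFrequencyProfile) -> float:
    """Nei-style multilocus G_ST between two frequency profiles.

    Per shared locus: Hs = mean of the two within-sample expected
    heterozygosities, Ht = expected heterozygosity of the unweighted mean
    frequency vector; F_ST = sum(Ht - Hs) / sum(Ht) over loci.  Returns 0
    when both samples are fixed for the same allele everywhere.
    """
    shared = [l for l in a.freqs if l in b.freqs]
    if not shared:
        raise ValueError("profiles share no locus")
    ht_sum = 0.0
    hs_sum = 0.0
    for locus in shared:
        alleles = sorted(set(a.freqs[locus]) | set(b.freqs[locus]), key=str)
        pa = np.array([a.freqs[locus].get(al, 0.0) for al in alleles])
        pb = np.array([b.freqs[locus].get(al, 0.0) for al in alleles])
        hs_sum += 0.5 * (_expected_het(pa) + _expected_het(pb))
        ht_sum += _expected_het((pa + pb) / 2.0)
    if ht_sum == 0.0:
        return 0.0
    fst = (ht_sum - hs_sum) / ht_sum
    if fst < 0:
        if fst < -1e-9:
            warnings.warn(f"negative F_ST estimate {fst:.3g} clipped to 0")
        fst = 0.0
    return min(fst, 1.0)


@dataclass
class PairwiseFstMatrix:
    """Symmetric, zero-diagonal F_ST matrix over labelled samples."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def fst_matrix(
    profiles: Mapping[str, AlleleFrequencyProfile] | Sequence[tuple[str, AlleleFrequencyProfile]],
) -> PairwiseFstMatrix:
    """All pairwise F_ST values between labelled profiles."""
    items = list(profiles.items()) if isinstance(profiles, Mapping) else list(profiles)
    labels = [lab for lab, _ in items]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate sample labels")
    if len(items) < 2:
        raise ValueError("need >= 2 profiles")
    n = len(items)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = pairwise_fst(items[i][1], items[j][1])
    return PairwiseFstMatrix(labels=labels, values=mat)


# ---------------------------------------------------------------------------
# PCoA


@dataclass
class PcoaResult:
    labels: list[str]
    coordinates: np.ndarray  # samples x axes, positive eigenvalues only
    eigenvalues: np.ndarray  # all eigenvalues, descending
    pct_variance: np.ndarray  # per positive axis, % of positive-eigenvalue total

    def to_frame(self) -> pd.DataFrame:
        cols = [f"axis{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.labels, columns=cols)


def pcoa(matrix: PairwiseFstMatrix | pd.DataFrame | np.ndarray, labels=None) -> PcoaResult:
    """Classical metric multidimensional scaling of a distance matrix.

    Squares the distances, double-centers (-1/2 J D^2 J), eigendecomposes,
    and scales eigenvectors by sqrt(eigenvalue).  Negative eigenvalues are
    reported but excluded from axes and the variance denominator; no
    Lingoes/Cailliez correction is applied.
    """
    if isinstance(matrix, PairwiseFstMatrix):
        d = matrix.values
        labels = matrix.labels
    elif isinstance(matrix, pd.DataFrame):
        d = matrix.to_numpy(dtype=float)
        labels = list(matrix.index)
    else:
        d = np.asarray(matrix, dtype=float)
        labels = list(labels) if labels is not None else [str(i) for i in range(d.shape[0])]
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")

    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-12, 1e-10 * max(abs(evals[0]), 1.0))
    pos = evals > tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    pct = 100.0 * evals[pos] / evals[pos].sum() if pos.any() else np.array([])
    return PcoaResult(labels=labels, coordinates=coords, eigenvalues=evals, pct_variance=pct)


# ---------------------------------------------------------------------------
# Percolation network


@dataclass
class PercolationNetwork:
    graph: nx.Graph  # retained edges; weight = distance, similarity = 1 - distance
    threshold: float  # largest MST edge = minimal connecting threshold
    labels: list[str]

    def edge_list(self) -> pd.DataFrame:
        rows = [
            {"node_a": a, "node_b": b, "fst": w["weight"], "similarity": w["similarity"]}
            for a, b, w in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["node_a", "node_b", "fst", "similarity"])


def percolation_network(matrix: PairwiseFstMatrix | pd.DataFrame) -> PercolationNetwork:
    """Keep all edges with distance <= the minimal threshold that connects the graph.

    That threshold equals the largest edge of a minimum spanning tree of
    the distance matrix.  Edge similarity is 1 - distance.
    """
    if isinstance(matrix, pd.DataFrame):
        matrix = PairwiseFstMatrix(labels=list(matrix.index), values=matrix.to_numpy(dtype=float))
    d = matrix.values
    if d.shape[0] < 2:
        raise ValueError("need >= 2 nodes")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains missing entries")
    # csgraph drops explicit zeros: offset so every off-diagonal edge survives
    offset = 1.0
    mst = minimum_spanning_tree(d + offset - np.eye(d.shape[0]) * offset).toarray()
    threshold = float(mst[mst > 0].max() - offset)
    g = nx.Graph()
    g.add_nodes_from(matrix.labels)
    n = d.shape[0]
    eps = 1e-12
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] <= threshold + eps:
                g.add_edge(
                    matrix.labels[i],
                    matrix.labels[j],
                    weight=float(d[i, j]),
                    similarity=float(1.0 - d[i, j]),
                )
    return PercolationNetwork(graph=g, threshold=threshold, labels=matrix.labels)


# ---------------------------------------------------------------------------
# Evanno delta-K


def evanno_delta_k(table: Mapping[int, Sequence[float]] | pd.DataFrame) -> pd.DataFrame:
    """Second-difference statistic over replicate clustering ln-likelihoods.

    delta_K(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K)),
    defined for interior K with sd > 0.  Input is either a mapping
    K -> replicate ln-probabilities or a two-column DataFrame (K, lnP)
    with repeated K rows.  Returns a table with a ``delta_k`` column
    (NaN at the boundary / zero-sd K values).
    """
    if isinstance(table, pd.DataFrame):
        kcol, lcol = table.columns[:2]
        grouped: dict[int, list[float]] = {
            int(k): list(v) for k, v in table.groupby(kcol)[lcol]
        }
    else:
        grouped = {int(k): list(v) for k, v in table.items()}
    ks = sorted(grouped)
    if len(ks) < 3:
        raise ValueError("need >= 3 K values")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("K values must be consecutive")
    for k in ks:
        if len(grouped[k]) < 2:
            raise ValueError(f"K={k} has a single replicate; sd undefined")
    mean = {k: float(np.mean(grouped[k])) for k in ks}
    sd = {k: float(np.std(grouped[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        if k == ks[0] or k == ks[-1]:
            dk = math.nan
        elif sd[k] == 0.0:
            warnings.warn(f"sd(L) = 0 at K={k}; delta_K undefined there")
            dk = math.nan
        else:
            dk = abs(mean[k + 1] - 2.0 * mean[k] + mean[k - 1]) / sd[k]
        rows.append(
            {"K": k, "n_reps": len(grouped[k]), "mean_lnp": mean[k], "sd_lnp": sd[k], "delta_k": dk}
        )
    return pd.DataFrame(rows)


def best_k(evanno_table: pd.DataFrame) -> int:
    """argmax of delta_K over interior K values with defined delta_K."""
    defined = evanno_table.dropna(subset=["delta_k"])
    if defined.empty:
        raise ValueError("delta_K undefined for every interior K")
    return int(defined.loc[defined["delta_k"].idxmax(), "K"])
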