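"""Forward simulation of clonal vs. sexually recombining bloom populations.

Generates diploid strain tables at microsatellite loci plus an
MT-determining locus, with tunable clonal skew, sexual-recombination
rate between MT+ and MT- strains, stepwise (+/-1 motif unit) mutation at
meiosis, and pooled amplicon reads with PCR slippage and point
substitutions.  All outputs are pure functions of (config, seed), and
per-date truth (genotypes, MT labels, pooled allele frequencies) is
retained so every downstream statistic can be checked against it.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .genotype_core import LocusGenotype, MatingType, StrainRecord

__all__ = [
    "SimLocus",
    "SimConfig",
    "SimTruth",
    "simulate_population_series",
    "equilibrium_strains",
    "simulate_pooled_reads",
    "make_mock_mixture",
    "reads_to_fasta",
    "reads_to_tsv",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class SimLocus:
    """One simulated microsatellite locus; allele = number of repeat units."""

    name: str
    motif: str
    flank5: str
    flank3: str
    min_units: int = 5
    max_units: int = 20

    def length_of(self, units: int) -> int:
        return len(self.flank5) + len(self.flank3) + units * len(self.motif)

    def units_of(self, length: int) -> int:
        span = length - len(self.flank5) - len(self.flank3)
        if span <= 0 or span % len(self.motif):
            raise ValueError(f"length {length} is not a whole-unit allele of {self.name}")
        return span // len(self.motif)

    def sequence_of(self, units: int) -> str:
        return self.flank5 + self.motif * units + self.flank3


def default_loci(n_loci: int = 5, rng: np.random.Generator | None = None) -> list[SimLocus]:
    """Convenience locus panel with distinct motifs and random flanks."""
    rng = rng or np.random.default_rng(0)
    motifs = ["AC", "AG", "AT", "TG", "TC", "CAA", "GAT", "CT"]
    loci = []
    for i in range(n_loci):
        f5 = "".join(rng.choice(list(_BASES), size=20))
        f3 = "".join(rng.choice(list(_BASES), size=20))
        loci.append(SimLocus(name=f"SL{i + 1}", motif=motifs[i % len(motifs)], flank5=f5, flank3=f3))
    return loci


@dataclass
class SimConfig:
    loci: list[SimLocus] = field(default_factory=default_loci)
    pop_size: int = 100
    sample_size: int | None = None  # strains "isolated" per date; None = whole census
    n_dates: int = 5
    sex_rate: float = 1.0  # probability an offspring is sexual
    clonal_skew: float = 1.0  # Dirichlet concentration over parents; lower = more skewed
    mutation_rate: float = 0.0  # per allele per meiosis, stepwise +/-1 unit
    mt_allele_a_size: int = 230
    mt_other_sizes: tuple[int, ...] = (210, 214, 218)
    depth: int = 10_000
    slippage_rate: float = 0.0  # per read, +/-1 motif unit
    substitution_rate: float = 0.0  # per base per read
    seed: int = 0
    start_date: dt.date = dt.date(2000, 1, 1)
    date_interval_days: int = 14

    def __post_init__(self) -> None:
        for p in (self.sex_rate, self.slippage_rate, self.substitution_rate, self.mutation_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.clonal_skew <= 0:
            raise ValueError("clonal_skew must be positive")

    def date_of(self, index: int) -> dt.date:
        return self.start_date + dt.timedelta(days=index * self.date_interval_days)


@dataclass
class SimTruth:
    """Per-date ground truth of a simulated series."""

    strains_by_date: dict[dt.date, list[StrainRecord]]
    pooled_freqs: dict[dt.date, dict[str, dict[int, float]]]  # date -> locus -> length -> freq
    mt_counts: dict[dt.date, tuple[int, int]]  # (n_plus, n_minus)
    events: list[str] = field(default_factory=list)

    @property
    def dates(self) -> list[dt.date]:
        return sorted(self.strains_by_date)


def _pooled_from_units(units: np.ndarray, loci: Sequence[SimLocus]) -> dict[str, dict[int, float]]:
    """Exact pooled length frequencies from a (pop, n_loci, 2) units array."""
    out: dict[str, dict[int, float]] = {}
    n_copies = units.shape[0] * 2
    for j, locus in enumerate(loci):
        vals, counts = np.unique(units[:, j, :], return_counts=True)
        out[locus.name] = {locus.length_of(int(u)): int(c) / n_copies for u, c in zip(vals, counts)}
    return out


def _records_from_units(
    units: np.ndarray, mt: np.ndarray, config: SimConfig, date: dt.date, prefix: str
) -> list[StrainRecord]:
    records = []
    for i in range(units.shape[0]):
        genotype = tuple(
            LocusGenotype(loc.name, (loc.length_of(int(units[i, j, 0])), loc.length_of(int(units[i, j, 1]))))
            for j, loc in enumerate(config.loci)
        )
        is_plus = config.mt_allele_a_size in (int(mt[i, 0]), int(mt[i, 1]))
        records.append(
            StrainRecord(
                strain_id=f"{prefix}s{i:04d}",
                sampling_date=date,
                genotype=genotype,
                mating_type=MatingType.PLUS if is_plus else MatingType.MINUS,
            )
        )
    return records


def _draw_founders(config: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    n = config.pop_size
    units = np.empty((n, len(config.loci), 2), dtype=np.int64)
    for j, loc in enumerate(config.loci):
        units[:, j, :] = rng.integers(loc.min_units, loc.max_units + 1, size=(n, 2))
    # one copy is allele A with probability 1/2 -> founding MT ratio ~ 50:50
    mt = np.empty((n, 2), dtype=np.int64)
    mt[:, 0] = rng.choice(config.mt_other_sizes, size=n)
    has_a = rng.random(n) < 0.5
    mt[:, 1] = np.where(has_a, config.mt_allele_a_size, rng.choice(config.mt_other_sizes, size=n))
    return units, mt


def simulate_population_series(config: SimConfig) -> tuple[list[StrainRecord], SimTruth]:
    """Simulate ``n_dates`` generations and return all strains plus truth.

    Date 0 holds founders with independent alleles per locus.  Each later
    date replaces the population: an offspring is clonal with probability
    ``1 - sex_rate`` (parent drawn from a Dirichlet(clonal_skew)-weighted
    multinomial) and otherwise sexual, taking one allele per locus from a
    random MT+ and a random MT- parent with stepwise mutation.  When a
    mating type is absent, requested sexual offspring fall back to clonal
    copying and the event is logged.
    """
    rng = np.random.default_rng(config.seed)
    units, mt = _draw_founders(config, rng)
    truth = SimTruth(strains_by_date={}, pooled_freqs={}, mt_counts={})
    all_records: list[StrainRecord] = []

    for di in range(config.n_dates):
        date = config.date_of(di)
        if di > 0:
            units, mt = _next_generation(units, mt, config, rng, truth.events, di)
        records = _records_from_units(units, mt, config, date, prefix=f"d{di:02d}")
        # pooled frequencies and MT counts describe the full census (what
        # pooled sequencing sees); the strain table is the isolated subsample
        n_plus = sum(1 for r in records if r.mating_type is MatingType.PLUS)
        truth.pooled_freqs[date] = _pooled_from_units(units, config.loci)
        truth.mt_counts[date] = (n_plus, len(records) - n_plus)
        if config.sample_size is not None and config.sample_size < len(records):
            picked = rng.choice(len(records), size=config.sample_size, replace=False)
            records = [records[i] for i in sorted(picked)]
        truth.strains_by_date[date] = records
        all_records.extend(records)
    return all_records, truth


def _next_generation(
    units: np.ndarray,
    mt: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
    events: list[str],
    date_index: int,
) -> tuple[np.ndarray, np.ndarray]:
    n = config.pop_size
    n_parents = units.shape[0]
    weights = rng.dirichlet(np.full(n_parents, config.clonal_skew))
    plus_idx = np.flatnonzero(
        (mt[:, 0] == config.mt_allele_a_size) | (mt[:, 1] == config.mt_allele_a_size)
    )
    minus_idx = np.setdiff1d(np.arange(n_parents), plus_idx)
    sex_possible = plus_idx.size > 0 and minus_idx.size > 0

    new_units = np.empty((n, len(config.loci), 2), dtype=np.int64)
    new_mt = np.empty((n, 2), dtype=np.int64)
    is_sexual = rng.random(n) < config.sex_rate
    if is_sexual.any() and not sex_possible:
        events.append(
            f"date {date_index}: {int(is_sexual.sum())} sexual offspring skipped "
            "(one mating type absent); produced clonally"
        )
        is_sexual[:] = False

    clonal = np.flatnonzero(~is_sexual)
    if clonal.size:
        parents = rng.choice(n_parents, size=clonal.size, p=weights)
        new_units[clonal] = units[parents]
        new_mt[clonal] = mt[parents]

    sexual = np.flatnonzero(is_sexual)
    for i in sexual:
        pa = int(rng.choice(plus_idx))
        pb = int(rng.choice(minus_idx))
        for j, loc in enumerate(config.loci):
            a = int(units[pa, j, rng.integers(2)])
            b = int(units[pb, j, rng.integers(2)])
            if config.mutation_rate:
                if rng.random() < config.mutation_rate:
                    a = max(1, a + (1 if rng.random() < 0.5 else -1))
                if rng.random() < config.mutation_rate:
                    b = max(1, b + (1 if rng.random() < 0.5 else -1))
            new_units[i, j] = (a, b)
        new_mt[i, 0] = mt[pa, rng.integers(2)]
        new_mt[i, 1] = mt[pb, rng.integers(2)]
    return new_units, new_mt


def equilibrium_strains(
    n_strains: int,
    config: SimConfig | None = None,
    seed: int = 0,
    date: dt.date = dt.date(2000, 1, 1),
) -> list[StrainRecord]:
    """Strains with alleles drawn independently per locus (linkage equilibrium)."""
    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    cfg = replace(config, pop_size=n_strains)
    units, mt = _draw_founders(cfg, rng)
    return _records_from_units(units, mt, cfg, date, prefix="eq")


# ---------------------------------------------------------------------------
# Pooled reads


def _apply_read_errors(
    reads: dict[str, int],
    locus: SimLocus,
    units_by_seq: Mapping[str, int],
    config: SimConfig,
    rng: np.random.Generator,
) -> dict[str, int]:
    """Per-read PCR slippage (+/-1 unit) then per-base substitution."""
    out: dict[str, int] = {}

    def add(seq: str, count: int) -> None:
        if count > 0:
            out[seq] = out.get(seq, 0) + count

    slipped: dict[str, int] = {}
    for seq, count in reads.items():
        n_slip = rng.binomial(count, config.slippage_rate) if config.slippage_rate else 0
        if n_slip:
            up = rng.binomial(n_slip, 0.5)
            u = units_by_seq[seq]
            if up:
                slipped[locus.sequence_of(u + 1)] = slipped.get(locus.sequence_of(u + 1), 0) + up
            down = n_slip - up
            if down:
                target = locus.sequence_of(max(1, u - 1))
                slipped[target] = slipped.get(target, 0) + down
        add(seq, count - n_slip)
    for seq, count in slipped.items():
        add(seq, count)

    if not config.substitution_rate:
        return out

    final: dict[str, int] = {}
    for seq, count in out.items():
        p_any = 1.0 - (1.0 - config.substitution_rate) ** len(seq)
        n_mut = rng.binomial(count, p_any)
        if count - n_mut:
            final[seq] = final.get(seq, 0) + (count - n_mut)
        for _ in range(n_mut):
            pos = int(rng.integers(len(seq)))
            alt = _BASES[int(rng.integers(3))]
            if alt == seq[pos]:  # pick a different base
                alt = _BASES[(_BASES.index(seq[pos]) + 1) % 4]
            mutated = seq[:pos] + alt + seq[pos + 1 :]
            final[mutated] = final.get(mutated, 0) + 1
    return final


def _reads_from_freqs(
    freqs: Mapping[int, float],
    locus: SimLocus,
    config: SimConfig,
    rng: np.random.Generator,
) -> dict[str, int]:
    lengths = sorted(freqs)
    probs = np.array([freqs[l] for l in lengths], dtype=float)
    probs = probs / probs.sum()
    counts = rng.multinomial(config.depth, probs)
    reads: dict[str, int] = {}
    units_by_seq: dict[str, int] = {}
    for length, c in zip(lengths, counts):
        if c == 0:
            continue
        u = locus.units_of(length)
        seq = locus.sequence_of(u)
        reads[seq] = reads.get(seq, 0) + int(c)
        units_by_seq[seq] = u
    return _apply_read_errors(reads, locus, units_by_seq, config, rng)


def simulate_pooled_reads(
    truth: SimTruth, config: SimConfig, seed: int | None = None
) -> dict[dt.date, dict[str, dict[str, int]]]:
    """Dereplicated reads per date and locus, drawn from the true pooled
    frequencies with the configured error model."""
    if config.depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    loci = {l.name: l for l in config.loci}
    out: dict[dt.date, dict[str, dict[str, int]]] = {}
    for date in truth.dates:
        out[date] = {}
        for locus_name, freqs in truth.pooled_freqs[date].items():
            out[date][locus_name] = _reads_from_freqs(freqs, loci[locus_name], config, rng)
    return out


def make_mock_mixture(
    strain_genotypes: Sequence[Mapping[str, tuple[int, int]]],
    proportions: Sequence[float],
    config: SimConfig,
    seed: int | None = None,
) -> tuple[dict[str, dict[str, int]], dict[str, dict[int, float]]]:
    """Pool known diploid genotypes at given proportions and sequence the pool.

    Each genotype maps locus name -> (length, length).  Expected allele
    frequency = sum over strains of proportion x (1.0 homozygous, 0.5 per
    heterozygous allele).  Returns (reads per locus, expected frequencies).
    """
    if not strain_genotypes:
        raise ValueError("need >= 1 strain")
    props = np.asarray(proportions, dtype=float)
    if props.size != len(strain_genotypes):
        raise ValueError("one proportion per strain required")
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions sum to {props.sum()}, not 1")
    if config.depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    expected: dict[str, dict[int, float]] = {}
    for locus in config.loci:
        freq: dict[int, float] = {}
        for geno, prop in zip(strain_genotypes, props):
            a, b = geno[locus.name]
            freq[a] = freq.get(a, 0.0) + prop * (1.0 if a == b else 0.5)
            if a != b:
                freq[b] = freq.get(b, 0.0) + prop * 0.5
        expected[locus.name] = freq

    reads = {
        locus.name: _reads_from_freqs(expected[locus.name], locus, config, rng)
        for locus in config.loci
    }
    return reads, expected


# ---------------------------------------------------------------------------
# Writers (formats read by the amplicon pipeline)


def reads_to_fasta(reads: Mapping[str, int], path) -> None:
    """Dereplicated FASTA with usearch/vsearch-style ';size=N' annotations."""
    with open(path, "w") as fh:
        for i, (seq, count) in enumerate(sorted(reads.items(), key=lambda kv: (-kv[1], kv[0]))):
            fh.write(f">amp{i + 1};size={count}\n{seq}\n")


def reads_to_tsv(reads_by_sample: Mapping[str, Mapping[str, int]], path) -> None:
    """TSV (sequence, sample, count) for a single locus across samples."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["sequence", "sample", "count"])
        for sample in sorted(reads_by_sample):
            for seq, count in sorted(reads_by_sample[sample].items()):
                w.writerow([seq, sample, count])
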