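"""Pooled microsatellite amplicon calling.

From per-sample merged, primer-trimmed amplicon sequences to filtered,
median-normalised allele-frequency tables with homoplasy-aware allele
naming and recombinant-flank detection.  The filter chain is strictly
ordered: singleton removal -> repeat filter -> allele calling ->
median normalisation -> per-sample abundance filter; a report records
reads removed at every stage.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "LocusSpec",
    "AmpliconTable",
    "AlleleCall",
    "AlleleFrequencyTable",
    "FilterReport",
    "build_amplicon_table",
    "read_counts_tsv",
    "filter_singletons",
    "longest_repeat_run",
    "repeat_filter",
    "call_alleles",
    "normalize_and_filter",
    "merge_replicates",
    "flank_typing",
    "run_locus_pipeline",
]


@dataclass
class LocusSpec:
    """Configuration of one pooled-amplicon microsatellite locus."""

    name: str
    motif: str
    min_repeat_units: int = 3
    abundance_threshold_pct: float = 0.0
    flank_min_len: int = 10

    def __post_init__(self) -> None:
        if not self.motif:
            raise ValueError("repeat motif must be non-empty")
        if self.abundance_threshold_pct < 0:
            raise ValueError("abundance threshold must be >= 0")


@dataclass
class AmpliconTable:
    """Distinct amplicon sequences x samples count matrix for one locus."""

    locus: str
    counts: pd.DataFrame  # index = sequence, columns = sample names, int counts

    @property
    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class AlleleCall:
    """A called allele: a distinct retained sequence, named 'length.index'."""

    locus: str
    sequence: str
    fragment_length: int
    homoplasy_index: int
    allele_name: str
    repeat_units: int
    run_start: int  # [run_start, run_end) spans the longest repeat run
    run_end: int
    total_count: int
    flank5_type: str | None = None
    flank3_type: str | None = None
    recombinant: bool = False

    @property
    def flank5(self) -> str:
        return self.sequence[: self.run_start]

    @property
    def flank3(self) -> str:
        return self.sequence[self.run_end :]


@dataclass
class AlleleFrequencyTable:
    """Allele x sample percentages after normalisation (and optional filtering)."""

    locus: str
    percentages: pd.DataFrame  # index = allele_name, columns = samples, in %
    normalized_counts: pd.DataFrame
    raw_totals: pd.Series
    excluded_samples: list[str] = field(default_factory=list)


@dataclass
class FilterReport:
    """Reads surviving each stage, and percentage removed per stage."""

    locus: str
    stages: list[tuple[str, int]] = field(default_factory=list)  # (stage name, reads after)

    def add(self, stage: str, reads: int) -> None:
        self.stages.append((stage, reads))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        prev = None
        for stage, reads in self.stages:
            removed_pct = 0.0 if prev in (None, 0) else 100.0 * (prev - reads) / prev
            rows.append({"stage": stage, "reads": reads, "pct_removed": removed_pct})
            prev = reads
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Table construction


def _parse_fasta_counts(path) -> dict[str, int]:
    """Dereplicated FASTA: count from a ';size=N' header annotation, else 1."""
    counts: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        size = 1
        for part in rec.description.replace(",", ";").split(";"):
            part = part.strip()
            if part.startswith("size="):
                size = int(part[len("size=") :])
        seq = str(rec.seq).upper()
        counts[seq] = counts.get(seq, 0) + size
    return counts


def build_amplicon_table(
    per_sample: Mapping[str, object] | Mapping[str, Mapping[str, int]],
    locus: LocusSpec,
) -> AmpliconTable:
    """Build the sequence x sample count matrix.

    ``per_sample`` maps sample name to either a FASTA path (dereplicated,
    ``;size=N`` headers) or an in-memory ``{sequence: count}`` mapping.
    Duplicate listings of a sequence within a sample are summed; an empty
    sample yields a zero column with a warning.
    """
    if not per_sample:
        raise ValueError("no input samples")
    sample_counts: dict[str, dict[str, int]] = {}
    for sample, src in per_sample.items():
        if isinstance(src, Mapping):
            counts: dict[str, int] = {}
            for seq, c in src.items():
                counts[seq.upper()] = counts.get(seq.upper(), 0) + int(c)
        else:
            counts = _parse_fasta_counts(src)
        if not counts:
            warnings.warn(f"sample {sample!r} contains no sequences")
        sample_counts[sample] = counts
    sequences = sorted({s for c in sample_counts.values() for s in c})
    df = pd.DataFrame(
        {samp: [c.get(seq, 0) for seq in sequences] for samp, c in sample_counts.items()},
        index=sequences,
        dtype=np.int64,
    )
    return AmpliconTable(locus=locus.name, counts=df)


def read_counts_tsv(path, locus: LocusSpec) -> AmpliconTable:
    """TSV with columns sequence, sample, count (header required)."""
    per_sample: dict[str, dict[str, int]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            s = per_sample.setdefault(row["sample"], {})
            seq = row["sequence"].upper()
            s[seq] = s.get(seq, 0) + int(row["count"])
    if not per_sample:
        raise ValueError(f"no rows in {path}")
    return build_amplicon_table(per_sample, locus)


# ---------------------------------------------------------------------------
# Filters


def filter_singletons(table: AmpliconTable) -> AmpliconTable:
    """Drop sequences whose dataset-wide total count is exactly 1."""
    totals = table.counts.sum(axis=1)
    kept = table.counts.loc[totals > 1]
    if kept.empty and not table.counts.empty:
        warnings.warn(f"locus {table.locus}: all sequences are singletons")
    return AmpliconTable(locus=table.locus, counts=kept)


def longest_repeat_run(sequence: str, motif: str) -> tuple[int, int]:
    """(units, start) of the longest uninterrupted exact tandem run of motif.

    Runs must consist of contiguous in-frame copies; interrupted repeats
    count only their longest uninterrupted stretch.  Returns (0, -1) when
    the motif does not occur.
    """
    l = len(motif)
    n = len(sequence)
    best_units, best_start = 0, -1
    # scan every start so off-frame runs are not missed (e.g. motif "AA" in "TAAAA")
    for i in range(n - l + 1):
        if sequence[i : i + l] != motif:
            continue
        units = 1
        while sequence[i + units * l : i + (units + 1) * l] == motif:
            units += 1
        if units > best_units:
            best_units, best_start = units, i
    return best_units, best_start


def repeat_filter(table: AmpliconTable, locus: LocusSpec) -> tuple[AmpliconTable, pd.DataFrame]:
    """Drop sequences with fewer than ``min_repeat_units`` tandem motif copies.

    Returns the filtered table plus a per-retained-sequence frame with
    ``repeat_units``, ``run_start`` and ``run_end`` (used downstream for
    flank decomposition).  Sequences without the motif are removed.
    """
    keep, meta = [], []
    for seq in table.counts.index:
        units, start = longest_repeat_run(seq, locus.motif)
        if units >= locus.min_repeat_units:
            keep.append(seq)
            meta.append(
                {
                    "sequence": seq,
                    "repeat_units": units,
                    "run_start": start,
                    "run_end": start + units * len(locus.motif),
                }
            )
    kept = table.counts.loc[keep]
    info = pd.DataFrame(meta, columns=["sequence", "repeat_units", "run_start", "run_end"])
    if not info.empty:
        info = info.set_index("sequence")
    return AmpliconTable(locus=table.locus, counts=kept), info


def call_alleles(
    table: AmpliconTable, locus: LocusSpec, repeat_info: pd.DataFrame
) -> tuple[list[AlleleCall], pd.DataFrame]:
    """Name alleles as '<length>.<index>'.

    Sequences are grouped by exact length; within a length, each distinct
    sequence is a separate (homoplastic) allele and indices follow
    descending dataset-wide count, ties broken lexicographically by
    sequence, so naming is deterministic under input-order shuffling.
    """
    totals = table.counts.sum(axis=1)
    order = sorted(
        table.counts.index,
        key=lambda s: (len(s), -int(totals[s]), s),
    )
    calls: list[AlleleCall] = []
    idx_within: dict[int, int] = {}
    for seq in order:
        length = len(seq)
        idx_within[length] = idx_within.get(length, 0) + 1
        ri = repeat_info.loc[seq]
        calls.append(
            AlleleCall(
                locus=locus.name,
                sequence=seq,
                fragment_length=length,
                homoplasy_index=idx_within[length],
                allele_name=f"{length}.{idx_within[length]}",
                repeat_units=int(ri["repeat_units"]),
                run_start=int(ri["run_start"]),
                run_end=int(ri["run_end"]),
                total_count=int(totals[seq]),
            )
        )
    allele_counts = table.counts.loc[[c.sequence for c in calls]].copy()
    allele_counts.index = pd.Index([c.allele_name for c in calls], name="allele")
    return calls, allele_counts


def normalize_and_filter(
    allele_counts: pd.DataFrame,
    locus: LocusSpec,
    min_depth: int = 1000,
    apply_threshold: bool = True,
    global_threshold: bool = False,
) -> AlleleFrequencyTable:
    """Median-normalise libraries and apply the per-sample abundance filter.

    Samples with raw total < ``min_depth`` are excluded (not an error).
    Remaining columns are scaled so each totals the median of raw totals;
    frequencies are percentages of the per-sample total.  Alleles below
    the locus threshold are zeroed per sample (``global_threshold=True``
    instead removes alleles whose maximum frequency over samples is below
    the threshold).  Alleles zero everywhere afterwards are dropped.
    """
    raw_totals = allele_counts.sum(axis=0)
    excluded = [s for s in allele_counts.columns if raw_totals[s] < min_depth]
    kept_cols = [s for s in allele_counts.columns if s not in excluded]
    if not kept_cols:
        raise ValueError(f"all samples are below the minimum depth of {min_depth}")
    counts = allele_counts[kept_cols].astype(float)
    totals = raw_totals[kept_cols].astype(float)
    median = float(np.median(totals.to_numpy()))
    normalized = counts * (median / totals)
    pct = 100.0 * counts / totals  # scaling preserves within-sample frequencies
    if apply_threshold and locus.abundance_threshold_pct > 0:
        if global_threshold:
            pct = pct.loc[pct.max(axis=1) >= locus.abundance_threshold_pct]
        else:
            pct = pct.where(pct >= locus.abundance_threshold_pct, 0.0)
    pct = pct.loc[(pct > 0).any(axis=1)]
    normalized = normalized.loc[pct.index]
    return AlleleFrequencyTable(
        locus=locus.name,
        percentages=pct,
        normalized_counts=normalized,
        raw_totals=raw_totals[kept_cols],
        excluded_samples=excluded,
    )


def merge_replicates(
    freq_table: AlleleFrequencyTable, replicate_map: Mapping[str, str]
) -> AlleleFrequencyTable:
    """Average allele frequencies over replicate samples of the same date.

    Every retained sample must be mapped; the mean includes zeros for
    replicates lacking an allele.
    """
    unmapped = [s for s in freq_table.percentages.columns if s not in replicate_map]
    if unmapped:
        raise ValueError(f"samples without a replicate mapping: {unmapped}")
    groups = {s: replicate_map[s] for s in freq_table.percentages.columns}
    pct = freq_table.percentages.T.groupby(groups).mean().T
    norm = freq_table.normalized_counts.T.groupby(groups).mean().T
    totals = freq_table.raw_totals.groupby(groups).sum()
    return AlleleFrequencyTable(
        locus=freq_table.locus,
        percentages=pct,
        normalized_counts=norm,
        raw_totals=totals,
        excluded_samples=list(freq_table.excluded_samples),
    )


# ---------------------------------------------------------------------------
# Flank typing


def flank_typing(calls: Sequence[AlleleCall], locus: LocusSpec) -> list[AlleleCall]:
    """Type 5'/3' flanks by exact sequence identity and flag recombinants.

    Flank types are labelled by descending total read abundance ("5A" >=
    "5B" ...).  The canonical pairing of a 5' type is the 3' type it
    co-occurs with at highest total abundance (and vice versa).  An allele
    is recombinant when both its flank types also occur in other alleles
    but its (5', 3') combination is neither flank's canonical partner.
    Flanks shorter than ``flank_min_len`` stay untyped (UNDEFINED) and
    never yield recombinant calls.
    """
    def type_labels(side: str, seqs: dict[str, int]) -> dict[str, str]:
        ranked = sorted(seqs, key=lambda s: (-seqs[s], s))
        letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
        return {
            s: f"{side}{letters[i] if i < 26 else str(i + 1)}" for i, s in enumerate(ranked)
        }

    f5_abund: dict[str, int] = {}
    f3_abund: dict[str, int] = {}
    for c in calls:
        if len(c.flank5) >= locus.flank_min_len:
            f5_abund[c.flank5] = f5_abund.get(c.flank5, 0) + c.total_count
        if len(c.flank3) >= locus.flank_min_len:
            f3_abund[c.flank3] = f3_abund.get(c.flank3, 0) + c.total_count
    if not f5_abund:
        warnings.warn(f"locus {locus.name}: 5' flanks too short to type")
    if not f3_abund:
        warnings.warn(f"locus {locus.name}: 3' flanks too short to type")
    lab5 = type_labels("5", f5_abund)
    lab3 = type_labels("3", f3_abund)

    # abundance of each (5' type, 3' type) combination
    pair_abund: dict[tuple[str, str], int] = {}
    for c in calls:
        t5, t3 = lab5.get(c.flank5), lab3.get(c.flank3)
        if t5 is not None and t3 is not None:
            pair_abund[(t5, t3)] = pair_abund.get((t5, t3), 0) + c.total_count
    canon5: dict[str, str] = {}
    canon3: dict[str, str] = {}
    for (t5, t3), ab in pair_abund.items():
        if t5 not in canon5 or ab > pair_abund[(t5, canon5[t5])]:
            canon5[t5] = t3
        if t3 not in canon3 or ab > pair_abund[(canon3[t3], t3)]:
            canon3[t3] = t5

    n_with_t5: dict[str, int] = {}
    n_with_t3: dict[str, int] = {}
    typed: list[tuple[AlleleCall, str | None, str | None]] = []
    for c in calls:
        t5, t3 = lab5.get(c.flank5), lab3.get(c.flank3)
        if t5 is not None:
            n_with_t5[t5] = n_with_t5.get(t5, 0) + 1
        if t3 is not None:
            n_with_t3[t3] = n_with_t3.get(t3, 0) + 1
        typed.append((c, t5, t3))

    out: list[AlleleCall] = []
    for c, t5, t3 in typed:
        recomb = False
        if t5 is not None and t3 is not None:
            shared5 = n_with_t5[t5] > 1
            shared3 = n_with_t3[t3] > 1
            recomb = (
                shared5 and shared3 and canon5[t5] != t3 and canon3[t3] != t5
            )
        out.append(
            AlleleCall(
                locus=c.locus,
                sequence=c.sequence,
                fragment_length=c.fragment_length,
                homoplasy_index=c.homoplasy_index,
                allele_name=c.allele_name,
                repeat_units=c.repeat_units,
                run_start=c.run_start,
                run_end=c.run_end,
                total_count=c.total_count,
                flank5_type=t5,
                flank3_type=t3,
                recombinant=recomb,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Orchestration


def run_locus_pipeline(
    table: AmpliconTable,
    locus: LocusSpec,
    min_depth: int = 1000,
    replicate_map: Mapping[str, str] | None = None,
    global_threshold: bool = False,
) -> dict:
    """Run the full chain for one locus; returns all intermediate artefacts."""
    report = FilterReport(locus=locus.name)
    report.add("input", table.total_reads)
    t1 = filter_singletons(table)
    report.add("singleton_filter", t1.total_reads)
    t2, repeat_info = repeat_filter(t1, locus)
    report.add("repeat_filter", t2.total_reads)
    calls, allele_counts = call_alleles(t2, locus, repeat_info)
    freq = normalize_and_filter(
        allele_counts, locus, min_depth=min_depth, global_threshold=global_threshold
    )
    retained = int(
        allele_counts.loc[freq.percentages.index, freq.percentages.columns]
        .to_numpy()
        .sum()
    )
    report.add("depth_and_abundance_filter", retained)
    calls = flank_typing(calls, locus)
    merged = merge_replicates(freq, replicate_map) if replicate_map else None
    return {
        "raw_table": table,
        "filtered_table": t2,
        "calls": calls,
        "allele_counts": allele_counts,
        "frequencies": freq,
        "merged": merged,
        "report": report,
    }
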