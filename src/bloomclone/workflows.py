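"""End-to-end report bundles for the two analyses.

``run_fingerprinting`` chains the strain-genotype statistics
(diversity -> linkage -> differentiation -> mating type);
``run_mpb`` chains the pooled-amplicon caller into differentiation.
Outputs are plain CSV files written atomically (complete bundle or
nothing), each carrying a provenance header (version, seed, config
hash).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .genotype_core import assign_mlgs, diversity_by_date, mlg_recurrence, read_genotype_table
from .linkage_stats import ia_by_date
from .mating_type import mt_ratio
from .mpb_pipeline import LocusSpec, read_counts_tsv, merge_replicates, run_locus_pipeline
from .popdiff import fst_matrix, pcoa, percolation_network, profile_from_percentages, profile_from_strains

logger = logging.getLogger("bloomclone")


@dataclass
class RunConfig:
    """Shared settings for a report run."""

    out_dir: Path
    seed: int = 0
    iterations: int = 1000
    min_strains_per_date: int = 3
    extra: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        # excludes out_dir so identical analyses hash identically
        fields = {k: str(v) for k, v in dataclasses.asdict(self).items() if k != "out_dir"}
        payload = json.dumps(fields, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# bloomclone {__version__} seed={config.seed} config={config.config_hash()}\n")
        df.to_csv(fh, index=index)


def _atomic_bundle(out_dir: Path):
    """Context manager: stage outputs in a temp dir, promote on success."""
    class _Bundle:
        def __enter__(self) -> Path:
            self.tmp = Path(tempfile.mkdtemp(prefix=".bloomclone-", dir=out_dir.parent))
            return self.tmp

        def __exit__(self, exc_type, exc, tb) -> bool:
            if exc_type is None:
                if out_dir.exists():
                    shutil.rmtree(out_dir)
                self.tmp.rename(out_dir)
            else:
                shutil.rmtree(self.tmp, ignore_errors=True)
            return False

    out_dir.parent.mkdir(parents=True, exist_ok=True)
    return _Bundle()


def run_fingerprinting(genotype_csv, config: RunConfig) -> dict[str, Path]:
    """Diversity, linkage, MT-ratio, F_ST/PCoA/network and MLG recurrence
    from one strain genotype table."""
    strains = read_genotype_table(genotype_csv)
    logger.info("fingerprinting: %d strains", len(strains))
    outputs: dict[str, Path] = {}
    with _atomic_bundle(config.out_dir) as tmp:
        div = diversity_by_date(strains)
        _write_csv(div, tmp / "diversity_by_date.csv", config)

        ia = ia_by_date(
            strains,
            n_iterations=config.iterations,
            seed=config.seed,
            min_strains=config.min_strains_per_date,
        )
        _write_csv(ia, tmp / "index_of_association.csv", config)

        mt = mt_ratio(strains)
        _write_csv(mt, tmp / "mt_ratio.csv", config)

        part = assign_mlgs(strains)
        membership = pd.DataFrame(
            sorted(part.mlg_ids.items()), columns=["strain_id", "mlg_id"]
        )
        _write_csv(membership, tmp / "mlg_membership.csv", config)
        rec = mlg_recurrence(part, strains)
        _write_csv(rec, tmp / "mlg_recurrence.csv", config, index=True)

        by_date: dict[dt.date, list] = {}
        for s in strains:
            by_date.setdefault(s.sampling_date, []).append(s)
        profiles = {
            d.isoformat(): profile_from_strains(group)
            for d, group in sorted(by_date.items())
            if any(s.is_complete for s in group)
        }
        if len(profiles) >= 2:
            fst = fst_matrix(profiles)
            _write_csv(fst.to_frame(), tmp / "fst_matrix.csv", config, index=True)
            ord_res = pcoa(fst)
            coords = ord_res.to_frame()
            coords.insert(0, "sample", coords.index)
            pct = pd.DataFrame(
                {"axis": range(1, len(ord_res.pct_variance) + 1), "pct_variance": ord_res.pct_variance}
            )
            _write_csv(coords, tmp / "pcoa_coordinates.csv", config)
            _write_csv(pct, tmp / "pcoa_variance.csv", config)
            net = percolation_network(fst)
            edges = net.edge_list()
            _write_csv(edges, tmp / "network_edges.csv", config)
        for name in (
            "diversity_by_date",
            "index_of_association",
            "mt_ratio",
            "mlg_membership",
            "mlg_recurrence",
            "fst_matrix",
            "pcoa_coordinates",
            "pcoa_variance",
            "network_edges",
        ):
            path = config.out_dir / f"{name}.csv"
            outputs[name] = path
    return {k: v for k, v in outputs.items() if v.exists()}


def run_mpb(
    reads_tsv_by_locus: Mapping[str, object],
    locus_specs: Mapping[str, LocusSpec],
    config: RunConfig,
    replicate_map: Mapping[str, str] | None = None,
    min_depth: int = 1000,
) -> dict[str, Path]:
    """Pooled-amplicon calling per locus, then F_ST + PCoA across samples."""
    outputs: dict[str, Path] = {}
    with _atomic_bundle(config.out_dir) as tmp:
        pct_by_locus: dict[str, pd.DataFrame] = {}
        for locus_name, tsv in reads_tsv_by_locus.items():
            spec = locus_specs[locus_name]
            table = read_counts_tsv(tsv, spec)
            result = run_locus_pipeline(
                table, spec, min_depth=min_depth, replicate_map=replicate_map
            )
            freq = result["merged"] or result["frequencies"]
            pct_by_locus[locus_name] = freq.percentages
            _write_csv(
                freq.percentages, tmp / f"{locus_name}_frequencies.csv", config, index=True
            )
            ann = pd.DataFrame(
                [
                    {
                        "allele": c.allele_name,
                        "length": c.fragment_length,
                        "homoplasy_index": c.homoplasy_index,
                        "repeat_units": c.repeat_units,
                        "flank5_type": c.flank5_type or "UNDEFINED",
                        "flank3_type": c.flank3_type or "UNDEFINED",
                        "recombinant": c.recombinant,
                        "total_count": c.total_count,
                    }
                    for c in result["calls"]
                ]
            )
            _write_csv(ann, tmp / f"{locus_name}_alleles.csv", config)
            _write_csv(result["report"].to_frame(), tmp / f"{locus_name}_filter_report.csv", config)
            if freq.excluded_samples:
                logger.warning(
                    "%s: samples below depth %d excluded: %s",
                    locus_name,
                    min_depth,
                    freq.excluded_samples,
                )

        samples = sorted(set.intersection(*(set(p.columns) for p in pct_by_locus.values())))
        if len(samples) >= 2:
            profiles = {}
            for sample in samples:
                pct = {
                    locus: table[sample].to_dict() for locus, table in pct_by_locus.items()
                }
                profiles[sample] = profile_from_percentages(pct)
            fst = fst_matrix(profiles)
            _write_csv(fst.to_frame(), tmp / "fst_matrix.csv", config, index=True)
            ord_res = pcoa(fst)
            coords = ord_res.to_frame()
            coords.insert(0, "sample", coords.index)
            pct_var = pd.DataFrame(
                {"axis": range(1, len(ord_res.pct_variance) + 1), "pct_variance": ord_res.pct_variance}
            )
            _write_csv(coords, tmp / "pcoa_coordinates.csv", config)
            _write_csv(pct_var, tmp / "pcoa_variance.csv", config)
        staged = list(tmp.glob("*.csv"))
        for p in staged:
            outputs[p.stem] = config.out_dir / p.name
    return outputs
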