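"""End-to-end wiring: diff -> density -> screen -> rank -> DE filter.

The configuration is a flat YAML mapping (paths plus thresholds) echoed
verbatim into the JSON report for provenance; outputs contain no
timestamps or hostnames so identical inputs give byte-identical reports.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import de as msde
from . import io as msio
from .density import (
    DEFAULT_BIN_SIZE,
    DEFAULT_DENSITY_THRESHOLD,
    DensityRegion,
    call_dense_regions,
    compute_bin_densities,
)
from .diff import DEFAULT_PROMOTER_LEN, GeneMethylationDelta, genome_wide_diff
from .models import DETable
from .screen import (
    DEFAULT_MIN_ABUNDANCE_LOSS,
    DEFAULT_MIN_SITE_LOSS,
    DEFAULT_REGULATOR_KEYWORDS,
    flag_in_region,
    identify_regulators,
    rank_candidates,
    screen_by_methylation,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration (caught before any computation)."""


@dataclass
class PipelineConfig:
    """All inputs, outputs and thresholds of one pipeline run."""

    annotation: Optional[str] = None
    wt_methylome: Optional[str] = None
    mut_methylome: Optional[str] = None
    pathway_table: Optional[str] = None
    de_tables: dict[str, str] = field(default_factory=dict)  # time label -> path
    out_dir: str = "methscreen_out"

    mod_type: str = "m4C"
    promoter_len: int = DEFAULT_PROMOTER_LEN
    min_score: Optional[float] = None
    bin_size: int = DEFAULT_BIN_SIZE
    density_threshold: float = DEFAULT_DENSITY_THRESHOLD
    density_enabled: bool = True
    min_site_loss: float = DEFAULT_MIN_SITE_LOSS
    min_abundance_loss: float = DEFAULT_MIN_ABUNDANCE_LOSS
    min_wt_sites: int = 1
    regulator_keywords: list[str] = field(
        default_factory=lambda: list(DEFAULT_REGULATOR_KEYWORDS)
    )
    min_abs_log2fc: float = 1.0
    max_padj: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name in ("annotation", "wt_methylome", "mut_methylome"):
            if getattr(self, name) is None:
                raise ConfigError(f"config field {name!r} is required")
        if self.density_enabled and self.pathway_table is None:
            raise ConfigError(
                "pathway_table is required while the density stage is enabled"
            )
        if self.promoter_len < 0:
            raise ConfigError("promoter_len must be >= 0")
        if self.bin_size < 1:
            raise ConfigError("bin_size must be >= 1")
        for name in ("density_threshold", "min_site_loss", "min_abundance_loss"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ConfigError(f"{name} must be within [0, 1], got {value}")
        if self.min_abs_log2fc <= 0 or self.max_padj <= 0:
            raise ConfigError("DE thresholds must be positive")
        if not self.regulator_keywords:
            raise ConfigError("regulator_keywords must be non-empty")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            payload = yaml.safe_load(handle) or {}
        if not isinstance(payload, dict):
            raise ConfigError(f"{path}: config must be a YAML mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(asdict(self), handle, sort_keys=True)

    def echo(self) -> dict:
        return asdict(self)


def _read_methylome(path: str, mod_type: str):
    if str(path).endswith((".gff", ".gff3")):
        return msio.read_basemods_gff(path, {mod_type})
    return msio.read_methylome_tsv(path).filter_mod_type({mod_type})


def write_deltas_tsv(deltas: Sequence[GeneMethylationDelta], path) -> None:
    """Serialize per-gene deltas (pipeline intermediate, re-readable)."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "gene_id", "mod_type", "cds_sites_wt", "cds_sites_lost",
                "cds_loss_fraction", "abundance_loss_fraction",
                "promoter_sites_wt", "promoter_sites_lost",
                "promoter_loss_fraction", "cds_lost_positions",
            ]
        )
        for d in deltas:
            writer.writerow(
                [
                    d.gene_id, d.mod_type, d.cds_sites_wt, d.cds_sites_lost,
                    repr(d.cds_loss_fraction), repr(d.abundance_loss_fraction),
                    d.promoter_sites_wt, d.promoter_sites_lost,
                    repr(d.promoter_loss_fraction),
                    ",".join(str(p) for p in d.cds_lost_positions),
                ]
            )


def read_deltas_tsv(path) -> list[GeneMethylationDelta]:
    out = []
    with open(path) as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            positions = tuple(
                int(p) for p in row["cds_lost_positions"].split(",") if p
            )
            out.append(
                GeneMethylationDelta(
                    gene_id=row["gene_id"],
                    mod_type=row["mod_type"],
                    cds_sites_wt=int(row["cds_sites_wt"]),
                    cds_sites_lost=int(row["cds_sites_lost"]),
                    cds_loss_fraction=float(row["cds_loss_fraction"]),
                    cds_lost_positions=positions,
                    abundance_loss_fraction=float(row["abundance_loss_fraction"]),
                    promoter_sites_wt=int(row["promoter_sites_wt"]),
                    promoter_sites_lost=int(row["promoter_sites_lost"]),
                    promoter_loss_fraction=float(row["promoter_loss_fraction"]),
                )
            )
    return out


def write_regions_tsv(regions: Sequence[DensityRegion], path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["start_ordinal", "end_ordinal", "n_bins", "max_density", "mean_density"]
        )
        for r in regions:
            writer.writerow(
                [r.start_ordinal, r.end_ordinal, r.n_bins,
                 repr(r.max_density), repr(r.mean_density)]
            )


def read_regions_tsv(path) -> list[DensityRegion]:
    out = []
    with open(path) as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            out.append(
                DensityRegion(
                    start_ordinal=int(row["start_ordinal"]),
                    end_ordinal=int(row["end_ordinal"]),
                    n_bins=int(row["n_bins"]),
                    max_density=float(row["max_density"]),
                    mean_density=float(row["mean_density"]),
                )
            )
    return out


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage and write the report files into ``out_dir``.

    Returns the report dictionary (also written as ``report.json``).
    """
    config.validate()
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    genes = msio.read_gene_annotation(config.annotation)
    wt = _read_methylome(config.wt_methylome, config.mod_type)
    mut = _read_methylome(config.mut_methylome, config.mod_type)
    logger.info("stage diff: %d genes, WT %d calls, mutant %d calls",
                len(genes), len(wt), len(mut))
    deltas, totals = genome_wide_diff(
        wt, mut, genes,
        promoter_len=config.promoter_len,
        min_score=config.min_score,
        mod_type=config.mod_type,
    )
    write_deltas_tsv(deltas, outdir / "deltas.tsv")

    regions: list[DensityRegion] = []
    if config.density_enabled:
        assignments = msio.read_pathway_table(config.pathway_table)
        bins = compute_bin_densities(genes, assignments, bin_size=config.bin_size)
        regions = call_dense_regions(bins, threshold=config.density_threshold)
        logger.info("stage density: %d bins, %d dense regions", len(bins), len(regions))
        write_regions_tsv(regions, outdir / "regions.tsv")
        msio.write_regions_bed(regions, genes, outdir / "regions.bed")

    regulator_map = identify_regulators(genes, config.regulator_keywords)
    candidates = screen_by_methylation(
        deltas, genes, regulator_map,
        min_site_loss=config.min_site_loss,
        min_abundance_loss=config.min_abundance_loss,
        min_wt_sites=config.min_wt_sites,
    )
    candidates = flag_in_region(candidates, regions)
    ranked = rank_candidates(candidates)
    logger.info(
        "stage screen: %d regulators, %d candidates (%d in dense regions)",
        sum(regulator_map.values()), len(ranked),
        sum(c.in_dense_region for c in ranked),
    )
    msio.write_candidate_report(
        ranked, outdir / "candidates.tsv", outdir / "candidates.json"
    )

    de_report: Optional[dict] = None
    if config.de_tables:
        tables: list[DETable] = [
            msio.read_de_table(path, label)
            for label, path in config.de_tables.items()
        ]
        crossover = msde.crossover_genes(
            tables, config.min_abs_log2fc, config.max_padj
        )
        results = msde.filter_consistent(crossover, tables)
        chosen = msde.selected(results)
        msde.write_consistency_tsv(
            results, [t.time_label for t in tables], outdir / "de_consistency.tsv"
        )
        de_report = {
            "time_labels": [t.time_label for t in tables],
            "n_crossover": len(results),
            "n_selected": len(chosen),
            "n_up": sum(r.direction == msde.UP for r in results),
            "n_down": sum(r.direction == msde.DOWN for r in results),
            "directions": {r.gene_id: r.direction for r in results},
        }
        logger.info(
            "stage de-filter: %d crossover genes, %d sign-consistent",
            de_report["n_crossover"], de_report["n_selected"],
        )

    report = {
        "config": config.echo(),
        "totals": {"wt_calls": totals.wt_total, "mut_calls": totals.mut_total},
        "n_genes": len(genes),
        "n_regulators": sum(regulator_map.values()),
        "regions": [
            {
                "start_ordinal": r.start_ordinal,
                "end_ordinal": r.end_ordinal,
                "label": r.label,
                "n_bins": r.n_bins,
                "max_density": r.max_density,
                "mean_density": r.mean_density,
            }
            for r in regions
        ],
        "n_candidates": len(ranked),
        "candidates": [
            {
                "rank": c.rank,
                "gene_id": c.gene_id,
                "orf_ordinal": c.orf_ordinal,
                "in_dense_region": c.in_dense_region,
                "cds_loss_fraction": c.delta.cds_loss_fraction,
                "abundance_loss_fraction": c.delta.abundance_loss_fraction,
                "promoter_loss_fraction": c.delta.promoter_loss_fraction,
            }
            for c in ranked
        ],
        "de": de_report,
    }
    with open(outdir / "report.json", "w") as handle:
        json.dump(report, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return report
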