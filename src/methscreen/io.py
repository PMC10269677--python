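"""Readers and writers for every external format the pipeline touches.

Formats
-------
* SMRT base-modification GFF3 (per-base modification calls),
* a plain methylome TSV equivalent to it,
* gene annotation GFF3 (single-interval bacterial CDS with ORF-ordinal
  locus tags),
* pathway-assignment and differential-expression TSVs,
* the candidate report (TSV mirror + full-precision JSON) and a BED file of
  called dense regions.

GFF3 coordinates are 1-based inclusive and stay that way internally; the
single conversion to 0-based half-open happens at BED emission.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Optional, Union

from .models import (
    KNOWN_MOD_TYPES,
    DETable,
    GeneModel,
    Methylome,
    ModificationCall,
    PathwayAssignment,
)

if TYPE_CHECKING:  # pragma: no cover
    from .density import DensityRegion
    from .screen import CandidateRecord

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

METHYLOME_TSV_COLUMNS = ["seqid", "position", "strand", "mod_type", "score", "coverage"]

#: Default locus-tag pattern: one integer capture group giving the ORF ordinal.
DEFAULT_ORDINAL_PATTERN = r"orf0*(\d+)$"


class ParseError(ValueError):
    """Malformed input file; the message names the file and offending line/row."""


def _parse_gff_attributes(field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            key, _, value = part.partition("=")
            attrs[key.strip()] = value.strip()
    return attrs


def _iter_gff_lines(path: PathLike):
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            yield lineno, fields


def read_basemods_gff(
    path: PathLike,
    mod_filter: Iterable[str] = frozenset({"m4C"}),
    sample_id: Optional[str] = None,
) -> Methylome:
    """Read a SMRT base-modification GFF3 file into a :class:`Methylome`.

    Both common dialects are accepted: the modification type may sit in
    column 3 directly (``m4C``) or column 3 may read ``modified_base`` with a
    ``type=m4C`` attribute.  Score comes from an ``identificationQv``
    attribute when present, else from the GFF score column; coverage from a
    ``coverage`` attribute.  Records whose type is not a known base
    modification are skipped with a warning; duplicate call keys keep the
    higher-scoring record.
    """
    mod_filter = set(mod_filter)
    methylome = Methylome(sample_id or Path(path).stem)
    n_seen = 0
    for lineno, fields in _iter_gff_lines(path):
        seqid, _source, ftype, start, _end, score_col, strand, _phase, attr_col = fields
        attrs = _parse_gff_attributes(attr_col)
        mod_type = ftype if ftype in KNOWN_MOD_TYPES else attrs.get("type", ftype)
        if mod_type not in KNOWN_MOD_TYPES:
            logger.warning(
                "%s: line %d: unknown modification type %r, record skipped",
                path, lineno, mod_type,
            )
            continue
        if mod_type not in mod_filter:
            continue
        if strand not in ("+", "-"):
            raise ParseError(f"{path}: line {lineno}: bad strand {strand!r}")
        try:
            position = int(start)
        except ValueError:
            raise ParseError(f"{path}: line {lineno}: non-integer start {start!r}") from None
        score: Optional[float] = None
        if "identificationQv" in attrs:
            score = float(attrs["identificationQv"])
        elif score_col not in (".", ""):
            score = float(score_col)
        coverage = int(attrs["coverage"]) if "coverage" in attrs else None
        methylome.add(
            ModificationCall(
                seqid=seqid,
                position=position,
                strand=strand,
                mod_type=mod_type,
                score=score,
                coverage=coverage,
            )
        )
        n_seen += 1
    logger.info(
        "%s: retained %d calls (%d records matched filter %s)",
        path, len(methylome), n_seen, sorted(mod_filter),
    )
    return methylome


def read_methylome_tsv(path: PathLike, sample_id: Optional[str] = None) -> Methylome:
    """Read the plain TSV methylome dialect (same contract as the GFF reader)."""
    methylome = Methylome(sample_id or Path(path).stem)
    with open(path) as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        header = reader.fieldnames or []
        for column in ("seqid", "position", "strand", "mod_type"):
            if column not in header:
                raise ParseError(f"{path}: missing mandatory column {column!r}")
        for rowno, row in enumerate(reader, start=2):
            mod_type = row["mod_type"]
            if mod_type not in KNOWN_MOD_TYPES:
                logger.warning(
                    "%s: row %d: unknown modification type %r, record skipped",
                    path, rowno, mod_type,
                )
                continue
            try:
                position = int(row["position"])
            except ValueError:
                raise ParseError(
                    f"{path}: row {rowno}: non-integer position {row['position']!r}"
                ) from None
            if position < 1:
                raise ParseError(f"{path}: row {rowno}: position must be >= 1")
            score_text = (row.get("score") or "").strip()
            coverage_text = (row.get("coverage") or "").strip()
            methylome.add(
                ModificationCall(
                    seqid=row["seqid"],
                    position=position,
                    strand=row["strand"],
                    mod_type=mod_type,
                    score=float(score_text) if score_text else None,
                    coverage=int(coverage_text) if coverage_text else None,
                )
            )
    logger.info("%s: retained %d calls", path, len(methylome))
    return methylome


def write_methylome_tsv(methylome: Methylome, path: PathLike) -> None:
    """Write a methylome as TSV; a round trip reproduces the keyed set exactly."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(METHYLOME_TSV_COLUMNS)
        for call in methylome.sorted_calls():
            writer.writerow(
                [
                    call.seqid,
                    call.position,
                    call.strand,
                    call.mod_type,
                    "" if call.score is None else format(call.score, "g"),
                    "" if call.coverage is None else call.coverage,
                ]
            )


def read_gene_annotation(
    path: PathLike,
    feature_kind: str = "CDS",
    ordinal_pattern: str = DEFAULT_ORDINAL_PATTERN,
) -> list[GeneModel]:
    """Read single-interval CDS features and their ORF ordinals from GFF3.

    Each kept feature must carry a ``locus_tag`` (or ``ID``) attribute whose
    text matches ``ordinal_pattern`` (one integer capture group).  Output is
    sorted by ordinal; duplicate ordinals and multi-part features are errors.
    """
    pattern = re.compile(ordinal_pattern)
    genes: dict[int, GeneModel] = {}
    bad_tags: list[str] = []
    for lineno, fields in _iter_gff_lines(path):
        seqid, _source, ftype, start, end, _score, strand, _phase, attr_col = fields
        if ftype != feature_kind:
            continue
        attrs = _parse_gff_attributes(attr_col)
        tag = attrs.get("locus_tag") or attrs.get("ID")
        if tag is None:
            raise ParseError(f"{path}: line {lineno}: feature has no locus_tag or ID")
        match = pattern.search(tag)
        if match is None:
            bad_tags.append(tag)
            continue
        ordinal = int(match.group(1))
        gene = GeneModel(
            gene_id=tag,
            orf_ordinal=ordinal,
            seqid=seqid,
            start=int(start),
            end=int(end),
            strand=strand,
            product=attrs.get("product", ""),
        )
        if ordinal in genes:
            raise ParseError(
                f"{path}: duplicate ORF ordinal {ordinal} "
                f"({genes[ordinal].gene_id!r} and {tag!r}); multi-part CDS "
                f"features are not supported"
            )
        genes[ordinal] = gene
    if bad_tags:
        raise ParseError(
            f"{path}: locus tags not matching ordinal pattern "
            f"{ordinal_pattern!r}: {', '.join(sorted(bad_tags))}"
        )
    return [genes[k] for k in sorted(genes)]


_TRUE_TOKENS = {"1", "true"}
_FALSE_TOKENS = {"0", "false"}


def read_pathway_table(path: PathLike) -> list[PathwayAssignment]:
    """Read the gene -> pathway-category membership TSV."""
    out: list[PathwayAssignment] = []
    seen: set[str] = set()
    with open(path) as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for column in ("gene_id", "in_category"):
            if column not in (reader.fieldnames or []):
                raise ParseError(f"{path}: missing mandatory column {column!r}")
        for rowno, row in enumerate(reader, start=2):
            token = row["in_category"].strip().lower()
            if token in _TRUE_TOKENS:
                member = True
            elif token in _FALSE_TOKENS:
                member = False
            else:
                raise ParseError(
                    f"{path}: row {rowno}: in_category must be one of 0/1/true/false"
                )
            gene_id = row["gene_id"]
            if gene_id in seen:
                raise ParseError(f"{path}: row {rowno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            out.append(PathwayAssignment(gene_id=gene_id, in_category=member))
    return out


def read_de_table(path: PathLike, time_label: str) -> DETable:
    """Read one time point's DE TSV (gene_id, log2fc, optional padj).

    When the padj column is missing entirely, every padj is absent and
    downstream significance falls back to the fold-change-only rule.
    """
    rows: dict[str, tuple[float, Optional[float]]] = {}
    with open(path) as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        header = reader.fieldnames or []
        for column in ("gene_id", "log2fc"):
            if column not in header:
                raise ParseError(f"{path}: missing mandatory column {column!r}")
        has_padj = "padj" in header
        for rowno, row in enumerate(reader, start=2):
            gene_id = row["gene_id"]
            if gene_id in rows:
                raise ParseError(f"{path}: row {rowno}: duplicate gene_id {gene_id!r}")
            try:
                log2fc = float(row["log2fc"])
            except ValueError:
                raise ParseError(
                    f"{path}: row {rowno}: non-numeric log2fc {row['log2fc']!r}"
                ) from None
            padj: Optional[float] = None
            if has_padj:
                padj_text = (row.get("padj") or "").strip()
                padj = float(padj_text) if padj_text else None
            rows[gene_id] = (log2fc, padj)
    return DETable(time_label=time_label, rows=rows)


def write_pathway_table(assignments: Iterable[PathwayAssignment], path: PathLike) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene_id", "in_category"])
        for assignment in assignments:
            writer.writerow([assignment.gene_id, int(assignment.in_category)])


def write_de_table(table: DETable, path: PathLike) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene_id", "log2fc", "padj"])
        for gene_id, (log2fc, padj) in table.rows.items():
            writer.writerow(
                [gene_id, format(log2fc, ".6g"), "" if padj is None else format(padj, "g")]
            )


def write_gene_annotation(genes: Iterable[GeneModel], path: PathLike) -> None:
    """Write genes as GFF3 CDS features (inverse of :func:`read_gene_annotation`)."""
    with open(path, "w", newline="") as handle:
        handle.write("##gff-version 3\n")
        for gene in genes:
            attrs = f"ID={gene.gene_id};locus_tag={gene.gene_id};product={gene.product}"
            handle.write(
                "\t".join(
                    [
                        gene.seqid,
                        "methscreen",
                        "CDS",
                        str(gene.start),
                        str(gene.end),
                        ".",
                        gene.strand,
                        "0",
                        attrs,
                    ]
                )
                + "\n"
            )


def write_candidate_report(
    records: "list[CandidateRecord]",
    path_tsv: PathLike,
    path_json: PathLike,
) -> None:
    """Emit the ranked candidate table as a human-readable TSV and a JSON twin.

    The TSV prints percentages the way the screen reports them (whole-percent
    site loss with lost/total counts, one-decimal abundance loss); the JSON
    carries the full-precision fractions so every printed cell can be
    re-derived.  Records must already be ranked.
    """
    from .diff import format_loss_percent  # local import to avoid a cycle

    for record in records:
        if record.rank is None:
            raise ValueError(f"unranked candidate record {record.gene_id!r}")
    with open(path_tsv, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "rank",
                "gene_id",
                "orf_ordinal",
                "cds_m4C_site_loss",
                "abundance_loss",
                "promoter_m4C_loss",
                "in_dense_region",
                "product",
            ]
        )
        for record in records:
            delta = record.delta
            cds_cell = (
                f"{format_loss_percent(delta.cds_loss_fraction, 0)} "
                f"({delta.cds_sites_lost}/{delta.cds_sites_wt})"
            )
            if delta.promoter_sites_wt > 0:
                promoter_cell = (
                    f"{format_loss_percent(delta.promoter_loss_fraction, 0)} "
                    f"({delta.promoter_sites_lost}/{delta.promoter_sites_wt})"
                )
            else:
                promoter_cell = "0"
            writer.writerow(
                [
                    record.rank,
                    record.gene_id,
                    record.orf_ordinal,
                    cds_cell,
                    format_loss_percent(delta.abundance_loss_fraction, 1),
                    promoter_cell,
                    int(record.in_dense_region),
                    record.product,
                ]
            )
    payload = [
        {
            "rank": record.rank,
            "gene_id": record.gene_id,
            "orf_ordinal": record.orf_ordinal,
            "product": record.product,
            "in_dense_region": record.in_dense_region,
            "cds_sites_wt": record.delta.cds_sites_wt,
            "cds_sites_lost": record.delta.cds_sites_lost,
            "cds_loss_fraction": record.delta.cds_loss_fraction,
            "abundance_loss_fraction": record.delta.abundance_loss_fraction,
            "cds_lost_positions": list(record.delta.cds_lost_positions),
            "promoter_sites_wt": record.delta.promoter_sites_wt,
            "promoter_sites_lost": record.delta.promoter_sites_lost,
            "promoter_loss_fraction": record.delta.promoter_loss_fraction,
        }
        for record in records
    ]
    with open(path_json, "w") as handle:
        json.dump(payload, handle, indent=2)
        handle.write("\n")


def write_regions_bed(
    regions: "list[DensityRegion]",
    genes: list[GeneModel],
    path: PathLike,
) -> None:
    """Write dense regions as BED (0-based half-open) spanning their genes.

    Each region's genomic span runs from the first to the last gene whose
    ordinal falls inside the region's half-open ordinal span.
    """
    by_ordinal = {gene.orf_ordinal: gene for gene in genes}
    with open(path, "w", newline="") as handle:
        for region in regions:
            members = [
                by_ordinal[o]
                for o in range(region.start_ordinal, region.end_ordinal)
                if o in by_ordinal
            ]
            if not members:
                logger.warning(
                    "region orf%d-orf%d contains no annotated genes, skipped in BED",
                    region.start_ordinal, region.end_ordinal,
                )
                continue
            seqids = {gene.seqid for gene in members}
            if len(seqids) > 1:
                raise ValueError(
                    f"region orf{region.start_ordinal}-orf{region.end_ordinal} "
                    f"spans multiple contigs: {sorted(seqids)}"
                )
            bed_start = min(gene.start for gene in members) - 1
            bed_end = max(gene.end for gene in members)
            name = f"orf{region.start_ordinal}-orf{region.end_ordinal}"
            score = min(1000, int(round(region.max_density * 1000)))
            handle.write(
                f"{members[0].seqid}\t{bed_start}\t{bed_end}\t{name}\t{score}\t.\n"
            )
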