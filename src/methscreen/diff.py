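"""Per-gene wild-type vs mutant m4C loss statistics.

A *lost* site is a call key (seqid, position, strand, mod_type) present in
the wild-type methylome and absent from the mutant methylome — the exact
set-difference definition.  Partial-methylation fractions are not modelled;
an optional identification-score threshold is the only filtering knob.

Two per-gene metrics drive the downstream screen:

* site-loss fraction   = lost CDS sites / wild-type CDS sites,
* abundance loss       = lost CDS sites / CDS length in bases
  (methylation abundance being methylated CDS sites per CDS base).

Calls on either strand within the CDS interval count toward the gene:
adjacent opposite-strand site pairs are a normal feature of m4C motifs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

from .models import CallKey, GeneModel, Methylome

logger = logging.getLogger(__name__)

#: Default upstream window scanned for promoter methylation, in bases.
#: A common bacterial promoter span; comfortably covers regulatory sites a
#: few bases upstream of the start codon.
DEFAULT_PROMOTER_LEN = 300


@dataclass(frozen=True, slots=True)
class GeneMethylationDelta:
    """Wild-type vs mutant methylation-loss statistics for one gene.

    ``cds_lost_positions`` are 1-based positions relative to the CDS start on
    the coding strand (for '-' genes: ``end - genomic + 1``).
    """

    gene_id: str
    mod_type: str
    cds_sites_wt: int
    cds_sites_lost: int
    cds_loss_fraction: float
    cds_lost_positions: tuple[int, ...]
    abundance_loss_fraction: float
    promoter_sites_wt: int
    promoter_sites_lost: int
    promoter_loss_fraction: float

    def __post_init__(self) -> None:
        if not (0 <= self.cds_sites_lost <= self.cds_sites_wt):
            raise ValueError(
                f"{self.gene_id}: lost sites {self.cds_sites_lost} outside "
                f"[0, {self.cds_sites_wt}]"
            )
        if not (0 <= self.promoter_sites_lost <= self.promoter_sites_wt):
            raise ValueError(f"{self.gene_id}: promoter lost sites out of range")
        if len(self.cds_lost_positions) != self.cds_sites_lost:
            raise ValueError(f"{self.gene_id}: lost-position list length mismatch")


def promoter_window(gene: GeneModel, promoter_len: int) -> tuple[int, int]:
    """Genomic interval (1-based inclusive) of the upstream promoter window.

    Strand-aware: upstream of the start codon on the coding-strand side,
    clipped at contig position 1.  Returns an empty interval (start > end)
    when ``promoter_len`` is 0 or the window is fully clipped.
    """
    if promoter_len < 0:
        raise ValueError("promoter_len must be >= 0")
    if gene.strand == "+":
        return (max(1, gene.start - promoter_len), gene.start - 1)
    return (gene.end + 1, gene.end + promoter_len)


def assign_sites_to_gene(
    methylome: Methylome,
    gene: GeneModel,
    promoter_len: int = DEFAULT_PROMOTER_LEN,
) -> tuple[set[CallKey], set[CallKey]]:
    """Partition a methylome's calls into this gene's CDS and promoter sets.

    Calls on either strand are counted in both windows.  The two sets can
    only overlap if the promoter window is degenerate, which cannot happen
    by construction.
    """
    p_start, p_end = promoter_window(gene, promoter_len)
    cds_keys = set(methylome.keys_in_interval(gene.seqid, gene.start, gene.end))
    promoter_keys = (
        set(methylome.keys_in_interval(gene.seqid, p_start, p_end)) - cds_keys
    )
    return cds_keys, promoter_keys


def relative_cds_position(gene: GeneModel, genomic_position: int) -> int:
    """1-based position relative to the CDS start on the coding strand."""
    if gene.strand == "+":
        return genomic_position - gene.start + 1
    return gene.end - genomic_position + 1


def diff_gene_methylation(
    wt: Methylome,
    mut: Methylome,
    gene: GeneModel,
    promoter_len: int = DEFAULT_PROMOTER_LEN,
    min_score: Optional[float] = None,
    mod_type: str = "m4C",
) -> GeneMethylationDelta:
    """Compute one gene's wild-type vs mutant methylation-loss statistics.

    ``min_score``, when given, drops calls scoring below it from *both*
    samples before differencing (unscored calls are kept).  A gene on a
    contig absent from both methylomes yields an all-zero delta with a
    warning.
    """
    wt = wt.filter_min_score(min_score)
    mut = mut.filter_min_score(min_score)
    if gene.seqid not in wt.contigs() | mut.contigs():
        logger.warning(
            "%s: contig %r absent from both methylomes; reporting zero loss",
            gene.gene_id, gene.seqid,
        )
    cds_wt, prom_wt = assign_sites_to_gene(wt, gene, promoter_len)
    cds_lost = {k for k in cds_wt if k not in mut}
    prom_lost = {k for k in prom_wt if k not in mut}
    lost_positions = tuple(sorted(relative_cds_position(gene, k[1]) for k in cds_lost))
    return GeneMethylationDelta(
        gene_id=gene.gene_id,
        mod_type=mod_type,
        cds_sites_wt=len(cds_wt),
        cds_sites_lost=len(cds_lost),
        cds_loss_fraction=len(cds_lost) / len(cds_wt) if cds_wt else 0.0,
        cds_lost_positions=lost_positions,
        abundance_loss_fraction=len(cds_lost) / gene.cds_length,
        promoter_sites_wt=len(prom_wt),
        promoter_sites_lost=len(prom_lost),
        promoter_loss_fraction=len(prom_lost) / len(prom_wt) if prom_wt else 0.0,
    )


@dataclass(frozen=True, slots=True)
class MethylomeTotals:
    """Whole-methylome call counts before any gene assignment."""

    wt_total: int
    mut_total: int


def genome_wide_diff(
    wt: Methylome,
    mut: Methylome,
    genes: Sequence[GeneModel],
    promoter_len: int = DEFAULT_PROMOTER_LEN,
    min_score: Optional[float] = None,
    mod_type: str = "m4C",
) -> tuple[list[GeneMethylationDelta], MethylomeTotals]:
    """Per-gene deltas for a whole annotation, plus whole-sample totals.

    Overlapping genes are permitted: a call inside two CDS intervals counts
    toward both genes (logged once).
    """
    ordinals = [g.orf_ordinal for g in genes]
    if ordinals != sorted(ordinals):
        raise ValueError("genes must be sorted by ORF ordinal")
    wt_f = wt.filter_min_score(min_score)
    mut_f = mut.filter_min_score(min_score)
    totals = MethylomeTotals(wt_total=len(wt_f), mut_total=len(mut_f))

    _warn_overlaps(genes)
    deltas = [
        diff_gene_methylation(wt_f, mut_f, gene, promoter_len, None, mod_type)
        for gene in genes
    ]
    logger.info(
        "genome-wide diff: %d genes, %d WT calls, %d mutant calls",
        len(genes), totals.wt_total, totals.mut_total,
    )
    return deltas, totals


def _warn_overlaps(genes: Sequence[GeneModel]) -> None:
    by_contig: dict[str, list[GeneModel]] = {}
    for gene in genes:
        by_contig.setdefault(gene.seqid, []).append(gene)
    n_overlaps = 0
    for members in by_contig.values():
        members = sorted(members, key=lambda g: g.start)
        for left, right in zip(members, members[1:]):
            if right.start <= left.end:
                n_overlaps += 1
    if n_overlaps:
        logger.info(
            "%d overlapping CDS pairs: shared calls count toward every "
            "overlapping gene", n_overlaps,
        )


def format_loss_percent(fraction: float, decimals: int = 0) -> str:
    """Render a loss fraction as a percentage, rounding half-up.

    Whole percents for site loss (6/7 -> "86%"), one decimal for abundance
    loss.  Trailing ".0" is dropped at one decimal so 1.0 prints as "1%".
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"fraction must be within [0, 1], got {fraction}")
    if decimals not in (0, 1):
        raise ValueError("decimals must be 0 or 1")
    quantum = Decimal(1).scaleb(-decimals)
    percent = (Decimal(repr(fraction)) * 100).quantize(quantum, rounding=ROUND_HALF_UP)
    text = format(percent, "f")
    if text.endswith(".0"):
        text = text[:-2]
    return f"{text}%"
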