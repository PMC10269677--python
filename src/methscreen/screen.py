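"""Screening, flagging and ranking of regulator candidates.

The mining filter keeps genes that (a) look like regulators by product
annotation, (b) lost strictly more than 80% of their wild-type CDS m4C
sites, and (c) lost at least 1% methylation abundance (lost CDS sites per
CDS base, compared after rounding to one decimal percent so a gene printed
as exactly "1%" passes).  Dense-region membership and promoter loss then
drive the ranking but never filter: a strong out-of-region candidate stays
in the report, just lower down.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

from .density import DensityRegion, ordinal_in_regions
from .diff import GeneMethylationDelta
from .models import GeneModel

#: Product-annotation keywords marking presumed regulatory genes
#: (case-insensitive substring match).
DEFAULT_REGULATOR_KEYWORDS = (
    "regulator",
    "regulatory protein",
    "transcription factor",
    "sigma factor",
)

DEFAULT_MIN_SITE_LOSS = 0.80
DEFAULT_MIN_ABUNDANCE_LOSS = 0.01


@dataclass(frozen=True, slots=True)
class CandidateRecord:
    """One screened regulator candidate; ``rank`` is set only after ranking."""

    gene_id: str
    orf_ordinal: int
    product: str
    delta: GeneMethylationDelta
    is_regulator: bool
    in_dense_region: bool = False
    rank: Optional[int] = None


def identify_regulators(
    genes: Sequence[GeneModel],
    keywords: Sequence[str] = DEFAULT_REGULATOR_KEYWORDS,
) -> dict[str, bool]:
    """Flag presumed regulatory genes by product-annotation keywords."""
    if not keywords:
        raise ValueError("keyword list must be non-empty")
    lowered = [k.lower() for k in keywords]
    return {
        g.gene_id: any(k in g.product.lower() for k in lowered) for g in genes
    }


def _percent_1dp(fraction: float) -> Decimal:
    """Fraction as a one-decimal percent, rounded half-up (0.00995 -> 1.0)."""
    return (Decimal(repr(fraction)) * 100).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)


def screen_by_methylation(
    deltas: Sequence[GeneMethylationDelta],
    genes: Sequence[GeneModel],
    regulator_map: Mapping[str, bool],
    min_site_loss: float = DEFAULT_MIN_SITE_LOSS,
    min_abundance_loss: float = DEFAULT_MIN_ABUNDANCE_LOSS,
    min_wt_sites: int = 1,
) -> list[CandidateRecord]:
    """Apply the regulator + methylation-loss screen.

    Keeps genes that are regulator-flagged, have at least ``min_wt_sites``
    wild-type CDS sites, lost strictly more than ``min_site_loss`` of them,
    and whose abundance loss rounds to at least ``min_abundance_loss`` at
    one decimal percent.  Output is ordered by ORF ordinal.
    """
    if not (0.0 <= min_site_loss <= 1.0 and 0.0 <= min_abundance_loss <= 1.0):
        raise ValueError("thresholds must be within [0, 1]")
    gene_by_id = {g.gene_id: g for g in genes}
    abundance_cut = _percent_1dp(min_abundance_loss)
    out: list[CandidateRecord] = []
    for delta in deltas:
        gene = gene_by_id.get(delta.gene_id)
        if gene is None:
            raise KeyError(f"delta for unknown gene {delta.gene_id!r}")
        if not regulator_map.get(delta.gene_id, False):
            continue
        if delta.cds_sites_wt < min_wt_sites:
            continue
        if delta.cds_loss_fraction <= min_site_loss:
            continue
        if _percent_1dp(delta.abundance_loss_fraction) < abundance_cut:
            continue
        out.append(
            CandidateRecord(
                gene_id=gene.gene_id,
                orf_ordinal=gene.orf_ordinal,
                product=gene.product,
                delta=delta,
                is_regulator=True,
            )
        )
    out.sort(key=lambda r: r.orf_ordinal)
    return out


def flag_in_region(
    candidates: Sequence[CandidateRecord],
    regions: Sequence[DensityRegion],
) -> list[CandidateRecord]:
    """Mark each candidate's dense-region membership by ORF ordinal."""
    return [
        replace(c, in_dense_region=ordinal_in_regions(c.orf_ordinal, regions))
        for c in candidates
    ]


def rank_candidates(candidates: Sequence[CandidateRecord]) -> list[CandidateRecord]:
    """Total-order ranking of screened candidates.

    Sort key: dense-region membership first, then promoter loss, CDS site
    loss and abundance loss (all descending), with the ORF ordinal as the
    final ascending tie-break — so the output never depends on input order.
    """
    ordered = sorted(
        candidates,
        key=lambda c: (
            -int(c.in_dense_region),
            -c.delta.promoter_loss_fraction,
            -c.delta.cds_loss_fraction,
            -c.delta.abundance_loss_fraction,
            c.orf_ordinal,
        ),
    )
    return [replace(c, rank=i) for i, c in enumerate(ordered, start=1)]
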