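"""Cross-timepoint differential-expression intersection and sign filter.

Genes differentially expressed at *every* analysed time point ("crossover"
genes) are intersected across the per-timepoint DE tables, then kept only
when their log2 fold change has the same sign at all time points — a gene
that flips direction between time points is unlikely to be a direct target
of a single repressor or activator.  A fold change of exactly 0 can never
be "the same direction" and makes a gene inconsistent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .models import DETable

logger = logging.getLogger(__name__)

#: Default significance rule: |log2FC| >= 1, adjusted p <= 0.05.  When a
#: table carries no adjusted p-values the fold-change bound alone decides.
DEFAULT_MIN_ABS_LOG2FC = 1.0
DEFAULT_MAX_PADJ = 0.05

UP = "up"
DOWN = "down"
INCONSISTENT = "inconsistent"


@dataclass(frozen=True, slots=True)
class ConsistencyResult:
    """Sign-consistency verdict for one crossover gene."""

    gene_id: str
    fc_vector: tuple[float, ...]
    direction: str  # up | down | inconsistent

    def __post_init__(self) -> None:
        if self.direction not in (UP, DOWN, INCONSISTENT):
            raise ValueError(f"bad direction {self.direction!r}")


def classify_direction(fc_vector: Sequence[float]) -> str:
    """'up' iff all fold changes > 0, 'down' iff all < 0, else inconsistent."""
    if not fc_vector:
        raise ValueError("empty fold-change vector")
    if all(fc > 0 for fc in fc_vector):
        return UP
    if all(fc < 0 for fc in fc_vector):
        return DOWN
    return INCONSISTENT


def significant_genes(
    table: DETable,
    min_abs_log2fc: float = DEFAULT_MIN_ABS_LOG2FC,
    max_padj: float = DEFAULT_MAX_PADJ,
) -> set[str]:
    """Genes passing the DE significance rule in one table.

    A gene is kept iff ``|log2fc| >= min_abs_log2fc`` and its adjusted p is
    either absent (fold-change-only fallback) or ``<= max_padj``.
    """
    if min_abs_log2fc <= 0 or max_padj <= 0:
        raise ValueError("thresholds must be positive")
    kept = {
        gene_id
        for gene_id, (log2fc, padj) in table.rows.items()
        if abs(log2fc) >= min_abs_log2fc and (padj is None or padj <= max_padj)
    }
    logger.info(
        "%s: %d/%d genes significant (|log2FC| >= %g, padj <= %g; padj-less "
        "rows fall back to the fold-change rule)",
        table.time_label, len(kept), len(table), min_abs_log2fc, max_padj,
    )
    return kept


def crossover_genes(
    tables: Sequence[DETable],
    min_abs_log2fc: float = DEFAULT_MIN_ABS_LOG2FC,
    max_padj: float = DEFAULT_MAX_PADJ,
) -> set[str]:
    """Genes significant at every time point (set intersection over tables)."""
    if not tables:
        raise ValueError("at least one DE table is required")
    sets = [significant_genes(t, min_abs_log2fc, max_padj) for t in tables]
    out = set.intersection(*sets)
    logger.info("%d crossover genes across %d time points", len(out), len(tables))
    return out


def filter_consistent(
    crossover: set[str],
    tables: Sequence[DETable],
) -> list[ConsistencyResult]:
    """Classify each crossover gene's direction across all time points.

    Every crossover gene must appear in every table; the fold-change vector
    follows the table order given.  Results are ordered by gene id; the
    "selected" subset is the results whose direction is not inconsistent.
    """
    results: list[ConsistencyResult] = []
    for gene_id in sorted(crossover):
        fcs: list[float] = []
        for table in tables:
            if gene_id not in table:
                raise KeyError(
                    f"gene {gene_id!r} missing from DE table {table.time_label!r}"
                )
            fcs.append(table.log2fc(gene_id))
        results.append(
            ConsistencyResult(
                gene_id=gene_id,
                fc_vector=tuple(fcs),
                direction=classify_direction(fcs),
            )
        )
    return results


def selected(results: Sequence[ConsistencyResult]) -> list[ConsistencyResult]:
    """The sign-consistent subset (direction 'up' or 'down')."""
    return [r for r in results if r.direction != INCONSISTENT]


def write_consistency_tsv(
    results: Sequence[ConsistencyResult],
    time_labels: Sequence[str],
    path,
) -> None:
    import csv

    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene_id", *[f"log2fc_{t}" for t in time_labels], "direction"])
        for r in results:
            writer.writerow(
                [r.gene_id, *[format(fc, ".6g") for fc in r.fc_vector], r.direction]
            )
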