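"""Calling ORF-ordinal regions dense in pathway-assigned genes.

Genes are indexed by their ORF ordinal (the integer in the locus tag) and
grouped into fixed, non-overlapping ordinal bins anchored at 0 (default
width 100 ordinals).  A bin's density is the fraction of genes *present* in
the bin that belong to the configured pathway category, so ordinal gaps do
not dilute it.  Bins whose density strictly exceeds the threshold are
merged with qualifying neighbours into regions; all spans are half-open
``[start, end)`` ordinal intervals.

A sliding scan (``step`` smaller than ``bin_size``) is available for
exploration; region merging then unions overlapping qualifying windows.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Optional, Sequence

from .models import GeneModel, PathwayAssignment

DEFAULT_BIN_SIZE = 100
DEFAULT_DENSITY_THRESHOLD = 0.10


@dataclass(frozen=True, slots=True)
class DensityBin:
    """One ordinal window and its pathway-gene density."""

    bin_index: int
    start_ordinal: int
    end_ordinal: int  # half-open
    n_genes: int
    n_assigned: int
    density: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.density <= 1.0):
            raise ValueError(f"bin {self.bin_index}: density outside [0, 1]")
        if self.end_ordinal <= self.start_ordinal:
            raise ValueError(f"bin {self.bin_index}: empty ordinal span")


@dataclass(frozen=True, slots=True)
class DensityRegion:
    """A merged run of qualifying bins, half-open on ordinals."""

    start_ordinal: int
    end_ordinal: int
    n_bins: int
    max_density: float
    mean_density: float

    def __post_init__(self) -> None:
        if self.end_ordinal <= self.start_ordinal:
            raise ValueError("region must span at least one ordinal")

    @property
    def label(self) -> str:
        return f"orf{self.start_ordinal}-orf{self.end_ordinal}"


def compute_bin_densities(
    genes: Sequence[GeneModel],
    assignments: Sequence[PathwayAssignment],
    bin_size: int = DEFAULT_BIN_SIZE,
    origin: int = 0,
    step: Optional[int] = None,
) -> list[DensityBin]:
    """Bin genes by ORF ordinal and score each bin's pathway-gene density.

    Fixed windows ``[origin + k*step, origin + k*step + bin_size)`` for
    ``k = 0, 1, ...``; the default ``step = bin_size`` gives non-overlapping
    bins in which every gene falls exactly once.  Windows beyond the last
    gene are not emitted; empty windows within range are (density 0).
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    step = bin_size if step is None else step
    if step < 1:
        raise ValueError("step must be >= 1")
    if not genes:
        return []
    member = {a.gene_id: a.in_category for a in assignments}
    ordinals = sorted(g.orf_ordinal for g in genes)
    assigned_ordinals = sorted(
        g.orf_ordinal for g in genes if member.get(g.gene_id, False)
    )
    last = ordinals[-1]
    bins: list[DensityBin] = []
    k = 0
    while origin + k * step <= last:
        start = origin + k * step
        end = start + bin_size
        n_genes = bisect.bisect_left(ordinals, end) - bisect.bisect_left(ordinals, start)
        n_assigned = bisect.bisect_left(assigned_ordinals, end) - bisect.bisect_left(
            assigned_ordinals, start
        )
        bins.append(
            DensityBin(
                bin_index=k,
                start_ordinal=start,
                end_ordinal=end,
                n_genes=n_genes,
                n_assigned=n_assigned,
                density=n_assigned / n_genes if n_genes else 0.0,
            )
        )
        k += 1
    return bins


def call_dense_regions(
    bins: Sequence[DensityBin],
    threshold: float = DEFAULT_DENSITY_THRESHOLD,
) -> list[DensityRegion]:
    """Merge bins whose density strictly exceeds ``threshold`` into regions.

    Qualifying bins are merged when their ordinal spans touch or overlap;
    the region span is the union of the merged bins' spans.  Input bins must
    be ordered by start ordinal.
    """
    starts = [b.start_ordinal for b in bins]
    if starts != sorted(starts):
        raise ValueError("bins must be ordered by start_ordinal")
    qualifying = [b for b in bins if b.density > threshold]
    regions: list[DensityRegion] = []
    run: list[DensityBin] = []
    for b in qualifying:
        if run and b.start_ordinal <= run[-1].end_ordinal:
            run.append(b)
        else:
            if run:
                regions.append(_merge_run(run))
            run = [b]
    if run:
        regions.append(_merge_run(run))
    return regions


def _merge_run(run: list[DensityBin]) -> DensityRegion:
    densities = [b.density for b in run]
    return DensityRegion(
        start_ordinal=run[0].start_ordinal,
        end_ordinal=max(b.end_ordinal for b in run),
        n_bins=len(run),
        max_density=max(densities),
        mean_density=sum(densities) / len(densities),
    )


def ordinal_in_regions(ordinal: int, regions: Sequence[DensityRegion]) -> bool:
    """True iff the ordinal falls inside some region's half-open span."""
    return any(r.start_ordinal <= ordinal < r.end_ordinal for r in regions)
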