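"""Core domain types shared by every pipeline stage.

A *methylome* here is the complete set of called modified-base positions of
one sample, keyed by ``(seqid, position, strand, mod_type)``.  Genes are
single-interval bacterial CDS records whose locus tags carry an ORF ordinal
(``orf4759`` -> 4759) used as a positional index along the chromosome.
"""

from __future__ import annotations

import bisect
import logging
import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional

logger = logging.getLogger(__name__)

#: Base modifications called per strand by SMRT kinetic analysis.
KNOWN_MOD_TYPES = frozenset({"m4C", "m6A", "m5C"})

#: (seqid, position, strand, mod_type) — the identity of one called site.
CallKey = tuple[str, int, str, str]


@dataclass(frozen=True, slots=True)
class ModificationCall:
    """One called modified base on one strand.

    ``score`` is the Phred-like identification quality; ``None`` means the
    caller did not report one.  ``coverage`` is the read depth at the site.
    """

    seqid: str
    position: int  # 1-based genomic coordinate
    strand: str
    mod_type: str
    score: Optional[float] = None
    coverage: Optional[int] = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.mod_type not in KNOWN_MOD_TYPES:
            raise ValueError(f"unknown mod_type {self.mod_type!r}")
        if self.score is not None and self.score < 0:
            raise ValueError(f"score must be non-negative, got {self.score}")
        if self.coverage is not None and self.coverage < 0:
            raise ValueError(f"coverage must be non-negative, got {self.coverage}")

    @property
    def key(self) -> CallKey:
        return (self.seqid, self.position, self.strand, self.mod_type)


class Methylome:
    """Keyed collection of :class:`ModificationCall` for one sample.

    Duplicate keys collapse deterministically to the call with the higher
    score (a call with a score outranks one without).
    """

    def __init__(self, sample_id: str = "", calls: Optional[Iterator[ModificationCall]] = None):
        self.sample_id = sample_id
        self._calls: dict[CallKey, ModificationCall] = {}
        self._index: Optional[dict[str, tuple[list[int], list[CallKey]]]] = None
        self._contigs: Optional[set[str]] = None
        for call in calls or ():
            self.add(call)

    def add(self, call: ModificationCall) -> None:
        self._index = None
        self._contigs = None
        existing = self._calls.get(call.key)
        if existing is None:
            self._calls[call.key] = call
        else:
            old = -math.inf if existing.score is None else existing.score
            new = -math.inf if call.score is None else call.score
            if new > old:
                self._calls[call.key] = call

    def keys_in_interval(self, seqid: str, lo: int, hi: int) -> list[CallKey]:
        """Call keys with genomic position in [lo, hi] on ``seqid`` (any strand).

        Backed by a per-contig sorted position index built lazily and
        invalidated on mutation.
        """
        if hi < lo:
            return []
        if self._index is None:
            index: dict[str, list[tuple[int, CallKey]]] = {}
            for key in self._calls:
                index.setdefault(key[0], []).append((key[1], key))
            self._index = {}
            for contig, entries in index.items():
                entries.sort()
                self._index[contig] = (
                    [e[0] for e in entries],
                    [e[1] for e in entries],
                )
        positions, keys = self._index.get(seqid, ([], []))
        left = bisect.bisect_left(positions, lo)
        right = bisect.bisect_right(positions, hi)
        return keys[left:right]

    def __len__(self) -> int:
        return len(self._calls)

    def __iter__(self) -> Iterator[ModificationCall]:
        return iter(self._calls.values())

    def __contains__(self, key: CallKey) -> bool:
        return key in self._calls

    @property
    def calls(self) -> Mapping[CallKey, ModificationCall]:
        return self._calls

    def keys(self) -> set[CallKey]:
        return set(self._calls)

    def contigs(self) -> set[str]:
        if self._contigs is None:
            self._contigs = {k[0] for k in self._calls}
        return self._contigs

    def filter_mod_type(self, mod_types: set[str] | frozenset[str]) -> "Methylome":
        out = Methylome(self.sample_id)
        out._calls = {k: c for k, c in self._calls.items() if c.mod_type in mod_types}
        return out

    def filter_min_score(self, min_score: Optional[float]) -> "Methylome":
        """Drop calls scoring below ``min_score``; unscored calls are kept."""
        if min_score is None:
            return self
        out = Methylome(self.sample_id)
        out._calls = {
            k: c for k, c in self._calls.items() if c.score is None or c.score >= min_score
        }
        return out

    def sorted_calls(self) -> list[ModificationCall]:
        return [self._calls[k] for k in sorted(self._calls)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Methylome):
            return NotImplemented
        return self._calls == other._calls

    def __repr__(self) -> str:
        return f"Methylome({self.sample_id!r}, n={len(self)})"


@dataclass(frozen=True, slots=True)
class GeneModel:
    """A single-interval bacterial CDS with an ORF ordinal.

    Coordinates are 1-based inclusive, matching GFF3.  Multi-part CDS
    features are out of scope and rejected at parse time.
    """

    gene_id: str
    orf_ordinal: int
    seqid: str
    start: int
    end: int
    strand: str
    product: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.orf_ordinal < 1:
            raise ValueError(f"{self.gene_id}: orf_ordinal must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.cds_length % 3 != 0:
            logger.warning(
                "%s: CDS length %d is not a multiple of 3", self.gene_id, self.cds_length
            )

    @property
    def cds_length(self) -> int:
        return self.end - self.start + 1

    @property
    def protein_length(self) -> int:
        """Encoded amino acids: codons minus the stop codon (621 bp -> 206 aa)."""
        return self.cds_length // 3 - 1


@dataclass(frozen=True, slots=True)
class PathwayAssignment:
    """Membership of one gene in the configured pathway category.

    The default category mirrors the KEGG "environmental information
    processing" assignment used when screening stress-response regulators.
    """

    gene_id: str
    in_category: bool


@dataclass
class DETable:
    """One time point's differential-expression results.

    ``rows`` maps gene_id to ``(log2fc, padj)``; ``padj`` is ``None`` when the
    source table carried no adjusted-p column.
    """

    time_label: str
    rows: dict[str, tuple[float, Optional[float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene_id, (log2fc, padj) in self.rows.items():
            if not math.isfinite(log2fc):
                raise ValueError(f"{self.time_label}/{gene_id}: log2fc must be finite")
            if padj is not None and not (0.0 <= padj <= 1.0):
                raise ValueError(f"{self.time_label}/{gene_id}: padj outside [0, 1]")

    def __len__(self) -> int:
        return len(self.rows)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.rows

    def log2fc(self, gene_id: str) -> float:
        return self.rows[gene_id][0]

    def padj(self, gene_id: str) -> Optional[float]:
        return self.rows[gene_id][1]
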