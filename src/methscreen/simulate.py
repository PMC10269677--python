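"""Seeded synthetic data with a planted ground-truth manifest.

The generator emulates the structure of a paired wild-type /
methyltransferase-knockout m4C study on a single bacterial chromosome:

* an annotation of single-interval CDS genes tiled along one contig with
  ORF ordinals 1..n, a configurable fraction carrying regulator-like
  product annotations;
* a wild-type methylome with sites placed uniformly over gene bodies and
  upstream intergenic windows, and a mutant methylome that loses *all*
  sites of a planted set of target genes (CDS and promoter) plus an
  independent background fraction of the remaining sites — mimicking
  near-complete loss at methyltransferase targets over partial genome-wide
  retention;
* a pathway-assignment table with membership enriched inside planted
  ordinal spans (clustered pathway genes) over a sparse background;
* per-timepoint DE tables in which planted genes are sign-consistent
  (up or down) at every time point and optional "mixed" genes flip sign.

Everything is driven by one master seed through per-generator derived
streams, so each piece can be regenerated independently and two runs with
the same seed produce byte-identical output files.

No sequence is simulated: the screen depends only on counts and positions,
so motif and kinetic realism are out of scope.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from . import io as msio
from .models import DETable, GeneModel, Methylome, ModificationCall, PathwayAssignment

RngLike = Union[int, np.random.Generator]

#: Planted methyltransferase targets are densely methylated: ~15 CDS sites
#: per kb, the density seen at archetypal targets (e.g. 9 sites in 621 bp).
PLANTED_SITE_PER_KB = 15.0

REGULATOR_PRODUCTS = (
    "Transcriptional regulator, TetR family",
    "Transcriptional regulator, AcrR family",
    "Transcriptional regulator, IclR family",
    "Transcriptional regulator, WhiB family",
    "Regulatory protein",
    "RNA polymerase sigma factor",
    "Two-component system response regulator",
)

OTHER_PRODUCTS = (
    "ABC transporter, ATP-binding protein",
    "O-antigen export system, permease protein",
    "Arsenate reductase, thioredoxin-coupled",
    "Flavin-dependent monooxygenase",
    "NADH:flavin oxidoreductase",
    "Peptidase S1 and S6, chymotrypsin/Hap",
    "Polyketide synthase module",
    "Hypothetical protein",
    "Thioredoxin reductase",
    "Arsenical resistance protein ACR3",
)


def _rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def derive_streams(seed: int, n: int) -> list[np.random.Generator]:
    """Independent child RNG streams derived from one master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


@dataclass
class SyntheticTruth:
    """Ground-truth manifest: what was planted, and with which settings."""

    seed: int
    planted_candidate_ids: list[str] = field(default_factory=list)
    planted_region_spans: list[tuple[int, int]] = field(default_factory=list)
    planted_up_ids: list[str] = field(default_factory=list)
    planted_down_ids: list[str] = field(default_factory=list)
    planted_mixed_ids: list[str] = field(default_factory=list)
    wt_site_counts: dict[str, int] = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "planted_candidate_ids": self.planted_candidate_ids,
            "planted_region_spans": [list(s) for s in self.planted_region_spans],
            "planted_up_ids": self.planted_up_ids,
            "planted_down_ids": self.planted_down_ids,
            "planted_mixed_ids": self.planted_mixed_ids,
            "wt_site_counts": self.wt_site_counts,
            "parameters": self.parameters,
        }
        with open(path, "w") as handle:
            json.dump(payload, handle, indent=2, sort_keys=True)
            handle.write("\n")

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as handle:
            payload = json.load(handle)
        payload["planted_region_spans"] = [
            tuple(s) for s in payload["planted_region_spans"]
        ]
        return cls(**payload)


def generate_annotation(
    n_genes: int,
    mean_cds_len: int = 900,
    intergenic_len: int = 150,
    regulator_fraction: float = 0.08,
    seed: RngLike = 0,
    seqid: str = "chr",
) -> list[GeneModel]:
    """Tile ``n_genes`` single-interval CDS genes along one contig.

    CDS lengths are drawn around ``mean_cds_len`` (multiples of 3, at least
    150 bp); consecutive genes are separated by exactly ``intergenic_len``
    bases; strands alternate at random.  ``regulator_fraction`` of products
    come from a regulator-keyword phrase list.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = _rng(seed)
    genes: list[GeneModel] = []
    cursor = intergenic_len + 1
    for ordinal in range(1, n_genes + 1):
        codons = max(50, int(round(rng.normal(mean_cds_len / 3, mean_cds_len / 9))))
        length = 3 * codons
        is_regulator = rng.random() < regulator_fraction
        pool = REGULATOR_PRODUCTS if is_regulator else OTHER_PRODUCTS
        product = pool[int(rng.integers(len(pool)))]
        genes.append(
            GeneModel(
                gene_id=f"orf{ordinal}",
                orf_ordinal=ordinal,
                seqid=seqid,
                start=cursor,
                end=cursor + length - 1,
                strand="+" if rng.random() < 0.5 else "-",
                product=product,
            )
        )
        cursor += length + intergenic_len
    return genes


def _upstream_gap_window(
    gene: GeneModel, genes_sorted: list[GeneModel], index: int, promoter_len: int
) -> tuple[int, int]:
    """Upstream promoter placement window, clipped to the intergenic gap.

    Sites are only placed between CDS intervals, so a planted gene's
    promoter loss can be made complete without touching a neighbour's CDS.
    """
    if gene.strand == "+":
        prev_end = genes_sorted[index - 1].end if index > 0 else 0
        lo = max(prev_end + 1, gene.start - promoter_len, 1)
        return (lo, gene.start - 1)
    next_start = (
        genes_sorted[index + 1].start
        if index + 1 < len(genes_sorted)
        else gene.end + promoter_len + 1
    )
    hi = min(next_start - 1, gene.end + promoter_len)
    return (gene.end + 1, hi)


def _place_sites(
    rng: np.random.Generator,
    seqid: str,
    lo: int,
    hi: int,
    count: int,
    occupied: set[int],
) -> list[ModificationCall]:
    """Place ``count`` distinct m4C calls uniformly in [lo, hi]."""
    width = hi - lo + 1
    if width <= 0 or count <= 0:
        return []
    available = [p for p in range(lo, hi + 1) if p not in occupied]
    count = min(count, len(available))
    positions = rng.choice(len(available), size=count, replace=False)
    calls = []
    for idx in sorted(int(i) for i in positions):
        position = available[idx]
        occupied.add(position)
        calls.append(
            ModificationCall(
                seqid=seqid,
                position=position,
                strand="+" if rng.random() < 0.5 else "-",
                mod_type="m4C",
                score=float(rng.integers(20, 200)),
                coverage=int(rng.poisson(60)) + 1,
            )
        )
    return calls


def generate_methylomes(
    genes: Sequence[GeneModel],
    site_rate: float = 8.0,
    planted_candidates: Sequence[str] = (),
    background_loss_rate: float = 0.3,
    promoter_len: int = 150,
    seed: RngLike = 0,
    min_wt_sites: int = 5,
) -> tuple[Methylome, Methylome, SyntheticTruth]:
    """Paired wild-type/mutant m4C methylomes with planted total loss.

    Wild-type sites are placed uniformly at ``site_rate`` sites per kb over
    CDS bodies and upstream intergenic promoter windows.  Planted genes are
    densely methylated (``PLANTED_SITE_PER_KB`` per kb of CDS, never fewer
    than ``min_wt_sites``, plus at least one promoter site).  The mutant
    methylome drops every site inside a planted gene's CDS or promoter
    window, then an independent ``background_loss_rate`` fraction of the
    remaining sites.
    """
    if not (0.0 <= background_loss_rate <= 1.0):
        raise ValueError("background_loss_rate must be within [0, 1]")
    planted = set(planted_candidates)
    known = {g.gene_id for g in genes}
    if not planted <= known:
        raise ValueError(f"planted genes not in annotation: {sorted(planted - known)}")
    rng = _rng(seed)
    genes_sorted = sorted(genes, key=lambda g: (g.seqid, g.start))
    occupied: set[int] = set()
    wt = Methylome("wt_synthetic")
    planted_intervals: list[tuple[str, int, int]] = []
    wt_site_counts: dict[str, int] = {}
    for index, gene in enumerate(genes_sorted):
        p_lo, p_hi = _upstream_gap_window(gene, genes_sorted, index, promoter_len)
        if gene.gene_id in planted:
            n_cds = max(min_wt_sites, math.ceil(PLANTED_SITE_PER_KB * gene.cds_length / 1000))
            n_prom = max(1, int(rng.poisson(site_rate * max(0, p_hi - p_lo + 1) / 1000)))
            planted_intervals.append((gene.seqid, gene.start, gene.end))
            if p_hi >= p_lo:
                planted_intervals.append((gene.seqid, p_lo, p_hi))
        else:
            n_cds = int(rng.poisson(site_rate * gene.cds_length / 1000))
            n_prom = int(rng.poisson(site_rate * max(0, p_hi - p_lo + 1) / 1000))
        calls = _place_sites(rng, gene.seqid, gene.start, gene.end, n_cds, occupied)
        calls += _place_sites(rng, gene.seqid, p_lo, p_hi, n_prom, occupied)
        wt_site_counts[gene.gene_id] = len(calls)
        for call in calls:
            wt.add(call)

    mut = Methylome("mut_synthetic")
    for call in wt:
        in_planted = any(
            call.seqid == seqid and lo <= call.position <= hi
            for seqid, lo, hi in planted_intervals
        )
        if in_planted:
            continue
        if background_loss_rate > 0 and rng.random() < background_loss_rate:
            continue
        mut.add(call)

    truth = SyntheticTruth(
        seed=-1,
        planted_candidate_ids=sorted(planted),
        wt_site_counts=wt_site_counts,
        parameters={
            "site_rate_per_kb": site_rate,
            "background_loss_rate": background_loss_rate,
            "promoter_len": promoter_len,
            "min_wt_sites": min_wt_sites,
            "planted_site_per_kb": PLANTED_SITE_PER_KB,
        },
    )
    return wt, mut, truth


def generate_pathway_table(
    genes: Sequence[GeneModel],
    region_spans: Sequence[tuple[int, int]] = (),
    in_region_rate: float = 0.3,
    background_rate: float = 0.02,
    seed: RngLike = 0,
) -> list[PathwayAssignment]:
    """Per-gene pathway membership, enriched inside planted ordinal spans."""
    for rate in (in_region_rate, background_rate):
        if not (0.0 <= rate <= 1.0):
            raise ValueError("rates must be within [0, 1]")
    rng = _rng(seed)
    out = []
    for gene in genes:
        inside = any(lo <= gene.orf_ordinal < hi for lo, hi in region_spans)
        rate = in_region_rate if inside else background_rate
        out.append(PathwayAssignment(gene.gene_id, bool(rng.random() < rate)))
    return out


def generate_de_tables(
    genes: Sequence[GeneModel],
    time_labels: Sequence[str] = ("48h", "72h", "120h"),
    planted_up: Sequence[str] = (),
    planted_down: Sequence[str] = (),
    planted_mixed: Sequence[str] = (),
    lfc_magnitude: float = 4.0,
    noise_sd: float = 0.3,
    null_sd: float = 0.3,
    seed: RngLike = 0,
) -> tuple[list[DETable], SyntheticTruth]:
    """Per-timepoint DE tables with sign-consistent planted genes.

    Planted up/down genes get ``±lfc_magnitude`` plus Gaussian noise at
    every time point (adjusted p 0.001); "mixed" genes get the magnitude
    with a deliberately flipped sign at the last time point, so they pass
    per-timepoint significance but fail the consistency filter; null genes
    get noise only (adjusted p 0.9).
    """
    up, down, mixed = set(planted_up), set(planted_down), set(planted_mixed)
    overlap = (up & down) | (up & mixed) | (down & mixed)
    if overlap:
        raise ValueError(f"planted DE sets overlap: {sorted(overlap)}")
    rng = _rng(seed)
    k = len(time_labels)
    tables = []
    for t_index, label in enumerate(time_labels):
        rows: dict[str, tuple[float, Optional[float]]] = {}
        for gene in genes:
            gid = gene.gene_id
            if gid in up:
                rows[gid] = (lfc_magnitude + rng.normal(0, noise_sd), 0.001)
            elif gid in down:
                rows[gid] = (-lfc_magnitude + rng.normal(0, noise_sd), 0.001)
            elif gid in mixed:
                sign = -1.0 if (t_index == k - 1 and k > 1) else 1.0
                rows[gid] = (sign * lfc_magnitude + rng.normal(0, noise_sd), 0.001)
            else:
                rows[gid] = (rng.normal(0, null_sd), 0.9)
        tables.append(DETable(time_label=label, rows=rows))
    truth = SyntheticTruth(
        seed=-1,
        planted_up_ids=sorted(up),
        planted_down_ids=sorted(down),
        planted_mixed_ids=sorted(mixed),
        parameters={
            "time_labels": list(time_labels),
            "lfc_magnitude": lfc_magnitude,
            "noise_sd": noise_sd,
            "null_sd": null_sd,
        },
    )
    return tables, truth


def default_region_spans(n_genes: int, n_regions: int = 4, bin_size: int = 100) -> list[tuple[int, int]]:
    """Evenly spaced planted ordinal spans aligned to bin boundaries.

    Span widths alternate between two and one bin, echoing the mix of
    single- and double-bin clusters seen in real pathway annotations.
    """
    spans: list[tuple[int, int]] = []
    for i in range(n_regions):
        center = (i + 1) * n_genes // (n_regions + 1)
        start = max(bin_size, (center // bin_size) * bin_size)
        width = 2 * bin_size if i % 2 == 0 else bin_size
        if start + width > n_genes:
            start = max(bin_size, ((n_genes - width) // bin_size) * bin_size)
        span = (start, start + width)
        if spans and span[0] < spans[-1][1]:
            continue
        spans.append(span)
    return spans


@dataclass
class ScenarioData:
    """A complete synthetic study: inputs for every pipeline stage + truth."""

    genes: list[GeneModel]
    wt: Methylome
    mut: Methylome
    assignments: list[PathwayAssignment]
    de_tables: list[DETable]
    truth: SyntheticTruth

    def write(self, outdir) -> dict[str, Path]:
        """Write every input file (plus the truth manifest) into ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "annotation": outdir / "annotation.gff3",
            "wt": outdir / "wt_methylome.tsv",
            "mut": outdir / "mut_methylome.tsv",
            "pathway": outdir / "pathway.tsv",
            "truth": outdir / "truth.json",
        }
        msio.write_gene_annotation(self.genes, paths["annotation"])
        msio.write_methylome_tsv(self.wt, paths["wt"])
        msio.write_methylome_tsv(self.mut, paths["mut"])
        msio.write_pathway_table(self.assignments, paths["pathway"])
        for table in self.de_tables:
            path = outdir / f"de_{table.time_label}.tsv"
            msio.write_de_table(table, path)
            paths[f"de_{table.time_label}"] = path
        self.truth.to_json(paths["truth"])
        return paths


def simulate_scenario(
    n_genes: int = 6000,
    seed: int = 0,
    n_in_region_candidates: int = 2,
    n_out_region_candidates: int = 5,
    n_planted_up: int = 2,
    n_planted_down: int = 7,
    n_planted_mixed: int = 3,
    site_rate: float = 8.0,
    background_loss_rate: float = 0.3,
    promoter_len: int = 150,
    in_region_rate: float = 0.3,
    background_rate: float = 0.02,
    noise_sd: float = 0.3,
    region_spans: Optional[Sequence[tuple[int, int]]] = None,
    time_labels: Sequence[str] = ("48h", "72h", "120h"),
    regulator_fraction: float = 0.08,
) -> ScenarioData:
    """Generate a full synthetic study mirroring the mining workflow's scale.

    Plants regulator-annotated methyltransferase-target genes both inside
    and outside pathway-dense ordinal spans, and sign-consistent plus
    sign-flipping DE genes, then records everything in the truth manifest.
    """
    ann_rng, meth_rng, path_rng, de_rng, pick_rng = derive_streams(seed, 5)
    genes = generate_annotation(
        n_genes, regulator_fraction=regulator_fraction, seed=ann_rng
    )
    spans = list(region_spans) if region_spans is not None else default_region_spans(n_genes)

    regulator_like = [
        g for g in genes if any(p == g.product for p in REGULATOR_PRODUCTS)
    ]
    in_span = [
        g for g in regulator_like
        if any(lo <= g.orf_ordinal < hi for lo, hi in spans)
    ]
    out_span = [g for g in regulator_like if g not in in_span]
    if len(in_span) < n_in_region_candidates or len(out_span) < n_out_region_candidates:
        raise ValueError(
            "not enough regulator-annotated genes to plant candidates; "
            "increase n_genes or regulator_fraction"
        )
    planted_in = [
        in_span[i] for i in sorted(
            pick_rng.choice(len(in_span), size=n_in_region_candidates, replace=False)
        )
    ]
    planted_out = [
        out_span[i] for i in sorted(
            pick_rng.choice(len(out_span), size=n_out_region_candidates, replace=False)
        )
    ]
    planted_candidates = sorted(
        (g.gene_id for g in planted_in + planted_out),
        key=lambda gid: int(gid.removeprefix("orf")),
    )

    wt, mut, meth_truth = generate_methylomes(
        genes,
        site_rate=site_rate,
        planted_candidates=planted_candidates,
        background_loss_rate=background_loss_rate,
        promoter_len=promoter_len,
        seed=meth_rng,
    )
    assignments = generate_pathway_table(
        genes, spans, in_region_rate, background_rate, seed=path_rng
    )

    non_candidates = [g.gene_id for g in genes if g.gene_id not in set(planted_candidates)]
    n_de = n_planted_up + n_planted_down + n_planted_mixed
    picked = [
        non_candidates[i]
        for i in sorted(pick_rng.choice(len(non_candidates), size=n_de, replace=False))
    ]
    planted_up = picked[:n_planted_up]
    planted_down = picked[n_planted_up:n_planted_up + n_planted_down]
    planted_mixed = picked[n_planted_up + n_planted_down:]
    de_tables, de_truth = generate_de_tables(
        genes,
        time_labels=time_labels,
        planted_up=planted_up,
        planted_down=planted_down,
        planted_mixed=planted_mixed,
        noise_sd=noise_sd,
        seed=de_rng,
    )

    truth = SyntheticTruth(
        seed=seed,
        planted_candidate_ids=list(planted_candidates),
        planted_region_spans=[tuple(s) for s in spans],
        planted_up_ids=de_truth.planted_up_ids,
        planted_down_ids=de_truth.planted_down_ids,
        planted_mixed_ids=de_truth.planted_mixed_ids,
        wt_site_counts=meth_truth.wt_site_counts,
        parameters={
            "n_genes": n_genes,
            "regulator_fraction": regulator_fraction,
            "in_region_rate": in_region_rate,
            "background_rate": background_rate,
            **meth_truth.parameters,
            **de_truth.parameters,
        },
    )
    return ScenarioData(
        genes=genes,
        wt=wt,
        mut=mut,
        assignments=assignments,
        de_tables=de_tables,
        truth=truth,
    )
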