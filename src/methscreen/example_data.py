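"""Worked example: the published S. roseosporus tagR mining results.

These are the printed end-point numbers of the wild-type vs ΔsroLm3 m4C
methylome screen that discovered the TetR-family regulator TagR
(orf4759), bundled so the arithmetic of every pipeline stage can be
checked against a real study without any download:

* the seven screened regulator genes with their lost/total CDS m4C site
  counts, promoter loss and product annotations;
* the four pathway-dense ORF-ordinal regions of the KEGG environmental
  information processing category;
* the twelve crossover genes of the ΔtagR time-course transcriptome
  (48 h, 72 h, 120 h) with their log2 fold changes — nine of which are
  sign-consistent (tagH and tagG up; seven arsenic-resistance-cluster
  genes down);
* the TagR gene itself: a 621 bp CDS (206 encoded amino acids) with nine
  CDS m4C sites and one site 9 bp upstream, all absent in the mutant.

The underlying raw methylomes are not redistributed here; only these
printed summary values are.
"""

from __future__ import annotations

from .models import DETable

#: Screened regulator genes: ordinal -> (lost, total) CDS m4C sites,
#: (promoter_lost, promoter_total), product annotation.
SCREENED_REGULATORS: list[dict] = [
    {"gene": "orf199", "ordinal": 199, "cds": (6, 7), "promoter": (0, 0),
     "product": "Transcriptional regulator, AcrR family"},
    {"gene": "orf441", "ordinal": 441, "cds": (7, 8), "promoter": (0, 0),
     "product": "Regulatory protein"},
    {"gene": "orf1070", "ordinal": 1070, "cds": (20, 24), "promoter": (0, 0),
     "product": "Regulator of polyketide synthase expression"},
    {"gene": "orf1818", "ordinal": 1818, "cds": (12, 13), "promoter": (0, 0),
     "product": "Transcriptional regulator, CdaR-family"},
    {"gene": "orf2391", "ordinal": 2391, "cds": (5, 6), "promoter": (0, 0),
     "product": "Transcriptional regulator, WhiB family"},
    {"gene": "tagR", "ordinal": 4759, "cds": (9, 9), "promoter": (1, 1),
     "product": "Transcriptional regulator, TetR family"},
    {"gene": "orf4820", "ordinal": 4820, "cds": (11, 12), "promoter": (0, 0),
     "product": "Transcriptional regulator, IclR family"},
]

#: The printed whole-percent site-loss strings for the rows above.
SCREENED_SITE_LOSS_PERCENTS = ["86%", "88%", "83%", "92%", "83%", "100%", "92%"]

#: Pathway-dense ORF-ordinal regions (half-open spans).
DENSE_REGION_SPANS: list[tuple[int, int]] = [
    (700, 900),
    (1600, 1700),
    (2200, 2300),
    (4700, 4900),
]

#: Time-course crossover genes: gene -> log2FC at (48 h, 72 h, 120 h).
CROSSOVER_LOG2FC: dict[str, tuple[float, float, float]] = {
    "tagH": (6.06, 6.19, 6.24),
    "tagG": (4.72, 5.01, 4.48),
    "orf488": (-1.26, -2.30, -4.24),
    "orf492": (-1.33, -1.92, -2.17),
    "orf494": (-2.07, -2.61, -2.43),
    "orf495": (-2.41, -2.86, -1.76),
    "orf496": (-2.15, -2.27, -1.76),
    "orf497": (-1.80, -1.85, -1.94),
    "orf3562": (-2.43, -3.83, -4.30),
    "orf1359": (-2.08, -1.18, 1.93),
    "orf2787": (-2.85, 1.21, 3.19),
    "orf961": (-1.48, 1.17, -3.46),
}

CROSSOVER_TIME_LABELS = ("48h", "72h", "120h")

#: TagR gene facts: CDS length and m4C site placement in the wild type.
TAGR_CDS_LENGTH = 621
TAGR_CDS_SITE_POSITIONS = (213, 237, 309, 314, 423, 462, 476, 477, 554)
TAGR_PROMOTER_SITE_UPSTREAM_BP = 9

#: Genome-scale context of the source study (not recomputable here).
WT_TOTAL_M4C_SITES = 23847
MUTANT_TOTAL_M4C_SITES = 15646
TOTAL_ORFS = 7144
PATHWAY_ASSIGNED_GENES = 269
PRESUMED_REGULATOR_GENES = 552


def crossover_de_tables() -> list[DETable]:
    """The published crossover fold changes as one DE table per time point.

    No adjusted p-values were printed alongside the fold changes, so every
    padj is absent and significance falls back to the fold-change rule.
    """
    tables = []
    for index, label in enumerate(CROSSOVER_TIME_LABELS):
        rows = {
            gene: (fcs[index], None) for gene, fcs in CROSSOVER_LOG2FC.items()
        }
        tables.append(DETable(time_label=label, rows=rows))
    return tables
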