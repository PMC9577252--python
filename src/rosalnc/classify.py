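"""Positional classification of lncRNAs against protein-coding genes.

Each lncRNA receives exactly one of four categories, tested in this
precedence order (exon-level evidence ranks above containment):

1. antisense          -- >=1 bp overlap between a lncRNA exon and a coding
                         exon on the opposite strand;
2. sense_overlapping  -- >=1 bp overlap with a coding exon on the same strand;
3. sense_intronic     -- lncRNA interval wholly inside a coding gene span
                         with no exonic overlap on either strand (containment,
                         not strand, drives this class);
4. lincRNA            -- everything else (intergenic).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .identify import longest_orf
from .io_formats import Gene, GeneAnnotation, TranscriptModel, ValidationError

logger = logging.getLogger(__name__)

CATEGORIES = ("lincRNA", "antisense", "sense_overlapping", "sense_intronic")


@dataclass(frozen=True)
class PositionalClass:
    transcript_id: str
    category: str
    partner_gene_id: Optional[str]
    strand_label: str  # Watson | Crick | unstranded

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown category {self.category!r}")
        if (self.partner_gene_id is None) != (self.category == "lincRNA"):
            raise ValidationError("partner gene present iff category != lincRNA")


def _strand_label(strand: str) -> str:
    return {"+": "Watson", "-": "Crick"}.get(strand, "unstranded")


def _closest(genes: Sequence[Gene], lnc: TranscriptModel) -> Gene:
    mid = lnc.interval.midpoint
    return min(genes, key=lambda g: (abs(g.interval.midpoint - mid), g.gene_id))


def classify_position(
    lnc: TranscriptModel, annotation: GeneAnnotation
) -> PositionalClass:
    """Assign one positional category relative to protein-coding genes."""
    coding = [g for g in annotation.protein_coding if g.interval.chrom == lnc.chrom]

    antisense_partners: list[Gene] = []
    sense_partners: list[Gene] = []
    containing: list[Gene] = []
    for gene in coding:
        exons = gene.exons or [gene.interval]
        opposite = same = False
        for ge in exons:
            for le in lnc.exons:
                if not le.overlaps(ge):
                    continue
                if {le.strand, ge.strand} == {"+", "-"}:
                    opposite = True
                elif le.strand == ge.strand and le.strand in ("+", "-"):
                    same = True
        if opposite:
            antisense_partners.append(gene)
        if same:
            sense_partners.append(gene)
        if not opposite and not same and gene.interval.contains(lnc.interval):
            # containment counts only without exonic overlap on either strand
            if not any(
                le.overlaps(ge) for ge in exons for le in lnc.exons
            ):
                containing.append(gene)

    if antisense_partners:
        partner = _closest(antisense_partners, lnc)
        category = "antisense"
    elif sense_partners:
        partner = _closest(sense_partners, lnc)
        category = "sense_overlapping"
    elif containing:
        partner = _closest(containing, lnc)
        category = "sense_intronic"
    else:
        return PositionalClass(
            lnc.transcript_id, "lincRNA", None, _strand_label(lnc.strand)
        )
    return PositionalClass(
        lnc.transcript_id, category, partner.gene_id, _strand_label(lnc.strand)
    )


def classify_all(
    lncRNAs: Sequence[TranscriptModel], annotation: GeneAnnotation
) -> list[PositionalClass]:
    return [classify_position(lnc, annotation) for lnc in lncRNAs]


def strand_counts(classes: Sequence[PositionalClass]) -> pd.DataFrame:
    """Per-category Watson/Crick (and unstranded) tallies."""
    n_unstranded = sum(c.strand_label == "unstranded" for c in classes)
    if n_unstranded:
        logger.warning("%d lncRNAs without strand counted as unstranded", n_unstranded)
    rows = []
    for cat in CATEGORIES:
        members = [c for c in classes if c.category == cat]
        rows.append(
            {
                "category": cat,
                "Watson": sum(c.strand_label == "Watson" for c in members),
                "Crick": sum(c.strand_label == "Crick" for c in members),
                "unstranded": sum(c.strand_label == "unstranded" for c in members),
            }
        )
    df = pd.DataFrame(rows).set_index("category")
    total = int(df.values.sum())
    df["proportion"] = df.sum(axis=1) / total if total else 0.0
    return df


# ---------------------------------------------------------------------------
# Feature distributions (length / exon count / ORF length)
# ---------------------------------------------------------------------------

LENGTH_BIN_EDGES = [0, 300, 400, 500, 600, 700, 800, 900, 1000]
LENGTH_BIN_LABELS = [
    "<300",
    "300-400",
    "400-500",
    "500-600",
    "600-700",
    "700-800",
    "800-900",
    "900-1000",
    ">1000",
]
EXON_BIN_LABELS = [str(i) for i in range(1, 11)] + [">10"]
ORF_BIN_EDGES = list(range(0, 1001, 100))
ORF_BIN_LABELS = [
    "<100",
    "100-200",
    "200-300",
    "300-400",
    "400-500",
    "500-600",
    "600-700",
    "700-800",
    "800-900",
    "900-1000",
    ">=1000",
]


def _bin_left_closed(value: float, edges: list[int], labels: list[str]) -> str:
    # labels has len(edges) entries; the last label is the open right tail
    for i in range(1, len(edges)):
        if value < edges[i]:
            return labels[i - 1]
    return labels[-1]


def _histogram(values, binner) -> pd.Series:
    counts: dict[str, int] = {}
    for v in values:
        label = binner(v)
        counts[label] = counts.get(label, 0) + 1
    return pd.Series(counts)


def feature_distributions(
    lncRNAs: Sequence[TranscriptModel],
    coding_transcripts: Sequence[TranscriptModel],
    sequences: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Binned length, exon-count and ORF-length distributions for both sets.

    Length bins are left-closed right-open (a 300 nt transcript falls in
    "300-400"; 1001 nt falls in ">1000"). Proportions sum to 1 per
    (set, feature). ORF lengths come from each transcript's sequence.
    """
    sequences = sequences or {}

    def seq_of(tx: TranscriptModel) -> Optional[str]:
        return tx.sequence or sequences.get(tx.transcript_id)

    rows = []
    for set_name, txs in (("lncRNA", lncRNAs), ("coding", coding_transcripts)):
        lengths = [len(seq_of(t)) if seq_of(t) else t.exon_union_length for t in txs]
        exon_counts = [t.n_exons for t in txs]
        orf_lengths = [
            longest_orf(seq_of(t)).aa_length for t in txs if seq_of(t) is not None
        ]
        features = {
            "length_nt": _histogram(
                lengths, lambda v: _bin_left_closed(v, LENGTH_BIN_EDGES, LENGTH_BIN_LABELS)
            ).reindex(LENGTH_BIN_LABELS, fill_value=0),
            "exon_count": _histogram(
                exon_counts, lambda v: str(v) if v <= 10 else ">10"
            ).reindex(EXON_BIN_LABELS, fill_value=0),
            "orf_aa": _histogram(
                orf_lengths, lambda v: _bin_left_closed(v, ORF_BIN_EDGES, ORF_BIN_LABELS)
            ).reindex(ORF_BIN_LABELS, fill_value=0),
        }
        for feature, counts in features.items():
            n = counts.sum()
            for bin_label, count in counts.items():
                rows.append(
                    {
                        "set": set_name,
                        "feature": feature,
                        "bin": bin_label,
                        "count": int(count),
                        "proportion": count / n if n else 0.0,
                    }
                )
    return pd.DataFrame(rows)
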