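"""The five-filter lncRNA identification cascade.

Assembled transcripts are filtered in sequence: (1) drop anything with
exonic overlap to housekeeping ncRNAs (rRNA/tRNA/snRNA/snoRNA), (2) drop
single-exon transcripts, (3) drop transcripts with a significant alignment
to annotated proteins, (4) split off transcripts matching annotated lncRNA
loci (these are accepted directly), then for the remaining candidates
(5) require length >= 200 nt with a longest ORF < 100 aa and (6) pass a
coding-potential gate (no Pfam domain hit, coding-potential score < 0).
The surviving set -- annotated plus novel -- is the lncRNA catalogue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .fickett import fickett_testcode
from .io_formats import (
    FilterCriteria,
    GeneAnnotation,
    GenomicInterval,
    HOUSEKEEPING_BIOTYPES,
    TranscriptModel,
    ValidationError,
)

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class OrfCall:
    """Longest ATG-initiated open reading frame in the forward frames."""

    aa_length: int
    start_nt: int
    frame: int
    transcript_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.aa_length < 0:
            raise ValidationError("negative ORF length")
        if self.aa_length > 0 and self.start_nt % 3 != self.frame:
            raise ValidationError("ORF start not congruent with frame")


def longest_orf(
    sequence: str, transcript_id: Optional[str] = None, six_frame: bool = False
) -> OrfCall:
    """Find the longest ORF (ATG .. in-frame stop) in the forward frames.

    The amino-acid length counts codons from the ATG through the codon before
    the stop (so ``ATGAAATAA`` -> 2). An ATG without a downstream in-frame
    stop is not an ORF. Codons containing N match neither ATG nor a stop.
    Ties break toward the smallest start offset, then the smallest frame.
    With ``six_frame=True`` the reverse complement is also scanned (for
    non-strand-specific assemblies); the reported coordinates then refer to
    whichever strand carried the winning ORF.
    """
    seq = sequence.upper()
    best = _scan_forward_frames(seq)
    if six_frame:
        comp = str.maketrans("ACGTN", "TGCAN")
        rc = seq.translate(comp)[::-1]
        rc_best = _scan_forward_frames(rc)
        if rc_best[0] > best[0]:
            best = rc_best
    aa, start, frame = best
    return OrfCall(aa_length=aa, start_nt=start, frame=frame, transcript_id=transcript_id)


def _scan_forward_frames(seq: str) -> tuple[int, int, int]:
    best_aa, best_start, best_frame = 0, 0, 0
    n = len(seq)
    for frame in range(3):
        open_start: Optional[int] = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in STOP_CODONS:
                if open_start is not None:
                    aa = (pos - open_start) // 3
                    if aa > best_aa or (
                        aa == best_aa
                        and aa > 0
                        and (open_start, frame) < (best_start, best_frame)
                    ):
                        best_aa, best_start, best_frame = aa, open_start, frame
                    open_start = None
            elif open_start is None and codon == "ATG":
                open_start = pos
    return best_aa, best_start, best_frame


# ---------------------------------------------------------------------------
# Individual filters
# ---------------------------------------------------------------------------


def _exonic_overlap(
    tx: TranscriptModel, exons: Sequence[GenomicInterval], same_strand: Optional[bool] = None
) -> bool:
    """>=1 bp overlap between any transcript exon and any reference exon.

    ``same_strand``: None ignores strand; True/False requires equal/opposite.
    """
    for e in tx.exons:
        for ref in exons:
            if not e.overlaps(ref):
                continue
            if same_strand is None:
                return True
            equal = e.strand == ref.strand and e.strand in ("+", "-")
            opposite = {e.strand, ref.strand} == {"+", "-"}
            if (same_strand and equal) or (not same_strand and opposite):
                return True
    return False


def filter_housekeeping(
    transcripts: Sequence[TranscriptModel], annotation: GeneAnnotation
) -> tuple[list[TranscriptModel], list[TranscriptModel]]:
    """Remove transcripts overlapping housekeeping ncRNA exons (either strand)."""
    hk_exons_by_chrom: dict[str, list[GenomicInterval]] = {}
    for gene in annotation.by_biotype(*HOUSEKEEPING_BIOTYPES):
        exons = gene.exons or [gene.interval]
        for e in exons:
            hk_exons_by_chrom.setdefault(e.chrom, []).append(e)
    kept, removed = [], []
    for tx in transcripts:
        refs = hk_exons_by_chrom.get(tx.chrom, [])
        (removed if _exonic_overlap(tx, refs, same_strand=None) else kept).append(tx)
    return kept, removed


def filter_exon_count(
    transcripts: Sequence[TranscriptModel], min_exons: int = 2
) -> tuple[list[TranscriptModel], list[TranscriptModel]]:
    kept = [tx for tx in transcripts if tx.n_exons >= min_exons]
    removed = [tx for tx in transcripts if tx.n_exons < min_exons]
    return kept, removed


def filter_coding_hits(
    transcripts: Sequence[TranscriptModel],
    hits,
    criteria: FilterCriteria = FilterCriteria(),
) -> tuple[list[TranscriptModel], list[TranscriptModel]]:
    """Remove transcripts with >=1 protein hit passing all three strict bounds.

    A hit qualifies iff p < coding_hit_max_p AND identity > the identity
    bound AND coverage > the coverage bound (all strict inequalities, so a
    hit at identity exactly 90.0 does not exclude).
    """
    qualifying = set()
    if hits is not None and len(hits):
        mask = (
            (hits["p_value"] < criteria.coding_hit_max_p)
            & (hits["identity_pct"] > criteria.coding_hit_min_identity_pct)
            & (hits["coverage_pct"] > criteria.coding_hit_min_coverage_pct)
        )
        qualifying = set(hits.loc[mask, "transcript_id"].astype(str))
    kept = [tx for tx in transcripts if tx.transcript_id not in qualifying]
    removed = [tx for tx in transcripts if tx.transcript_id in qualifying]
    return kept, removed


def split_annotated(
    transcripts: Sequence[TranscriptModel], annotation: GeneAnnotation
) -> tuple[list[TranscriptModel], list[TranscriptModel]]:
    """Route transcripts matching annotated lncRNA loci out of the novel path.

    A transcript matches when any of its exons overlaps an exon of a
    biotype-lncRNA gene by >=1 bp on the same strand (exon-level overlap
    rather than full chain identity tolerates assembly boundary jitter).
    Returns (annotated_lncRNAs, transcripts continuing the cascade).
    """
    lnc_exons_by_chrom: dict[str, list[GenomicInterval]] = {}
    for gene in annotation.by_biotype("lncRNA"):
        for e in gene.exons or [gene.interval]:
            lnc_exons_by_chrom.setdefault(e.chrom, []).append(e)
    annotated, unannotated = [], []
    for tx in transcripts:
        refs = lnc_exons_by_chrom.get(tx.chrom, [])
        if _exonic_overlap(tx, refs, same_strand=True):
            annotated.append(tx)
        else:
            unannotated.append(tx)
    return annotated, unannotated


def filter_length_orf(
    transcripts: Sequence[TranscriptModel],
    sequences: Mapping[str, str],
    criteria: FilterCriteria = FilterCriteria(),
) -> tuple[list[TranscriptModel], list[TranscriptModel]]:
    """Keep transcripts with length >= 200 nt and longest ORF < 100 aa."""
    kept, removed = [], []
    for tx in transcripts:
        seq = tx.sequence or sequences.get(tx.transcript_id)
        if seq is None:
            logger.warning("%s removed: no_sequence", tx.transcript_id)
            removed.append(tx)
            continue
        if (
            len(seq) >= criteria.min_length_nt
            and longest_orf(seq).aa_length < criteria.max_orf_aa
        ):
            kept.append(tx)
        else:
            removed.append(tx)
    return kept, removed


def builtin_coding_score(sequence: str) -> float:
    """Heuristic coding-potential score; negative indicates non-coding.

    score = 2 * (ORF_coverage - 0.5) + (fickett_testcode - 0.95), where
    ORF_coverage is the fraction of the transcript covered by the longest
    ORF. A stand-in scorer used when no external score table is supplied.
    """
    if not sequence:
        return -1.0
    orf = longest_orf(sequence)
    coverage = 3 * orf.aa_length / len(sequence)
    return 2.0 * (coverage - 0.5) + (fickett_testcode(sequence) - 0.95)


@dataclass(frozen=True)
class CodingPotentialScore:
    transcript_id: str
    score: float
    source: str  # "external_table" | "builtin_heuristic"


def coding_potential_gate(
    transcripts: Sequence[TranscriptModel],
    sequences: Mapping[str, str],
    external_scores: Optional[Mapping[str, float]] = None,
    pfam_hits: Optional[Mapping[str, float]] = None,
    criteria: FilterCriteria = FilterCriteria(),
) -> tuple[list[TranscriptModel], list[TranscriptModel], list[CodingPotentialScore]]:
    """Final gate: Pfam-domain hit removes; then score < 0 keeps.

    ``pfam_hits`` maps transcript id to the best (smallest) domain E-value;
    E <= pfam_evalue_max removes the transcript regardless of score.
    External scores take precedence over the builtin heuristic.
    """
    kept, removed, scores = [], [], []
    for tx in transcripts:
        tid = tx.transcript_id
        if pfam_hits and tid in pfam_hits and pfam_hits[tid] <= criteria.pfam_evalue_max:
            removed.append(tx)
            continue
        if external_scores is not None and tid in external_scores:
            score = CodingPotentialScore(tid, float(external_scores[tid]), "external_table")
        else:
            seq = tx.sequence or sequences.get(tid)
            if seq is None:
                raise ValidationError(
                    f"{tid}: no coding-potential evidence and no sequence"
                )
            score = CodingPotentialScore(tid, builtin_coding_score(seq), "builtin_heuristic")
        scores.append(score)
        (kept if score.score < criteria.cpc_score_max else removed).append(tx)
    return kept, removed, scores


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CascadeStage:
    name: str
    n_input: int
    n_removed: int
    n_surviving: int

    def __post_init__(self) -> None:
        if self.n_surviving != self.n_input - self.n_removed:
            raise ValidationError(
                f"stage {self.name}: surviving != input - removed"
            )
        if min(self.n_input, self.n_removed, self.n_surviving) < 0:
            raise ValidationError(f"stage {self.name}: negative count")


@dataclass
class CascadeReport:
    """Stage-by-stage accounting of the identification cascade."""

    stages: list[CascadeStage]
    annotated_lncRNAs: list[str] = field(default_factory=list)
    novel_lncRNAs: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a, b in zip(self.stages, self.stages[1:]):
            if b.n_input > a.n_surviving:
                raise ValidationError(
                    f"stage {b.name}: input exceeds previous survivors"
                )
        if set(self.annotated_lncRNAs) & set(self.novel_lncRNAs):
            raise ValidationError("annotated and novel lncRNA sets overlap")

    @property
    def lncRNA_ids(self) -> set[str]:
        return set(self.annotated_lncRNAs) | set(self.novel_lncRNAs)

    @property
    def n_lncRNAs(self) -> int:
        return len(self.annotated_lncRNAs) + len(self.novel_lncRNAs)

    def to_records(self) -> list[dict]:
        return [vars(s) | {} for s in self.stages]


def run_cascade(
    transcripts: Sequence[TranscriptModel],
    annotation: GeneAnnotation,
    hits=None,
    sequences: Optional[Mapping[str, str]] = None,
    external_scores: Optional[Mapping[str, float]] = None,
    pfam_hits: Optional[Mapping[str, float]] = None,
    criteria: FilterCriteria = FilterCriteria(),
) -> tuple[CascadeReport, list[TranscriptModel], list[TranscriptModel]]:
    """Run the full cascade; returns (report, annotated, novel) transcripts."""
    sequences = sequences or {}
    stages: list[CascadeStage] = []

    def record(name: str, n_in: int, kept_list, removed_list):
        stages.append(CascadeStage(name, n_in, len(removed_list), len(kept_list)))

    current = list(transcripts)
    kept, removed = filter_housekeeping(current, annotation)
    record("housekeeping_ncRNA", len(current), kept, removed)
    current = kept

    kept, removed = filter_exon_count(current, criteria.min_exons)
    record("exon_count", len(current), kept, removed)
    current = kept

    kept, removed = filter_coding_hits(current, hits, criteria)
    record("coding_alignment", len(current), kept, removed)
    current = kept

    annotated, current = split_annotated(current, annotation)
    # routed transcripts leave the novel pipeline; counted as "removed" here
    stages.append(
        CascadeStage("annotated_split", len(current) + len(annotated), len(annotated), len(current))
    )

    kept, removed = filter_length_orf(current, sequences, criteria)
    record("length_orf", len(current), kept, removed)
    current = kept

    novel, removed, _scores = coding_potential_gate(
        current, sequences, external_scores, pfam_hits, criteria
    )
    record("coding_potential", len(current), novel, removed)

    report = CascadeReport(
        stages=stages,
        annotated_lncRNAs=[t.transcript_id for t in annotated],
        novel_lncRNAs=[t.transcript_id for t in novel],
    )
    return report, annotated, novel
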