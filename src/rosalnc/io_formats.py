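"""Shared genomic types and readers/writers for external file formats.

All coordinates inside the library are 0-based, half-open ``[start, end)``.
GTF/GFF3 I/O converts from/to the 1-based inclusive convention of those
formats at the boundary, so interval arithmetic elsewhere never has to think
about off-by-one corrections.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")

#: closed biotype vocabulary; anything else is coerced to "other"
BIOTYPES = (
    "protein_coding",
    "rRNA",
    "tRNA",
    "snRNA",
    "snoRNA",
    "lncRNA",
    "other",
)

HOUSEKEEPING_BIOTYPES = frozenset({"rRNA", "tRNA", "snRNA", "snoRNA"})

_VALID_NT = frozenset("ACGTN")


class ParseError(ValueError):
    """Raised when an input file cannot be parsed."""


class ValidationError(ValueError):
    """Raised when parsed data violates a domain invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:[{self.start},{self.end})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp (strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def gap_to(self, other: "GenomicInterval") -> Optional[int]:
        """Distance in bp between closest edges; 0 when overlapping.

        Returns None for intervals on different chromosomes.
        """
        if self.chrom != other.chrom:
            return None
        if self.overlaps(other):
            return 0
        if other.start >= self.end:
            return other.start - self.end
        return self.start - other.end

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class TranscriptModel:
    """An assembled transcript: exon chain plus optional sense-strand sequence."""

    transcript_id: str
    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval]
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: transcript needs >=1 exon")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1:
            raise ValidationError(f"{self.transcript_id}: exons on mixed chromosomes")
        if len(strands) > 1:
            raise ValidationError(f"{self.transcript_id}: exons on mixed strands")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValidationError(f"{self.transcript_id}: overlapping exons")
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            bad = set(self.sequence) - _VALID_NT
            if bad:
                raise ValidationError(
                    f"{self.transcript_id}: invalid nucleotide(s) {sorted(bad)}"
                )
            if len(self.sequence) != self.exon_union_length:
                raise ValidationError(
                    f"{self.transcript_id}: sequence length {len(self.sequence)} "
                    f"!= exon union length {self.exon_union_length}"
                )

    @classmethod
    def from_exons(
        cls,
        transcript_id: str,
        gene_id: str,
        exons: Sequence[GenomicInterval],
        sequence: Optional[str] = None,
    ) -> "TranscriptModel":
        exons = sorted(exons, key=lambda e: e.start)
        span = GenomicInterval(
            exons[0].chrom, exons[0].start, exons[-1].end, exons[0].strand
        )
        return cls(transcript_id, gene_id, span, list(exons), sequence)

    @property
    def exon_union_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass
class Gene:
    gene_id: str
    interval: GenomicInterval
    biotype: str
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            self.biotype = "other"
        for e in self.exons:
            if not self.interval.contains(e):
                raise ValidationError(
                    f"{self.gene_id}: exon outside gene interval"
                )
        self.exons = sorted(self.exons, key=lambda e: e.start)


@dataclass
class GeneAnnotation:
    """Reference gene set with biotypes, the classification substrate."""

    genes: list[Gene]

    def by_biotype(self, *biotypes: str) -> list[Gene]:
        wanted = set(biotypes)
        return [g for g in self.genes if g.biotype in wanted]

    @property
    def protein_coding(self) -> list[Gene]:
        return self.by_biotype("protein_coding")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class FilterCriteria:
    """Every threshold of the lncRNA identification cascade in one place."""

    min_length_nt: int = 200
    max_orf_aa: int = 100  # exclusive: ORF must be < 100 aa
    min_exons: int = 2
    coding_hit_max_p: float = 1.0e-10  # exclusive: removed when p < this
    coding_hit_min_identity_pct: float = 90.0  # exclusive: removed when id > this
    coding_hit_min_coverage_pct: float = 80.0  # exclusive: removed when cov > this
    pfam_evalue_max: float = 1e-5  # inclusive: removed when E <= this
    cpc_score_max: float = 0.0  # exclusive: kept when score < this

    def __post_init__(self) -> None:
        if self.min_length_nt <= 0 or self.max_orf_aa <= 0 or self.min_exons <= 0:
            raise ValidationError("length/ORF/exon bounds must be positive")
        if self.coding_hit_max_p <= 0 or self.pfam_evalue_max <= 0:
            raise ValidationError("p/E-value bounds must be positive")


@dataclass
class ExpressionMatrix:
    """Transcripts x samples abundance (FPKM scale) with sample metadata.

    ``values``: DataFrame indexed by transcript id, columns = sample ids.
    ``sample_meta``: DataFrame indexed by sample id with columns
    ``cultivar``, ``stage``, ``replicate``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate transcript ids in expression matrix")
        if (self.values.values < 0).any():
            raise ValidationError("negative expression values")
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise ValidationError(f"samples without metadata: {sorted(missing)}")
        for col in ("cultivar", "stage", "replicate"):
            if col not in self.sample_meta.columns:
                raise ValidationError(f"sample metadata lacks column {col!r}")
            if self.sample_meta[col].isna().any():
                raise ValidationError(f"incomplete sample metadata in {col!r}")

    @property
    def stages(self) -> list[str]:
        seen: list[str] = []
        for s in self.sample_meta["stage"]:
            if s not in seen:
                seen.append(s)
        return seen

    def samples_for(
        self, stage: Optional[str] = None, cultivar: Optional[str] = None
    ) -> list[str]:
        meta = self.sample_meta.loc[list(self.values.columns)]
        mask = pd.Series(True, index=meta.index)
        if stage is not None:
            mask &= meta["stage"] == stage
        if cultivar is not None:
            mask &= meta["cultivar"] == cultivar
        return list(meta.index[mask])


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_attributes(text: str, lineno: int) -> dict[str, str]:
    attrs = dict(_GTF_ATTR_RE.findall(text))
    if not attrs:
        raise ParseError(f"malformed GTF attribute field at line {lineno}: {text!r}")
    return attrs


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read transcript models from a GTF file (exon features only).

    1-based inclusive GTF coordinates become 0-based half-open. Exons are
    grouped per ``transcript_id`` and sorted by start; mixed-strand exon sets
    within one transcript raise :class:`ValidationError`.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    gene_of: dict[str, str] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"expected 9 tab-separated fields at line {lineno}, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start, end, _score, strand, _frame, attr = fields
            if feature != "exon":
                continue
            attrs = _parse_gtf_attributes(attr, lineno)
            if "transcript_id" not in attrs or "gene_id" not in attrs:
                raise ParseError(
                    f"exon without transcript_id/gene_id at line {lineno}"
                )
            try:
                iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"bad exon coordinates at line {lineno}: {exc}")
            tid = attrs["transcript_id"]
            if tid not in exons:
                exons[tid] = []
                order.append(tid)
                gene_of[tid] = attrs["gene_id"]
            exons[tid].append(iv)
    return [TranscriptModel.from_exons(tid, gene_of[tid], exons[tid]) for tid in order]


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcript models as GTF (transcript + exon features)."""
    with open(path, "w") as fh:
        for tx in transcripts:
            attr = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
            iv = tx.interval
            fh.write(
                f"{iv.chrom}\trosalnc\ttranscript\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attr}\n"
            )
            for e in tx.exons:
                fh.write(
                    f"{e.chrom}\trosalnc\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{e.strand}\t.\t{attr}\n"
                )


# ---------------------------------------------------------------------------
# GFF3 (reference annotation)
# ---------------------------------------------------------------------------


def read_gff3(path: str | Path) -> GeneAnnotation:
    """Read a reference gene annotation with biotypes from GFF3.

    Uses gffutils with an in-memory database; gene features carry a
    ``biotype`` (or ``gene_biotype``) attribute and exon children link via
    ``Parent``. Unknown biotypes map to ``other``.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[Gene] = []
    for g in db.features_of_type("gene", order_by="start"):
        biotype = (
            g.attributes.get("biotype", g.attributes.get("gene_biotype", ["other"]))
        )[0]
        iv = GenomicInterval(g.seqid, g.start - 1, g.end, g.strand or ".")
        exon_ivs = [
            GenomicInterval(e.seqid, e.start - 1, e.end, e.strand or ".")
            for e in db.children(g, featuretype="exon", order_by="start")
        ]
        genes.append(Gene(g.id, iv, biotype, exon_ivs))
    return GeneAnnotation(genes)


def write_gff3(annotation: GeneAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in annotation.genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\trosalnc\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={g.gene_id};biotype={g.biotype}\n"
            )
            for i, e in enumerate(g.exons, start=1):
                fh.write(
                    f"{e.chrom}\trosalnc\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{e.strand}\t.\tID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read transcript sequences; upper-cases and validates the alphabet."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ParseError(f"duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - _VALID_NT
        if bad:
            raise ParseError(f"{rec.id}: non-ACGTN character(s) {sorted(bad)}")
        sequences[rec.id] = seq
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=tid, description="") for tid, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Tabular inputs
# ---------------------------------------------------------------------------

HIT_COLUMNS = ["transcript_id", "subject_id", "identity_pct", "coverage_pct", "p_value"]


def read_hit_table(path: str | Path) -> pd.DataFrame:
    """Read a coding-alignment hit table.

    BLAST-style tabular layout extended with an explicit (query) coverage
    column: transcript_id, subject_id, identity_pct, coverage_pct, p_value.
    A leading header row naming the columns is tolerated.
    """
    try:
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=HIT_COLUMNS)
    if df.empty:
        return pd.DataFrame(columns=HIT_COLUMNS)
    if df.shape[1] != len(HIT_COLUMNS):
        raise ParseError(
            f"hit table must have {len(HIT_COLUMNS)} columns, got {df.shape[1]}"
        )
    if str(df.iloc[0, 0]) == "transcript_id":  # header row present
        df = df.iloc[1:].reset_index(drop=True)
    df.columns = HIT_COLUMNS
    for col in ("identity_pct", "coverage_pct", "p_value"):
        df[col] = pd.to_numeric(df[col])
        if (df[col] < 0).any():
            raise ValidationError(f"negative values in hit-table column {col!r}")
    return df


def write_hit_table(hits: pd.DataFrame, path: str | Path) -> None:
    hits.to_csv(path, sep="\t", header=False, index=False)


def read_expression(values_path: str | Path, meta_path: str | Path) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return ExpressionMatrix(values, meta)


def write_expression(expr: ExpressionMatrix, values_path: str | Path, meta_path: str | Path) -> None:
    expr.values.to_csv(values_path, sep="\t", index_label="transcript_id")
    expr.sample_meta.to_csv(meta_path, sep="\t", index_label="sample_id")


def read_score_table(path: str | Path) -> dict[str, float]:
    """Read a two-column (id, score) TSV, e.g. external coding-potential scores."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "score"], comment="#")
    if not df.empty and str(df.iloc[0, 0]) == "id":
        df = df.iloc[1:]
    return dict(zip(df["id"].astype(str), pd.to_numeric(df["score"])))
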