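"""Seeded synthetic fixture bundles with a planted ground-truth manifest.

The generator emulates the data shapes of a rose flowering-stage experiment:
a small annotated genome with multi-exon coding genes, housekeeping ncRNAs
and (partially) annotated lncRNA loci; an assembled transcript set containing
the four lncRNA positional classes, coding transcripts, coding-like decoys
and single-exon noise; 3-stage x 3-replicate x 4-cultivar expression (36
samples, comfortably above the 15-sample minimum a co-expression network
needs) with planted up-down / down-up differential-expression patterns and
module-structured co-expression; per-sample volatile emission vectors tied to
module eigen-trajectories at planted correlations; and GC-MS peak tables
back-computed from the target emission rates through the inverse of the
internal-standard formula.

Everything is deterministic given the seed: one seed spawns fixed per-artifact
sub-streams so that regenerating with the same configuration reproduces the
bundle byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .identify import longest_orf
from .io_formats import (
    ExpressionMatrix,
    Gene,
    GeneAnnotation,
    GenomicInterval,
    TranscriptModel,
    write_expression,
    write_fasta,
    write_gff3,
    write_gtf,
    write_hit_table,
)
from .volatiles import GCMS_COLUMNS

NT = np.array(list("ACGT"))

LNC_CLASSES = ("lincRNA", "antisense", "sense_overlapping", "sense_intronic")

DEFAULT_COMPOUNDS = {
    # compound -> class; ten scent compounds plus two non-scent controls
    "geraniol": "terpenoid",
    "nerol": "terpenoid",
    "citral": "terpenoid",
    "beta-pinene": "terpenoid",
    "trans-beta-ocimene": "terpenoid",
    "phenethyl_alcohol": "phenylpropanoid_benzenoid",
    "3,5-dimethoxytoluene": "phenylpropanoid_benzenoid",
    "methyleugenol": "phenylpropanoid_benzenoid",
    "cis-3-hexenyl_acetate": "fatty_acid_derivative",
    "4-hexen-1-ol_acetate": "fatty_acid_derivative",
    "nonanal": "non_scent",
    "decane": "non_scent",
}


class GenerationError(RuntimeError):
    """Raised when a constrained artifact cannot be generated."""


class ConfigError(ValueError):
    """Raised for infeasible simulation configurations."""


@dataclass
class SimConfig:
    """Study-design parameters of the simulated experiment."""

    seed: int = 0
    n_coding_genes: int = 300
    n_lnc_per_class: dict[str, int] = field(
        default_factory=lambda: {
            "lincRNA": 63,
            "antisense": 30,
            "sense_overlapping": 10,
            "sense_intronic": 30,
        }
    )
    n_housekeeping: int = 20
    n_single_exon_noise: int = 40
    n_coding_like_decoys: int = 20
    chrom_length_bp: int = 4_500_000
    stages: tuple[str, ...] = ("EF", "SF", "LF")
    replicates_per_stage: int = 3
    n_cultivars: int = 4
    n_modules: int = 13
    module_size_range: tuple[int, int] = (6, 10)
    #: (compound, module index, target Pearson r); None -> default layout
    trait_link: Optional[list[tuple[str, int, float]]] = None
    de_pattern_counts: dict[str, int] = field(
        default_factory=lambda: {"up_down": 9, "down_up": 9, "single_transition": 8}
    )
    n_low_expression_de: int = 3  # DE by ratio but below the 0.5 floor everywhere
    n_coexpr_pairs: int = 20
    annotated_lnc_fraction: float = 0.5
    noise_sd: float = 0.2  # log2-scale multiplicative expression noise

    def __post_init__(self) -> None:
        counts = [
            self.n_coding_genes,
            self.n_housekeeping,
            self.n_single_exon_noise,
            self.n_coding_like_decoys,
            *self.n_lnc_per_class.values(),
        ]
        if any(c < 0 for c in counts):
            raise ConfigError("all counts must be >= 0")
        if set(self.n_lnc_per_class) != set(LNC_CLASSES):
            raise ConfigError(f"n_lnc_per_class must cover {LNC_CLASSES}")
        hosts_needed = (
            self.n_lnc_per_class["antisense"]
            + self.n_lnc_per_class["sense_overlapping"]
            + self.n_lnc_per_class["sense_intronic"]
        )
        if hosts_needed > self.n_coding_genes:
            raise ConfigError("not enough coding genes to host gene-linked lncRNAs")
        if self.trait_link is not None:
            for _c, m, r in self.trait_link:
                if not (-1 < r < 1):
                    raise ConfigError("target correlations must lie in (-1, 1)")
                if not (0 <= m < self.n_modules):
                    raise ConfigError("trait link references missing module")

    @property
    def n_samples(self) -> int:
        return self.n_cultivars * len(self.stages) * self.replicates_per_stage

    @property
    def cultivars(self) -> list[str]:
        return [f"cv{i + 1}" for i in range(self.n_cultivars)]

    def default_trait_link(self) -> list[tuple[str, int, float]]:
        if self.trait_link is not None:
            return self.trait_link
        scent = [c for c, cls in DEFAULT_COMPOUNDS.items() if cls != "non_scent"]
        return [(c, i % self.n_modules, 0.9) for i, c in enumerate(scent)]


@dataclass
class TruthManifest:
    """Ground truth for every planted feature of a bundle."""

    transcripts: dict[str, dict]  # id -> {category, lnc_class, annotated, orf_aa, ...}
    modules: list[dict]  # {index, members, trajectory}
    compounds: dict[str, dict]  # name -> {class, module_index, planted_r, rates}
    coexpr_pairs: list[tuple[str, str]]
    samples: list[str]
    config: dict

    def ids_of_category(self, category: str) -> set[str]:
        return {t for t, info in self.transcripts.items() if info["category"] == category}

    @property
    def lncRNA_ids(self) -> set[str]:
        return self.ids_of_category("lncRNA")

    def to_json(self) -> str:
        def _plain(obj):
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            raise TypeError(f"not JSON serializable: {type(obj)}")

        return json.dumps(asdict(self), sort_keys=True, indent=1, default=_plain)


@dataclass
class Bundle:
    annotation: GeneAnnotation
    transcripts: list[TranscriptModel]
    sequences: dict[str, str]
    hits: pd.DataFrame
    cpc_scores: dict[str, float]
    expression: ExpressionMatrix
    gcms: pd.DataFrame
    compound_classes: dict[str, str]
    ct_table: pd.DataFrame
    manifest: TruthManifest


# ---------------------------------------------------------------------------
# Sequence construction
# ---------------------------------------------------------------------------

_STOP_BLOCK = "TAAATAGATGA"  # stop codons at offsets 0, 4, 8: one per frame


def _random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join(NT[rng.integers(0, 4, size=length)])


def _strip_atg(seq: str) -> str:
    chars = list(seq)
    for i in range(len(chars) - 2):
        if chars[i] == "A" and chars[i + 1] == "T" and chars[i + 2] == "G":
            chars[i + 2] = "C"
    return "".join(chars)


def plant_orf_free_sequence(
    length_nt: int, max_orf_aa: int, rng: np.random.Generator, max_attempts: int = 200
) -> str:
    """Random sequence whose longest forward-frame ORF is < max_orf_aa codons.

    Strategy: rejection-sample random sequences; if that fails, interleave
    random filler with short blocks carrying a stop codon in each of the
    three frames; as a last resort remove every ATG (a sequence with no start
    codon has no ORF). The returned sequence is always verified with the
    ORF finder.
    """
    if length_nt < 1 or max_orf_aa < 1:
        raise GenerationError("length_nt and max_orf_aa must be >= 1")

    for _ in range(max_attempts):
        seq = _random_nt(rng, length_nt)
        if longest_orf(seq).aa_length < max_orf_aa:
            return seq

    gap = max(3, 3 * max_orf_aa - 24)
    for _ in range(max_attempts):
        parts: list[str] = []
        remaining = length_nt
        while remaining > 0:
            take = min(gap, remaining)
            parts.append(_random_nt(rng, take))
            remaining -= take
            if remaining > 0:
                block = _STOP_BLOCK[: min(len(_STOP_BLOCK), remaining)]
                parts.append(block)
                remaining -= len(block)
        seq = "".join(parts)
        if longest_orf(seq).aa_length < max_orf_aa:
            return seq

    seq = _strip_atg(_random_nt(rng, length_nt))
    if longest_orf(seq).aa_length < max_orf_aa:
        return seq
    raise GenerationError(
        f"could not satisfy ORF < {max_orf_aa} aa at length {length_nt}"
    )


_STOPS = ("TAA", "TAG", "TGA")

#: position-specific base probabilities (A,C,G,T) per codon position,
#: emulating the compositional bias of plant coding sequence (G-rich first
#: position, G-poor A/T-rich second, C/G-leaning wobble)
_CODON_POSITION_PROBS = np.array(
    [
        [0.29, 0.18, 0.34, 0.19],
        [0.33, 0.22, 0.15, 0.30],
        [0.17, 0.28, 0.27, 0.28],
    ]
)


def _biased_codon(rng: np.random.Generator) -> str:
    while True:
        codon = "".join(
            NT[rng.choice(4, p=_CODON_POSITION_PROBS[i])] for i in range(3)
        )
        if codon not in _STOPS:
            return codon


def _coding_sequence(
    length_nt: int, orf_aa: int, rng: np.random.Generator
) -> tuple[str, int]:
    """Sequence of given length with a planted ORF of ``orf_aa`` codons.

    ORF codons are drawn with codon-position compositional bias so the
    planted reading frame looks statistically coding-like, not just long.
    Flanks are kept ORF-poor so the planted frame stays the longest; the
    realized longest ORF (which may slightly exceed the planted one) is
    returned alongside.
    """
    orf_nt = 3 * orf_aa + 3  # codons incl. ATG, plus the stop
    if orf_nt > length_nt:
        raise GenerationError("planted ORF longer than the transcript")
    body = ["ATG"]
    for _ in range(orf_aa - 1):
        body.append(_biased_codon(rng))
    body.append(_STOPS[rng.integers(0, 3)])
    flank_total = length_nt - orf_nt
    prefix_len = int(rng.integers(0, flank_total + 1)) if flank_total else 0
    prefix = (
        plant_orf_free_sequence(prefix_len, max(1, min(50, orf_aa)), rng)
        if prefix_len
        else ""
    )
    suffix_len = flank_total - prefix_len
    suffix = (
        plant_orf_free_sequence(suffix_len, max(1, min(50, orf_aa)), rng)
        if suffix_len
        else ""
    )
    seq = prefix + "".join(body) + suffix
    return seq, longest_orf(seq).aa_length


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


def _split_lengths(total: int, n_parts: int, rng: np.random.Generator, min_part: int) -> list[int]:
    if n_parts * min_part > total:
        raise GenerationError("cannot split length")
    extra = total - n_parts * min_part
    cuts = np.sort(rng.integers(0, extra + 1, size=n_parts - 1)) if n_parts > 1 else []
    bounds = [0, *cuts, extra]
    return [min_part + bounds[i + 1] - bounds[i] for i in range(n_parts)]


def _exon_chain(
    chrom: str, start: int, strand: str, exon_lens: Sequence[int], intron_lens: Sequence[int]
) -> list[GenomicInterval]:
    exons = []
    pos = start
    for i, elen in enumerate(exon_lens):
        exons.append(GenomicInterval(chrom, pos, pos + elen, strand))
        pos += elen
        if i < len(intron_lens):
            pos += intron_lens[i]
    return exons


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------

_SUBSTREAMS = {
    "geometry": 11,
    "sequence": 23,
    "expression": 37,
    "volatiles": 41,
    "gcms": 53,
    "ct": 67,
    "evidence": 79,
}


def _rng_for(config: SimConfig, artifact: str) -> np.random.Generator:
    return np.random.default_rng([_SUBSTREAMS[artifact], config.seed % 2**31])


def generate(config: SimConfig = SimConfig()) -> Bundle:  # noqa: C901
    """Generate a complete fixture bundle with its truth manifest."""
    chrom = "chr1"
    geo = _rng_for(config, "geometry")
    seq_rng = _rng_for(config, "sequence")

    n_linc = config.n_lnc_per_class["lincRNA"]
    unit_kinds = (
        ["coding"] * config.n_coding_genes
        + ["housekeeping"] * config.n_housekeeping
        + ["lincRNA"] * n_linc
        + ["noise"] * config.n_single_exon_noise
        + ["decoy"] * config.n_coding_like_decoys
    )
    n_units = len(unit_kinds)
    window = config.chrom_length_bp // max(n_units, 1)
    if window < 7500:
        raise ConfigError(
            f"chrom_length_bp too small: window {window} bp < 7500 bp per feature"
        )
    order = geo.permutation(n_units)
    kinds_in_order = [unit_kinds[i] for i in order]

    genes: list[Gene] = []
    transcripts: list[TranscriptModel] = []
    sequences: dict[str, str] = {}
    truth: dict[str, dict] = {}
    coding_genes: list[Gene] = []
    hk_biotypes = ["rRNA", "tRNA", "snRNA", "snoRNA"]

    serial = 0

    def next_tid() -> str:
        nonlocal serial
        serial += 1
        return f"TCONS_{serial:08d}"

    def record(tx: TranscriptModel, seq: Optional[str], **info) -> None:
        transcripts.append(tx)
        if seq is not None:
            sequences[tx.transcript_id] = seq
        entry = {
            "category": info.pop("category"),
            "lnc_class": info.pop("lnc_class", None),
            "annotated": info.pop("annotated", False),
            "orf_aa": info.pop("orf_aa", None),
            "length_nt": tx.exon_union_length,
            "n_exons": tx.n_exons,
            "de_pattern": None,
            "module_index": None,
            **info,
        }
        truth[tx.transcript_id] = entry

    def make_lnc_transcript(
        exons: list[GenomicInterval], gene_id: str
    ) -> tuple[TranscriptModel, str, int]:
        length = sum(e.length for e in exons)
        max_orf = min(99, max(10, length // 12))
        seq = plant_orf_free_sequence(length, max_orf, seq_rng)
        tx = TranscriptModel.from_exons(next_tid(), gene_id, exons, seq)
        return tx, seq, longest_orf(seq).aa_length

    # --- place units along the chromosome -----------------------------------
    for u, kind in enumerate(kinds_in_order):
        base = u * window
        strand = "+" if geo.random() < 0.5 else "-"
        if kind == "coding":
            exon_lens = list(geo.integers(150, 401, size=3))
            intron_lens = [int(geo.integers(400, 1201)), int(geo.integers(2000, 3501))]
            start = base + 700
            exons = _exon_chain(chrom, start, strand, exon_lens, intron_lens)
            gid = f"gene{len(coding_genes) + 1:04d}"
            gene = Gene(
                gid,
                GenomicInterval(chrom, exons[0].start, exons[-1].end, strand),
                "protein_coding",
                exons,
            )
            genes.append(gene)
            coding_genes.append(gene)
            length = sum(exon_lens)
            lo = max(100, int(0.65 * length / 3))
            hi = max(lo + 1, int(0.90 * length / 3))
            orf_aa = int(geo.integers(lo, hi))
            seq, realized = _coding_sequence(length, orf_aa, seq_rng)
            tx = TranscriptModel.from_exons(next_tid(), gid, exons, seq)
            record(tx, seq, category="coding", orf_aa=realized, host_gene=gid)
        elif kind == "housekeeping":
            length = int(geo.integers(120, 2001))
            start = base + 700
            iv = GenomicInterval(chrom, start, start + length, strand)
            biotype = hk_biotypes[len([g for g in genes if g.biotype in hk_biotypes]) % 4]
            gid = f"hk{u:04d}"
            genes.append(Gene(gid, iv, biotype, [iv]))
            seq = plant_orf_free_sequence(length, min(99, max(10, length // 12)), seq_rng)
            tx = TranscriptModel.from_exons(next_tid(), gid, [iv], seq)
            record(tx, seq, category="housekeeping", host_gene=gid)
        elif kind == "lincRNA":
            n_ex = int(geo.integers(2, 4))
            exon_lens = [int(geo.integers(125, 601)) for _ in range(n_ex)]
            intron_lens = [int(geo.integers(200, 800)) for _ in range(n_ex - 1)]
            exons = _exon_chain(chrom, base + 700, strand, exon_lens, intron_lens)
            gid = f"lncg{u:04d}"
            tx, seq, orf_aa = make_lnc_transcript(exons, gid)
            record(tx, seq, category="lncRNA", lnc_class="lincRNA", orf_aa=orf_aa)
        elif kind == "noise":
            length = int(geo.integers(80, 1501))
            iv = GenomicInterval(chrom, base + 700, base + 700 + length, strand)
            seq = plant_orf_free_sequence(length, min(99, max(5, length // 12)), seq_rng)
            tx = TranscriptModel.from_exons(next_tid(), f"noiseg{u:04d}", [iv], seq)
            record(tx, seq, category="noise")
        else:  # decoy: each subtype fails exactly one downstream gate
            n_decoys_so_far = sum(
                1 for t in truth.values() if t["category"] == "decoy"
            )
            subtype = ("hit", "cpc", "long_orf")[n_decoys_so_far % 3]
            gid = f"decoyg{u:04d}"
            if subtype == "long_orf":
                # big enough exons to host a >= 100 aa reading frame
                exon_lens = [int(geo.integers(250, 500)), int(geo.integers(250, 500))]
            else:
                exon_lens = [int(geo.integers(150, 500)), int(geo.integers(150, 500))]
            intron = [int(geo.integers(200, 800))]
            exons = _exon_chain(chrom, base + 700, strand, exon_lens, intron)
            length = sum(exon_lens)
            if subtype == "long_orf":
                lo = max(100, int(0.65 * length / 3))
                hi = max(lo + 1, int(0.90 * length / 3))
                orf_aa = min(int(geo.integers(lo, hi)), (length - 3) // 3)
                seq, realized = _coding_sequence(length, orf_aa, seq_rng)
                tx = TranscriptModel.from_exons(next_tid(), gid, exons, seq)
                record(tx, seq, category="decoy", orf_aa=realized, decoy_subtype=subtype)
            else:
                tx, seq, orf_aa = make_lnc_transcript(exons, gid)
                record(tx, seq, category="decoy", orf_aa=orf_aa, decoy_subtype=subtype)

    # --- gene-linked lncRNA classes -----------------------------------------
    host_ids = geo.permutation(len(coding_genes))
    cursor = 0

    def next_hosts(n: int) -> list[Gene]:
        nonlocal cursor
        out = [coding_genes[i] for i in host_ids[cursor : cursor + n]]
        cursor += n
        return out

    for host in next_hosts(config.n_lnc_per_class["antisense"]):
        e1 = host.exons[0]
        anti_strand = "-" if host.interval.strand == "+" else "+"
        ov_len = min(100, e1.length)
        exon_a = GenomicInterval(chrom, e1.start - 100, e1.start + ov_len, anti_strand)
        exon_b = GenomicInterval(chrom, e1.start - 500, e1.start - 300, anti_strand)
        tx, seq, orf_aa = make_lnc_transcript([exon_b, exon_a], f"lncg_as_{host.gene_id}")
        record(
            tx, seq, category="lncRNA", lnc_class="antisense", orf_aa=orf_aa,
            host_gene=host.gene_id,
        )

    for host in next_hosts(config.n_lnc_per_class["sense_overlapping"]):
        e3 = host.exons[-1]
        strand = host.interval.strand
        exon_a = GenomicInterval(chrom, e3.end - 100, e3.end + 100, strand)
        exon_b = GenomicInterval(chrom, e3.end + 300, e3.end + 600, strand)
        tx, seq, orf_aa = make_lnc_transcript([exon_a, exon_b], f"lncg_so_{host.gene_id}")
        record(
            tx, seq, category="lncRNA", lnc_class="sense_overlapping", orf_aa=orf_aa,
            host_gene=host.gene_id,
        )

    for host in next_hosts(config.n_lnc_per_class["sense_intronic"]):
        # second intron is guaranteed >= 2000 bp by construction
        intron_start = host.exons[1].end
        strand = "+" if geo.random() < 0.5 else "-"
        exon_a = GenomicInterval(chrom, intron_start + 100, intron_start + 400, strand)
        exon_b = GenomicInterval(chrom, intron_start + 600, intron_start + 900, strand)
        tx, seq, orf_aa = make_lnc_transcript([exon_a, exon_b], f"lncg_si_{host.gene_id}")
        record(
            tx, seq, category="lncRNA", lnc_class="sense_intronic", orf_aa=orf_aa,
            host_gene=host.gene_id,
        )

    # --- annotate a fraction of lncRNA loci in the reference ----------------
    lnc_ids = sorted(t for t, info in truth.items() if info["category"] == "lncRNA")
    by_class: dict[str, list[str]] = {c: [] for c in LNC_CLASSES}
    for tid in lnc_ids:
        by_class[truth[tid]["lnc_class"]].append(tid)
    tx_by_id = {t.transcript_id: t for t in transcripts}
    for cls, members in by_class.items():
        n_annot = int(round(config.annotated_lnc_fraction * len(members)))
        for tid in members[:n_annot]:
            tx = tx_by_id[tid]
            genes.append(
                Gene(
                    f"lncanno_{tid}",
                    GenomicInterval(chrom, tx.interval.start, tx.interval.end, tx.strand),
                    "lncRNA",
                    list(tx.exons),
                )
            )
            truth[tid]["annotated"] = True

    annotation = GeneAnnotation(sorted(genes, key=lambda g: g.interval.start))

    # --- evidence tables: hits and coding-potential scores -------------------
    ev = _rng_for(config, "evidence")
    hit_rows = []
    for tid, info in sorted(truth.items()):
        if info["category"] == "coding" or (
            info["category"] == "decoy" and info.get("decoy_subtype") == "hit"
        ):
            for _ in range(int(ev.integers(1, 3))):
                hit_rows.append(
                    {
                        "transcript_id": tid,
                        "subject_id": f"prot_{tid}",
                        "identity_pct": round(float(ev.uniform(92, 99.5)), 2),
                        "coverage_pct": round(float(ev.uniform(82, 99)), 2),
                        "p_value": float(10.0 ** ev.uniform(-40, -15)),
                    }
                )
    # sub-threshold hits: one disqualifying field each, rotating
    sub_ids = by_class["lincRNA"][-9:]
    for i, tid in enumerate(sub_ids):
        weak = i % 3
        hit_rows.append(
            {
                "transcript_id": tid,
                "subject_id": f"weak_{tid}",
                "identity_pct": 85.0 if weak == 1 else round(float(ev.uniform(92, 99)), 2),
                "coverage_pct": 70.0 if weak == 2 else round(float(ev.uniform(82, 99)), 2),
                "p_value": 1e-5 if weak == 0 else float(10.0 ** ev.uniform(-40, -15)),
            }
        )
        truth[tid]["subthreshold_hit_field"] = ("p_value", "identity_pct", "coverage_pct")[weak]
    hits = pd.DataFrame(hit_rows, columns=[
        "transcript_id", "subject_id", "identity_pct", "coverage_pct", "p_value"
    ])

    cpc_scores: dict[str, float] = {}
    for tid, info in sorted(truth.items()):
        coding_like = info["category"] == "coding" or (
            info["category"] == "decoy"
            and info.get("decoy_subtype") in ("cpc", "long_orf")
        )
        if coding_like:
            cpc_scores[tid] = round(float(ev.uniform(0.5, 3.0)), 4)
        else:
            cpc_scores[tid] = round(float(-ev.uniform(0.5, 3.0)), 4)

    # --- expression ----------------------------------------------------------
    ex = _rng_for(config, "expression")
    samples = [
        f"{cv}_{stage}_{rep + 1}"
        for cv in config.cultivars
        for stage in config.stages
        for rep in range(config.replicates_per_stage)
    ]
    stage_of = {s: s.split("_")[1] for s in samples}
    n_s = len(samples)

    # module membership and DE plants among lncRNAs
    de_total = sum(config.de_pattern_counts.values()) + config.n_low_expression_de
    module_sizes = [
        int(ex.integers(config.module_size_range[0], config.module_size_range[1] + 1))
        for _ in range(config.n_modules)
    ]
    if de_total + sum(module_sizes) > len(lnc_ids):
        # shrink modules to fit the lncRNA pool, never below the minimum size
        available = len(lnc_ids) - de_total
        if available < config.n_modules * config.module_size_range[0]:
            raise ConfigError("not enough lncRNAs for the requested modules and DE plants")
        while sum(module_sizes) > available:
            i = int(np.argmax(module_sizes))
            module_sizes[i] -= 1

    pool = list(ex.permutation(sorted(lnc_ids)))
    de_ids = [pool.pop() for _ in range(de_total)]
    module_members: list[list[str]] = []
    for size in module_sizes:
        module_members.append([pool.pop() for _ in range(size)])

    log2x = pd.DataFrame(0.0, index=[t.transcript_id for t in transcripts], columns=samples)
    base = pd.Series(
        ex.uniform(2, 6, size=len(log2x.index)), index=log2x.index
    )
    noise = lambda: ex.normal(0.0, config.noise_sd, size=n_s)  # noqa: E731

    # default: flat expression around the transcript's base level
    for tid in log2x.index:
        log2x.loc[tid] = base[tid] + noise()

    # planted module structure
    trajectories = []
    stage_index = {s: i for i, s in enumerate(config.stages)}
    for m, members in enumerate(module_members):
        traj = ex.normal(0.0, 1.0, size=n_s)
        trajectories.append(traj)
        for tid in members:
            loading = float(ex.uniform(0.8, 1.2))
            log2x.loc[tid] = base[tid] + loading * traj + noise()
            truth[tid]["module_index"] = m

    # planted DE patterns (stage-level mean shifts, identical across cultivars)
    pattern_list = (
        ["up_down"] * config.de_pattern_counts.get("up_down", 0)
        + ["down_up"] * config.de_pattern_counts.get("down_up", 0)
        + ["single_transition"] * config.de_pattern_counts.get("single_transition", 0)
        + ["low_expression"] * config.n_low_expression_de
    )
    for tid, pattern in zip(de_ids, pattern_list):
        d1 = float(ex.uniform(2.0, 3.5))
        d2 = float(ex.uniform(2.0, 3.5))
        if pattern == "up_down":
            offsets = [0.0, d1, d1 - d2]
        elif pattern == "down_up":
            offsets = [0.0, -d1, -d1 + d2]
        elif pattern == "single_transition":
            direction = 1.0 if ex.random() < 0.5 else -1.0
            if ex.random() < 0.5:
                offsets = [0.0, direction * d1, direction * d1]
            else:
                offsets = [0.0, 0.0, direction * d2]
        else:  # low_expression: strong ratios at negligible absolute level
            offsets = [0.0, d1, d1 - d2]
        b = base[tid] if pattern != "low_expression" else float(np.log2(0.02))
        stage_mean = [b + o for o in offsets]
        log2x.loc[tid] = (
            np.array([stage_mean[stage_index[stage_of[s]]] for s in samples]) + noise()
        )
        truth[tid]["de_pattern"] = pattern

    # planted co-expression partners: gene tracks its lncRNA profile
    coexpr_pairs: list[tuple[str, str]] = []
    partner_genes = [g for g in coding_genes[: config.n_coexpr_pairs]]
    gene_tx = {info["host_gene"]: tid for tid, info in truth.items() if info["category"] == "coding"}
    for gene, lnc_tid in zip(partner_genes, de_ids[: config.n_coexpr_pairs]):
        gtid = gene_tx[gene.gene_id]
        log2x.loc[gtid] = log2x.loc[lnc_tid] + float(ex.uniform(-1, 1)) + ex.normal(
            0.0, 0.05, size=n_s
        )
        coexpr_pairs.append((lnc_tid, gtid))

    values = (2.0 ** log2x).round(4)
    meta = pd.DataFrame(
        {
            "cultivar": [s.split("_")[0] for s in samples],
            "stage": [s.split("_")[1] for s in samples],
            "replicate": [int(s.split("_")[2]) for s in samples],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    expression = ExpressionMatrix(values, meta)

    # --- volatiles and GC-MS -------------------------------------------------
    vol = _rng_for(config, "volatiles")
    links = {c: (m, r) for c, m, r in config.default_trait_link()}
    compound_classes = dict(DEFAULT_COMPOUNDS)
    for c in links:
        compound_classes.setdefault(c, "terpenoid")
    compounds_info: dict[str, dict] = {}
    rates = {}
    for compound, cls in compound_classes.items():
        base_rate = float(vol.uniform(0.5, 10.0))
        if compound in links:
            m, r = links[compound]
            traj = trajectories[m]
            z = (traj - traj.mean()) / traj.std()
            mix = r * z + np.sqrt(1 - r**2) * vol.normal(0.0, 1.0, size=n_s)
        else:
            m, r = None, None
            mix = vol.normal(0.0, 1.0, size=n_s)
        vec = np.maximum(base_rate * (1.0 + 0.2 * mix), 1e-4)
        rates[compound] = vec
        compounds_info[compound] = {
            "class": cls,
            "module_index": m,
            "planted_r": r,
            "rates": {s: float(v) for s, v in zip(samples, vec)},
        }

    gc = _rng_for(config, "gcms")
    is_conc, is_vol, mass, time_h = 0.865, 10.0, 3.0, 2.0 / 3.0
    gcms_rows = []
    for s_i, sample in enumerate(samples):
        is_area = float(gc.uniform(5e4, 2e5))
        for compound in compound_classes:
            rate = rates[compound][s_i]
            peak = rate * mass * time_h / (is_conc * is_vol) * is_area
            gcms_rows.append(
                {
                    "sample_id": sample,
                    "compound": compound,
                    "peak_area": peak,
                    "is_peak_area": is_area,
                    "is_concentration": is_conc,
                    "is_volume": is_vol,
                    "sample_mass": mass,
                    "extraction_time": time_h,
                }
            )
    gcms = pd.DataFrame(gcms_rows, columns=GCMS_COLUMNS)

    # --- qPCR Ct table --------------------------------------------------------
    ctr = _rng_for(config, "ct")
    qpcr_targets = [
        tid for tid in de_ids if truth[tid]["de_pattern"] in ("up_down", "down_up")
    ][:10]
    ct_rows = []
    primary = config.cultivars[0]
    for sample in expression.samples_for(cultivar=primary):
        for tid in qpcr_targets:
            x = float(values.loc[tid, sample])
            ct_rows.append(
                {
                    "sample_id": sample,
                    "target_id": tid,
                    "ct": 30.0 - float(np.log2(x + 0.01)) + float(ctr.normal(0, 0.15)),
                }
            )
        ct_rows.append(
            {
                "sample_id": sample,
                "target_id": "GAPDH",
                "ct": 19.0 + float(ctr.normal(0, 0.1)),
            }
        )
    ct_table = pd.DataFrame(ct_rows, columns=["sample_id", "target_id", "ct"])

    manifest = TruthManifest(
        transcripts=truth,
        modules=[
            {"index": m, "members": members, "trajectory": [float(v) for v in trajectories[m]]}
            for m, members in enumerate(module_members)
        ],
        compounds=compounds_info,
        coexpr_pairs=coexpr_pairs,
        samples=samples,
        config=_config_dict(config),
    )
    return Bundle(
        annotation=annotation,
        transcripts=transcripts,
        sequences=sequences,
        hits=hits,
        cpc_scores=cpc_scores,
        expression=expression,
        gcms=gcms,
        compound_classes=compound_classes,
        ct_table=ct_table,
        manifest=manifest,
    )


def _config_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["stages"] = list(config.stages)
    d["module_size_range"] = list(config.module_size_range)
    return d


# ---------------------------------------------------------------------------
# Writing a bundle to disk
# ---------------------------------------------------------------------------

BUNDLE_FILES = {
    "annotation": "annotation.gff3",
    "gtf": "transcripts.gtf",
    "fasta": "transcripts.fasta",
    "hits": "hits.tsv",
    "cpc": "cpc_scores.tsv",
    "expression": "expression.tsv",
    "meta": "sample_meta.tsv",
    "gcms": "gcms_peaks.tsv",
    "classes": "compound_classes.tsv",
    "ct": "ct_table.tsv",
    "manifest": "manifest.json",
}


def write_bundle(bundle: Bundle, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: outdir / v for k, v in BUNDLE_FILES.items()}
    write_gff3(bundle.annotation, paths["annotation"])
    write_gtf(bundle.transcripts, paths["gtf"])
    write_fasta(bundle.sequences, paths["fasta"])
    write_hit_table(bundle.hits, paths["hits"])
    with open(paths["cpc"], "w") as fh:
        for tid, score in sorted(bundle.cpc_scores.items()):
            fh.write(f"{tid}\t{score!r}\n")
    write_expression(bundle.expression, paths["expression"], paths["meta"])
    bundle.gcms.to_csv(paths["gcms"], sep="\t", index=False)
    with open(paths["classes"], "w") as fh:
        for compound, cls in sorted(bundle.compound_classes.items()):
            fh.write(f"{compound}\t{cls}\n")
    bundle.ct_table.to_csv(paths["ct"], sep="\t", index=False)
    paths["manifest"].write_text(bundle.manifest.to_json())
    return paths


# ---------------------------------------------------------------------------
# Focused simulators reused by validation studies
# ---------------------------------------------------------------------------


def simulate_de_experiment(
    n_null: int = 200,
    n_de: int = 40,
    log2fc: float = 2.0,
    noise_sd: float = 0.25,
    replicates: int = 3,
    seed: int = 0,
) -> tuple[ExpressionMatrix, set[str], set[str]]:
    """Two-stage expression matrix with planted fold changes.

    Half the DE transcripts go up, half down, by ``log2fc`` on the log2
    scale with per-replicate log-normal noise. Returns the matrix plus the
    planted up- and down-regulated id sets.
    """
    rng = np.random.default_rng([97, seed % 2**31])
    ids = [f"t{i:04d}" for i in range(n_null + n_de)]
    samples = [f"cv1_{st}_{r + 1}" for st in ("EF", "SF") for r in range(replicates)]
    base = rng.uniform(2, 6, size=len(ids))
    shift = np.zeros(len(ids))
    n_up = n_de // 2
    shift[n_null : n_null + n_up] = log2fc
    shift[n_null + n_up :] = -log2fc
    log2x = np.empty((len(ids), len(samples)))
    for j, s in enumerate(samples):
        stage_shift = shift if s.split("_")[1] == "SF" else np.zeros(len(ids))
        log2x[:, j] = base + stage_shift + rng.normal(0, noise_sd, size=len(ids))
    values = pd.DataFrame(2.0**log2x, index=ids, columns=samples)
    meta = pd.DataFrame(
        {
            "cultivar": [s.split("_")[0] for s in samples],
            "stage": [s.split("_")[1] for s in samples],
            "replicate": [int(s.split("_")[2]) for s in samples],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    up = set(ids[n_null : n_null + n_up])
    down = set(ids[n_null + n_up :])
    return ExpressionMatrix(values, meta), up, down


def simulate_module_expression(
    n_modules: int = 13,
    module_size_range: tuple[int, int] = (6, 10),
    n_samples: int = 36,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, int], np.ndarray]:
    """Module-structured expression (log2 scale) with planted memberships.

    Returns (expression genes x samples, id -> module index, trajectories
    [n_modules x n_samples]).
    """
    rng = np.random.default_rng([113, seed % 2**31])
    sizes = rng.integers(
        module_size_range[0], module_size_range[1] + 1, size=n_modules
    )
    trajectories = rng.normal(0.0, 1.0, size=(n_modules, n_samples))
    rows, labels = [], {}
    ids = []
    for m in range(n_modules):
        for k in range(sizes[m]):
            tid = f"m{m:02d}_g{k:02d}"
            loading = rng.uniform(0.8, 1.2)
            rows.append(
                rng.uniform(2, 6)
                + loading * trajectories[m]
                + rng.normal(0, noise_sd, size=n_samples)
            )
            labels[tid] = m
            ids.append(tid)
    samples = [f"s{j:02d}" for j in range(n_samples)]
    return pd.DataFrame(rows, index=ids, columns=samples), labels, trajectories


def simulate_trait_vectors(
    trajectories: np.ndarray,
    links: Sequence[tuple[str, int, float]],
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample trait vectors correlated with module trajectories."""
    rng = np.random.default_rng([127, seed % 2**31])
    n_samples = trajectories.shape[1]
    rows = {}
    for name, m, r in links:
        traj = trajectories[m]
        z = (traj - traj.mean()) / traj.std()
        mix = r * z + np.sqrt(1 - r**2) * rng.normal(0, 1, size=n_samples)
        base = rng.uniform(0.5, 10.0)
        rows[name] = np.maximum(base * (1 + 0.2 * mix), 1e-4)
    return pd.DataFrame(rows, index=[f"s{j:02d}" for j in range(n_samples)]).T
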