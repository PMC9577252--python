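import bisect

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rosalnc.identify import (
    CascadeReport,
    CascadeStage,
    builtin_coding_score,
    coding_potential_gate,
    filter_coding_hits,
    filter_exon_count,
    filter_housekeeping,
    filter_length_orf,
    longest_orf,
    run_cascade,
    split_annotated,
)
from rosalnc.io_formats import (
    FilterCriteria,
    Gene,
    GeneAnnotation,
    GenomicInterval,
    TranscriptModel,
    ValidationError,
)
from rosalnc.synthetic import plant_orf_free_sequence

import pandas as pd


# ---------------------------------------------------------------------------
# Independent ORF oracle: enumerate every ATG and find its first in-frame
# stop by bisecting precomputed per-frame stop positions.
# ---------------------------------------------------------------------------

STOPS = ("TAA", "TAG", "TGA")


def orf_oracle(seq: str) -> tuple[int, int, int]:
    seq = seq.upper()
    stops_by_frame = [[], [], []]
    for i in range(len(seq) - 2):
        if seq[i : i + 3] in STOPS:
            stops_by_frame[i % 3].append(i)
    best = (0, 0, 0)  # aa, start, frame
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        frame = i % 3
        stops = stops_by_frame[frame]
        j = bisect.bisect_right(stops, i)
        if j == len(stops):
            continue
        aa = (stops[j] - i) // 3
        if aa > best[0] or (aa == best[0] and aa > 0 and (i, frame) < (best[1], best[2])):
            best = (aa, i, frame)
    return best


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestLongestOrf:
    @pytest.mark.parametrize(
        "seq,aa",
        [
            ("ATGAAATAA", 2),  # M K stop
            ("TTTTTTTTT", 0),  # no ATG
            ("ATGTAA", 1),  # M stop
            ("ATG", 0),  # start without stop is not an ORF
            ("", 0),
            ("ATGNNNTAA", 2),  # N codon is neither start nor stop
            ("AATGTAACCC", 1),  # frame 1 ORF
        ],
    )
    def test_known_orfs(self, seq, aa):
        assert longest_orf(seq).aa_length == aa

    def test_tie_breaks_to_smallest_start(self):
        # two single-codon ORFs; the earlier start must win
        seq = "ATGTAAATGTAA"
        call = longest_orf(seq)
        assert (call.aa_length, call.start_nt) == (1, 0)

    def test_start_congruent_with_frame(self):
        call = longest_orf("AATGTAACCC")
        assert call.start_nt % 3 == call.frame == 1

    def test_matches_exhaustive_oracle_on_random_sequences(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            seq = random_seq(rng, int(rng.integers(30, 3001)))
            call = longest_orf(seq)
            aa, start, frame = orf_oracle(seq)
            assert (call.aa_length, call.start_nt, call.frame) == (aa, start, frame)

    @given(st.text(alphabet="ACGTN", min_size=0, max_size=400))
    def test_matches_oracle_property(self, seq):
        call = longest_orf(seq)
        aa, start, frame = orf_oracle(seq)
        assert (call.aa_length, call.start_nt, call.frame) == (aa, start, frame)

    def test_six_frame_finds_reverse_orf(self):
        fwd = "ATGAAAAAATAA"  # 3-aa ORF
        comp = str.maketrans("ACGT", "TGCA")
        rc = fwd.translate(comp)[::-1]
        assert longest_orf(rc).aa_length < 3
        assert longest_orf(rc, six_frame=True).aa_length == 3


def _tx(tid, exons, gene="g"):
    return TranscriptModel.from_exons(tid, gene, exons)


class TestFilters:
    def test_housekeeping_abutting_exon_kept_overlapping_removed(self):
        anno = GeneAnnotation(
            [
                Gene(
                    "trna1",
                    GenomicInterval("chr1", 100, 200, "+"),
                    "tRNA",
                    [GenomicInterval("chr1", 100, 200, "+")],
                )
            ]
        )
        abutting = _tx("t_ab", [GenomicInterval("chr1", 200, 300, "+")])
        inside = _tx("t_in", [GenomicInterval("chr1", 120, 180, "-")])
        kept, removed = filter_housekeeping([abutting, inside], anno)
        assert [t.transcript_id for t in kept] == ["t_ab"]
        assert [t.transcript_id for t in removed] == ["t_in"]

    def test_exon_count_boundary(self):
        one = _tx("t1", [GenomicInterval("chr1", 0, 100, "+")])
        two = _tx(
            "t2",
            [GenomicInterval("chr1", 0, 100, "+"), GenomicInterval("chr1", 200, 300, "+")],
        )
        kept, removed = filter_exon_count([one, two], min_exons=2)
        assert [t.transcript_id for t in kept] == ["t2"]
        assert [t.transcript_id for t in removed] == ["t1"]

    @pytest.mark.parametrize(
        "identity,coverage,p,excluded",
        [
            (90.0, 85.0, 1e-20, False),  # identity boundary is strict
            (95.0, 80.0, 1e-20, False),  # coverage boundary is strict
            (95.0, 85.0, 1e-10, False),  # p boundary is strict
            (95.0, 85.0, 1e-20, True),
        ],
    )
    def test_coding_hit_thresholds_strict(self, identity, coverage, p, excluded):
        tx = _tx("t1", [GenomicInterval("chr1", 0, 300, "+")])
        hits = pd.DataFrame(
            [
                {
                    "transcript_id": "t1",
                    "subject_id": "p1",
                    "identity_pct": identity,
                    "coverage_pct": coverage,
                    "p_value": p,
                }
            ]
        )
        kept, removed = filter_coding_hits([tx], hits)
        assert bool(removed) == excluded

    def test_split_annotated_requires_same_strand(self):
        anno = GeneAnnotation(
            [
                Gene(
                    "lg1",
                    GenomicInterval("chr1", 100, 500, "+"),
                    "lncRNA",
                    [GenomicInterval("chr1", 100, 500, "+")],
                )
            ]
        )
        same = _tx("t_same", [GenomicInterval("chr1", 150, 400, "+")])
        opp = _tx("t_opp", [GenomicInterval("chr1", 150, 400, "-")])
        annotated, rest = split_annotated([same, opp], anno)
        assert [t.transcript_id for t in annotated] == ["t_same"]
        assert [t.transcript_id for t in rest] == ["t_opp"]

    def test_length_orf_boundaries(self):
        rng = np.random.default_rng(0)
        short = plant_orf_free_sequence(199, 100, rng)
        exact = plant_orf_free_sequence(200, 100, rng)
        # 100-aa ORF (removed): ATG + 99 codons + stop = 303 nt + padding
        coding = "ATG" + "AAA" * 99 + "TAA" + "C" * 10
        seqs = {"t_short": short, "t_ok": exact, "t_orf": coding}
        txs = [
            _tx(tid, [GenomicInterval("chr1", 0, len(s), "+")])
            for tid, s in seqs.items()
        ]
        kept, removed = filter_length_orf(txs, seqs)
        assert {t.transcript_id for t in kept} == {"t_ok"}
        assert {t.transcript_id for t in removed} == {"t_short", "t_orf"}

    def test_missing_sequence_removed_not_crash(self):
        tx = _tx("t1", [GenomicInterval("chr1", 0, 300, "+")])
        kept, removed = filter_length_orf([tx], {})
        assert kept == [] and removed == [tx]

    def test_gate_external_score_and_pfam_precedence(self):
        t1 = _tx("t1", [GenomicInterval("chr1", 0, 300, "+")])
        t2 = _tx("t2", [GenomicInterval("chr1", 400, 700, "+")])
        kept, removed, scores = coding_potential_gate(
            [t1, t2],
            sequences={},
            external_scores={"t1": -1.2, "t2": -1.2},
            pfam_hits={"t2": 1e-6},  # domain hit removes despite negative score
        )
        assert [t.transcript_id for t in kept] == ["t1"]
        assert [t.transcript_id for t in removed] == ["t2"]
        assert scores[0].source == "external_table"

    def test_gate_without_any_evidence_errors(self):
        tx = _tx("t1", [GenomicInterval("chr1", 0, 300, "+")])
        with pytest.raises(ValidationError):
            coding_potential_gate([tx], sequences={}, external_scores=None)


class TestBuiltinHeuristic:
    def test_long_orf_sequences_score_positive(self, bundle):
        coding_like = [
            tid
            for tid, info in bundle.manifest.transcripts.items()
            if info["category"] == "coding"
            or info.get("decoy_subtype") == "long_orf"
        ]
        scores = [builtin_coding_score(bundle.sequences[t]) for t in coding_like]
        assert np.mean([s > 0 for s in scores]) >= 0.9

    def test_orf_poor_lncRNAs_score_negative(self, bundle):
        lnc = sorted(bundle.manifest.lncRNA_ids)
        scores = [builtin_coding_score(bundle.sequences[t]) for t in lnc]
        assert np.mean([s < 0 for s in scores]) >= 0.9


class TestCascade:
    def test_empty_input_all_zero(self, bundle):
        report, annotated, novel = run_cascade([], bundle.annotation)
        assert all(s.n_input == 0 and s.n_surviving == 0 for s in report.stages)
        assert annotated == [] and novel == []

    def test_rerun_is_deterministic(self, bundle, cascade):
        report2, _, _ = run_cascade(
            bundle.transcripts,
            bundle.annotation,
            bundle.hits,
            bundle.sequences,
            bundle.cpc_scores,
        )
        assert report2.stages == cascade[0].stages
        assert report2.annotated_lncRNAs == cascade[0].annotated_lncRNAs
        assert report2.novel_lncRNAs == cascade[0].novel_lncRNAs

    def test_stage_accounting(self, cascade):
        report = cascade[0]
        for a, b in zip(report.stages, report.stages[1:]):
            assert b.n_input == a.n_surviving
        for s in report.stages:
            assert s.n_surviving == s.n_input - s.n_removed

    def test_housekeeping_and_exon_filters_commute(self, bundle):
        a1, _ = filter_housekeeping(bundle.transcripts, bundle.annotation)
        a2, _ = filter_exon_count(a1)
        b1, _ = filter_exon_count(bundle.transcripts)
        b2, _ = filter_housekeeping(b1, bundle.annotation)
        assert {t.transcript_id for t in a2} == {t.transcript_id for t in b2}

    def test_final_set_satisfies_constraints(self, bundle, cascade):
        report, annotated, novel = cascade
        criteria = FilterCriteria()
        for tx in annotated + novel:
            assert tx.n_exons >= criteria.min_exons
        for tx in novel:
            seq = bundle.sequences[tx.transcript_id]
            assert len(seq) >= criteria.min_length_nt
            assert longest_orf(seq).aa_length < criteria.max_orf_aa

    def test_invalid_report_rejected(self):
        with pytest.raises(ValidationError):
            CascadeStage("x", 10, 3, 8)
        with pytest.raises(ValidationError):
            CascadeReport(
                stages=[CascadeStage("a", 10, 2, 8), CascadeStage("b", 9, 0, 9)]
            )
        with pytest.raises(ValidationError):
            CascadeReport(stages=[], annotated_lncRNAs=["x"], novel_lncRNAs=["x"])
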