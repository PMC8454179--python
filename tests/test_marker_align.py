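"""Smith–Waterman engine, six-frame translation and marker anchoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aspmat.genome_io import GenomeSequence
from aspmat.marker_align import (
    Marker,
    MarkerSet,
    Scoring,
    anchor_markers,
    revcomp,
    six_frame_translate,
    smith_waterman,
)
from aspmat.synthetic_data import random_dna

dna = st.text(alphabet="ACGT", min_size=1, max_size=12)


def sw_oracle(a, b, match=2, mismatch=-3, gap_open=5, gap_extend=2):
    """Brute-force local alignment DP without the affine E/F optimization.

    Gaps of length k are scored in one step (gap_open + k*gap_extend),
    scanning all k — quadratic per cell, independent of the optimized
    three-matrix recurrence it checks.
    """
    n, m = len(a), len(b)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            v = max(0, H[i - 1][j - 1] + s)
            for k in range(1, i + 1):
                v = max(v, H[i - k][j] - gap_open - gap_extend * k)
            for k in range(1, j + 1):
                v = max(v, H[i][j - k] - gap_open - gap_extend * k)
            H[i][j] = v
            best = max(best, v)
    return best


class TestSmithWaterman:
    @pytest.mark.parametrize("n", [1, 5, 40])
    def test_identical_sequences_score_2n(self, n):
        seq = ("ACGT" * (n // 4 + 1))[:n]
        aln = smith_waterman(seq, seq)
        assert aln.score == 2 * n
        assert aln.a_interval == (0, n) and aln.b_interval == (0, n)
        assert aln.identity == 100.0

    def test_dissimilar_pair_scores_zero(self):
        aln = smith_waterman("AAAA", "CCCC")
        assert aln.score == 0
        assert aln.a_interval == (0, 0) and aln.b_interval == (0, 0)
        assert aln.pairs == []

    def test_gap_is_opened_when_worth_it(self):
        # 20 matches around a single deleted base: 40 - (5+2) = 33
        a = "ACGTACGTAC" + "GTACGTACGT"
        b = "ACGTACGTAC" + "T" + "GTACGTACGT"
        assert smith_waterman(a, b).score == 33

    @given(dna, dna)
    @settings(max_examples=200)
    def test_matches_bruteforce_oracle(self, a, b):
        assert smith_waterman(a, b).score == sw_oracle(a, b)

    @given(dna, dna)
    def test_matches_biopython_aligner(self, a, b):
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = 2
        aligner.mismatch_score = -3
        aligner.open_gap_score = -7  # first gapped base: open + extend
        aligner.extend_gap_score = -2
        assert smith_waterman(a, b).score == int(aligner.score(a, b))

    @given(dna, dna)
    def test_reverse_complement_symmetry(self, a, b):
        assert smith_waterman(a, b).score == smith_waterman(revcomp(a), revcomp(b)).score

    @given(dna, dna)
    def test_relaxing_mismatch_never_decreases_score(self, a, b):
        strict = smith_waterman(a, b, Scoring(mismatch=-3)).score
        relaxed = smith_waterman(a, b, Scoring(mismatch=-1)).score
        assert relaxed >= strict

    def test_alphabet_mismatch_rejected(self):
        with pytest.raises(ValueError, match="alphabet mismatch"):
            smith_waterman("ACGT", "MKLW")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            smith_waterman("", "ACGT")

    def test_protein_alignment_uses_blosum(self):
        aln = smith_waterman("MKWVTF", "MKWVTF", alphabet="aa")
        # BLOSUM62 diagonal: M5 K5 W11 V4 T5 F6
        assert aln.score == 36


class TestSixFrameTranslate:
    def test_single_codon(self):
        frames = dict((f[0], f[2]) for f in six_frame_translate("ATG"))
        assert frames["+1"] == "M"

    def test_stop_codon_rendered(self):
        frames = dict((f[0], f[2]) for f in six_frame_translate("ATGAAATAG"))
        assert frames["+1"] == "MK*"

    @pytest.mark.parametrize("seq", ["ATGAAATAGC", "ACGTACGTACGT", "TTTT"])
    def test_minus_one_equals_plus_one_of_revcomp(self, seq):
        minus1 = dict((f[0], f[2]) for f in six_frame_translate(seq))["-1"]
        plus1 = dict((f[0], f[2]) for f in six_frame_translate(revcomp(seq)))["+1"]
        assert minus1 == plus1


def _plant(rng, marker_seq, length=20_000, pos=8_000, gc=49.6, mutate_at=None):
    backbone = random_dna(rng, length, gc)
    seq = marker_seq
    if mutate_at is not None:
        arr = list(seq)
        for i in mutate_at:
            arr[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[i]]
        seq = "".join(arr)
    return GenomeSequence("ctg", backbone[:pos] + seq + backbone[pos:])


class TestAnchorMarkers:
    def test_exact_plant_found_at_position(self, panel, rng):
        marker = panel["apnB"]
        contig = _plant(rng, marker.seq, pos=5_000)
        (hit,) = anchor_markers(contig, MarkerSet({"apnB": marker}))
        assert (hit.start, hit.end) == (5_000, 5_000 + len(marker.seq))
        assert hit.strand == "+"
        assert hit.score_fraction == pytest.approx(1.0)

    def test_revcomp_plant_same_score_minus_strand(self, panel, rng):
        marker = panel["apnB"]
        fwd = anchor_markers(_plant(rng, marker.seq), MarkerSet({"apnB": marker}))[0]
        rev = anchor_markers(
            _plant(np.random.default_rng(12345), revcomp(marker.seq)),
            MarkerSet({"apnB": marker}),
        )[0]
        assert rev.score == fwd.score
        assert rev.strand == "-"
        assert (rev.start, rev.end) == (fwd.start, fwd.end)

    def test_mutated_plant_recovered_across_seeds(self, panel):
        marker = panel["slaB"]
        n = len(marker.seq)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            sites = rng.choice(n, size=int(0.05 * n), replace=False)
            contig = _plant(rng, marker.seq, pos=6_000, mutate_at=sites)
            (hit,) = anchor_markers(contig, MarkerSet({"slaB": marker}))
            assert hit.start < 6_000 + n and hit.end > 6_000  # overlaps the plant

    def test_random_contig_yields_no_high_confidence_hits(self, panel):
        markers = MarkerSet({"apnB": panel["apnB"]})
        for seed in range(20):
            contig = GenomeSequence("r", random_dna(np.random.default_rng(seed), 10_000, 50))
            assert anchor_markers(contig, markers, min_score_fraction=0.9) == []

    def test_contig_shorter_than_marker_is_empty_not_error(self, panel):
        contig = GenomeSequence("tiny", "ACGTACGTAC")
        assert anchor_markers(contig, MarkerSet({"apnB": panel["apnB"]})) == []

    def test_protein_and_nucleotide_routes_agree(self, rng):
        # a synthetic gene: ATG + 240 random codons, searched as nt and as aa
        codons = ["".join(c) for c in zip(*[iter(random_dna(rng, 720, 50))] * 3)]
        codons = [c for c in codons if c not in {"TAA", "TAG", "TGA"}]
        gene = "ATG" + "".join(codons)
        gene = gene[: len(gene) - len(gene) % 3]
        from Bio.Seq import Seq

        prot = str(Seq(gene).translate())
        contig = _plant(rng, gene, pos=4_001)
        nt_hit = anchor_markers(contig, MarkerSet({"g": Marker("g", gene, "nt")}))[0]
        aa_hit = anchor_markers(contig, MarkerSet({"g": Marker("g", prot, "aa")}))[0]
        assert aa_hit.strand == nt_hit.strand == "+"
        overlap = min(nt_hit.end, aa_hit.end) - max(nt_hit.start, aa_hit.start)
        assert overlap > 0.9 * (nt_hit.end - nt_hit.start)

    def test_protein_route_finds_minus_strand_gene(self, rng):
        codons = ["".join(c) for c in zip(*[iter(random_dna(rng, 600, 50))] * 3)]
        codons = [c for c in codons if c not in {"TAA", "TAG", "TGA"}]
        gene = "ATG" + "".join(codons)
        from Bio.Seq import Seq

        prot = str(Seq(gene[: len(gene) - len(gene) % 3]).translate())
        contig = _plant(rng, revcomp(gene), pos=7_000)
        (hit,) = anchor_markers(contig, MarkerSet({"g": Marker("g", prot, "aa")}))
        assert hit.strand == "-"
        assert hit.start < 7_000 + len(gene) and hit.end > 7_000


class TestMarkerSet:
    def test_fasta_roundtrip_with_alphabet_tags(self, tmp_path, panel):
        p = tmp_path / "markers.fasta"
        panel.to_fasta(p)
        back = MarkerSet.from_fasta(p)
        assert set(back.entries) == set(panel.entries)
        assert back["slaB"].seq == panel["slaB"].seq
        assert back.missing_required() == []

    def test_empty_marker_rejected(self):
        with pytest.raises(ValueError):
            Marker("x", "", "nt")

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError):
            Marker("x", "ACGT", "rna")
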