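"""Homology blocks, inversion detection, breakpoints and motif scanning."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from aspmat.locus_compare import (
    CompareParams,
    annotate_motif_breakpoint_proximity,
    detect_inverted_mat_block,
    find_breakpoints,
    homology_blocks,
    motif_scan,
)
from aspmat.marker_align import revcomp
from aspmat.synthetic_data import MatLocusPlan, random_dna, simulate_mat_locus


@pytest.fixture(scope="module")
def base_seq():
    return random_dna(np.random.default_rng(42), 30_000, 50.0)


@pytest.fixture(scope="module")
def inversion_pair(base_seq):
    """locus B = locus A with its middle third reverse-complemented."""
    third = len(base_seq) // 3
    b = base_seq[:third] + revcomp(base_seq[third : 2 * third]) + base_seq[2 * third :]
    return base_seq, b, third


class TestHomologyBlocks:
    def test_self_comparison_single_forward_block(self, base_seq):
        blocks = homology_blocks(base_seq, base_seq)
        assert len(blocks) == 1
        (bl,) = blocks
        assert bl.orientation == "forward"
        covered = bl.interval_a[1] - bl.interval_a[0]
        assert covered >= 0.99 * len(base_seq)

    def test_constructed_inversion_three_blocks(self, inversion_pair):
        a, b, third = inversion_pair
        blocks = homology_blocks(a, b)
        assert [bl.orientation for bl in blocks] == ["forward", "inverted", "forward"]
        mid = blocks[1]
        assert abs(mid.interval_a[0] - third) <= 25
        assert abs(mid.interval_a[1] - 2 * third) <= 25

    def test_unrelated_sequences_no_blocks(self):
        r = np.random.default_rng(7)
        assert homology_blocks(random_dna(r, 5000, 50), random_dna(r, 5000, 50)) == []

    def test_swapping_loci_swaps_intervals_and_keeps_orientation(self, inversion_pair):
        a, b, _ = inversion_pair
        ab = homology_blocks(a, b)
        ba = homology_blocks(b, a)
        assert sorted((bl.interval_b, bl.interval_a, bl.orientation) for bl in ab) == sorted(
            (bl.interval_a, bl.interval_b, bl.orientation) for bl in ba
        )

    def test_blocks_non_overlapping_on_each_locus(self, inversion_pair):
        a, b, _ = inversion_pair
        blocks = homology_blocks(a, b)
        for key in ("interval_a", "interval_b"):
            ivs = sorted(getattr(bl, key) for bl in blocks)
            assert all(e1 <= s2 for (_, e1), (s2, _) in zip(ivs, ivs[1:]))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            homology_blocks("", "ACGT")


class TestDetectInvertedMatBlock:
    def test_mat_inside_inverted_block(self, inversion_pair):
        a, b, third = inversion_pair
        blocks = homology_blocks(a, b)
        mat = (third + 1000, third + 2000)
        assert detect_inverted_mat_block(blocks, mat, mat) == "inverted"

    def test_mat_inside_forward_block(self, inversion_pair):
        a, b, _ = inversion_pair
        blocks = homology_blocks(a, b)
        assert detect_inverted_mat_block(blocks, (100, 1100), (100, 1100)) == "co-oriented"

    def test_mat_in_unaligned_gap_not_covered(self, base_seq):
        blocks = homology_blocks(base_seq, base_seq)
        beyond = (len(base_seq) + 10, len(base_seq) + 20)
        assert detect_inverted_mat_block(blocks, beyond, beyond) == "not-covered"

    def test_conserved_vs_flipped_locus_pair_is_inverted(self, panel):
        # same idiomorph in both layouts so the MAT gene itself is homologous
        lc, tc = simulate_mat_locus(MatLocusPlan("MAT1-1", "conserved"), panel, np.random.default_rng(1))
        lf, tf = simulate_mat_locus(MatLocusPlan("MAT1-1", "flipped"), panel, np.random.default_rng(2))
        blocks = homology_blocks(lc, lf)
        mat_c = next(p for p in tc.marker_placements if p[0] == "MAT1-1-1_alpha")
        mat_f = next(p for p in tf.marker_placements if p[0] == "MAT1-1-1_alpha")
        call = detect_inverted_mat_block(blocks, (mat_c[2], mat_c[3]), (mat_f[2], mat_f[3]))
        assert call == "inverted"

    def test_both_conserved_pair_is_co_oriented(self, panel):
        l1, t1 = simulate_mat_locus(MatLocusPlan("MAT1-2", "conserved"), panel, np.random.default_rng(3))
        l2, t2 = simulate_mat_locus(MatLocusPlan("MAT1-2", "conserved"), panel, np.random.default_rng(4))
        blocks = homology_blocks(l1, l2)
        m1 = next(p for p in t1.marker_placements if p[0] == "MAT1-2-1_HMG")
        m2 = next(p for p in t2.marker_placements if p[0] == "MAT1-2-1_HMG")
        assert detect_inverted_mat_block(blocks, (m1[2], m1[3]), (m2[2], m2[3])) == "co-oriented"


class TestFindBreakpoints:
    def test_full_length_forward_block_no_breakpoints(self, base_seq):
        blocks = homology_blocks(base_seq, base_seq)
        assert find_breakpoints(blocks, (len(base_seq), len(base_seq))) == []

    def test_empty_block_set_no_breakpoints(self):
        assert find_breakpoints([], (1000, 1000)) == []

    def test_constructed_inversion_two_breakpoints_per_locus(self, inversion_pair):
        a, b, third = inversion_pair
        blocks = homology_blocks(a, b)
        bps = find_breakpoints(blocks, (len(a), len(b)))
        for locus in "AB":
            here = sorted(bp.position for bp in bps if bp.locus == locus)
            assert len(here) == 2
            assert abs(here[0] - third) <= 2000
            assert abs(here[1] - 2 * third) <= 2000

    def test_breakpoint_count_consistency(self, inversion_pair):
        a, b, _ = inversion_pair
        params = CompareParams()
        blocks = homology_blocks(a, b, params)
        bps = find_breakpoints(blocks, (len(a), len(b)), params)
        for locus, L, key in (("A", len(a), "interval_a"), ("B", len(b), "interval_b")):
            ivs = sorted(
                (getattr(bl, key), bl.orientation) for bl in blocks
            )
            expected = 0
            prev_end, prev_orient = None, None
            for (s, e), orient in ivs:
                if prev_end is None:
                    expected += s > params.min_gap
                else:
                    gap = s - prev_end
                    expected += (gap > params.min_gap) or (orient != prev_orient)
                prev_end, prev_orient = e, orient
            expected += (L - prev_end) > params.min_gap
            assert sum(bp.locus == locus for bp in bps) == expected


def naive_motif_scan(seq, motif, both=True):
    hits = []
    targets = [(motif, "+")]
    rc = revcomp(motif)
    if both and rc != motif:
        targets.append((rc, "-"))
    for pat, strand in targets:
        for i in range(len(seq) - len(pat) + 1):
            if seq[i : i + len(pat)] == pat:
                hits.append((i, strand))
    return sorted(hits)


class TestMotifScan:
    def test_motif_equal_to_sequence_start(self):
        (site,) = motif_scan("TTACACTG", "TTACACT", search_both_strands=False)
        assert site.start == 0
        assert site.position == 1  # 1-based in reports
        assert site.strand == "+"

    def test_planted_copies_both_strands(self, rng):
        body = random_dna(rng, 2000, 50)
        m = "TTACACT"
        seq = body[:300] + m + body[300:900] + m + body[900:1500] + revcomp(m) + body[1500:]
        sites = motif_scan(seq, m)
        planted = naive_motif_scan(seq, m)
        assert [(s.start, s.strand) for s in sites] == planted
        assert sum(s.strand == "-" for s in sites) >= 1

    def test_motif_free_sequence_empty(self):
        assert motif_scan("AAAAAAAA", "TTACACT") == []

    def test_invalid_motif_rejected(self):
        with pytest.raises(ValueError):
            motif_scan("ACGTACGT", "TTN")
        with pytest.raises(ValueError):
            motif_scan("ACG", "ACGT")

    @given(st.text(alphabet="ACGT", min_size=8, max_size=200), st.text(alphabet="ACGT", min_size=2, max_size=7))
    def test_equals_naive_sliding_search(self, seq, motif):
        got = [(s.start, s.strand) for s in motif_scan(seq, motif)]
        assert got == naive_motif_scan(seq, motif)

    def test_overlapping_occurrences_all_reported(self):
        sites = motif_scan("ATATATATA", "ATA", search_both_strands=False)
        assert [s.start for s in sites] == [0, 2, 4, 6]


class TestMotifBreakpointProximity:
    def test_site_at_joint_is_proximal(self, inversion_pair):
        a, b, third = inversion_pair
        blocks = homology_blocks(a, b)
        bps = find_breakpoints(blocks, (len(a), len(b)))
        from aspmat.locus_compare import MotifSite

        joint_site = MotifSite("A", third - 3, "+", "TTACACT")
        far_site = MotifSite("A", 2000, "+", "TTACACT")
        annotated = annotate_motif_breakpoint_proximity([joint_site, far_site], bps)
        assert annotated[0].proximal is True
        assert annotated[0].distance_to_nearest_breakpoint <= 30
        assert annotated[1].proximal is False

    def test_no_breakpoints_leaves_distance_absent(self):
        from aspmat.locus_compare import MotifSite

        (site,) = annotate_motif_breakpoint_proximity(
            [MotifSite("A", 10, "+", "TTACACT")], []
        )
        assert site.distance_to_nearest_breakpoint is None
        assert site.proximal is None
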