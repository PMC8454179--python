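"""Pairwise locus comparison: homology blocks, inversions, breakpoints, motifs.

Two locus sequences are decomposed into collinear homology blocks by
seeding exact k-mer matches on both strands, merging co-diagonal seeds
into anchors, and chaining order-consistent anchors of one orientation
into blocks (gap tolerance ``chain_gap``).  Transitions between blocks of
different orientation, and unaligned gaps longer than ``min_gap``, define
breakpoints.  A motif scanner locates exact occurrences of a short motif
(default TTACACT, the 7-bp repeat found at the homology breaks of the
A. niger MAT1-1 locus) and annotates their distance to the nearest
breakpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .marker_align import MarkerHit, _encode, _kmer_hashes, revcomp


@dataclass
class CompareParams:
    anchor_min_len: int = 20  # seed k-mer length
    min_block_score: int = 100  # summed match score (2 per matched bp)
    chain_gap: int = 2_000
    min_gap: int = 200  # unaligned gap below this emits no breakpoint


@dataclass
class HomologyBlock:
    """A chained run of same-orientation anchors between locus A and B.

    Intervals are 0-based half-open on each locus, always in forward
    coordinates.  For an inverted block the start of ``interval_a`` pairs
    with the end of ``interval_b``.
    """

    interval_a: tuple[int, int]
    interval_b: tuple[int, int]
    orientation: str  # forward | inverted
    score: int


@dataclass(frozen=True)
class Breakpoint:
    locus: str  # "A" | "B"
    position: int
    kind: str  # orientation-change | gap
    left_block: int | None  # block index or None for locus end
    right_block: int | None


@dataclass
class MotifSite:
    locus: str
    start: int  # 0-based
    strand: str
    motif: str
    distance_to_nearest_breakpoint: int | None = None
    proximal: bool | None = None

    @property
    def position(self) -> int:
        """1-based start coordinate, as printed in reports."""
        return self.start + 1


@dataclass(frozen=True)
class _Anchor:
    a_start: int
    a_end: int
    b_start: int  # in chain space: forward coords for "+", revcomp coords for "-"
    b_end: int
    orientation: str


def _seed_anchors(a: str, b: str, k: int) -> list[_Anchor]:
    """Exact k-mer matches merged along diagonals, both orientations."""
    ca = _encode(a, "nt")
    ha = _kmer_hashes(ca, k, 5)
    index: dict[int, list[int]] = {}
    for i, h in enumerate(ha.tolist()):
        index.setdefault(h, []).append(i)
    anchors: list[_Anchor] = []
    for orientation, bseq in (("forward", b), ("inverted", revcomp(b))):
        hb = _kmer_hashes(_encode(bseq, "nt"), k, 5)
        # diagonal -> [a_start, a_end, b_start, b_end] of the open run
        open_runs: dict[int, list[int]] = {}
        for j, h in enumerate(hb.tolist()):
            for i in index.get(h, ()):
                d = j - i
                run = open_runs.get(d)
                if run is not None and i <= run[1]:
                    run[1] = i + k
                    run[3] = j + k
                else:
                    if run is not None:
                        anchors.append(_Anchor(run[0], run[1], run[2], run[3], orientation))
                    open_runs[d] = [i, i + k, j, j + k]
        for run in open_runs.values():
            anchors.append(_Anchor(run[0], run[1], run[2], run[3], orientation))
    return anchors


def _chain(anchors: list[_Anchor], chain_gap: int, k: int) -> list[list[_Anchor]]:
    """Greedy collinear chaining; order conflicts start new chains."""
    chains: list[list[_Anchor]] = []
    for anc in sorted(anchors, key=lambda x: (x.a_start, x.b_start)):
        placed = False
        for chain in chains:
            last = chain[-1]
            if last.orientation != anc.orientation:
                continue
            ga = anc.a_start - last.a_end
            gb = anc.b_start - last.b_end
            if -k < ga <= chain_gap and -k < gb <= chain_gap and abs(ga - gb) <= chain_gap:
                chain.append(anc)
                placed = True
                break
        if not placed:
            chains.append([anc])
    return chains


def _matched_len(chain: list[_Anchor]) -> int:
    total, cur = 0, -1
    for anc in sorted(chain, key=lambda x: x.a_start):
        s = max(anc.a_start, cur)
        if anc.a_end > s:
            total += anc.a_end - s
            cur = anc.a_end
    return total


def homology_blocks(
    locus_a: str,
    locus_b: str,
    params: CompareParams | None = None,
) -> list[HomologyBlock]:
    """Chained same-orientation homology blocks between two loci.

    Blocks are score-filtered and made non-overlapping on each locus
    (lower-scoring blocks are trimmed at the ends, dropped if consumed).
    Returned sorted by position on locus A.
    """
    if not locus_a or not locus_b:
        raise ValueError("homology_blocks requires non-empty sequences")
    p = params or CompareParams()
    k = p.anchor_min_len
    if len(locus_a) < k or len(locus_b) < k:
        return []
    Lb = len(locus_b)
    chains = _chain(_seed_anchors(locus_a, locus_b, k), p.chain_gap, k)
    blocks: list[HomologyBlock] = []
    for chain in chains:
        score = 2 * _matched_len(chain)
        if score < p.min_block_score:
            continue
        a0 = min(c.a_start for c in chain)
        a1 = max(c.a_end for c in chain)
        b0 = min(c.b_start for c in chain)
        b1 = max(c.b_end for c in chain)
        orientation = chain[0].orientation
        if orientation == "inverted":
            b0, b1 = Lb - b1, Lb - b0  # map revcomp coords back to forward
        blocks.append(HomologyBlock((a0, a1), (b0, b1), orientation, score))

    # enforce non-overlap on each locus, keeping higher-scoring blocks intact
    blocks.sort(key=lambda bl: -bl.score)
    kept: list[HomologyBlock] = []
    for bl in blocks:
        ia, ib = bl.interval_a, bl.interval_b
        ok = True
        for other in kept:
            for which, iv, oiv in (("a", ia, other.interval_a), ("b", ib, other.interval_b)):
                s, e = iv
                os_, oe = oiv
                if e <= os_ or s >= oe:
                    continue
                # trim the overlapping end of the lower-scoring block
                if s < os_:
                    e = os_
                elif e > oe:
                    s = oe
                else:
                    s = e  # fully contained: drop
                if which == "a":
                    ia = (s, e)
                else:
                    ib = (s, e)
            if ia[1] - ia[0] <= 0 or ib[1] - ib[0] <= 0:
                ok = False
                break
        if ok:
            kept.append(replace(bl, interval_a=ia, interval_b=ib))
    kept.sort(key=lambda bl: bl.interval_a[0])
    return kept


def detect_inverted_mat_block(
    blocks: Sequence[HomologyBlock],
    mat_hit_a: MarkerHit | tuple[int, int],
    mat_hit_b: MarkerHit | tuple[int, int],
) -> str:
    """Orientation of the block containing the MAT gene on both loci.

    Returns ``co-oriented``, ``inverted`` or ``not-covered`` (the MAT
    position falls in an unaligned gap on either locus).
    """

    def mid(h) -> float:
        if isinstance(h, MarkerHit):
            return h.midpoint
        return (h[0] + h[1]) / 2

    ma, mb = mid(mat_hit_a), mid(mat_hit_b)
    for bl in blocks:
        if bl.interval_a[0] <= ma < bl.interval_a[1] and bl.interval_b[0] <= mb < bl.interval_b[1]:
            return "co-oriented" if bl.orientation == "forward" else "inverted"
    return "not-covered"


def find_breakpoints(
    blocks: Sequence[HomologyBlock],
    locus_lengths: tuple[int, int],
    params: CompareParams | None = None,
) -> list[Breakpoint]:
    """Breakpoints per locus at orientation changes and unaligned gaps.

    Adjacent blocks separated by <= ``min_gap`` are breakpoints only when
    their orientations differ (position: junction midpoint); wider gaps
    are gap breakpoints at the gap midpoint, including terminal gaps
    against the locus ends.
    """
    p = params or CompareParams()
    out: list[Breakpoint] = []
    if not blocks:
        return out
    for locus, L, key in (("A", locus_lengths[0], "interval_a"), ("B", locus_lengths[1], "interval_b")):
        order = sorted(range(len(blocks)), key=lambda i: getattr(blocks[i], key)[0])
        first = getattr(blocks[order[0]], key)
        last = getattr(blocks[order[-1]], key)
        if first[0] > p.min_gap:
            out.append(Breakpoint(locus, first[0] // 2, "gap", None, order[0]))
        for i1, i2 in zip(order, order[1:]):
            e1 = getattr(blocks[i1], key)[1]
            s2 = getattr(blocks[i2], key)[0]
            gap = s2 - e1
            if gap > p.min_gap:
                out.append(Breakpoint(locus, e1 + gap // 2, "gap", i1, i2))
            elif blocks[i1].orientation != blocks[i2].orientation:
                out.append(
                    Breakpoint(locus, (e1 + max(s2, e1)) // 2, "orientation-change", i1, i2)
                )
        if L - last[1] > p.min_gap:
            out.append(Breakpoint(locus, last[1] + (L - last[1]) // 2, "gap", order[-1], None))
    return out


def motif_scan(
    seq: str,
    motif: str = "TTACACT",
    search_both_strands: bool = True,
    locus: str = "A",
) -> list[MotifSite]:
    """All exact (and optionally reverse-complement) motif occurrences.

    Overlapping occurrences are all reported; sites are sorted by
    position.  The motif must be plain A/C/G/T.
    """
    motif = motif.upper()
    if not motif or set(motif) - set("ACGT"):
        raise ValueError(f"motif must be non-empty A/C/G/T, got {motif!r}")
    if len(motif) >= len(seq):
        raise ValueError("motif must be shorter than the sequence")
    seq = seq.upper()
    sites: list[MotifSite] = []
    targets = [(motif, "+")]
    rc = revcomp(motif)
    if search_both_strands and rc != motif:
        targets.append((rc, "-"))
    for pattern, strand in targets:
        start = seq.find(pattern)
        while start != -1:
            sites.append(MotifSite(locus=locus, start=start, strand=strand, motif=motif))
            start = seq.find(pattern, start + 1)
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def annotate_motif_breakpoint_proximity(
    sites: Sequence[MotifSite],
    breakpoints: Sequence[Breakpoint],
    max_distance: int = 1000,
) -> list[MotifSite]:
    """Annotate each site with its distance to the nearest same-locus breakpoint.

    Sites on loci with no breakpoints keep distance ``None``.
    """
    out = []
    for s in sites:
        positions = [bp.position for bp in breakpoints if bp.locus == s.locus]
        if not positions:
            out.append(replace(s, distance_to_nearest_breakpoint=None, proximal=None))
            continue
        mid = s.start + len(s.motif) / 2
        d = int(min(abs(mid - p) for p in positions))
        out.append(replace(s, distance_to_nearest_breakpoint=d, proximal=d <= max_distance))
    return out
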