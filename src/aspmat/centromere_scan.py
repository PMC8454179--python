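"""Centromere-candidate calling: long AT-rich intervals devoid of annotated ORFs.

The scan works in three resolutions: coarse non-overlapping windows (1 kb)
flag low-GC runs quickly; run boundaries are then refined at 25-bp
resolution to the GC transition; finally annotated ORFs are applied as an
exclusion filter — a candidate may tolerate a bounded number of short ORFs
(the centromeric mobile-element case) but is split at any longer gene.

The reported candidate interval is the refined low-GC run; the gap between
the nearest flanking annotated ORFs is recorded alongside it in
``flanking_orf_bounds`` rather than replacing the GC-derived boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .gc_landscape import GCIsland, find_gc_islands, gc_content, windowed_gc
from .genome_io import GeneFeature, GenomeSequence

log = logging.getLogger(__name__)


@dataclass
class CentromereParams:
    """Tunable scan parameters.

    gc_threshold sits between typical centromeric GC (17–19%) and the
    genomic background (~50%); min_len reflects the "at least 80 kb"
    scale of the ORF deserts being sought.
    """

    gc_threshold: float = 30.0
    min_len: int = 80_000
    merge_gap: int = 2_000
    max_small_orfs: int = 1
    small_orf_max_len: int = 300
    coarse_window: int = 1_000
    fine_window: int = 25


@dataclass
class CentromereCandidate:
    contig_id: str
    start: int
    end: int
    mean_gc: float
    min_gc: float
    max_gc: float
    contained_orfs: list[GeneFeature] = field(default_factory=list)
    islands: list[GCIsland] = field(default_factory=list)
    flanking_orf_bounds: tuple[int | None, int | None] = (None, None)
    gc_only: bool = False  # no annotation supplied; ORF filter skipped

    @property
    def length(self) -> int:
        return self.end - self.start


def _low_gc_runs(seq: str, params: CentromereParams) -> list[tuple[int, int]]:
    """Coarse flagged runs merged over gaps <= merge_gap, in bp."""
    L = len(seq)
    if L < params.coarse_window:
        return []
    prof = windowed_gc(seq, window=params.coarse_window)
    vals = np.nan_to_num(prof.values, nan=params.gc_threshold)  # all-N: not low on its own
    low = vals < params.gc_threshold
    runs: list[list[int]] = []
    for i in np.flatnonzero(low):
        ws = int(prof.starts[i])
        we = ws + params.coarse_window
        if runs and ws - runs[-1][1] <= params.merge_gap:
            runs[-1][1] = we
        else:
            runs.append([ws, we])
    return [(s, e) for s, e in runs]


def _refine_boundary(seq: str, pos: int, direction: int, params: CentromereParams) -> int:
    """Walk a run edge outward/inward in fine windows until the GC transition.

    ``direction`` -1 refines a left edge, +1 a right edge.  Returns the
    refined boundary coordinate.
    """
    w = params.fine_window
    look = 4 * w  # smoothing span: single fine windows are too noisy at ~50% GC
    L = len(seq)
    thr = params.gc_threshold

    def win_gc(a: int, span: int) -> float:
        a = max(0, min(a, L - span))
        v = gc_content(seq[a : a + span])
        return thr if np.isnan(v) else v

    b = pos
    if direction < 0:
        # extend left while the span just outside is still low
        while b - w >= 0 and win_gc(b - look, look) < thr:
            b -= w
        # shrink right while the span just inside is not low
        while b + w <= L and win_gc(b, look) >= thr:
            b += w
    else:
        while b + w <= L and win_gc(b, look) < thr:
            b += w
        while b - w >= 0 and win_gc(b - look, look) >= thr:
            b -= w
    return max(0, min(b, L))


def _apply_orf_filter(
    run: tuple[int, int],
    tree: IntervalTree,
    params: CentromereParams,
) -> list[tuple[int, int, list[GeneFeature]]]:
    """Split a low-GC run at disallowed ORFs; returns (start, end, tolerated) pieces."""
    s, e = run
    overlapping = sorted(tree.overlap(s, e), key=lambda iv: iv.begin)
    big = [iv for iv in overlapping if iv.data.length > params.small_orf_max_len]
    small = [iv.data for iv in overlapping if iv.data.length <= params.small_orf_max_len]

    pieces: list[tuple[int, int]] = []
    cur = s
    for iv in big:
        if iv.begin > cur:
            pieces.append((cur, min(iv.begin, e)))
        cur = max(cur, iv.end)
    if cur < e:
        pieces.append((cur, e))

    out: list[tuple[int, int, list[GeneFeature]]] = []
    for ps, pe in pieces:
        inside = sorted(
            (f for f in small if f.start < pe and f.end > ps), key=lambda f: f.start
        )
        if len(inside) <= params.max_small_orfs:
            out.append((ps, pe, inside))
            continue
        # gene-dense despite short ORFs: split at every small ORF too
        cur = ps
        for f in inside:
            if f.start > cur:
                out.append((cur, min(f.start, pe), []))
            cur = max(cur, f.end)
        if cur < pe:
            out.append((cur, pe, []))
    return out


def scan_centromeres(
    genome: Sequence[GenomeSequence],
    annotation: Sequence[GeneFeature] | None,
    params: CentromereParams | None = None,
) -> list[CentromereCandidate]:
    """Call putative centromeres on each contig.

    With ``annotation=None`` the ORF filter is skipped and candidates are
    labelled ``gc_only``.  Raises if the annotation references a contig
    absent from the genome or if ``min_len`` is below the scan window.
    """
    params = params or CentromereParams()
    if params.min_len < params.coarse_window:
        raise ValueError("min_len must be >= the coarse scan window")
    contig_ids = {g.id for g in genome}
    trees: dict[str, IntervalTree] = {cid: IntervalTree() for cid in contig_ids}
    if annotation is not None:
        for f in annotation:
            if f.contig_id not in contig_ids:
                raise ValueError(f"annotation references unknown contig {f.contig_id!r}")
            trees[f.contig_id].addi(f.start, f.end, f)

    candidates: list[CentromereCandidate] = []
    for contig in genome:
        runs = _low_gc_runs(contig.seq, params)
        refined = []
        for s, e in runs:
            rs = _refine_boundary(contig.seq, s, -1, params)
            re_ = _refine_boundary(contig.seq, e, +1, params)
            if re_ > rs:
                refined.append((rs, re_))
        for run in refined:
            if annotation is None:
                pieces = [(run[0], run[1], [])]
            else:
                pieces = _apply_orf_filter(run, trees[contig.id], params)
            for ps, pe, tolerated in pieces:
                if pe - ps < params.min_len:
                    continue
                sub = contig.seq[ps:pe]
                prof = windowed_gc(sub, window=params.fine_window)
                vals = prof.values[~np.isnan(prof.values)]
                mean = gc_content(sub)
                islands = find_gc_islands(contig.seq, region=(ps, pe))
                before = [iv.end for iv in trees[contig.id] if iv.end <= ps]
                after = [iv.begin for iv in trees[contig.id] if iv.begin >= pe]
                candidates.append(
                    CentromereCandidate(
                        contig_id=contig.id,
                        start=ps,
                        end=pe,
                        mean_gc=float(mean),
                        min_gc=float(vals.min()) if len(vals) else float("nan"),
                        max_gc=float(vals.max()) if len(vals) else float("nan"),
                        contained_orfs=tolerated,
                        islands=islands,
                        flanking_orf_bounds=(
                            max(before) if before else None,
                            min(after) if after else None,
                        ),
                        gc_only=annotation is None,
                    )
                )
    candidates.sort(key=lambda c: (c.contig_id, c.start))
    return candidates


def centromere_report(candidates: Sequence[CentromereCandidate]) -> tuple[list[tuple], pd.DataFrame]:
    """BED rows and a TSV-ready table, ordered by contig then start."""
    cands = sorted(candidates, key=lambda c: (c.contig_id, c.start))
    bed = [(c.contig_id, c.start, c.end, f"centromere_{i + 1}") for i, c in enumerate(cands)]
    df = pd.DataFrame(
        {
            "contig": [c.contig_id for c in cands],
            "start": [c.start for c in cands],
            "end": [c.end for c in cands],
            "length": [c.length for c in cands],
            "mean_gc": [round(c.mean_gc, 2) for c in cands],
            "min_gc": [round(c.min_gc, 2) for c in cands],
            "max_gc": [round(c.max_gc, 2) for c in cands],
            "n_contained_orfs": [len(c.contained_orfs) for c in cands],
            "n_islands": [len(c.islands) for c in cands],
            "gc_only": [c.gc_only for c in cands],
        }
    )
    return bed, df
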