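"""Mating-type locus calling: idiomorph and conserved/flipped orientation.

A heterothallic assembly carries one of two idiomorphs — MAT1-1 (alpha-box
gene MAT1-1-1) or MAT1-2 (HMG-box gene MAT1-2-1); homothallic assemblies
carry both.  The locus configuration is read off the order of the
conserved anchors around the MAT gene:

* conserved — the MAT gene lies between apnB and slaB
  (order adeA .. apnB .. MAT .. slaB);
* flipped — the MAT gene lies between adeA and apnB with slaB on the same
  side as apnB (order adeA .. MAT .. apnB .. slaB).

Assembly strand is arbitrary, so each contig is first normalized so that
adeA precedes slaB (mirroring coordinates when needed); "between" is then
evaluated on hit midpoints.  The ORF directions of apnB/coxM/apcE relative
to the flank genes corroborate the positional call but never determine it;
a contradiction sets the ``direction-inconsistent`` flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .genome_io import GenomeSequence
from .marker_align import MarkerHit, MarkerSet, Scoring, anchor_markers

log = logging.getLogger(__name__)

IDIOMORPH_MARKERS = {"MAT1-1": "MAT1-1-1_alpha", "MAT1-2": "MAT1-2-1_HMG"}
#: genes inside the invertible cassette whose direction corroborates the call
CASSETTE_GENES = ("apnB", "coxM", "apcE")


@dataclass
class MatParams:
    min_score_fraction: float = 0.5
    #: maximum span from the outermost flank anchor to slaB before the
    #: locus is considered broken
    max_span: int = 100_000


@dataclass
class MatLocusCall:
    idiomorph: str  # MAT1-1 | MAT1-2 | both | none
    orientation: str  # conserved | flipped | undetermined
    locus_interval: tuple[str, int, int] | None = None  # (contig, start, end)
    evidence: list[MarkerHit] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "idiomorph": self.idiomorph,
            "orientation": self.orientation,
            "locus_interval": list(self.locus_interval) if self.locus_interval else None,
            "flags": sorted(self.flags),
            "evidence": [
                {
                    "marker": h.marker_name,
                    "contig": h.contig_id,
                    "start": h.start,
                    "end": h.end,
                    "strand": h.strand,
                    "score": h.score,
                    "score_fraction": round(h.score_fraction, 4),
                }
                for h in self.evidence
            ],
        }


def _best_by_marker(hits: Sequence[MarkerHit]) -> dict[str, MarkerHit]:
    best: dict[str, MarkerHit] = {}
    for h in hits:
        if h.marker_name not in best or h.score > best[h.marker_name].score:
            best[h.marker_name] = h
    return best


def classify_idiomorph(hits: Sequence[MarkerHit]) -> tuple[str, list[str]]:
    """Idiomorph from the mating-type marker hits; returns (call, flags).

    Overlapping alpha-box and HMG hits on the same interval are treated as
    one chimeric signal: the higher score fraction wins and an ambiguity
    flag is raised.
    """
    best = _best_by_marker(hits)
    alpha = best.get(IDIOMORPH_MARKERS["MAT1-1"])
    hmg = best.get(IDIOMORPH_MARKERS["MAT1-2"])
    flags: list[str] = []
    if alpha and hmg:
        same_contig = alpha.contig_id == hmg.contig_id
        overlap = (
            same_contig
            and min(alpha.end, hmg.end) - max(alpha.start, hmg.start)
            > 0.5 * min(alpha.end - alpha.start, hmg.end - hmg.start)
        )
        if overlap:
            flags.append("chimeric-mat-hit")
            winner = "MAT1-1" if alpha.score_fraction >= hmg.score_fraction else "MAT1-2"
            return winner, flags
        return "both", flags
    if alpha:
        return "MAT1-1", flags
    if hmg:
        return "MAT1-2", flags
    return "none", flags


def _normalized_midpoints(anchors: dict[str, MarkerHit]) -> dict[str, float]:
    """Hit midpoints, mirrored so adeA precedes slaB (strand normalization).

    With only one flank gene present the raw coordinates are used; every
    "between" relation evaluated downstream is mirror-invariant, so the
    call does not depend on this choice.
    """
    mids = {n: h.midpoint for n, h in anchors.items()}
    if "adeA" in mids and "slaB" in mids and mids["adeA"] > mids["slaB"]:
        hi = max(mids.values())
        mids = {n: hi - m for n, m in mids.items()}
    return mids


def _relative_strand(a: MarkerHit, b: MarkerHit) -> int:
    return 1 if a.strand == b.strand else -1


def _direction_consistent(anchors: dict[str, MarkerHit], orientation: str) -> bool:
    """Check apnB/coxM/apcE direction against the positional call.

    In the conserved layout the cassette genes share the flank genes'
    relative strand; in the flipped layout the cassette has been
    reverse-complemented, so they oppose it.  Evaluated as a majority vote
    over the cassette genes that were anchored; vacuously consistent when
    no flank reference or no cassette gene is available.
    """
    ref = anchors.get("adeA") or anchors.get("slaB")
    if ref is None:
        return True
    votes = [
        _relative_strand(anchors[g], ref)
        for g in CASSETTE_GENES
        if g in anchors and anchors[g].contig_id == ref.contig_id
    ]
    if not votes:
        return True
    majority = 1 if sum(votes) >= 0 else -1
    expected = 1 if orientation == "conserved" else -1
    return majority == expected


def classify_orientation(
    hits: Sequence[MarkerHit], mat_marker: str | None = None
) -> tuple[str, list[str]]:
    """Conserved/flipped/undetermined from anchor order; returns (call, flags).

    Requires the MAT gene, apnB and at least one of slaB/adeA on one
    contig; a conserved call additionally requires slaB (its absence
    degrades conserved to undetermined, never to flipped).
    """
    best = _best_by_marker(hits)
    flags: list[str] = []
    if mat_marker is None:
        idio, _ = classify_idiomorph(hits)
        if idio in IDIOMORPH_MARKERS:
            mat_marker = IDIOMORPH_MARKERS[idio]
        elif idio == "both":
            calls = {
                classify_orientation(hits, mat_marker=m)[0]
                for m in IDIOMORPH_MARKERS.values()
            }
            if len(calls) == 1:
                return calls.pop(), flags
            return "undetermined", ["ambiguous-orientation"]
        else:
            return "undetermined", ["missing-markers"]

    mat = best.get(mat_marker)
    apnB = best.get("apnB")
    slaB = best.get("slaB")
    adeA = best.get("adeA")
    if mat is None or apnB is None or (slaB is None and adeA is None):
        return "undetermined", ["missing-markers"]
    present = {"MAT": mat, "apnB": apnB}
    if slaB:
        present["slaB"] = slaB
    if adeA:
        present["adeA"] = adeA
    contigs = {h.contig_id for h in present.values()}
    if len(contigs) > 1:
        return "undetermined", ["multi-scaffold"]

    anchors = {n: best[n] for n in ("adeA", "apnB", "slaB", "coxM", "apcE") if n in best}
    anchors[mat_marker] = mat
    mids = _normalized_midpoints({**{k: v for k, v in anchors.items()}, "MAT": mat})
    m_mat, m_apnB = mids["MAT"], mids["apnB"]
    m_slaB = mids.get("slaB")
    m_adeA = mids.get("adeA")

    orientation = None
    if m_slaB is not None and min(m_apnB, m_slaB) < m_mat < max(m_apnB, m_slaB):
        # MAT between apnB and slaB; adeA (if present) must sit beyond apnB
        if m_adeA is None or not (min(m_apnB, m_slaB) < m_adeA < max(m_apnB, m_slaB)):
            orientation = "conserved"
    if orientation is None and m_adeA is not None and min(m_adeA, m_apnB) < m_mat < max(m_adeA, m_apnB):
        # MAT between adeA and apnB; slaB (if present) must lie on apnB's side
        if m_slaB is None or abs(m_slaB - m_apnB) < abs(m_slaB - m_adeA):
            orientation = "flipped"
    if orientation is None:
        return "undetermined", ["anchor-order-unrecognized"]
    if not _direction_consistent({**anchors, mat_marker: mat}, orientation):
        flags.append("direction-inconsistent")
    return orientation, flags


def call_mat_locus(
    genome: Sequence[GenomeSequence],
    markers: MarkerSet,
    params: MatParams | None = None,
    scoring: Scoring | None = None,
) -> MatLocusCall:
    """Whole-assembly MAT call: anchor markers per contig, then classify."""
    params = params or MatParams()
    if not genome:
        raise ValueError("call_mat_locus requires a non-empty genome")
    all_hits: list[MarkerHit] = []
    for contig in genome:
        all_hits.extend(
            anchor_markers(
                contig, markers,
                min_score_fraction=params.min_score_fraction,
                scoring=scoring,
            )
        )
    best = _best_by_marker(all_hits)
    hits = list(best.values())
    idiomorph, flags = classify_idiomorph(hits)
    orientation, oflags = classify_orientation(hits)
    flags = flags + oflags
    if idiomorph == "none":
        flags.append("missing-markers")

    locus_interval = None
    if orientation != "undetermined":
        flank_names = [n for n in ("adeA", "apnB") if n in best]
        if flank_names and "slaB" in best:
            contig_id = best["slaB"].contig_id
            coords = [best[n].start for n in flank_names + ["slaB"]] + [
                best[n].end for n in flank_names + ["slaB"]
            ]
            mat_names = [m for m in IDIOMORPH_MARKERS.values() if m in best]
            coords += [best[m].start for m in mat_names] + [best[m].end for m in mat_names]
            lo, hi = min(coords), max(coords)
            if hi - lo > params.max_span:
                orientation = "undetermined"
                flags.append("locus-span-exceeded")
            else:
                locus_interval = (contig_id, lo, hi)
    return MatLocusCall(
        idiomorph=idiomorph,
        orientation=orientation,
        locus_interval=locus_interval,
        evidence=hits,
        flags=sorted(set(flags)),
    )


def classify_panel(
    genomes: dict[str, Sequence[GenomeSequence]],
    markers: MarkerSet,
    params: MatParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-strain MAT calls plus (idiomorph, orientation) summary counts.

    Multi-scaffold strains are flagged in their row and excluded from the
    orientation summary cells (counted under orientation "undetermined").
    """
    rows = []
    for name, genome in genomes.items():
        call = call_mat_locus(genome, markers, params=params)
        rows.append(
            {
                "strain": name,
                "idiomorph": call.idiomorph,
                "orientation": call.orientation,
                "flags": ";".join(call.flags),
            }
        )
    table = pd.DataFrame(rows)
    summary = (
        table.groupby(["idiomorph", "orientation"]).size().reset_index(name="n_strains")
    )
    return table, summary
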