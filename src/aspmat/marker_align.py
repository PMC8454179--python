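"""Local alignment engine and marker-gene placement.

Implements exact Smith–Waterman local alignment with affine gap penalties
(a gap of length L costs ``gap_open + L * gap_extend``) as the reference
homology engine, plus a seed-and-extend wrapper that places named marker
genes (slaB, apnB, adeA, apcE, coxM and the mating-type genes) on contigs:
exact k-mer seeds locate candidate windows, and the exact DP is run inside
each window.  Protein markers are searched against six-frame translations
and mapped back to nucleotide coordinates.

Traceback is deterministic with tie order diagonal > up > left; among
equal-scoring end cells the first in row-major order is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from numba import njit

from .genome_io import GenomeSequence

NT_ALPHABET = "ACGTN"
AA_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_NEG = -(2 ** 28)

_NT_INDEX = np.full(128, -1, dtype=np.int8)
for _i, _c in enumerate(NT_ALPHABET):
    _NT_INDEX[ord(_c)] = _i
_AA_INDEX = np.full(128, -1, dtype=np.int8)
for _i, _c in enumerate(AA_ALPHABET):
    _AA_INDEX[ord(_c)] = _i

_RC = str.maketrans("ACGTNRYSWKMBDHVacgtn", "TGCANYRSWMKVHDBtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class Scoring:
    """Alignment scoring: blast-like nucleotide defaults, BLOSUM62 for protein."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    protein_matrix: str = "BLOSUM62"
    protein_gap_open: int = 11
    protein_gap_extend: int = 1


DEFAULT_SCORING = Scoring()


@lru_cache(maxsize=4)
def _nt_submat(match: int, mismatch: int) -> np.ndarray:
    m = np.full((5, 5), mismatch, dtype=np.int32)
    np.fill_diagonal(m, match)
    m[4, :] = mismatch  # N never matches, including N vs N
    m[:, 4] = mismatch
    return m


@lru_cache(maxsize=2)
def _aa_submat(name: str) -> np.ndarray:
    bl = substitution_matrices.load(name)
    k = len(AA_ALPHABET)
    m = np.full((k, k), -4, dtype=np.int32)
    for i, a in enumerate(AA_ALPHABET):
        for j, b in enumerate(AA_ALPHABET):
            if a in bl.alphabet and b in bl.alphabet:
                m[i, j] = int(bl[a, b])
    return m


def _infer_alphabet(seq: str) -> str:
    return "nt" if set(seq.upper()) <= set(NT_ALPHABET) else "aa"


def _encode(seq: str, alphabet: str) -> np.ndarray:
    idx = _NT_INDEX if alphabet == "nt" else _AA_INDEX
    codes = idx[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        bad = sorted(set(seq.upper()) - set(NT_ALPHABET if alphabet == "nt" else AA_ALPHABET))
        raise ValueError(f"residues {bad} invalid for {alphabet} alphabet")
    return codes.astype(np.int8)


@njit(cache=True)
def _sw_fill(a, b, sub, gap_open, gap_extend):  # pragma: no cover - numba kernel
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), _NEG, dtype=np.int32)
    F = np.full((n + 1, m + 1), _NEG, dtype=np.int32)
    go_ge = gap_open + gap_extend
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            e = E[i, j - 1] - gap_extend
            t = H[i, j - 1] - go_ge
            if t > e:
                e = t
            E[i, j] = e
            f = F[i - 1, j] - gap_extend
            t = H[i - 1, j] - go_ge
            if t > f:
                f = t
            F[i, j] = f
            h = H[i - 1, j - 1] + sub[ai, b[j - 1]]
            if f > h:
                h = f
            if e > h:
                h = e
            if h < 0:
                h = 0
            H[i, j] = h
    return H, E, F


@dataclass
class LocalAlignment:
    """An optimal local alignment of a (query) against b (subject).

    Intervals are 0-based half-open on each input; ``pairs`` lists the
    aligned (query, subject) residue index pairs along the traceback.
    An empty alignment (score 0) has empty intervals.
    """

    score: int
    a_interval: tuple[int, int]
    b_interval: tuple[int, int]
    strand: str
    identity: float
    pairs: list[tuple[int, int]]


def smith_waterman(
    a: str,
    b: str,
    scoring: Scoring | None = None,
    alphabet: str = "auto",
) -> LocalAlignment:
    """Optimal Smith–Waterman local alignment under affine-gap scoring.

    ``alphabet`` is "nt", "aa" or "auto" (inferred per sequence; a
    nucleotide/protein mixture raises).
    """
    if not a or not b:
        raise ValueError("smith_waterman requires non-empty sequences")
    scoring = scoring or DEFAULT_SCORING
    if alphabet == "auto":
        aa_, ab_ = _infer_alphabet(a), _infer_alphabet(b)
        if aa_ != ab_:
            raise ValueError(f"alphabet mismatch: {aa_} query vs {ab_} subject")
        alphabet = aa_
    if alphabet == "nt":
        sub = _nt_submat(scoring.match, scoring.mismatch)
        go, ge = scoring.gap_open, scoring.gap_extend
    elif alphabet == "aa":
        sub = _aa_submat(scoring.protein_matrix)
        go, ge = scoring.protein_gap_open, scoring.protein_gap_extend
    else:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    ca, cb = _encode(a, alphabet), _encode(b, alphabet)
    H, E, F = _sw_fill(ca, cb, sub, np.int32(go), np.int32(ge))
    score = int(H.max())
    if score == 0:
        return LocalAlignment(0, (0, 0), (0, 0), "+", 0.0, [])
    i, j = np.unravel_index(int(H.argmax()), H.shape)
    i, j = int(i), int(j)
    end_i, end_j = i, j
    pairs: list[tuple[int, int]] = []
    matches = columns = 0
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            h = H[i, j]
            if h == 0:
                break
            if h == H[i - 1, j - 1] + sub[ca[i - 1], cb[j - 1]]:
                pairs.append((i - 1, j - 1))
                matches += int(ca[i - 1] == cb[j - 1])
                columns += 1
                i -= 1
                j -= 1
            elif h == F[i, j]:
                state = "F"
            elif h == E[i, j]:
                state = "E"
            else:  # pragma: no cover - DP consistency
                raise AssertionError("inconsistent traceback")
        elif state == "F":
            closed = F[i, j] == H[i - 1, j] - (go + ge)
            columns += 1
            i -= 1
            if closed:
                state = "H"
        else:  # E
            closed = E[i, j] == H[i, j - 1] - (go + ge)
            columns += 1
            j -= 1
            if closed:
                state = "H"
    pairs.reverse()
    identity = 100.0 * matches / columns if columns else 0.0
    return LocalAlignment(
        score=score,
        a_interval=(i, end_i),
        b_interval=(j, end_j),
        strand="+",
        identity=identity,
        pairs=pairs,
    )


def six_frame_translate(seq: str) -> list[tuple[str, int, str]]:
    """Translate all six reading frames with the standard genetic code.

    Returns ``(frame_label, offset, peptide)`` triples; frames +1..+3 read
    the sequence at offsets 0..2, frames -1..-3 read the reverse
    complement at offsets 0..2.  Stop codons appear as ``*``.
    """
    if not seq:
        raise ValueError("six_frame_translate requires a non-empty sequence")
    frames = []
    rc = revcomp(seq)
    for off in range(3):
        for label, s in ((f"+{off + 1}", seq), (f"-{off + 1}", rc)):
            sub = s[off:]
            sub = sub[: len(sub) - len(sub) % 3]
            pep = str(Seq(sub).translate()) if sub else ""
            frames.append((label, off, pep))
    order = {"+1": 0, "+2": 1, "+3": 2, "-1": 3, "-2": 4, "-3": 5}
    frames.sort(key=lambda t: order[t[0]])
    return frames


# ---------------------------------------------------------------------------
# marker panels and anchoring


@dataclass(frozen=True)
class Marker:
    name: str
    seq: str
    alphabet: str  # "nt" | "aa"

    def __post_init__(self):
        if not self.seq:
            raise ValueError(f"marker {self.name}: empty sequence")
        if self.alphabet not in {"nt", "aa"}:
            raise ValueError(f"marker {self.name}: alphabet must be nt or aa")
        _encode(self.seq, self.alphabet)  # residue check

    def self_score(self, scoring: Scoring = DEFAULT_SCORING) -> int:
        if self.alphabet == "nt":
            return scoring.match * len(self.seq)
        sub = _aa_submat(scoring.protein_matrix)
        codes = _encode(self.seq, "aa")
        return int(sub[codes, codes].sum())


REQUIRED_MARKERS = ("slaB", "apnB", "adeA", "apcE", "coxM", "MAT1-1-1_alpha", "MAT1-2-1_HMG")
OPTIONAL_MARKERS = ("MAT1-2-4",)


@dataclass
class MarkerSet:
    """Named marker panel (gene/protein queries for locus anchoring)."""

    entries: dict[str, Marker]

    def __post_init__(self):
        for name, m in self.entries.items():
            if name != m.name:
                raise ValueError(f"marker key {name!r} != marker name {m.name!r}")

    def missing_required(self) -> list[str]:
        return [n for n in REQUIRED_MARKERS if n not in self.entries]

    def __getitem__(self, name: str) -> Marker:
        return self.entries[name]

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __iter__(self):
        return iter(self.entries.values())

    @classmethod
    def from_fasta(cls, path) -> "MarkerSet":
        """Read a panel from FASTA with ``>name|nt`` / ``>name|aa`` headers."""
        from Bio import SeqIO

        entries = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if "|" in rec.id:
                name, alph = rec.id.rsplit("|", 1)
            else:
                name, alph = rec.id, "nt"
            if name in entries:
                raise ValueError(f"duplicate marker name {name!r}")
            entries[name] = Marker(name, str(rec.seq).upper(), alph)
        if not entries:
            raise ValueError(f"no markers found in {path}")
        return cls(entries)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for m in self.entries.values():
                fh.write(f">{m.name}|{m.alphabet}\n{m.seq}\n")


@dataclass(frozen=True)
class MarkerHit:
    """Placement of a named marker on a contig (0-based half-open interval)."""

    marker_name: str
    contig_id: str
    start: int
    end: int
    strand: str
    score: int
    score_fraction: float

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


def _kmer_hashes(codes: np.ndarray, k: int, base: int) -> np.ndarray:
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    h = np.zeros(n, dtype=np.uint64)
    for t in range(k):
        h = h * np.uint64(base) + codes[t : t + n].astype(np.uint64)
    return h


def _seed_windows(
    marker_codes: np.ndarray,
    subject_codes: np.ndarray,
    k: int,
    base: int,
    pad: int,
) -> list[tuple[int, int]]:
    """Merged candidate windows on the subject around exact k-mer seed matches."""
    mh = np.unique(_kmer_hashes(marker_codes, k, base))
    if len(mh) == 0:
        return []
    sh = _kmer_hashes(subject_codes, k, base)
    hits = np.flatnonzero(np.isin(sh, mh))
    if len(hits) == 0:
        return []
    L = len(subject_codes)
    windows: list[list[int]] = []
    for p in hits:
        ws, we = max(0, int(p) - pad), min(L, int(p) + k + pad)
        if windows and ws <= windows[-1][1]:
            windows[-1][1] = max(windows[-1][1], we)
        else:
            windows.append([ws, we])
    return [(s, e) for s, e in windows]


def _best_window_alignment(
    marker_seq: str,
    subject: str,
    windows: list[tuple[int, int]],
    scoring: Scoring,
    alphabet: str,
) -> list[tuple[int, LocalAlignment, tuple[int, int]]]:
    """Run exact DP in each window; return (score, alignment, window) records."""
    out = []
    for ws, we in windows:
        aln = smith_waterman(marker_seq, subject[ws:we], scoring=scoring, alphabet=alphabet)
        if aln.score > 0:
            out.append((aln.score, aln, (ws, we)))
    return out


def anchor_markers(
    contig: GenomeSequence,
    markers: MarkerSet,
    min_score_fraction: float = 0.5,
    scoring: Scoring | None = None,
    seed_k: int = 16,
    aa_seed_k: int = 5,
    report_all: bool = False,
) -> list[MarkerHit]:
    """Place each marker on the contig, both strands, best hit per marker.

    Nucleotide markers are seeded with exact ``seed_k``-mers on the contig
    and its reverse complement, then aligned exactly within each candidate
    window.  Protein markers are seeded on the six-frame translations and
    their hits mapped back to nucleotide coordinates.  Hits scoring below
    ``min_score_fraction`` of the marker self-score are discarded.  A
    contig too short to seed returns an empty list, not an error.
    """
    scoring = scoring or DEFAULT_SCORING
    seq = contig.seq
    hits: list[MarkerHit] = []
    rc = revcomp(seq)
    nt_codes = {"+": None, "-": None}
    frames = None

    for marker in markers:
        self_score = marker.self_score(scoring)
        candidates: list[MarkerHit] = []
        if marker.alphabet == "nt":
            if len(seq) < seed_k or len(marker.seq) < seed_k:
                continue
            mcodes = _encode(marker.seq, "nt")
            pad = len(marker.seq) + 50
            for strand, subject in (("+", seq), ("-", rc)):
                if nt_codes[strand] is None:
                    nt_codes[strand] = _encode(subject, "nt")
                windows = _seed_windows(mcodes, nt_codes[strand], seed_k, 5, pad)
                for score, aln, (ws, _) in _best_window_alignment(
                    marker.seq, subject, windows, scoring, "nt"
                ):
                    s, e = ws + aln.b_interval[0], ws + aln.b_interval[1]
                    if strand == "-":
                        s, e = len(seq) - e, len(seq) - s
                    candidates.append(
                        MarkerHit(marker.name, contig.id, s, e, strand, score, score / self_score)
                    )
        else:
            if frames is None:
                frames = six_frame_translate(seq) if len(seq) >= 3 else []
            mcodes = _encode(marker.seq, "aa")
            pad = len(marker.seq) + 20
            for label, off, pep in frames:
                if len(pep) < aa_seed_k or len(marker.seq) < aa_seed_k:
                    continue
                pcodes = _encode(pep, "aa")
                windows = _seed_windows(mcodes, pcodes, aa_seed_k, len(AA_ALPHABET), pad)
                for score, aln, (ws, _) in _best_window_alignment(
                    marker.seq, pep, windows, scoring, "aa"
                ):
                    aas, aae = ws + aln.b_interval[0], ws + aln.b_interval[1]
                    nt_s, nt_e = off + 3 * aas, off + 3 * aae
                    if label.startswith("-"):
                        nt_s, nt_e = len(seq) - nt_e, len(seq) - nt_s
                    strand = "+" if label.startswith("+") else "-"
                    candidates.append(
                        MarkerHit(marker.name, contig.id, nt_s, nt_e, strand, score, score / self_score)
                    )
        candidates = [c for c in candidates if c.score_fraction >= min_score_fraction]
        candidates.sort(key=lambda h: (-h.score, h.start))
        if report_all:
            hits.extend(candidates)
        elif candidates:
            hits.append(candidates[0])
    return hits
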