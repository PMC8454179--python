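"""Seeded simulation of toy fungal genomes with planted ground truth.

The generator emulates the genomic structure the analysis modules assume:
chromosome backbones near 49.6% GC; one planted centromere-like interval
per chromosome (88–100 kb drawn uniformly, GC 17.1–18.4%) free of
annotated genes, optionally carrying a short ORF inside an elevated-GC
island (the embedded mobile-element case); annotated filler genes outside
the centromeres; and MAT loci assembled from marker cassettes in either
the conserved or the flipped configuration, with TTACACT motif copies
planted at the cassette joints.

Bases are drawn i.i.d. per region at the region's target GC; no
dinucleotide structure, repeats or indels are modelled.  All randomness
flows through one :class:`numpy.random.Generator` (PCG64) seeded from the
config, so identical configs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_io import GeneFeature, GenomeSequence
from .marker_align import Marker, MarkerSet, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: default marker gene lengths (bp); single-kb scale like the real flank genes
DEFAULT_MARKER_LENGTHS = {
    "slaB": 1200,
    "apnB": 1000,
    "adeA": 1000,
    "apcE": 900,
    "coxM": 800,
    "MAT1-1-1_alpha": 1100,
    "MAT1-2-1_HMG": 1100,
    "MAT1-2-4": 700,
}
_PANEL_SEED = 20210921  # fixed: the default panel is a stable reference object


def random_dna(rng: np.random.Generator, length: int, gc: float = 50.0) -> str:
    """I.i.d. DNA of the given GC percentage (in expectation)."""
    if length <= 0:
        raise ValueError("length must be positive")
    g = gc / 200.0
    p = np.array([0.5 - g, g, g, 0.5 - g])
    draws = rng.choice(4, size=length, p=p)
    return _BASES[draws].tobytes().decode("ascii")


def default_marker_panel(gc: float = 50.0) -> MarkerSet:
    """The synthetic default marker panel (fixed internal seed, so stable).

    Purely synthetic stand-in sequences for the flank/MAT genes; real
    panels are supplied as FASTA via :meth:`MarkerSet.from_fasta`.
    """
    rng = np.random.default_rng(_PANEL_SEED)
    entries = {
        # markers are kept free of the TTACACT motif so planted motif
        # copies in simulated loci stay exactly countable
        name: Marker(name, _scrub_motif(random_dna(rng, length, gc), "TTACACT", []), "nt")
        for name, length in DEFAULT_MARKER_LENGTHS.items()
    }
    return MarkerSet(entries)


@dataclass
class CentromereSpec:
    count_per_chromosome: int = 1
    length_range: tuple[int, int] = (88_000, 100_000)
    gc_range: tuple[float, float] = (17.1, 18.4)
    #: optional planted ORF length inside the centromere (the 219-nt case)
    small_orf: int | None = None
    #: plant an elevated-GC island around the small ORF (mobile-element case).
    #: Scanning such a genome needs merge_gap > island_length for the
    #: centromere to be called in one piece.
    island: bool = False
    island_length: int = 7_000
    island_gc: float = 45.0


@dataclass
class GeneSpec:
    count: int = 60
    length_range: tuple[int, int] = (900, 3000)
    min_gap: int = 10_000  # clearance between genes and planted centromeres


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 8
    chromosome_length: int = 1_000_000
    backbone_gc: float = 49.6
    centromere: CentromereSpec = field(default_factory=CentromereSpec)
    genes: GeneSpec = field(default_factory=GeneSpec)
    mutation_rate: float = 0.0
    rng_algorithm: str = "PCG64"  # echoed for provenance; fixed

    def __post_init__(self):
        lo, hi = self.centromere.length_range
        if not (0 < lo <= hi):
            raise ValueError("centromere length_range must be ordered and positive")
        glo, ghi = self.centromere.gc_range
        if not (0 <= glo <= ghi <= 100):
            raise ValueError("centromere gc_range must be ordered percentages")
        if self.backbone_gc <= ghi:
            raise ValueError("backbone_gc must exceed the centromere gc_range maximum")


@dataclass
class SimulationTruth:
    centromeres: list[tuple[str, int, int]] = field(default_factory=list)
    genes: list[GeneFeature] = field(default_factory=list)
    islands: list[tuple[str, int, int]] = field(default_factory=list)
    marker_placements: list[tuple[str, str, int, int, str]] = field(default_factory=list)
    motif_sites: list[tuple[str, int, str]] = field(default_factory=list)
    idiomorph: str | None = None
    orientation: str | None = None


@dataclass
class SimulatedGenome:
    sequences: list[GenomeSequence]
    features: list[GeneFeature]
    truth: SimulationTruth
    config: SimulationConfig


def _place_genes(
    rng: np.random.Generator,
    chrom_len: int,
    forbidden: list[tuple[int, int]],
    spec: GeneSpec,
    contig_id: str,
    id_offset: int,
) -> list[GeneFeature]:
    """Plant non-overlapping gene annotations clear of forbidden intervals."""
    genes: list[GeneFeature] = []
    occupied = [(max(0, s - spec.min_gap), min(chrom_len, e + spec.min_gap)) for s, e in forbidden]
    attempts = 0
    while len(genes) < spec.count and attempts < spec.count * 50:
        attempts += 1
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        if chrom_len <= length:
            break
        start = int(rng.integers(0, chrom_len - length))
        end = start + length
        if any(start < oe and end > os_ for os_, oe in occupied):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneFeature(contig_id, start, end, strand, f"g{id_offset + len(genes) + 1}")
        )
        occupied.append((start, end))
    if len(genes) < spec.count:
        raise ValueError(
            f"could not place {spec.count} genes on {contig_id}: chromosome too crowded"
        )
    genes.sort(key=lambda g: g.start)
    return genes


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Simulate chromosomes with planted centromeres and gene annotations."""
    rng = np.random.default_rng(config.seed)
    cen = config.centromere
    total_cen = cen.count_per_chromosome * cen.length_range[1]
    if total_cen + 2 * config.genes.min_gap >= config.chromosome_length:
        raise ValueError("planted features exceed chromosome length")

    sequences: list[GenomeSequence] = []
    features: list[GeneFeature] = []
    truth = SimulationTruth()
    gene_counter = 0
    for c in range(config.n_chromosomes):
        cid = f"chr{c + 1}"
        L = config.chromosome_length
        seq = np.frombuffer(
            random_dna(rng, L, config.backbone_gc).encode("ascii"), dtype=np.uint8
        ).copy()
        forbidden: list[tuple[int, int]] = []
        margin = config.genes.min_gap
        for _ in range(cen.count_per_chromosome):
            clen = int(rng.integers(cen.length_range[0], cen.length_range[1] + 1))
            cgc = float(rng.uniform(cen.gc_range[0], cen.gc_range[1]))
            for _try in range(200):
                start = int(rng.integers(margin, L - clen - margin))
                if not any(
                    start - margin < fe and start + clen + margin > fs
                    for fs, fe in forbidden
                ):
                    break
            else:
                raise ValueError("could not place centromere: chromosome too crowded")
            block = random_dna(rng, clen, cgc)
            seq[start : start + clen] = np.frombuffer(block.encode("ascii"), dtype=np.uint8)
            truth.centromeres.append((cid, start, start + clen))
            forbidden.append((start, start + clen))
            if cen.island:
                isl_len = min(cen.island_length, clen)
                isl_start = start + (clen - isl_len) // 2
                island = random_dna(rng, isl_len, cen.island_gc)
                seq[isl_start : isl_start + isl_len] = np.frombuffer(
                    island.encode("ascii"), dtype=np.uint8
                )
                truth.islands.append((cid, isl_start, isl_start + isl_len))
            if cen.small_orf:
                orf_start = start + (clen - cen.small_orf) // 2
                gene_counter += 1
                orf = GeneFeature(
                    cid, orf_start, orf_start + cen.small_orf, "+", f"g{gene_counter}"
                )
                features.append(orf)
                truth.genes.append(orf)
        genes = _place_genes(rng, L, forbidden, config.genes, cid, gene_counter)
        gene_counter += len(genes)
        features.extend(genes)
        truth.genes.extend(genes)
        sequences.append(GenomeSequence(cid, seq.tobytes().decode("ascii")))
    features.sort(key=lambda f: (f.contig_id, f.start))
    return SimulatedGenome(sequences=sequences, features=features, truth=truth, config=config)


# ---------------------------------------------------------------------------
# MAT locus construction


@dataclass
class MatLocusPlan:
    idiomorph: str  # MAT1-1 | MAT1-2 | both
    orientation: str  # conserved | flipped
    spacer: int = 1_500  # bp between cassette genes
    n_filler_genes: int = 5  # anonymous genes between apcE and slaB (7 total with coxM/apcE)
    filler_length: int = 1_200
    #: motif copies: "joint_left", "joint_right" and/or integer offsets into the locus
    motif_plan: tuple = ("joint_left", "joint_right")
    motif: str = "TTACACT"


def _scrub_motif(seq: str, motif: str, protect: list[tuple[int, int]]) -> str:
    """Remove chance occurrences of motif (both strands) outside protected intervals.

    Each occurrence has its middle base cycled to the next one; repeated
    until clean.  Occurrences overlapping a protected interval are left.
    """
    targets = {motif, revcomp(motif)}
    nxt = {"A": "C", "C": "G", "G": "T", "T": "A"}
    arr = list(seq)
    k = len(motif)
    for _ in range(10):  # converges immediately in practice
        dirty = False
        s = "".join(arr)
        for pat in targets:
            start = s.find(pat)
            while start != -1:
                if not any(start < pe and start + k > ps for ps, pe in protect):
                    mid = start + k // 2
                    arr[mid] = nxt[arr[mid]]
                    dirty = True
                start = s.find(pat, start + 1)
        if not dirty:
            return "".join(arr)
    raise AssertionError("motif scrubbing did not converge")


def _mat_gene_names(idiomorph: str) -> list[str]:
    if idiomorph == "MAT1-1":
        return ["MAT1-1-1_alpha"]
    if idiomorph == "MAT1-2":
        return ["MAT1-2-1_HMG", "MAT1-2-4"]
    if idiomorph == "both":
        return ["MAT1-1-1_alpha", "MAT1-2-1_HMG"]
    raise ValueError(f"unknown idiomorph {idiomorph!r}")


def simulate_mat_locus(
    plan: MatLocusPlan,
    markers: MarkerSet | None = None,
    rng: np.random.Generator | None = None,
    gc: float = 49.6,
) -> tuple[str, SimulationTruth]:
    """Build a MAT locus sequence from marker cassettes, with planted truth.

    Conserved layout: adeA – [apnB – MAT – coxM – apcE – fillers] – slaB.
    Flipped layout: the bracketed cassette is reverse-complemented in
    place, yielding adeA – [fillers' – apcE' – coxM' – MAT' – apnB'] – slaB
    (MAT between adeA and apnB, slaB on apnB's side).  Marker truth
    coordinates and strands refer to the emitted sequence.
    """
    if plan.orientation not in {"conserved", "flipped"}:
        raise ValueError(f"orientation must be conserved or flipped, got {plan.orientation!r}")
    if plan.idiomorph == "both" and plan.orientation == "flipped":
        raise ValueError("flipped layout with both idiomorphs is not supported")
    markers = markers or default_marker_panel()
    rng = rng if rng is not None else np.random.default_rng(0)

    def spacer() -> str:
        return random_dna(rng, plan.spacer, gc)

    # cassette assembled in conserved orientation first: (name|None, seq)
    cassette: list[tuple[str | None, str]] = []
    mat_names = [n for n in _mat_gene_names(plan.idiomorph) if n in markers]
    cassette.append(("apnB", markers["apnB"].seq))
    cassette.append((None, spacer()))
    for mn in mat_names:
        cassette.append((mn, markers[mn].seq))
        cassette.append((None, spacer()))
    cassette.append(("coxM", markers["coxM"].seq))
    cassette.append((None, spacer()))
    cassette.append(("apcE", markers["apcE"].seq))
    for _ in range(plan.n_filler_genes):
        cassette.append((None, spacer()))
        cassette.append((None, random_dna(rng, plan.filler_length, gc)))

    truth = SimulationTruth(idiomorph=plan.idiomorph, orientation=plan.orientation)
    parts: list[str] = []
    placements: list[tuple[str, int, int, str]] = []  # relative to locus

    def emit(name: str | None, seq: str, strand: str = "+") -> None:
        pos = sum(len(x) for x in parts)
        parts.append(seq)
        if name is not None:
            placements.append((name, pos, pos + len(seq), strand))

    emit("adeA", markers["adeA"].seq)
    emit(None, spacer())
    joint_left = sum(len(x) for x in parts)
    if plan.orientation == "conserved":
        for name, seq in cassette:
            emit(name, seq)
    else:
        cassette_seq = "".join(seq for _, seq in cassette)
        pos0 = sum(len(x) for x in parts)
        Lc = len(cassette_seq)
        off = 0
        for name, seq in cassette:
            if name is not None:
                # interval within the reverse-complemented cassette
                placements.append((name, pos0 + Lc - (off + len(seq)), pos0 + Lc - off, "-"))
            off += len(seq)
        parts.append(revcomp(cassette_seq))
    joint_right = sum(len(x) for x in parts)
    emit(None, spacer())
    emit("slaB", markers["slaB"].seq)

    locus = "".join(parts)
    # scrub chance motif occurrences outside marker genes so the planted
    # copies are the only ones (makes motif truth exact)
    marker_ivs = [(s, e) for _, s, e, _ in placements]
    locus = _scrub_motif(locus, plan.motif, marker_ivs)
    # plant motif copies by overwriting (keeps all planted coordinates exact)
    motif_positions: list[int] = []
    for item in plan.motif_plan:
        if item == "joint_left":
            pos = joint_left - len(plan.motif)
        elif item == "joint_right":
            pos = joint_right
        else:
            pos = int(item)
        motif_positions.append(pos)
    arr = np.frombuffer(locus.encode("ascii"), dtype=np.uint8).copy()
    for pos in motif_positions:
        arr[pos : pos + len(plan.motif)] = np.frombuffer(
            plan.motif.encode("ascii"), dtype=np.uint8
        )
        truth.motif_sites.append(("locus", pos, "+"))
    locus = arr.tobytes().decode("ascii")
    for name, s, e, strand in placements:
        truth.marker_placements.append((name, "locus", s, e, strand))
    return locus, truth


@dataclass
class IsolateSpec:
    idiomorph: str
    orientation: str
    split_locus: bool = False  # emit the locus across two contigs (gap case)


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute bases i.i.d. at the given rate (no indels)."""
    if rate == 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    sites = np.flatnonzero(rng.random(len(arr)) < rate)
    if len(sites):
        # shift each hit base by 1-3 within ACGT so it always changes
        idx = np.searchsorted(_BASES, arr[sites])
        idx = np.where(idx >= 4, 0, idx)  # N and friends become A-shifted
        arr[sites] = _BASES[(idx + rng.integers(1, 4, size=len(sites))) % 4]
    return arr.tobytes().decode("ascii")


def simulate_isolate_panel(
    n: int,
    composition: Sequence[IsolateSpec | tuple],
    divergence: float = 0.02,
    seed: int = 0,
    markers: MarkerSet | None = None,
    backbone_length: int = 60_000,
    backbone_gc: float = 49.6,
) -> tuple[dict[str, list[GenomeSequence]], pd.DataFrame]:
    """Simulate a panel of isolates with known idiomorph/orientation labels.

    Each isolate carries the template locus for its (idiomorph,
    orientation) label, substituted at rate ``divergence``, embedded at a
    random position in an independent backbone contig.  ``split_locus``
    isolates are emitted as two contigs broken between the MAT gene and
    apnB (the multi-scaffold case).  Returns genomes keyed by isolate name
    and a truth table.
    """
    if len(composition) != n:
        raise ValueError(f"composition length {len(composition)} != n {n}")
    if divergence >= 0.5:
        raise ValueError("divergence >= 0.5 leaves markers unrecoverable by design")
    markers = markers or default_marker_panel()
    rng = np.random.default_rng(seed)
    specs = [s if isinstance(s, IsolateSpec) else IsolateSpec(*s) for s in composition]

    templates: dict[tuple[str, str], tuple[str, SimulationTruth]] = {}
    for spec in specs:
        key = (spec.idiomorph, spec.orientation)
        if key not in templates:
            templates[key] = simulate_mat_locus(
                MatLocusPlan(idiomorph=spec.idiomorph, orientation=spec.orientation),
                markers=markers,
                rng=rng,
                gc=backbone_gc,
            )

    genomes: dict[str, list[GenomeSequence]] = {}
    rows = []
    for i, spec in enumerate(specs):
        name = f"isolate_{i + 1:03d}"
        locus, truth = templates[(spec.idiomorph, spec.orientation)]
        backbone = random_dna(rng, backbone_length, backbone_gc)
        insert_at = int(rng.integers(backbone_length // 4, 3 * backbone_length // 4))
        contig = backbone[:insert_at] + locus + backbone[insert_at:]
        contig = mutate(contig, divergence, rng)
        if spec.split_locus:
            by_name = {p[0]: p for p in truth.marker_placements}
            mat_name = next(
                p for p in ("MAT1-1-1_alpha", "MAT1-2-1_HMG") if p in by_name
            )
            mat_iv = by_name[mat_name]
            apn_iv = by_name["apnB"]
            cut_rel = (min(mat_iv[3], apn_iv[3]) + max(mat_iv[2], apn_iv[2])) // 2
            cut = insert_at + cut_rel
            genomes[name] = [
                GenomeSequence(f"{name}_ctg1", contig[:cut]),
                GenomeSequence(f"{name}_ctg2", contig[cut:]),
            ]
        else:
            genomes[name] = [GenomeSequence(f"{name}_ctg1", contig)]
        rows.append(
            {
                "strain": name,
                "idiomorph": spec.idiomorph,
                "orientation": spec.orientation,
                "split_locus": spec.split_locus,
                "locus_start": insert_at,
                "locus_end": insert_at + len(locus),
            }
        )
    return genomes, pd.DataFrame(rows)
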