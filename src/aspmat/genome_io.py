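"""Assembly I/O and assembly-level statistics.

Coordinate conventions
----------------------
All intervals are stored 0-based half-open internally.  Human-facing
reports and GFF3 output are 1-based inclusive; BED output is 0-based
half-open.  :func:`interval_length` converts between the two dialects.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

#: IUPAC nucleotide ambiguity codes accepted on read.  Codes other than
#: A/C/G/T/N are normalized to N because downstream GC arithmetic is
#: defined only on the 5-letter alphabet.
IUPAC_NT = set("ACGTNRYSWKMBDHV")
_AMBIGUOUS = IUPAC_NT - set("ACGTN")


@dataclass
class GenomeSequence:
    """One named DNA sequence (contig, scaffold or mitochondrial record)."""

    id: str
    seq: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("GenomeSequence id must be non-empty")
        self.seq = self.seq.upper()

    @property
    def length(self) -> int:
        return len(self.seq)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.seq)


@dataclass(frozen=True)
class GeneFeature:
    """An annotated gene/CDS interval, 0-based half-open internally."""

    contig_id: str
    start: int
    end: int
    strand: str
    feature_id: str
    type: str = "gene"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"feature {self.feature_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"feature {self.feature_id}: strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def start_1based(self) -> int:
        return self.start + 1

    @property
    def end_1based(self) -> int:
        return self.end


@dataclass(frozen=True)
class AssemblyStats:
    n_records: int
    total_bp: int
    n50: int
    l50: int
    gc_percent: float


def _normalize_residues(record_id: str, seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - IUPAC_NT
    if bad:
        raise ValueError(
            f"record {record_id!r} contains non-IUPAC nucleotide residues: {sorted(bad)}"
        )
    amb = set(seq) & _AMBIGUOUS
    if amb:
        log.warning(
            "record %s: normalizing IUPAC ambiguity codes %s to N", record_id, sorted(amb)
        )
        seq = seq.translate(str.maketrans({c: "N" for c in _AMBIGUOUS}))
    return seq


def read_fasta(path: str | os.PathLike) -> list[GenomeSequence]:
    """Read a FASTA file into :class:`GenomeSequence` records (order preserved).

    Raises ``ValueError`` on duplicate record IDs, an empty file, or
    residues outside the IUPAC nucleotide alphabet.  Ambiguity codes other
    than N are normalized to N with a logged warning.
    """
    records: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record ID {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(GenomeSequence(rec.id, _normalize_residues(rec.id, str(rec.seq))))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(seqs: Iterable[GenomeSequence], path: str | os.PathLike, wrap: int = 80) -> None:
    """Write records as multi-line FASTA wrapped at ``wrap`` columns."""
    with open(path, "w") as fh:
        writer = FastaWriter(fh, wrap=wrap)
        writer.write_file(
            SeqRecord(Seq(s.seq), id=s.id, description="") for s in seqs
        )


def read_gff3(
    path: str | os.PathLike,
    contig: str | None = None,
    types: Sequence[str] | None = None,
) -> list[GeneFeature]:
    """Read gene/CDS rows from a GFF3 file into internal 0-based half-open features.

    ``contig`` and ``types`` filter the returned collection.  Rows with
    ``end < start`` or a strand other than ``+``/``-`` raise ``ValueError``.
    """
    try:
        db = gffutils.create_db(
            os.fspath(path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except gffutils.exceptions.EmptyInputError:
        return []
    out: list[GeneFeature] = []
    for f in db.all_features():
        if f.end < f.start:
            raise ValueError(f"GFF3 row {f.id}: end ({f.end}) < start ({f.start})")
        if f.strand not in {"+", "-"}:
            raise ValueError(f"GFF3 row {f.id}: unsupported strand {f.strand!r}")
        if contig is not None and f.seqid != contig:
            continue
        if types is not None and f.featuretype not in types:
            continue
        out.append(
            GeneFeature(
                contig_id=f.seqid,
                start=f.start - 1,
                end=f.end,
                strand=f.strand,
                feature_id=f.id,
                type=f.featuretype,
            )
        )
    return out


def write_gff3(features: Iterable[GeneFeature], path: str | os.PathLike, source: str = "aspmat") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                f"{f.contig_id}\t{source}\t{f.type}\t{f.start_1based}\t{f.end_1based}"
                f"\t.\t{f.strand}\t.\tID={f.feature_id}\n"
            )


def interval_length(start: int, end: int, convention: str = "one-based-inclusive") -> int:
    """Length of an interval under the named coordinate convention.

    one-based-inclusive: ``end - start + 1`` (requires ``end >= start``);
    zero-based-half-open: ``end - start`` (requires ``end > start``).
    """
    if convention == "one-based-inclusive":
        if end < start:
            raise ValueError(f"inclusive interval requires end >= start, got {start}..{end}")
        return end - start + 1
    if convention == "zero-based-half-open":
        if end <= start:
            raise ValueError(f"half-open interval requires end > start, got [{start}, {end})")
        return end - start
    raise ValueError(f"unknown coordinate convention {convention!r}")


def assembly_stats(seqs: Sequence[GenomeSequence], n_policy: str = "exclude-N") -> AssemblyStats:
    """N50/L50/GC summary of an assembly (cumulative-sum N50 definition).

    N50 is the length of the smallest record in the minimal set of largest
    records whose summed length reaches half the assembly; L50 is the size
    of that set.  GC is computed over the concatenated residues under
    ``n_policy`` (see :func:`aspmat.gc_landscape.gc_content`).
    """
    from .gc_landscape import gc_content

    if not seqs:
        raise ValueError("assembly_stats requires a non-empty collection")
    lengths = sorted((s.length for s in seqs), reverse=True)
    total = sum(lengths)
    half = total / 2
    cum = 0
    n50 = lengths[0]
    l50 = len(lengths)
    for i, L in enumerate(lengths):
        cum += L
        if cum >= half:
            n50, l50 = L, i + 1
            break
    gc = gc_content("".join(s.seq for s in seqs), n_policy=n_policy)
    return AssemblyStats(
        n_records=len(seqs), total_bp=total, n50=n50, l50=l50, gc_percent=gc
    )


def write_bed(
    intervals: Iterable[tuple],
    path: str | os.PathLike,
    header: str | None = None,
) -> None:
    """Write ``(contig, start, end[, name, ...])`` tuples as BED (0-based half-open)."""
    with open(path, "w") as fh:
        if header:
            fh.write(header.rstrip("\n") + "\n")
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_tsv_report(report: pd.DataFrame, path: str | os.PathLike) -> None:
    report.to_csv(path, sep="\t", index=False)


def read_tsv_report(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json_report(report: dict, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json_report(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        return json.load(fh)
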