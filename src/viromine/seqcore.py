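"""Sequence primitives shared by every pipeline stage.

Contigs are plain uppercase DNA over the alphabet ``{A, C, G, T, N}``; any
other symbol is mapped to ``N`` on input.  All coordinates in this package
are 0-based, half-open and expressed on the forward strand; conversion to
1-based happens only in human-readable report writers.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "ContigRecord",
    "GeneCall",
    "read_fasta",
    "write_fasta",
    "gc_content",
    "revcomp",
    "translate",
    "call_orfs",
    "gene_calls_to_tsv",
]

_NON_ACGTN = re.compile(r"[^ACGTN]")

#: translation table used throughout (bacterial/archaeal code)
TRANSLATION_TABLE = 11

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class ContigRecord:
    """One assembled sequence with its sample provenance.

    ``depth_m``, ``fraction`` and ``station_id`` are optional metadata used
    by the recruitment/distribution stages; ``fraction`` is one of
    ``viral`` (<0.22 um), ``free-living`` (0.22-5 um) or ``particle``
    (5-20 um) when present.
    """

    contig_id: str
    sequence: str
    sample_id: str = ""
    depth_m: Optional[float] = None
    fraction: Optional[str] = None
    station_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.sequence = clean_sequence(self.sequence)

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    @property
    def gc_fraction(self) -> float:
        return gc_content(self.sequence)


@dataclass
class GeneCall:
    """A called ORF, with protein and forward-strand coordinates.

    ``start``/``end`` are 0-based half-open on the forward strand and span
    the full ORF including the stop codon, so ``end - start`` is divisible
    by 3 and the protein has ``(end - start) / 3 - 1`` residues.
    ``frame`` is the reading frame (0..2) on the ORF's own strand.
    """

    contig_id: str
    start: int
    end: int
    strand: str
    frame: int
    protein: str
    label: str = "hypothetical"


def clean_sequence(seq: str) -> str:
    """Uppercase and map non-ACGTN symbols to N."""
    return _NON_ACGTN.sub("N", seq.upper())


def gc_content(sequence: str) -> float:
    """(G+C) / (A+C+G+T), ignoring N.  NaN when no unambiguous base."""
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    denom = gc + seq.count("A") + seq.count("T")
    if denom == 0:
        return math.nan
    return gc / denom


def revcomp(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def translate(sequence: str) -> str:
    """Translate a DNA string (table 11); trailing partial codon dropped."""
    usable = len(sequence) - len(sequence) % 3
    return str(Seq(sequence[:usable]).translate(table=TRANSLATION_TABLE))


def read_fasta(
    path: str | Path,
    sample_id: str = "",
    depth_m: Optional[float] = None,
    fraction: Optional[str] = None,
    station_id: Optional[str] = None,
) -> list[ContigRecord]:
    """Read a FASTA file into :class:`ContigRecord` objects.

    IDs are the first whitespace-delimited token of the header.  Duplicate
    IDs and empty files are rejected.
    """
    records: list[ContigRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence ID in {path}: {rec.id!r}")
        seen.add(rec.id)
        records.append(
            ContigRecord(
                contig_id=rec.id,
                sequence=str(rec.seq),
                sample_id=sample_id,
                depth_m=depth_m,
                fraction=fraction,
                station_id=station_id,
            )
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ContigRecord | tuple[str, str]], path: str | Path, width: int = 70) -> None:
    """Write records (or ``(id, sequence)`` pairs) as wrapped FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, ContigRecord):
                name, seq = rec.contig_id, rec.sequence
            else:
                name, seq = rec
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _orfs_one_strand(seq: str, min_codons: int) -> list[tuple[int, int, int, str]]:
    """Maximal ORFs on the given strand: (start, end, frame, protein).

    For each in-frame stop, the ORF begins at the first start codon after
    the previous stop.  Coordinates are on ``seq`` itself.
    """
    out = []
    n = len(seq)
    for frame in range(3):
        start: Optional[int] = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in STOP_CODONS:
                if start is not None:
                    end = pos + 3
                    if (end - start) // 3 >= min_codons:
                        protein = translate(seq[start : end - 3])
                        out.append((start, end, frame, protein))
                    start = None
            elif start is None and codon in START_CODONS:
                start = pos
    return out


def call_orfs(sequence: str, min_codons: int = 60, contig_id: str = "") -> list[GeneCall]:
    """Call maximal ORFs in all six frames.

    An ORF runs from a start codon (ATG/GTG/TTG) to the first in-frame stop
    and must span at least ``min_codons`` codons including the stop.
    Reverse-strand ORFs are reported in forward-strand coordinates.
    """
    seq = clean_sequence(sequence)
    n = len(seq)
    calls: list[GeneCall] = []
    for s, e, frame, protein in _orfs_one_strand(seq, min_codons):
        calls.append(GeneCall(contig_id, s, e, "+", frame, protein))
    for s, e, frame, protein in _orfs_one_strand(revcomp(seq), min_codons):
        calls.append(GeneCall(contig_id, n - e, n - s, "-", frame, protein))
    calls.sort(key=lambda g: (g.start, g.end, g.strand))
    return calls


def gene_calls_to_tsv(calls: Iterable[GeneCall], path: str | Path) -> None:
    """Export gene calls as a GFF3-like TSV (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\tstrand\tlabel\n")
        for g in calls:
            fh.write(f"{g.contig_id}\t{g.start + 1}\t{g.end}\t{g.strand}\t{g.label}\n")
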