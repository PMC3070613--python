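"""Sequence I/O and core DNA primitives.

All internal coordinates are 0-based half-open on the plus strand; the
format writers convert at the boundary (BED stays 0-based half-open,
GFF3 becomes 1-based inclusive).
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path
from typing import NamedTuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

DNA_ALPHABET = frozenset("ACGTN")

# IUPAC nucleotide complement, used both for plain sequences and for
# degenerate motif consensi.
_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A", "N": "N",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
}
_COMPLEMENT_TABLE = str.maketrans(_COMPLEMENT)


class SeqFormatError(ValueError):
    """Raised for malformed sequence files or illegal characters."""


def normalize_seq(seq: str) -> str:
    """Uppercase, map U to T, and validate against the {A,C,G,T,N} alphabet."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - DNA_ALPHABET
    if bad:
        raise SeqFormatError(
            f"illegal sequence character(s): {', '.join(sorted(bad))}"
        )
    return s


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes allowed)."""
    s = seq.upper()
    bad = set(s) - set(_COMPLEMENT)
    if bad:
        raise SeqFormatError(
            f"illegal character(s) for reverse complement: "
            f"{', '.join(sorted(bad))}"
        )
    return s.translate(_COMPLEMENT_TABLE)[::-1]


@dataclasses.dataclass
class SequenceRecord:
    """A named DNA sequence (template, PRE fragment, primer product...)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord.id must be non-empty")
        self.seq = normalize_seq(self.seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclasses.dataclass(frozen=True)
class Interval:
    """0-based half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-record FASTA file, normalizing sequences.

    Records are returned in file order. Lowercase and RNA 'U' are
    normalized; any other character outside {A,C,G,T,N} raises
    :class:`SeqFormatError` naming the offending line.
    """
    path = Path(path)
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            seq = normalize_seq(str(rec.seq))
        except SeqFormatError as exc:
            raise SeqFormatError(
                f"{path}: record {rec.id!r} (near line "
                f"{_find_record_line(path, rec.id)}): {exc}"
            ) from exc
        if rec.id in seen:
            raise SeqFormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(SequenceRecord(id=rec.id, seq=seq, description=desc))
    return records


def _find_record_line(path: Path, rec_id: str) -> int:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">") and line[1:].split()[0:1] == [rec_id]:
                return lineno
    return 0


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path, line_width: int = 60
) -> None:
    """Write records as standard FASTA; round-trips with :func:`read_fasta`."""
    bio_records = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=line_width)
    writer.write_file(bio_records)


class ParsedHit(NamedTuple):
    """A motif hit as re-read from a BED/GFF3 export."""

    motif_name: str
    interval: Interval
    matched_text: str


def _check_bounds(hits, seq_lengths: Mapping[str, int] | None) -> None:
    if seq_lengths is None:
        return
    for h in hits:
        iv = h.interval
        if iv.seq_id not in seq_lengths:
            raise ValueError(f"hit references unknown sequence {iv.seq_id!r}")
        if iv.end > seq_lengths[iv.seq_id]:
            raise ValueError(
                f"hit [{iv.start}, {iv.end}) out of bounds for "
                f"{iv.seq_id!r} (length {seq_lengths[iv.seq_id]})"
            )


def write_hits_bed(
    hits: Sequence,
    path: str | Path,
    seq_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write motif hits as BED6 (0-based half-open).

    The name column carries ``motif_name:matched_text``.
    """
    _check_bounds(hits, seq_lengths)
    with open(path, "w") as fh:
        for h in hits:
            iv = h.interval
            fh.write(
                f"{iv.seq_id}\t{iv.start}\t{iv.end}\t"
                f"{h.motif_name}:{h.matched_text}\t0\t{iv.strand}\n"
            )


def read_hits_bed(path: str | Path) -> list[ParsedHit]:
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise SeqFormatError(f"{path}:{lineno}: expected 6 BED columns")
            name, text = fields[3].split(":", 1)
            hits.append(
                ParsedHit(
                    motif_name=name,
                    interval=Interval(
                        fields[0], int(fields[1]), int(fields[2]),
                        strand=fields[5],
                    ),
                    matched_text=text,
                )
            )
    return hits


def write_hits_gff3(
    hits: Sequence,
    path: str | Path,
    seq_lengths: Mapping[str, int] | None = None,
    source: str = "prequant",
) -> None:
    """Write motif hits as GFF3 (1-based inclusive coordinates)."""
    _check_bounds(hits, seq_lengths)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for h in hits:
            iv = h.interval
            fh.write(
                f"{iv.seq_id}\t{source}\tnucleotide_motif\t"
                f"{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t"
                f"Name={h.motif_name};matched_text={h.matched_text}\n"
            )


def read_hits_gff3(path: str | Path) -> list[ParsedHit]:
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise SeqFormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            hits.append(
                ParsedHit(
                    motif_name=attrs["Name"],
                    interval=Interval(
                        fields[0], int(fields[3]) - 1, int(fields[4]),
                        strand=fields[6],
                    ),
                    matched_text=attrs.get("matched_text", ""),
                )
            )
    return hits
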