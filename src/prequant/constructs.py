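"""In-silico construction of PRE reporter constructs from printed primers.

Cloning primers carry a 5' non-genomic tail with a restriction site
followed by a template-annealing 3' portion; mutagenesis primer pairs
are fully mutually reverse-complementary and span a deletion junction
(QuikChange design). From primer sequences alone this module rebuilds
amplicons and deletion products deterministically, and accounts for the
motif blocks gained or lost by each edit.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import pandas as pd
from Bio.Restriction import NotI, SpeI, XbaI

from .motifs import MotifModel, RepeatBlock, merge_hits_to_blocks, scan_motifs
from .seqio import SequenceRecord, normalize_seq, reverse_complement


@dataclasses.dataclass(frozen=True)
class RestrictionSite:
    """A restriction enzyme and its recognition sequence."""

    enzyme: str
    recognition: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "recognition", normalize_seq(self.recognition))


def default_enzyme_catalog() -> list[RestrictionSite]:
    """Recognition sites for the enzymes used in the construct series."""
    return [
        RestrictionSite("NotI", str(NotI.site)),
        RestrictionSite("XbaI", str(XbaI.site)),
        RestrictionSite("SpeI", str(SpeI.site)),
    ]


@dataclasses.dataclass(frozen=True)
class PrimerRecord:
    """A primer split into 5' tail and 3' template-annealing portion."""

    name: str
    direction: str  # {"forward", "reverse"}
    full_seq: str
    tail: str
    annealing: str
    enzyme: str | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "reverse"):
            raise ValueError(f"invalid primer direction {self.direction!r}")
        if self.tail + self.annealing != self.full_seq:
            raise ValueError("tail + annealing must reconstruct full_seq")


class PrimerError(ValueError):
    pass


class JunctionNotFoundError(PrimerError):
    pass


class AmbiguousJunctionError(PrimerError):
    def __init__(self, message: str, candidates: list):
        super().__init__(message)
        self.candidates = candidates


def split_primer(
    full_seq: str,
    enzyme_catalog: Sequence[RestrictionSite] | None = None,
    name: str = "",
    direction: str = "forward",
    max_tail_search: int = 16,
    min_annealing: int = 10,
) -> PrimerRecord:
    """Split a primer into tail and annealing portions.

    The tail is the shortest prefix ending at the end of the first
    catalog recognition-site occurrence located within the first
    ``max_tail_search`` bases; a primer without such a site (typical for
    mutagenesis primers) gets an empty tail.
    """
    full_seq = normalize_seq(full_seq)
    catalog = (
        list(enzyme_catalog) if enzyme_catalog is not None
        else default_enzyme_catalog()
    )
    prefix = full_seq[:max_tail_search]
    best: tuple[int, int, str] | None = None  # (site_start, site_end, enzyme)
    for site in catalog:
        pos = prefix.find(site.recognition)
        while pos != -1:
            end = pos + len(site.recognition)
            if end <= max_tail_search:
                cand = (pos, end, site.enzyme)
                if best is None or cand[:2] < best[:2]:
                    best = cand
            pos = prefix.find(site.recognition, pos + 1)
    if best is None:
        tail, enzyme = "", None
    else:
        tail, enzyme = full_seq[: best[1]], best[2]
    annealing = full_seq[len(tail):]
    if len(annealing) < min_annealing:
        raise PrimerError(
            f"primer {name or full_seq!r}: annealing portion "
            f"({len(annealing)} nt) shorter than {min_annealing}"
        )
    return PrimerRecord(
        name=name or full_seq,
        direction=direction,
        full_seq=full_seq,
        tail=tail,
        annealing=annealing,
        enzyme=enzyme,
    )


def read_primer_table(
    path: str | Path,
    enzyme_catalog: Sequence[RestrictionSite] | None = None,
) -> list[PrimerRecord]:
    """Read a delimited primer table (columns: name, direction, sequence, enzyme).

    The enzyme column is informational ('-' for none); tails are
    recovered by restriction-site search via :func:`split_primer`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"name", "direction", "sequence"}
    missing = required - set(df.columns)
    if missing:
        raise PrimerError(f"primer table missing column(s): {sorted(missing)}")
    primers = []
    for row in df.itertuples(index=False):
        primers.append(
            split_primer(
                row.sequence.strip(),
                enzyme_catalog,
                name=row.name.strip(),
                direction=row.direction.strip().lower(),
            )
        )
    return primers


def validate_quikchange_pair(fwd: PrimerRecord, rev: PrimerRecord) -> bool:
    """True iff the pair is mutually reverse-complementary (QuikChange design)."""
    if not fwd.full_seq or not rev.full_seq:
        raise PrimerError("empty primer in QuikChange pair")
    return fwd.full_seq == reverse_complement(rev.full_seq)


@dataclasses.dataclass(frozen=True)
class ConstructSpec:
    """A derived construct and the edit that produced it."""

    name: str
    template_id: str
    edit_type: str  # {"amplicon", "quikchange_deletion", "prefix_deletion"}
    product: SequenceRecord
    deletion_start: int | None = None
    deletion_end: int | None = None
    deleted_seq: str | None = None

    @property
    def is_noop(self) -> bool:
        return self.deleted_seq == ""


def _find_all(haystack: str, needle: str) -> list[int]:
    out, pos = [], haystack.find(needle)
    while pos != -1:
        out.append(pos)
        pos = haystack.find(needle, pos + 1)
    return out


def in_silico_pcr(
    template: SequenceRecord,
    fwd: PrimerRecord,
    rev: PrimerRecord,
    name: str | None = None,
) -> SequenceRecord:
    """Amplicon from exact-match primer annealing on a template.

    The forward annealing portion must occur exactly once on the plus
    strand and the reverse-complemented reverse annealing portion
    exactly once downstream of it. Product = forward tail + template
    segment through the reverse site + reverse-complemented reverse
    tail.
    """
    fwd_sites = _find_all(template.seq, fwd.annealing)
    if len(fwd_sites) != 1:
        raise PrimerError(
            f"forward primer {fwd.name!r}: {len(fwd_sites)} annealing sites "
            f"on {template.id!r} (need exactly 1)"
        )
    rev_target = reverse_complement(rev.annealing)
    rev_sites = _find_all(template.seq, rev_target)
    if len(rev_sites) != 1:
        raise PrimerError(
            f"reverse primer {rev.name!r}: {len(rev_sites)} annealing sites "
            f"on {template.id!r} (need exactly 1)"
        )
    f_start = fwd_sites[0]
    r_end = rev_sites[0] + len(rev_target)
    if rev_sites[0] < f_start:
        raise PrimerError(
            f"reverse site of {rev.name!r} lies upstream of forward site "
            f"of {fwd.name!r} on {template.id!r}"
        )
    product = fwd.tail + template.seq[f_start:r_end] + reverse_complement(rev.tail)
    return SequenceRecord(
        id=name or f"{template.id}_amplicon",
        seq=product,
        description=f"amplicon {fwd.name}/{rev.name} on {template.id}",
    )


def apply_quikchange_deletion(
    template: SequenceRecord,
    fwd: PrimerRecord,
    rev: PrimerRecord,
    min_halfsite: int = 10,
    name: str | None = None,
) -> ConstructSpec:
    """Reconstruct the deletion encoded by a QuikChange primer pair.

    The forward primer is split into left+right halves (each at least
    ``min_halfsite`` nt); the left half must match the template at some
    position i and the right half at some j >= i + len(left). The
    deleted segment is template[i+len(left):j). All candidate splits
    are enumerated; splits that merely slide along a repeat produce the
    same product and are accepted, genuinely different products raise
    :class:`AmbiguousJunctionError`. A zero-length deletion (junction
    already present) is returned flagged as a no-op.
    """
    if not validate_quikchange_pair(fwd, rev):
        raise PrimerError(
            f"primers {fwd.name!r}/{rev.name!r} are not mutually "
            f"reverse-complementary"
        )
    primer = fwd.full_seq
    seq = template.seq
    candidates: list[tuple[int, int, int]] = []  # (del_start, del_end, split)
    for k in range(min_halfsite, len(primer) - min_halfsite + 1):
        left, right = primer[:k], primer[k:]
        for i in _find_all(seq, left):
            for j in _find_all(seq, right):
                if j >= i + k:
                    candidates.append((i + k, j, k))
    if not candidates:
        raise JunctionNotFoundError(
            f"junction not found for primer {fwd.name!r} on {template.id!r}"
        )
    products = {seq[:ds] + seq[de:] for ds, de, _ in candidates}
    if len(products) > 1:
        listing = ", ".join(
            f"[{ds},{de}) split={k}" for ds, de, k in sorted(candidates)
        )
        raise AmbiguousJunctionError(
            f"ambiguous junction for primer {fwd.name!r} on "
            f"{template.id!r}: candidates {listing}",
            sorted(candidates),
        )
    del_start, del_end, _ = min(candidates)
    product_seq = products.pop()
    cname = name or f"{template.id}_{fwd.name}"
    return ConstructSpec(
        name=cname,
        template_id=template.id,
        edit_type="quikchange_deletion",
        product=SequenceRecord(
            id=cname,
            seq=product_seq,
            description=(
                f"QuikChange deletion [{del_start},{del_end}) of {template.id}"
            ),
        ),
        deletion_start=del_start,
        deletion_end=del_end,
        deleted_seq=seq[del_start:del_end],
    )


def _block_keys(
    record: SequenceRecord, motifs: Iterable[MotifModel], flank: int
) -> tuple[list[RepeatBlock], list[tuple], list[tuple]]:
    """Blocks with a context key (motif, flanked text) and a text key."""
    hits = scan_motifs(record, motifs)
    blocks = merge_hits_to_blocks(hits)
    ctx_keys, text_keys = [], []
    for b in blocks:
        lo = max(0, b.interval.start - flank)
        hi = min(len(record), b.interval.end + flank)
        text = record.seq[b.interval.start:b.interval.end]
        ctx_keys.append((b.motif_name, record.seq[lo:hi]))
        text_keys.append((b.motif_name, text))
    return blocks, ctx_keys, text_keys


def diff_construct_motifs(
    seq_before: SequenceRecord,
    seq_after: SequenceRecord,
    motifs: Iterable[MotifModel],
    flank: int = 8,
) -> tuple[list[RepeatBlock], list[RepeatBlock]]:
    """Motif blocks lost and gained by an edit.

    Blocks are matched between the two sequences by matched text and
    flanking context (``flank`` bases each side), so an unchanged block
    re-identifies itself despite the coordinate shift introduced by a
    deletion. Blocks whose context changed — for example a block that
    now abuts the deletion junction — are matched by motif name and
    block text alone in a second pass; only genuinely unmatched blocks
    are reported. Returns (lost, gained).
    """
    motifs = list(motifs)
    b_blocks, b_ctx, b_text = _block_keys(seq_before, motifs, flank)
    a_blocks, a_ctx, a_text = _block_keys(seq_after, motifs, flank)

    b_open = list(range(len(b_blocks)))
    a_open = list(range(len(a_blocks)))
    for keys_b, keys_a in ((b_ctx, a_ctx), (b_text, a_text)):
        for bi in list(b_open):
            for ai in a_open:
                if keys_b[bi] == keys_a[ai]:
                    b_open.remove(bi)
                    a_open.remove(ai)
                    break
    lost = [b_blocks[i] for i in b_open]
    gained = [a_blocks[i] for i in a_open]
    return lost, gained


def write_deletion_report(specs: Sequence[ConstructSpec], path, motifs=None) -> None:
    """Delimited report: construct, deletion coords, length, lost blocks."""
    rows = []
    for s in specs:
        rows.append(
            {
                "construct": s.name,
                "template": s.template_id,
                "edit_type": s.edit_type,
                "deletion_start": s.deletion_start,
                "deletion_end": s.deletion_end,
                "deleted_length": (
                    len(s.deleted_seq) if s.deleted_seq is not None else None
                ),
                "product_length": len(s.product),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
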