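"""PRE motif scanning, repeat-block merging, and pair-density scoring.

A PRE (Polycomb/Trithorax response element) is characterized less by any
single binding site than by a local clustering of short motifs for
ZESTE, GAGA factor/Pipsqueak (GAF/PSQ), Pleiohomeotic (PHO/PHOL) and the
sequence-mining-derived GTGT motif. This module locates motif
occurrences given as IUPAC consensi (both strands, overlapping matches
included), merges tandem occurrences into repeat blocks, and computes a
sliding-window score counting co-occurring motif pairs within a
characteristic pairing distance — high-scoring windows are PRE
candidates.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping, Sequence

from .seqio import Interval, SequenceRecord, reverse_complement

#: IUPAC nucleotide letter classes. A subject-sequence ``N`` matches no
#: motif symbol (the classes below contain plain bases only), so masked
#: regions never produce hits.
IUPAC_CLASSES: Mapping[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"),
    "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"),
    "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


@dataclasses.dataclass(frozen=True)
class MotifModel:
    """An IUPAC consensus motif with fixed matching semantics."""

    name: str
    consensus: str
    both_strands: bool = True

    def __len__(self) -> int:
        return len(self.consensus)


def compile_motif(name: str, consensus: str, both_strands: bool = True) -> MotifModel:
    """Validate and build a :class:`MotifModel`.

    Raises ``ValueError`` naming the first character outside the
    15-letter IUPAC nucleotide alphabet.
    """
    if not consensus:
        raise ValueError("motif consensus must be non-empty")
    consensus = consensus.upper()
    for ch in consensus:
        if ch not in IUPAC_CLASSES:
            raise ValueError(
                f"motif {name!r}: illegal IUPAC character {ch!r} in consensus"
            )
    return MotifModel(name=name, consensus=consensus, both_strands=both_strands)


def default_motifs() -> list[MotifModel]:
    """The default PRE motif set.

    GAF/PSQ (GAGAG) and PHO/PHOL (GCCAT core) are the classical PRE
    motifs; GTGT (GTGTG here, configurable) is the sequence-mining
    derived PRE-enriched motif; the ZESTE consensus (YGAGYG) follows
    common usage and is likewise configurable.
    """
    return [
        compile_motif("GAF/PSQ", "GAGAG"),
        compile_motif("PHO/PHOL", "GCCAT"),
        compile_motif("ZESTE", "YGAGYG"),
        compile_motif("GTGT", "GTGTG"),
    ]


@dataclasses.dataclass(frozen=True)
class MotifHit:
    """One motif occurrence, in plus-strand coordinates.

    ``matched_text`` is the motif-strand text: the template substring for
    plus-strand hits, its reverse complement for minus-strand hits.
    """

    motif_name: str
    interval: Interval
    matched_text: str


@dataclasses.dataclass(frozen=True)
class RepeatBlock:
    """A maximal chain of overlapping/bookended same-motif hits."""

    motif_name: str
    interval: Interval
    n_overlapping_hits: int


def _matches_at(seq: str, pattern: str, i: int) -> bool:
    for k, ch in enumerate(pattern):
        if seq[i + k] not in IUPAC_CLASSES[ch]:
            return False
    return True


def scan_motifs(
    record: SequenceRecord, motifs: Iterable[MotifModel]
) -> list[MotifHit]:
    """All occurrences of every motif, overlapping matches included.

    Minus-strand matches (occurrences of the reverse-complemented
    consensus on the plus strand) are reported in plus-strand
    coordinates with strand ``-``. Output is sorted by
    (start, motif_name, strand) and deterministic.
    """
    seq = record.seq
    hits: list[MotifHit] = []
    for motif in motifs:
        m = len(motif.consensus)
        patterns = [(motif.consensus, "+")]
        if motif.both_strands:
            patterns.append((reverse_complement(motif.consensus), "-"))
        for pattern, strand in patterns:
            for i in range(len(seq) - m + 1):
                if _matches_at(seq, pattern, i):
                    text = seq[i:i + m]
                    if strand == "-":
                        text = reverse_complement(text)
                    hits.append(
                        MotifHit(
                            motif_name=motif.name,
                            interval=Interval(record.id, i, i + m, strand),
                            matched_text=text,
                        )
                    )
    hits.sort(key=lambda h: (h.interval.start, h.motif_name, h.interval.strand))
    return hits


def merge_hits_to_blocks(hits: Sequence[MotifHit]) -> list[RepeatBlock]:
    """Merge overlapping or bookended same-motif hits into repeat blocks.

    Tandem repeats of a short motif (for example several adjacent GTGT
    occurrences) are reported as one block with the number of underlying
    hits, matching how repeat tracts are annotated on construct maps.
    Strand is collapsed to ``+`` for the merged block.
    """
    if not hits:
        return []
    seq_ids = {h.interval.seq_id for h in hits}
    if len(seq_ids) > 1:
        raise ValueError(
            f"hits span multiple sequences: {', '.join(sorted(seq_ids))}"
        )
    seq_id = seq_ids.pop()
    blocks: list[RepeatBlock] = []
    by_motif: dict[str, list[MotifHit]] = {}
    for h in hits:
        by_motif.setdefault(h.motif_name, []).append(h)
    for motif_name in sorted(by_motif):
        spans = sorted(
            (h.interval.start, h.interval.end) for h in by_motif[motif_name]
        )
        cur_start, cur_end = spans[0]
        count = 1
        for start, end in spans[1:]:
            if start <= cur_end:  # overlapping or bookended
                cur_end = max(cur_end, end)
                count += 1
            else:
                blocks.append(
                    RepeatBlock(
                        motif_name,
                        Interval(seq_id, cur_start, cur_end),
                        count,
                    )
                )
                cur_start, cur_end, count = start, end, 1
        blocks.append(
            RepeatBlock(motif_name, Interval(seq_id, cur_start, cur_end), count)
        )
    blocks.sort(key=lambda b: (b.interval.start, b.motif_name))
    return blocks


def count_motifs_in_window(
    record: SequenceRecord, motif: MotifModel, center: int, halfwidth: int
) -> int:
    """Number of hits lying wholly inside ``[center-halfwidth, center+halfwidth)``.

    The window is clipped to sequence bounds; both strands are counted.
    """
    if halfwidth <= 0:
        raise ValueError("halfwidth must be positive")
    if not (0 <= center < max(len(record), 1)):
        raise ValueError(f"center {center} outside sequence {record.id!r}")
    lo = max(0, center - halfwidth)
    hi = min(len(record), center + halfwidth)
    hits = scan_motifs(record, [motif])
    return sum(1 for h in hits if lo <= h.interval.start and h.interval.end <= hi)


@dataclasses.dataclass
class ScoreParams:
    """Sliding-window pair-density score parameters.

    The score of a window is the weighted count of unordered motif-hit
    pairs whose start-to-start distance is at most ``pair_distance`` —
    the characteristic scale over which PRE motif pairs co-occur
    (comparable to the size of minimal PRE core fragments). Defaults:
    500 bp windows sliding by 100 bp, 220 bp pairing distance, unit
    weight for every motif-type pair.
    """

    window_length: int = 500
    step: int = 100
    pair_distance: int = 220
    pair_weights: dict[frozenset[str], float] | None = None

    def __post_init__(self) -> None:
        if not (self.window_length >= self.pair_distance > 0):
            raise ValueError("require window_length >= pair_distance > 0")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.pair_weights is not None:
            for key, w in self.pair_weights.items():
                if w < 0:
                    raise ValueError(f"negative pair weight for {set(key)}")

    def weight(self, motif_a: str, motif_b: str) -> float:
        if self.pair_weights is None:
            return 1.0
        return self.pair_weights.get(frozenset((motif_a, motif_b)), 0.0)


@dataclasses.dataclass
class ScoreTrack:
    """Window scores along one sequence."""

    seq_id: str
    starts: list[int]
    centers: list[int]
    scores: list[float]
    window_length: int

    def __post_init__(self) -> None:
        if not (len(self.starts) == len(self.centers) == len(self.scores)):
            raise ValueError("starts, centers and scores must align")
        if any(b <= a for a, b in zip(self.centers, self.centers[1:])):
            raise ValueError("window centers must be strictly increasing")
        if any(s < 0 for s in self.scores):
            raise ValueError("scores must be non-negative")


def _window_starts(seq_len: int, params: ScoreParams) -> tuple[list[int], int]:
    """Window start positions and the effective window length."""
    if seq_len < params.window_length:
        return [0], seq_len
    return (
        list(range(0, seq_len - params.window_length + 1, params.step)),
        params.window_length,
    )


def pre_score_track(
    record: SequenceRecord,
    motifs: Iterable[MotifModel],
    params: ScoreParams | None = None,
) -> ScoreTrack:
    """Pair-density PRE score for each sliding window.

    score(window) = sum over unordered distinct hit pairs {a, b} fully
    inside the window with |start_a - start_b| <= pair_distance of
    weight(motif_a, motif_b). Pairs of hits of the same motif type
    count once per unordered pair. A sequence shorter than the window
    yields a single window spanning the whole sequence.
    """
    params = params or ScoreParams()
    hits = scan_motifs(record, motifs)
    starts, eff_len = _window_starts(len(record), params)
    spans = [(h.interval.start, h.interval.end, h.motif_name) for h in hits]
    scores = []
    for w in starts:
        inside = [s for s in spans if s[0] >= w and s[1] <= w + eff_len]
        total = 0.0
        for i in range(len(inside)):
            for j in range(i + 1, len(inside)):
                if abs(inside[i][0] - inside[j][0]) <= params.pair_distance:
                    total += params.weight(inside[i][2], inside[j][2])
        scores.append(total)
    return ScoreTrack(
        seq_id=record.id,
        starts=starts,
        centers=[w + eff_len // 2 for w in starts],
        scores=scores,
        window_length=eff_len,
    )


@dataclasses.dataclass(frozen=True)
class ScoredRegion:
    """The highest-scoring window of a score track."""

    interval: Interval
    score: float
    all_zero: bool = False


def highest_scoring_region(track: ScoreTrack) -> ScoredRegion:
    """The window achieving the maximum score; ties break leftmost.

    An all-zero track returns the leftmost window flagged ``all_zero``.
    """
    if not track.scores:
        raise ValueError("empty score track")
    best = max(range(len(track.scores)), key=lambda i: (track.scores[i], -i))
    all_zero = all(s == 0 for s in track.scores)
    if all_zero:
        best = 0
    start = track.starts[best]
    return ScoredRegion(
        interval=Interval(track.seq_id, start, start + track.window_length),
        score=track.scores[best],
        all_zero=all_zero,
    )


def write_score_track(track: ScoreTrack, path) -> None:
    """Export a track as 2-column delimited text (center, score)."""
    with open(path, "w") as fh:
        fh.write("center\tscore\n")
        for c, s in zip(track.centers, track.scores):
            fh.write(f"{c}\t{s:g}\n")
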