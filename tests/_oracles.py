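"""Independent brute-force oracles used to cross-check the package.

Everything here is written naively and separately from the library
implementation: position-by-position scanning, O(n^2) pair counting,
and sweep-based interval union.
"""

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def naive_rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def naive_scan(seq: str, consensus: str, both_strands: bool = True):
    """All (start, end, strand) occurrences, overlapping included.

    Subject 'N' matches nothing (the IUPAC classes hold plain bases
    only, and the subject is checked against them directly).
    """
    out = []
    for pattern, strand in [(consensus, "+")] + (
        [(naive_rc(consensus), "-")] if both_strands else []
    ):
        m = len(pattern)
        for i in range(len(seq) - m + 1):
            if all(seq[i + k] in IUPAC[pattern[k]] for k in range(m)):
                out.append((i, i + m, strand))
    return sorted(out)


def naive_union(intervals):
    """Union of intervals by sweep; bookended intervals merge."""
    merged = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def naive_window_pair_score(
    seq, motif_consensi, window_start, window_length, pair_distance,
    weight=None,
):
    """O(h^2) pair count for one window.

    motif_consensi: mapping name -> (consensus, both_strands). A hit
    pair counts when both hits lie wholly inside the window and their
    start-to-start distance is <= pair_distance; same-motif pairs count
    as unordered distinct pairs.
    """
    hits = []
    for name, (consensus, both) in motif_consensi.items():
        for start, end, strand in naive_scan(seq, consensus, both):
            if start >= window_start and end <= window_start + window_length:
                hits.append((start, name))
    total = 0.0
    for a in range(len(hits)):
        for b in range(a + 1, len(hits)):
            if abs(hits[a][0] - hits[b][0]) <= pair_distance:
                if weight is None:
                    total += 1.0
                else:
                    total += weight(hits[a][1], hits[b][1])
    return total
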