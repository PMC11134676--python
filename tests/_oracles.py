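"""Independent brute-force oracles used only by the tests.

Each oracle is written as a direct transcription of the definition it checks
(character-by-character scans, per-base recomputation, exhaustive chain
enumeration) and shares no code with the implementation.
"""
from __future__ import annotations

import itertools

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def contexts_bruteforce(seq: str) -> dict:
    """{(pos, strand): context} by scanning trinucleotides on both strands."""
    out = {}
    n = len(seq)
    for strand in "+-":
        s = seq if strand == "+" else revcomp(seq)
        for i, ch in enumerate(s):
            if ch != "C":
                continue
            pos = i if strand == "+" else n - 1 - i
            tri = s[i:i + 3]
            if len(tri) < 3 or "N" in tri:
                ctx = "ambiguous"
            elif tri[1] == "G":
                ctx = "CG"
            elif tri[2] == "G":
                ctx = "CHG"
            else:
                ctx = "CHH"
            out[(pos, strand)] = ctx
    return out


def region_level_bruteforce(calls, chrom, lo, hi, context, min_cov):
    """Pooled level over one interval by scanning every call row."""
    m = c = n = 0
    for row in calls.itertuples():
        if (row.chrom == chrom and lo <= row.pos < hi
                and row.context == context and row.coverage >= min_cov):
            m += row.methylated
            c += row.coverage
            n += 1
    return (m / c if n else float("nan")), n


def best_chain_bruteforce(anchors, max_gap):
    """Exhaustive maximum-score collinear chain over <= ~12 anchors.

    ``anchors``: list of (rank_a, rank_b, score). Tries every subset order
    compatible with strictly increasing rank_a and strictly monotone rank_b
    (either orientation) under the rank-gap cap; returns the best total score.
    """
    best = 0.0
    idx = range(len(anchors))
    for r in range(1, len(anchors) + 1):
        for combo in itertools.combinations(idx, r):
            chain = sorted((anchors[i] for i in combo), key=lambda t: (t[0], t[1]))
            ra = [t[0] for t in chain]
            rb = [t[1] for t in chain]
            if any(ra[i] >= ra[i + 1] for i in range(r - 1)):
                continue
            if any(ra[i + 1] - ra[i] > max_gap for i in range(r - 1)):
                continue
            inc = all(rb[i] < rb[i + 1] and rb[i + 1] - rb[i] <= max_gap
                      for i in range(r - 1))
            dec = all(rb[i] > rb[i + 1] and rb[i] - rb[i + 1] <= max_gap
                      for i in range(r - 1))
            if inc or dec:
                best = max(best, sum(t[2] for t in chain))
    return best


def reciprocal_overlap(a_start, a_end, b_start, b_end, frac=0.5) -> bool:
    ov = max(0, min(a_end, b_end) - max(a_start, b_start))
    return ov >= frac * (a_end - a_start) and ov >= frac * (b_end - b_start)
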