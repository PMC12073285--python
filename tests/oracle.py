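"""Independent brute-force SSR scanner used as a test oracle.

Enumerates every (start, motif length, copy count) triple exhaustively and
keeps the maximal ones; no shared code with ssrmine.repeat_miner beyond the
criteria container.
"""

from __future__ import annotations


def _primitive(motif: str) -> bool:
    k = len(motif)
    return not any(
        k % d == 0 and motif == motif[:d] * (k // d) for d in range(1, k)
    )


def brute_force_ssrs(seq: str, min_repeats: dict[int, int]) -> set[tuple]:
    """All maximal perfect repeat tracts as (start, end, motif) with 1-based
    inclusive coordinates.

    A triple qualifies when: the motif (length k) is primitive and N-free,
    `count` >= the class minimum, the window is `count` exact copies, the
    window cannot slide left by one base under period k (leftmost anchoring;
    N never matches anything), and no further full copy follows.
    """
    s = seq.upper()
    n = len(s)
    out = set()
    for k, min_count in min_repeats.items():
        for start in range(n - k * min_count + 1):
            motif = s[start : start + k]
            if "N" in motif or not _primitive(motif):
                continue
            # leftmost anchoring under period k
            if start > 0 and s[start - 1] == s[start + k - 1] and s[start - 1] != "N":
                continue
            count = 1
            while s[start + count * k : start + (count + 1) * k] == motif:
                count += 1
            if count >= min_count:
                out.add((start + 1, start + count * k, motif))
    return out
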