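"""Small shared helpers: DNA alphabet checks and reverse complement."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DNA_BASES = frozenset("ACGT")
DNA_BASES_N = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, allow_n: bool = True, what: str = "sequence") -> str:
    """Upper-case *seq* and reject characters outside the DNA alphabet."""
    seq = seq.upper()
    allowed = DNA_BASES_N if allow_n else DNA_BASES
    bad = set(seq) - allowed
    if bad:
        raise ValueError(f"invalid {what}: non-DNA characters {sorted(bad)}")
    return seq
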