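"""MISA-compatible detection and motif accounting of simple sequence repeats.

A simple sequence repeat (SSR, microsatellite) is a perfect tandem array of a
1-6 nt motif.  Detection follows the convention of genome-scale repeat
finders: a tract is reported when the number of complete motif copies reaches
a per-motif-length minimum (here 10 copies for mononucleotide motifs, 6 for
dinucleotide, 5 for tri- through hexanucleotide), tracts are maximal (not
extendable by a full motif copy in either direction), and each tract is
explained by its shortest motif — (AT)6, never (ATAT)3.  Motifs are grouped
with their reverse complement for accounting ("TAT/ATA"), because a repeat
read from the other strand is the same locus; rotations stay distinct.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from ._util import revcomp, validate_dna

#: minimum number of complete motif copies for a tract to count, by motif length
DEFAULT_MIN_REPEATS: Mapping[int, int] = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}

#: two tracts closer than this many bp are flagged as a compound SSR
DEFAULT_MAX_COMPOUND_GAP = 100

CLASS_NAMES = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}


@dataclass(frozen=True)
class RepeatCriteria:
    """Detection thresholds: minimum copy number per motif length and the
    maximum gap (bp) under which adjacent tracts are called compound."""

    min_repeats: Mapping[int, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_REPEATS)
    )
    max_compound_gap: int = DEFAULT_MAX_COMPOUND_GAP

    def __post_init__(self) -> None:
        if set(self.min_repeats) - set(range(1, 7)):
            raise ValueError("min_repeats keys must be motif lengths 1-6")
        if any(v < 1 for v in self.min_repeats.values()):
            raise ValueError("all minimum repeat counts must be >= 1")
        if self.max_compound_gap < 0:
            raise ValueError("max_compound_gap must be >= 0")


@dataclass(frozen=True)
class SSRHit:
    """One detected tandem repeat tract (1-based inclusive coordinates)."""

    seq_id: str
    start: int
    end: int
    motif: str
    repeat_count: int
    compound: bool = False

    @property
    def motif_len(self) -> int:
        return len(self.motif)

    @property
    def canonical_label(self) -> str:
        return canonical_motif(self.motif)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def class_name(self) -> str:
        return CLASS_NAMES[self.motif_len]


def is_primitive(motif: str) -> bool:
    """True if *motif* is not itself a tandem repetition of a shorter motif."""
    k = len(motif)
    for d in range(1, k):
        if k % d == 0 and motif == motif[:d] * (k // d):
            return False
    return True


def canonical_motif(motif: str, collapse: bool = False) -> str:
    """Label pairing a motif with its reverse complement, e.g. ``"TAT/ATA"``.

    Rotations remain distinct (AT/AT and TA/TA are different labels).  With
    ``collapse=True`` the pair is reported under its lexicographically
    smaller member, so a motif and its reverse complement map to one label.
    """
    if not 1 <= len(motif) <= 6:
        raise ValueError("motif length must be 1-6")
    motif = validate_dna(motif, allow_n=False, what="motif")
    rc = revcomp(motif)
    if collapse:
        motif = min(motif, rc)
        rc = revcomp(motif)
    return f"{motif}/{rc}"


def find_ssrs(
    sequence: str,
    criteria: RepeatCriteria | None = None,
    seq_id: str = "",
) -> list[SSRHit]:
    """Detect all maximal perfect SSR tracts in *sequence*.

    For every motif length k the sequence is scanned for maximal runs of
    period k (positions where ``s[i] == s[i+k]``); a run yields a hit when it
    holds at least the required number of complete motif copies and its motif
    is primitive (primitivity is what makes the shortest-motif explanation
    win: the period-4 view of (AT)6 has motif ATAT, which is rejected).
    N never participates in a repeat.  Hits are returned sorted by start and
    carry the compound flag for tracts within ``max_compound_gap`` bp of a
    neighbour.
    """
    criteria = criteria or RepeatCriteria()
    s = validate_dna(sequence, allow_n=True)
    n = len(s)
    hits: list[SSRHit] = []
    for k, min_count in sorted(criteria.min_repeats.items()):
        i = 0
        limit = n - k
        while i < limit:
            if s[i] != s[i + k] or s[i] == "N":
                i += 1
                continue
            # maximal period-k run starting at i (i is leftmost by construction)
            j = i
            while j < limit and s[j] == s[j + k] and s[j] != "N":
                j += 1
            run_len = j - i + k  # bases i .. j+k-1
            count = run_len // k
            if count >= min_count:
                motif = s[i : i + k]
                if is_primitive(motif):
                    hits.append(
                        SSRHit(
                            seq_id=seq_id,
                            start=i + 1,
                            end=i + count * k,
                            motif=motif,
                            repeat_count=count,
                        )
                    )
            i = j + 1
    hits.sort(key=lambda h: (h.start, h.motif_len))
    return flag_compound(hits, criteria.max_compound_gap)


def flag_compound(hits: Sequence[SSRHit], max_gap: int) -> list[SSRHit]:
    """Set ``compound=True`` on every hit whose gap to an adjacent hit on the
    same sequence is at most *max_gap* bp (overlapping tracts count too)."""
    out = list(hits)
    for a in range(len(out) - 1):
        b = a + 1
        if out[a].seq_id != out[b].seq_id:
            continue
        gap = out[b].start - out[a].end - 1
        if gap <= max_gap:
            out[a] = replace(out[a], compound=True)
            out[b] = replace(out[b], compound=True)
    return out


@dataclass
class MotifSummary:
    """Per-class and per-motif accounting of a set of SSR hits."""

    class_counts: dict[int, int]
    label_counts: dict[int, Counter]  # motif_len -> canonical label -> count

    @classmethod
    def from_hits(cls, hits: Iterable[SSRHit]) -> "MotifSummary":
        class_counts: dict[int, int] = {}
        label_counts: dict[int, Counter] = {}
        for h in hits:
            class_counts[h.motif_len] = class_counts.get(h.motif_len, 0) + 1
            label_counts.setdefault(h.motif_len, Counter())[h.canonical_label] += 1
        return cls(class_counts, label_counts)

    @classmethod
    def from_counts(
        cls, label_counts: Mapping[str, int]
    ) -> "MotifSummary":
        """Build a summary from pre-tabulated canonical-label counts
        (e.g. ``{"A/T": 3013, "AT/AT": 15194, ...}``)."""
        lc: dict[int, Counter] = {}
        for label, count in label_counts.items():
            k = len(label.split("/")[0])
            lc.setdefault(k, Counter())[label] += count
        cc = {k: sum(c.values()) for k, c in lc.items()}
        return cls(cc, lc)

    @property
    def total(self) -> int:
        return sum(self.class_counts.values())

    def class_share(self, motif_len: int) -> float:
        """Percentage of all hits in one motif-length class (2 dp)."""
        if self.total == 0:
            return 0.0
        return round(100.0 * self.class_counts.get(motif_len, 0) / self.total, 2)

    def label_share(self, label: str) -> float:
        """Within-class percentage of one canonical motif label (2 dp)."""
        k = len(label.split("/")[0])
        cls_total = self.class_counts.get(k, 0)
        if cls_total == 0:
            return 0.0
        return round(100.0 * self.label_counts[k].get(label, 0) / cls_total, 2)

    def distinct_motifs(self, motif_len: int) -> int:
        return len(self.label_counts.get(motif_len, ()))

    def class_table(self) -> pd.DataFrame:
        rows = [
            {
                "class": CLASS_NAMES[k],
                "motif_len": k,
                "count": self.class_counts.get(k, 0),
                "share_pct": self.class_share(k),
                "distinct_motifs": self.distinct_motifs(k),
            }
            for k in sorted(self.class_counts)
        ]
        return pd.DataFrame(rows)

    def motif_table(self) -> pd.DataFrame:
        rows = [
            {
                "motif_len": k,
                "label": label,
                "count": cnt,
                "within_class_pct": self.label_share(label),
            }
            for k in sorted(self.label_counts)
            for label, cnt in self.label_counts[k].most_common()
        ]
        return pd.DataFrame(rows)


def summarize_motifs(hits: Iterable[SSRHit]) -> MotifSummary:
    """Tabulate hits by motif-length class and canonical motif label."""
    return MotifSummary.from_hits(hits)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[tuple[str, str]]:
    """Read a (possibly multi-record, line-wrapped) FASTA file."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def scan_fasta(path, criteria: RepeatCriteria | None = None) -> list[SSRHit]:
    """Run :func:`find_ssrs` over every record of a FASTA file."""
    hits: list[SSRHit] = []
    for seq_id, seq in read_fasta(path):
        hits.extend(find_ssrs(seq, criteria, seq_id=seq_id))
    return hits


HIT_COLUMNS = [
    "seq_id", "start", "end", "motif", "canonical_label",
    "repeat_count", "class", "compound",
]


def write_hits_tsv(hits: Sequence[SSRHit], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(HIT_COLUMNS)
        for h in hits:
            w.writerow(
                [h.seq_id, h.start, h.end, h.motif, h.canonical_label,
                 h.repeat_count, h.class_name, int(h.compound)]
            )
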