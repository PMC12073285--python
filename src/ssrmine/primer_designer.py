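"""SSR flank extraction and primer pair enumeration/filtering.

Templates are the SSR tract plus 150 bp of flank on each side.  Candidate
primers are every window in the flanks satisfying length (18-27 nt, optimum
20), melting temperature (57-61 degC, optimum 60, pair difference <= 5) and
GC content (20-80%) constraints, paired so the PCR product spans the whole
tract with a size of 100-300 bp.  Pairs are ranked by a simple documented
penalty and the best few per locus are kept; a separate post-filter rejects
pairs with short products, mononucleotide runs of 4+ inside a primer, or
primer GC outside a stricter 40-60% band ("extreme GC").

Melting temperatures use self-implemented nearest-neighbour thermodynamics
(SantaLucia 1998 unified parameters, monovalent-salt entropy correction) with
the Wallace rule 2(A+T)+4(G+C) available as a quick fallback.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from ._util import revcomp, validate_dna
from .variant_pipeline import SSRLocus

# SantaLucia (1998) unified nearest-neighbour parameters:
# dH kcal/mol, dS cal/(mol K) per stacked pair, plus terminal initiation.
_NN_DH_DS = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_INIT_GC = (0.1, -2.8)
_INIT_AT = (2.3, 4.1)
_R = 1.987  # cal/(mol K)


@dataclass(frozen=True)
class PrimerParams:
    """Design window and post-filter settings (temperatures degC, GC %)."""

    tm_min: float = 57.0
    tm_opt: float = 60.0
    tm_max: float = 61.0
    max_pair_tm_diff: float = 5.0
    len_range: tuple[int, int] = (18, 27)
    len_opt: int = 20
    gc_range: tuple[float, float] = (20.0, 80.0)
    product_range: tuple[int, int] = (100, 300)
    flank: int = 150
    max_homopolymer: int = 3
    reject_gc_outside: tuple[float, float] = (40.0, 60.0)
    pairs_per_locus: int = 3
    tm_mode: str = "nn"  # "nn" | "wallace"

    def __post_init__(self) -> None:
        for lo, hi in (self.len_range, self.gc_range, self.product_range,
                       self.reject_gc_outside):
            if lo > hi:
                raise ValueError("range bounds out of order")
        if self.flank <= 0:
            raise ValueError("flank must be > 0")


# penalty weights for ranking candidate pairs (documented constants; summed
# over both primers, plus a mild preference for mid-range products)
PENALTY_LEN = 1.0       # per nt away from len_opt
PENALTY_TM = 1.0        # per degC away from tm_opt
PENALTY_GC = 0.25       # per GC % away from 50
PENALTY_PRODUCT = 0.01  # per bp away from the product-range midpoint


@dataclass
class Template:
    """Tract +/- flank extracted from a reference sequence; coordinates of
    the tract within the template are 1-based inclusive."""

    locus_id: str
    seq: str
    tract_start: int
    tract_end: int
    genome_start: int  # 1-based start of the template on its chromosome


@dataclass
class PrimerPair:
    locus_id: str
    forward: str
    reverse: str  # 5'->3' on the opposite strand
    fwd_start: int  # 1-based template positions
    fwd_end: int
    rev_start: int  # template coordinates of the reverse-binding window
    rev_end: int
    tm_f: float
    tm_r: float
    gc_f: float
    gc_r: float
    product_size: int
    score: float


def gc_content(seq: str) -> float:
    """GC percentage of a DNA string."""
    seq = validate_dna(seq, allow_n=False, what="primer")
    if not seq:
        raise ValueError("empty sequence")
    return 100.0 * sum(c in "GC" for c in seq) / len(seq)


def melting_temperature(
    seq: str,
    mode: str = "nn",
    primer_nM: float = 25.0,
    partner_nM: float = 25.0,
    Na_mM: float = 50.0,
) -> float:
    """Primer melting temperature in degC.

    ``mode="nn"`` (default): nearest-neighbour thermodynamics, SantaLucia
    1998 unified parameter set, Tm = 1000 dH / (dS + R ln CT) - 273.15 with
    CT the effective strand concentration (primer - partner/2) and an
    entropy salt correction 0.368 (n-1) ln[Na+].  ``mode="wallace"``: the
    rule 2(A+T) + 4(G+C), adequate only for short oligos.
    """
    seq = validate_dna(seq, allow_n=False, what="primer")
    if len(seq) < 8:
        raise ValueError("primer too short for a meaningful Tm (need >= 8 nt)")
    if mode == "wallace":
        at = sum(c in "AT" for c in seq)
        return 2.0 * at + 4.0 * (len(seq) - at)
    if mode != "nn":
        raise ValueError("mode must be 'nn' or 'wallace'")
    dh = ds = 0.0
    for a, b in zip(seq, seq[1:]):
        h, s = _NN_DH_DS[a + b]
        dh += h
        ds += s
    for terminal in (seq[0], seq[-1]):
        h, s = _INIT_GC if terminal in "GC" else _INIT_AT
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(Na_mM / 1000.0)
    ct = (primer_nM - partner_nM / 2.0) * 1e-9
    return 1000.0 * dh / (ds + _R * math.log(ct)) - 273.15


def extract_flanks(
    reference: dict[str, str] | Sequence[tuple[str, str]],
    locus: SSRLocus,
    tract_start: int,
    tract_end: int,
    flank: int = 150,
) -> Template:
    """Template = tract +/- *flank* bp, truncated at sequence ends.

    *tract_start*/*tract_end* are 1-based chromosome coordinates of the SSR
    tract (for variant-derived loci, its projection onto the reference).
    """
    ref = dict(reference)
    if locus.chrom not in ref:
        raise KeyError(f"chromosome {locus.chrom} not in reference")
    seq = ref[locus.chrom]
    start = max(1, tract_start - flank)
    end = min(len(seq), tract_end + flank)
    return Template(
        locus_id=locus.locus_id,
        seq=seq[start - 1 : end],
        tract_start=tract_start - start + 1,
        tract_end=tract_end - start + 1,
        genome_start=start,
    )


def _window_ok(seq: str, params: PrimerParams) -> tuple[float, float] | None:
    gc = gc_content(seq)
    if not params.gc_range[0] <= gc <= params.gc_range[1]:
        return None
    tm = melting_temperature(seq, mode=params.tm_mode)
    if not params.tm_min <= tm <= params.tm_max:
        return None
    return tm, gc


def enumerate_primer_pairs(
    template: Template, params: PrimerParams | None = None
) -> tuple[list[PrimerPair], str | None]:
    """All feasible primer pairs spanning the tract, ranked; returns the top
    ``pairs_per_locus`` and a reason code (or None) when empty.

    Forward windows lie wholly upstream of the tract, reverse windows wholly
    downstream (reverse primer reported 5'->3' on the bottom strand); the
    enumeration is deterministic for fixed inputs.
    """
    params = params or PrimerParams()
    seq = template.seq
    n = len(seq)
    if n < params.product_range[0]:
        return [], "template_too_short"
    lo, hi = params.len_range
    mid_product = sum(params.product_range) / 2.0

    fwd: list[tuple[int, int, str, float, float]] = []
    for start in range(1, template.tract_start):
        for L in range(lo, hi + 1):
            end = start + L - 1
            if end >= template.tract_start:
                break
            w = seq[start - 1 : end]
            ok = _window_ok(w, params)
            if ok:
                fwd.append((start, end, w, *ok))
    if not fwd:
        return [], "no_forward_candidates"

    rev: list[tuple[int, int, str, float, float]] = []
    for end in range(template.tract_end + 1, n + 1):
        for L in range(lo, hi + 1):
            start = end - L + 1
            if start <= template.tract_end:
                break
            w = revcomp(seq[start - 1 : end])
            ok = _window_ok(w, params)
            if ok:
                rev.append((start, end, w, *ok))
    if not rev:
        return [], "no_reverse_candidates"

    pairs: list[PrimerPair] = []
    for fs, fe, fseq, ftm, fgc in fwd:
        for rs, re_, rseq, rtm, rgc in rev:
            product = re_ - fs + 1
            if not params.product_range[0] <= product <= params.product_range[1]:
                continue
            if abs(ftm - rtm) > params.max_pair_tm_diff:
                continue
            score = (
                PENALTY_LEN * (abs(len(fseq) - params.len_opt)
                               + abs(len(rseq) - params.len_opt))
                + PENALTY_TM * (abs(ftm - params.tm_opt) + abs(rtm - params.tm_opt))
                + PENALTY_GC * (abs(fgc - 50.0) + abs(rgc - 50.0))
                + PENALTY_PRODUCT * abs(product - mid_product)
            )
            pairs.append(PrimerPair(
                locus_id=template.locus_id,
                forward=fseq, reverse=rseq,
                fwd_start=fs, fwd_end=fe, rev_start=rs, rev_end=re_,
                tm_f=ftm, tm_r=rtm, gc_f=fgc, gc_r=rgc,
                product_size=product, score=score,
            ))
    if not pairs:
        return [], "no_feasible_pair"
    pairs.sort(key=lambda p: (p.score, p.fwd_start, p.rev_end))
    return pairs[: params.pairs_per_locus], None


def has_homopolymer(seq: str, max_run: int = 3) -> bool:
    """True if *seq* contains a mononucleotide run longer than *max_run*."""
    run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        if run > max_run:
            return True
    return False


def _has_di_run(seq: str, copies: int = 3) -> bool:
    for i in range(len(seq) - 2 * copies + 1):
        unit = seq[i : i + 2]
        if unit[0] == unit[1]:
            continue
        if seq[i : i + 2 * copies] == unit * copies:
            return True
    return False


def filter_primer_pairs(
    pairs: Sequence[PrimerPair],
    params: PrimerParams | None = None,
    reject_di_runs: bool = False,
) -> tuple[list[PrimerPair], dict[str, int]]:
    """Post-design rejection: short products, homopolymer runs of
    ``max_homopolymer + 1`` or more in either primer, or primer GC outside
    the ``reject_gc_outside`` band.  A pair failing several rules is tallied
    under the first one; tally counts + accepted = input."""
    params = params or PrimerParams()
    lo_gc, hi_gc = params.reject_gc_outside
    accepted: list[PrimerPair] = []
    tally = {"short_product": 0, "homopolymer": 0, "extreme_gc": 0,
             "dinucleotide_run": 0}
    for p in pairs:
        if p.product_size < params.product_range[0]:
            tally["short_product"] += 1
        elif has_homopolymer(p.forward, params.max_homopolymer) or \
                has_homopolymer(p.reverse, params.max_homopolymer):
            tally["homopolymer"] += 1
        elif not (lo_gc <= p.gc_f <= hi_gc) or not (lo_gc <= p.gc_r <= hi_gc):
            tally["extreme_gc"] += 1
        elif reject_di_runs and (_has_di_run(p.forward) or _has_di_run(p.reverse)):
            tally["dinucleotide_run"] += 1
        else:
            accepted.append(p)
    return accepted, tally


PRIMER_COLUMNS = [
    "primer_id", "locus_id", "forward", "reverse", "tm_f", "tm_r",
    "gc_f", "gc_r", "product_size", "score",
]


def write_primer_tsv(pairs: Sequence[PrimerPair], path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(PRIMER_COLUMNS)
        for i, p in enumerate(pairs, 1):
            w.writerow([
                f"{p.locus_id}_p{i}", p.locus_id, p.forward, p.reverse,
                f"{p.tm_f:.2f}", f"{p.tm_r:.2f}", f"{p.gc_f:.1f}",
                f"{p.gc_r:.1f}", p.product_size, f"{p.score:.3f}",
            ])
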