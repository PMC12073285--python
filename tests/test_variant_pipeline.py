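"""Long-InDel extraction, QC rules, locus collapsing and candidate selection."""

import numpy as np
import pytest

from conftest import make_matrix
from ssrmine.variant_pipeline import (
    QCThresholds,
    SSRLocus,
    VariantRecord,
    apply_qc,
    collapse_to_loci,
    extract_long_indels,
    filter_locus_classes,
    genotype_frequencies,
    mine_variant_ssrs,
    select_candidates,
)


def rec(ref="A", alts=("A" + "TA" * 6,), qual=100.0, n=4, gq=90, dp=30,
        gts=None):
    gts = gts or [(0, 1)] * n
    return VariantRecord(
        chrom="scaffold_1", pos=500, ref=ref, alts=tuple(alts), qual=qual,
        genotypes=list(gts),
        gq=np.full(len(gts), float(gq)), dp=np.full(len(gts), float(dp)),
    )


# ---------------------------------------------------------------------------
# long-InDel extraction
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "ref, alt, kept",
    [
        ("A", "A" + "TA" * 6, True),   # +12 nt insertion
        ("A", "A" + "T" * 10, False),  # exactly +10: strict inequality
        ("A" + "T" * 11, "A", True),   # -11 nt deletion
        ("A", "G", False),             # SNP
    ],
)
def test_long_indel_rule(ref, alt, kept):
    out = list(extract_long_indels([rec(ref=ref, alts=(alt,))]))
    assert bool(out) is kept


def test_malformed_alleles_skipped_with_warning(caplog):
    out = list(extract_long_indels([rec(alts=("<DEL>",))]))
    assert out == []


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def test_site_qual_strictly_above_threshold():
    passed, tally = apply_qc([rec(qual=39.9)])
    assert passed == [] and tally["qual"] == 1
    passed, tally = apply_qc([rec(qual=40.0)])
    assert passed == [] and tally["qual"] == 1  # strict >
    passed, _ = apply_qc([rec(qual=40.1)])
    assert len(passed) == 1


@pytest.mark.parametrize("dp, masked", [(5, False), (100, False), (4, True), (101, True)])
def test_dp_bounds_inclusive(dp, masked):
    r = rec(n=1, dp=dp)
    passed, _ = apply_qc([r])
    call = passed[0].genotypes[0] if passed else None
    if masked:
        # single masked call -> 100% missing and monomorphic MAF 0 passes
        # the "lt" MAF arm, so the site survives with the call missing
        assert call == (-1, -1)
    else:
        assert call == (0, 1)


def test_gq_strictly_above_threshold():
    passed, _ = apply_qc([rec(n=1, gq=40)])
    assert passed[0].genotypes[0] == (-1, -1)
    passed, _ = apply_qc([rec(n=1, gq=41)])
    assert passed[0].genotypes[0] == (0, 1)


def test_maf_missing_disjunction_litteral_mode():
    """60 samples, 4 missing (6.7%) and MAF 0.3: fails both arms under
    maf_mode='lt' and is rejected."""
    gts = [(0, 1)] * 36 + [(0, 0)] * 20 + [(-1, -1)] * 4
    gq = np.r_[np.full(56, 90.0), np.full(4, 10.0)]
    r = VariantRecord("s", 1, "A", ("A" + "T" * 12,), 100.0, gts,
                      gq=gq, dp=np.full(60, 30.0))
    passed, tally = apply_qc([r], QCThresholds(maf_mode="lt"))
    assert passed == [] and tally["maf_or_missing"] == 1
    # conventional mode keeps the common variant despite the missingness
    passed, _ = apply_qc([r], QCThresholds(maf_mode="ge"))
    assert len(passed) == 1


def test_qc_tally_accounts_for_every_rejection():
    recs = [rec(qual=10), rec(qual=100), rec(qual=50)]
    passed, tally = apply_qc(recs)
    assert len(passed) + sum(tally.values()) == len(recs)


def test_missing_gq_dp_fields_warn_and_mask():
    r = VariantRecord("s", 1, "A", ("A" + "T" * 12,), 100.0, [(0, 1)] * 3,
                      gq=None, dp=None)
    with pytest.warns(UserWarning):
        passed, _ = apply_qc([r])
    assert all(g == (-1, -1) for g in passed[0].genotypes)


# ---------------------------------------------------------------------------
# mining and collapsing
# ---------------------------------------------------------------------------

def test_mine_variant_ssrs_annotates_source_site():
    r = rec(alts=("A" + "AT" * 7,))
    (cand,) = mine_variant_ssrs([r])
    assert (cand.chrom, cand.pos) == ("scaffold_1", 500)
    assert cand.hit.motif in ("AT", "TA")


def test_allele_without_repeat_yields_no_candidate():
    r = rec(alts=("A" + "GATCGTACGGT" * 2,))
    assert mine_variant_ssrs([r]) == []


def test_two_repeat_bearing_alts_both_contribute():
    r = rec(alts=("A" + "AT" * 7, "A" + "AT" * 9))
    cands = mine_variant_ssrs([r])
    assert len(cands) == 2
    loci = collapse_to_loci(cands)
    assert len(loci) == 1
    assert loci[0].n_supporting_sequences == 2


def test_collapse_uses_chrom_pos_key_and_majority_motif():
    from ssrmine.repeat_miner import SSRHit
    from ssrmine.variant_pipeline import LocusCandidate

    cands = [
        LocusCandidate("Scaffold_5532", 102997041, SSRHit("x", 1, 12, "CA", 6)),
        LocusCandidate("Scaffold_5532", 102997041, SSRHit("x", 1, 14, "CA", 7)),
        LocusCandidate("Scaffold_5532", 102997041, SSRHit("x", 1, 12, "AC", 6)),
    ]
    (locus,) = collapse_to_loci(cands)
    assert locus.locus_id == "Scaffold_5532_102997041"
    assert locus.n_supporting_sequences == 3
    assert locus.motif == "CA"


def test_distinct_keys_stay_distinct():
    from ssrmine.repeat_miner import SSRHit
    from ssrmine.variant_pipeline import LocusCandidate

    cands = [
        LocusCandidate("s1", p, SSRHit("x", 1, 12, "CA", 6)) for p in (10, 20, 30)
    ]
    assert len(collapse_to_loci(cands)) == 3


# ---------------------------------------------------------------------------
# class filters
# ---------------------------------------------------------------------------

def _locus(locus_id, chrom, pos, motif, compound=False):
    return SSRLocus(locus_id, chrom, pos, motif, 1,
                    mononucleotide=len(motif) == 1, compound=compound)


def test_filter_drops_mono_and_compound_keeps_isolated():
    loci = [
        _locus("a", "c1", 100, "A"),          # mono -> dropped
        _locus("b", "c1", 5000, "AT"),        # di pair 50 bp apart
        _locus("c", "c1", 5050, "GA"),        # -> both compound
        _locus("d", "c1", 9000, "ATG"),       # isolated tri -> kept
    ]
    kept = filter_locus_classes(loci)
    assert [l.locus_id for l in kept] == ["d"]


def test_filter_is_idempotent_and_order_preserving():
    loci = [_locus(f"l{i}", "c1", 1000 * (i + 1), "ATG") for i in range(5)]
    once = filter_locus_classes(loci)
    assert [l.locus_id for l in once] == [f"l{i}" for i in range(5)]
    assert [l.locus_id for l in filter_locus_classes(once)] == \
        [l.locus_id for l in once]


# ---------------------------------------------------------------------------
# genotype frequencies and candidate selection
# ---------------------------------------------------------------------------

def test_genotype_frequencies_hand_count():
    m = make_matrix({"L1": [(180, 180), (180, 180), (180, 184), (184, 184)]})
    s = genotype_frequencies(m, "L1")
    assert s.ranked == (0.5, 0.25, 0.25)
    assert s.n_genotyped == 4


def test_monomorphic_locus_single_genotype():
    m = make_matrix({"L1": [(180, 180)] * 5})
    assert genotype_frequencies(m, "L1").ranked == (1.0,)


def test_all_missing_locus_errors():
    m = make_matrix({"L1": [(0, 0)] * 3})
    with pytest.raises(ValueError):
        genotype_frequencies(m, "L1")


def test_frequencies_sum_to_one(rng):
    calls = [tuple(sorted(rng.integers(180, 190, size=2))) for _ in range(50)]
    m = make_matrix({"L1": calls})
    s = genotype_frequencies(m, "L1")
    assert sum(s.ranked) == pytest.approx(1.0, abs=1e-9)
    assert all(a >= b for a, b in zip(s.ranked, s.ranked[1:]))


@pytest.mark.parametrize(
    "ranked, kept",
    [((1.0,), False), ((0.53, 0.47), True), ((0.97, 0.03), False)],
)
def test_secondary_common_genotype_rule(ranked, kept):
    from ssrmine.variant_pipeline import GenotypeFrequencySummary

    locus = _locus("x", "c1", 1, "ATG")
    summaries = {"x": GenotypeFrequencySummary("x", ranked, 100)}
    out = select_candidates([locus], summaries)
    assert (len(out) == 1) is kept
    assert locus.has_secondary_genotype is kept
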