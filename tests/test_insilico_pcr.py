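import numpy as np
import pytest

from bathygap.insilico_pcr import (
    DEFAULT_PRIMERS,
    MARKER_FAMILIES,
    AmpliconHit,
    PrimerPair,
    aggregate_species,
    count_mismatches,
    encode,
    find_primer_sites,
    reverse_complement,
    run_insilico_pcr,
)
from bathygap.io_formats import ReferenceSequence
from oracles import brute_force_pcr, rc, scan


def _embed(fwd_site, insert, rev_site, rng, flank=60):
    """Template: flank + fwd site + insert + revcomp(rev site) + flank."""
    bases = np.array(list("ACGT"))
    left = "".join(rng.choice(bases, flank))
    right = "".join(rng.choice(bases, flank))
    return left + fwd_site + insert + reverse_complement(rev_site) + right, flank


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "seq,expected",
    [("ACGT", "ACGT"), ("AAAC", "GTTT"), ("ARN", "NYT"), ("A", "T")],
)
def test_reverse_complement(seq, expected):
    assert reverse_complement(seq) == expected


def test_reverse_complement_is_involution(rng):
    s = "".join(rng.choice(list("ACGTRYSWKMBDHVN"), 500))
    assert reverse_complement(reverse_complement(s)) == s


def test_encode_rejects_non_iupac():
    with pytest.raises(ValueError):
        encode("ACGT-")


def test_count_mismatches_iupac_sets():
    assert count_mismatches("ACGT", "ACGT") == 0
    assert count_mismatches("R", "A") == 0  # R = {A, G}
    assert count_mismatches("R", "G") == 0
    assert count_mismatches("R", "C") == 1
    assert count_mismatches("N", "C") == 0  # N matches everything
    assert count_mismatches("ACGT", "TGCA") == 4
    with pytest.raises(ValueError):
        count_mismatches("ACGT", "ACG")


def test_mifish_u_and_e_primers_differ_as_published():
    u, e = DEFAULT_PRIMERS["MiFish-U"], DEFAULT_PRIMERS["MiFish-E"]
    assert count_mismatches(u.reverse, e.reverse) == 1
    assert count_mismatches(u.forward, e.forward) == 2
    assert MARKER_FAMILIES["MiFish-U"] == MARKER_FAMILIES["MiFish-E"] == "MiFish"


def test_primer_pair_validation():
    with pytest.raises(ValueError):
        PrimerPair("m", "ACGT", "ACGTACGTACGT")  # forward too short
    with pytest.raises(ValueError):
        PrimerPair("m", "ACGTACGTACGT", "ACGTACGTACGT", max_mismatch=-1)
    with pytest.raises(ValueError):
        PrimerPair("m", "ACGTACGTACGT", "ACGTACGTACGT",
                   insert_min_bp=10, insert_max_bp=5)


# ---------------------------------------------------------------------------
# site finding
# ---------------------------------------------------------------------------


def test_find_primer_sites_exact_and_mismatched(rng):
    primer = "ACACCGCCCGTCACTCT"
    seq, flank = _embed(primer, "A" * 40, "CTTCCGGTACACTTACCATG", rng)
    sites = find_primer_sites(seq, primer, 0)
    assert (flank, 0) in sites
    # three substitutions found at cap 3, not at cap 2
    mutated = list(primer)
    mutated[0], mutated[5], mutated[10] = "T", "T", "A"
    seq2 = seq[:flank] + "".join(mutated) + seq[flank + len(primer):]
    assert (flank, 3) in find_primer_sites(seq2, primer, 3)
    assert all(s != flank for s, _ in find_primer_sites(seq2, primer, 2))


def test_find_primer_sites_short_sequence():
    assert find_primer_sites("ACG", "ACGTACGTACGT", 3) == []


def test_find_primer_sites_against_naive_scan(rng):
    primer = DEFAULT_PRIMERS["teleo"].forward
    for _ in range(50):
        seq = "".join(rng.choice(list("ACGT"), int(rng.integers(30, 400))))
        for cap in range(4):
            got = dict(find_primer_sites(seq, primer, cap))
            assert got == scan(seq, primer, cap)


# ---------------------------------------------------------------------------
# amplicon search
# ---------------------------------------------------------------------------


def test_run_insilico_pcr_constructed_hit(rng):
    pair = DEFAULT_PRIMERS["teleo"]
    insert = "".join(rng.choice(list("ACGT"), 60))
    seq, flank = _embed(pair.forward, insert, pair.reverse, rng)
    hits = run_insilico_pcr(ReferenceSequence("s", "sp", seq), pair)
    plus = [h for h in hits if h.strand == "+"]
    assert len(plus) == 1
    h = plus[0]
    assert h.fwd_start == flank
    assert h.fwd_end == flank + len(pair.forward)
    assert h.rev_start == h.fwd_end + 60
    assert (h.fwd_mismatches, h.rev_mismatches) == (0, 0)
    assert h.insert_sequence == insert
    assert h.insert_length_bp == 60


def test_run_insilico_pcr_insert_bounds(rng):
    pair = DEFAULT_PRIMERS["teleo"]  # insert bounds [30, 120]
    for n, expect in [(29, 0), (30, 1), (120, 1), (121, 0)]:
        insert = "".join(rng.choice(list("ACGT"), n))
        seq, _ = _embed(pair.forward, insert, pair.reverse, rng)
        hits = [h for h in run_insilico_pcr(ReferenceSequence("s", "sp", seq), pair)
                if h.strand == "+"]
        assert len(hits) == expect, f"insert {n} bp"


def test_run_insilico_pcr_strand_symmetry(rng):
    pair = DEFAULT_PRIMERS["MiFish-U"]
    insert = "".join(rng.choice(list("ACGT"), 170))
    seq, _ = _embed(pair.forward, insert, pair.reverse, rng)
    fwd_rec = ReferenceSequence("s", "sp", seq)
    rev_rec = ReferenceSequence("s", "sp", reverse_complement(seq))
    key = lambda h: (h.fwd_mismatches, h.rev_mismatches, h.insert_sequence)
    assert sorted(map(key, run_insilico_pcr(fwd_rec, pair))) == sorted(
        map(key, run_insilico_pcr(rev_rec, pair))
    )


def test_run_insilico_pcr_threshold_monotonicity(rng):
    base = DEFAULT_PRIMERS["teleo"]
    mutated = "T" + base.forward[1:-1] + base.forward[-1]  # 1 substitution
    insert = "".join(rng.choice(list("ACGT"), 80))
    seq, _ = _embed(mutated, insert, base.reverse, rng)
    rec = ReferenceSequence("s", "sp", seq)
    prev: set = set()
    for cap in range(4):
        pair = PrimerPair(base.marker, base.forward, base.reverse, cap,
                          base.insert_min_bp, base.insert_max_bp)
        now = {(h.fwd_start, h.rev_start, h.strand) for h in run_insilico_pcr(rec, pair)}
        assert prev <= now  # raising the cap never removes a hit
        prev = now


def test_run_insilico_pcr_matches_oracle_on_fuzzed_sequences(rng):
    pair = DEFAULT_PRIMERS["teleo"]
    for i in range(30):
        seq = "".join(rng.choice(list("ACGT"), int(rng.integers(60, 500))))
        if i % 2:  # plant a (possibly over-mutated) template in half the cases
            site = list(pair.forward)
            for j in rng.choice(len(site), int(rng.integers(0, 5)), replace=False):
                site[j] = str(rng.choice(list("ACGT")))
            insert = "".join(rng.choice(list("ACGT"), int(rng.integers(25, 130))))
            seq, _ = _embed("".join(site), insert, pair.reverse, rng)
        rec = ReferenceSequence("s", "sp", seq)
        got = {
            (h.fwd_start, h.rev_start, h.strand, h.fwd_mismatches,
             h.rev_mismatches, h.insert_sequence)
            for h in run_insilico_pcr(rec, pair)
        }
        want = brute_force_pcr(seq, pair.forward, pair.reverse,
                               pair.max_mismatch, pair.insert_min_bp,
                               pair.insert_max_bp)
        assert got == want


def test_zero_hits_is_valid(rng):
    seq = "".join(rng.choice(list("ACGT"), 300))
    rec = ReferenceSequence("s", "sp", seq)
    for pair in DEFAULT_PRIMERS.values():
        assert isinstance(run_insilico_pcr(rec, pair), list)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def _hit(seq_id, sp, marker, fmm, rmm, fwd_start=0, rev_start=100):
    return AmpliconHit(seq_id, sp, marker, "+", fwd_start, fwd_start + 17,
                       rev_start, rev_start + 20, fmm, rmm, "A" * 60)


def test_aggregate_conservative_maxima_across_sequences():
    # two sequences of one species: per-primer maxima taken independently
    hits = [_hit("s1", "sp1", "teleo", 0, 2), _hit("s2", "sp1", "teleo", 1, 0)]
    (amp,) = [a for a in aggregate_species(hits, ["sp1"], ["teleo"])]
    assert amp.amplified and amp.source == "in_silico"
    assert (amp.cons_fwd_mismatches, amp.cons_rev_mismatches) == (1, 2)


def test_aggregate_representative_is_minimal_per_sequence():
    # one sequence with two hits: totals 2 vs 1 -> the (1, 0) hit represents it
    hits = [_hit("s1", "sp1", "teleo", 0, 2), _hit("s1", "sp1", "teleo", 1, 0,
                                                    fwd_start=5, rev_start=105)]
    (amp,) = aggregate_species(hits, ["sp1"], ["teleo"])
    assert (amp.cons_fwd_mismatches, amp.cons_rev_mismatches) == (1, 0)


def test_aggregate_custom_db_and_absent():
    amps = aggregate_species(
        [], ["sp1", "sp2"], ["teleo", "MiFish-U"],
        custom_db={("sp1", "MiFish-U")},
    )
    by = {(a.species_id, a.marker): a for a in amps}
    custom = by[("sp1", "MiFish-U")]
    assert custom.amplified and custom.source == "custom_db"
    assert custom.cons_fwd_mismatches is None  # unknown mismatches
    assert not by[("sp1", "teleo")].amplified
    assert not by[("sp2", "MiFish-U")].amplified


def test_aggregate_ignores_species_outside_pool():
    amps = aggregate_species([_hit("s1", "ghost", "teleo", 0, 0)], ["sp1"], ["teleo"])
    assert len(amps) == 1 and not amps[0].amplified
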