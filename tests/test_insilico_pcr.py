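import random
from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st

import naive_pcr
from primerval import (
    PrimerPair,
    ReferenceRecord,
    amplify,
    amplify_db,
    designate_hit,
    find_binding_sites,
    iupac_mismatches,
    reverse_complement,
)

from conftest import make_lineage, mutate_positions, random_seq

IUPAC = "ACGTRYSWKMBDHVN"


def hit_tuple(h):
    return (h.strand, h.fwd_start, h.fwd_end, h.rev_start, h.rev_end,
            h.mismatches_fwd, h.mismatches_rev, h.metabarcode)


class TestIupacMismatches:
    def test_identity_is_zero(self):
        assert iupac_mismatches("GTACACACCGCCCGTC", "GTACACACCGCCCGTC") == 0

    def test_degenerate_set_semantics(self):
        # S = {C,G}: intersects C, not A
        assert iupac_mismatches("S", "C") == 0
        assert iupac_mismatches("S", "A") == 1

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            iupac_mismatches("ACGT", "ACG")

    @settings(max_examples=1000, derandomize=True, deadline=None)
    @given(st.tuples(st.text(IUPAC, min_size=18, max_size=18),
                     st.text(IUPAC, min_size=18, max_size=18)))
    def test_equals_set_intersection_oracle(self, pair):
        primer, window = pair
        assert iupac_mismatches(primer, window) == \
            naive_pcr.mismatches(primer, window)


class TestFindBindingSites:
    def test_planted_verbatim_site_found(self, euka02):
        rng = random.Random(0)
        seq = random_seq(rng, 100) + euka02.forward.replace(
            "S", "C").replace("R", "A") + random_seq(rng, 100)
        sites = find_binding_sites(seq, euka02.forward, 0)
        assert (100, 100 + len(euka02.forward), 0) in sites

    def test_site_with_four_substitutions_absent_at_budget_three(self):
        rng = random.Random(1)
        primer = "GTACACACCGCCCGTC"
        planted = mutate_positions(rng, primer, 4)
        seq = random_seq(rng, 80) + planted + random_seq(rng, 80)
        sites = find_binding_sites(seq, primer, 3)
        assert all(s != 80 for s, _, _ in sites)

    def test_matches_naive_all_windows_scan(self):
        rng = random.Random(2)
        for trial in range(25):
            seq = random_seq(rng, rng.randint(60, 400))
            primer = "".join(rng.choice(IUPAC) for _ in range(18))
            for budget in (0, 3):
                assert find_binding_sites(seq, primer, budget) == \
                    naive_pcr.sites(seq, primer, budget)

    def test_ascending_start_order(self):
        rng = random.Random(3)
        seq = random_seq(rng, 500)
        starts = [s for s, _, _ in find_binding_sites(seq, "NNNNNNNNNN", 0)]
        assert starts == sorted(starts)


class TestAmplify:
    def make_record(self, pair, gap, rng, fwd_mm=0, rev_mm=0):
        fwd = mutate_positions(
            rng, "".join(rng.choice(sorted(naive_pcr.SETS[c]))
                         for c in pair.forward), fwd_mm)
        rev = mutate_positions(
            rng, "".join(rng.choice(sorted(naive_pcr.SETS[c]))
                         for c in pair.reverse), rev_mm)
        region = random_seq(rng, gap)
        seq = random_seq(rng, 40) + fwd + region + \
            reverse_complement(rev) + random_seq(rng, 40)
        return ReferenceRecord("t", seq, make_lineage()), region

    def test_constructed_template_single_exact_hit(self, euka02):
        rng = random.Random(4)
        record, region = self.make_record(euka02, 200, rng)
        hits = amplify(record, euka02, 3)
        plus = [h for h in hits if h.strand == "+"]
        assert len(plus) == 1
        (h,) = plus
        assert h.metabarcode == region and h.amplicon_len == 200
        assert (h.mismatches_fwd, h.mismatches_rev) == (0, 0)

    def test_length_bounds_exclude_hit(self, euka02):
        rng = random.Random(4)
        record, _ = self.make_record(euka02, 200, rng)
        narrow = PrimerPair(euka02.name, euka02.forward, euka02.reverse,
                            300, 700)
        assert amplify(record, narrow, 3) == []

    def test_matches_bruteforce_on_random_planted_templates(self, euka02):
        rng = random.Random(5)
        for trial in range(100):
            record, _ = self.make_record(
                euka02, rng.randint(20, 450), rng,
                fwd_mm=rng.randint(0, 4), rev_mm=rng.randint(0, 4))
            got = sorted(hit_tuple(h) for h in amplify(record, euka02, 3))
            expected = sorted(naive_pcr.amplify(
                record.sequence, euka02.forward, euka02.reverse,
                euka02.min_len, euka02.max_len, 3))
            assert got == expected

    def test_hits_satisfy_their_invariants(self, panel):
        rng = random.Random(6)
        for pair in panel:
            record, _ = self.make_record(
                pair, rng.randint(pair.min_len, min(pair.max_len, 600)),
                rng, fwd_mm=rng.randint(0, 3), rev_mm=rng.randint(0, 3))
            for h in amplify(record, pair, 3):
                assert pair.min_len <= h.amplicon_len <= pair.max_len
                assert h.mismatches_fwd <= 3 and h.mismatches_rev <= 3
                if h.strand == "+":
                    assert h.fwd_end <= h.rev_start
                else:
                    assert h.rev_end <= h.fwd_start

    def test_monotone_in_budget_and_bounds(self, euka02):
        rng = random.Random(7)
        record, _ = self.make_record(euka02, 150, rng, fwd_mm=2, rev_mm=1)
        for lo_budget in range(3):
            narrow = set(map(hit_tuple, amplify(record, euka02, lo_budget)))
            wide = set(map(hit_tuple, amplify(record, euka02, lo_budget + 1)))
            assert narrow <= wide
        tight = PrimerPair("t", euka02.forward, euka02.reverse, 100, 200)
        loose = PrimerPair("t", euka02.forward, euka02.reverse, 50, 400)
        assert set(map(hit_tuple, amplify(record, tight, 3))) <= \
            set(map(hit_tuple, amplify(record, loose, 3)))

    def test_strand_symmetry_of_metabarcodes(self, euka02):
        rng = random.Random(8)
        record, _ = self.make_record(euka02, 120, rng)
        flipped = ReferenceRecord(
            "t", reverse_complement(record.sequence), record.lineage)
        assert Counter(h.metabarcode for h in amplify(record, euka02, 3)) \
            == Counter(h.metabarcode for h in amplify(flipped, euka02, 3))

    def test_negative_budget_rejected(self, euka02, toy_records):
        with pytest.raises(ValueError):
            amplify(toy_records[0], euka02, -1)


class TestAmplifyDb:
    def test_empty_db_empty_result(self, euka02):
        result = amplify_db([], euka02, 3)
        assert result.hits == {} and result.n_total == 0

    def test_all_exact_sites_all_amplified(self, euka02):
        rng = random.Random(9)
        helper = TestAmplify()
        records = [
            ReferenceRecord(f"r{i}", helper.make_record(
                euka02, 100 + i, rng)[0].sequence, make_lineage())
            for i in range(10)
        ]
        result = amplify_db(records, euka02, 3)
        assert result.n_amplified == 10
        assert all(result.is_amplified(r.record_id) for r in records)

    def test_designated_hit_is_shortest_then_leftmost(self, euka02):
        rng = random.Random(10)
        helper = TestAmplify()
        rec, _ = helper.make_record(euka02, 120, rng)
        hits = amplify(rec, euka02, 3)
        chosen = designate_hit(hits)
        best = min(h.amplicon_len for h in hits)
        assert chosen.amplicon_len == best
        assert chosen.fwd_start == min(
            h.fwd_start for h in hits if h.amplicon_len == best)
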