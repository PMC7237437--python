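import math
import random

import numpy as np
import pytest

from smithrna.energy import duplex_energy
from smithrna.genome import reverse_complement
from smithrna.targets import (
    SeedMatch,
    Thresholds,
    UTRRecord,
    accessibility_ddG,
    count_matches,
    evaluate_targets,
    seed_scan,
)


def _rand(n, rng):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(17)


class TestSeedScan:
    def test_planted_seed_complement_found(self):
        centroid = "AAAGCTACGTAAAAAAAAAAA"  # nt 4-10 = GCTACGT
        utr = UTRRecord("u", "TTTTT" + reverse_complement("GCTACGT") + "TTTTT")
        hits = seed_scan(centroid, utr)
        assert [(h.start, h.end) for h in hits] == [(6, 12)]

    def test_full_reverse_complement_has_one_site(self, rng):
        c = _rand(22, rng)
        utr = UTRRecord("u", reverse_complement(c))
        assert len(seed_scan(c, utr)) == 1

    def test_matches_brute_force_substring_scan(self, rng):
        c = _rand(22, rng)
        motif = reverse_complement(c[3:10])
        utr_seq = _rand(1000, rng)
        expected = [i + 1 for i in range(len(utr_seq) - 6)
                    if utr_seq[i : i + 7] == motif]
        got = [h.start for h in seed_scan(c, UTRRecord("u", utr_seq))]
        assert got == expected

    def test_short_centroid_rejected(self):
        with pytest.raises(ValueError):
            seed_scan("ACGTACGTA", UTRRecord("u", "ACGT" * 10))

    def test_rna_input_normalized(self):
        centroid = "AAAGCUACGUAAAAAAAAAAA"
        utr = UTRRecord("u", "TTTTTACGTAGCTTTTT")
        assert len(seed_scan(centroid, utr)) == 1


class TestCountMatches:
    def test_perfect_complement_counts_full_length(self, rng):
        c = _rand(22, rng)
        utr_seq = _rand(60, rng) + reverse_complement(c) + _rand(60, rng)
        utr = UTRRecord("u", utr_seq)
        (sm,) = seed_scan(c, utr)
        assert count_matches(c, utr, sm) == 22

    def test_seed_only_plant_stays_below_threshold(self, rng):
        # complement only at the seed: chance matches elsewhere stay < 11
        for _ in range(10):
            c = _rand(22, rng)
            utr_seq = _rand(80, rng) + reverse_complement(c[3:10]) + _rand(80, rng)
            utr = UTRRecord("u", utr_seq)
            for sm in seed_scan(c, utr):
                assert count_matches(c, utr, sm) < 11

    def test_constructed_boundary_instance(self, rng):
        # exactly 11 complementary positions in the best gapless offset:
        # seed (7) + 4 adjacent complementary bases, then junk that can't pair
        c = _rand(22, rng)
        partial = reverse_complement(c[3:14])  # complements centroid nt 4-14
        utr_seq = "T" * 40 + partial + "T" * 40
        # make flanking T runs unable to extend the alignment: centroid
        # positions 1-3 and 15-22 set to T so they mismatch the A complement
        c2 = "TTT" + c[3:14] + "T" * 8
        utr = UTRRecord("u", "T" * 40 + reverse_complement(c2[3:14]) + "T" * 40)
        (sm,) = seed_scan(c2, utr)
        assert count_matches(c2, utr, sm) == 11

    def test_enumeration_oracle_on_small_windows(self, rng):
        # brute force over all offsets and segments must agree
        def oracle(c, utr_seq, sm):
            margin = len(c) + 30
            lo = max(1, sm.start - margin)
            hi = min(len(utr_seq), sm.end + margin)
            wrc = reverse_complement(utr_seq[lo - 1 : hi])
            s_lo, s_hi = hi - sm.end, hi - sm.start
            best = (-10**9, 0)
            for off in range(-(len(c) - 1), len(wrc)):
                a, b = max(0, -off), min(len(c), len(wrc) - off)
                if a >= b or off + a > s_lo or off + b - 1 < s_hi:
                    continue
                cols = [1 if c[i] == wrc[i + off] else -3 for i in range(a, b)]
                rel_lo, rel_hi = s_lo - off - a, s_hi - off - a
                for i in range(0, rel_lo + 1):
                    for j in range(rel_hi, len(cols)):
                        sc = sum(cols[i : j + 1])
                        nm = cols[i : j + 1].count(1)
                        if sc > best[0]:
                            best = (sc, nm)
            return best[1]

        for _ in range(5):
            c = _rand(20, rng)
            utr_seq = _rand(50, rng) + reverse_complement(c[3:10]) + _rand(50, rng)
            utr = UTRRecord("u", utr_seq)
            for sm in seed_scan(c, utr):
                assert count_matches(c, utr, sm) == oracle(c, utr_seq, sm)


class TestAccessibility:
    def test_unstructured_utr_has_zero_opening_cost(self):
        utr = UTRRecord("u", "A" * 200)
        sm = SeedMatch("u", 100, 106)
        assert accessibility_ddG(utr, sm, -25.0) == pytest.approx(-25.0)

    def test_site_inside_hairpin_stem_costs_energy(self, rng):
        stem = _rand(20, rng)
        hairpin = stem + "AAAA" + reverse_complement(stem)
        utr_seq = _rand(50, rng) + hairpin + _rand(50, rng)
        utr = UTRRecord("u", utr_seq)
        sm = SeedMatch("u", 51, 57)  # inside the 5' stem arm
        ddg = accessibility_ddG(utr, sm, -25.0)
        assert ddg > -25.0  # dG_open > 0

    def test_opening_cost_nonnegative_for_any_input(self, rng):
        for _ in range(5):
            utr = UTRRecord("u", _rand(150, rng))
            sm = SeedMatch("u", 70, 76)
            assert accessibility_ddG(utr, sm, -20.0) >= -20.0

    def test_window_truncated_at_boundaries(self, rng):
        utr = UTRRecord("u", _rand(60, rng))  # shorter than the fold window
        sm = SeedMatch("u", 10, 16)
        assert math.isfinite(accessibility_ddG(utr, sm, -25.0))


class TestEvaluateTargets:
    def test_planted_perfect_complement_passes_all_gates(self, rng):
        c = _rand(22, rng)
        utr = UTRRecord("u", _rand(150, rng) + reverse_complement(c) + _rand(150, rng))
        hits = evaluate_targets(c, [utr])
        assert len(hits) == 1
        h = hits[0]
        assert h.n_matches == 22 and h.dg_duplex < -20 and h.ddg < -9
        assert all(h.flags.values())

    def test_output_is_subset_of_seed_scan(self, rng):
        c = _rand(22, rng)
        utrs = [UTRRecord(f"u{i}", _rand(400, rng)) for i in range(20)]
        utrs.append(UTRRecord("planted",
                              _rand(100, rng) + reverse_complement(c) + _rand(100, rng)))
        hits = evaluate_targets(c, utrs)
        seeded = {(u.id, s.start) for u in utrs for s in seed_scan(c, u)}
        assert {(h.utr_id, h.seed.start) for h in hits} <= seeded

    def test_threshold_monotonicity(self, rng):
        c = _rand(22, rng)
        utrs = [UTRRecord("planted",
                          _rand(100, rng) + reverse_complement(c) + _rand(100, rng))]
        base = evaluate_targets(c, utrs)
        stricter = [
            Thresholds(min_matches=23),
            Thresholds(max_ddg=-40.0),
            Thresholds(max_dg=-60.0),
        ]
        for th in stricter:
            assert len(evaluate_targets(c, utrs, th)) <= len(base)

    def test_insufficient_matches_excluded_despite_energy(self, rng):
        # perfect complement but min_matches above centroid length: no hits
        c = _rand(22, rng)
        utrs = [UTRRecord("u", _rand(80, rng) + reverse_complement(c) + _rand(80, rng))]
        assert evaluate_targets(c, utrs, Thresholds(min_matches=23)) == []

    def test_shuffled_utrs_yield_no_hits(self, rng):
        c = _rand(22, rng)
        base = list(_rand(100, rng) + reverse_complement(c) + _rand(100, rng))
        hits = 0
        for _ in range(30):
            rng.shuffle(base)
            hits += len(evaluate_targets(c, [UTRRecord("u", "".join(base))]))
        assert hits == 0

    def test_multiple_utrs_can_be_hit(self, rng):
        c = _rand(22, rng)
        utrs = [
            UTRRecord(f"u{i}", _rand(90, rng) + reverse_complement(c) + _rand(90, rng))
            for i in range(3)
        ]
        hits = evaluate_targets(c, utrs)
        assert {h.utr_id for h in hits} == {"u0", "u1", "u2"}

    def test_empty_utrome(self, rng):
        assert evaluate_targets(_rand(22, rng), []) == []


def test_perfect_site_beats_single_mismatch_variants(rng):
    # requirement-6 energy is strictly lowest for the exact complement
    c = _rand(22, rng)
    site = reverse_complement(c)
    e0 = duplex_energy(c, site)
    assert e0 < -20
    for pos in range(0, 22, 5):
        for b in "ACGT":
            if b == site[pos]:
                continue
            assert duplex_energy(c, site[:pos] + b + site[pos + 1:]) > e0
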