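import itertools
import random

import pytest

from ssforge.fixtures import CASE_PATTERNS, FixtureSpec, make_disulphide_fixture
from ssforge.loopdb import (ConnectivityPattern, build_loop_database,
                            classify_topology, load_database,
                            parse_connectivity, percent_identity,
                            save_database, search)


def brute_force_topology(pairing):
    """Independent oracle: enumerate the interval relation of every loop pair."""
    loops = sorted(tuple(sorted(p)) for p in pairing)
    if len(loops) < 2:
        return "independent"
    rels = set()
    for (a, b), (c, d) in itertools.combinations(loops, 2):
        if (a, b) > (c, d):
            (a, b), (c, d) = (c, d), (a, b)
        span1, span2 = set(range(a, b + 1)), set(range(c, d + 1))
        inter = span1 & span2
        if not inter:
            rels.add("independent")
        elif inter == span2 or inter == span1:
            rels.add("nested")
        else:
            rels.add("interlocked")
    return rels.pop() if len(rels) == 1 else "mixed"


class TestParseConnectivity:
    def test_three_bridge_cyclotide_pattern(self):
        pat = parse_connectivity("C4-C19, C9-C21, C14-C26")
        assert pat.canonical_offsets == (0, 5, 10, 15, 17, 22)
        assert set(pat.pairing) == {(4, 19), (9, 21), (14, 26)}

    def test_two_bridge_conotoxin_pattern(self):
        pat = parse_connectivity("C2-C10, C4-C11")
        assert pat.canonical_offsets == (0, 2, 8, 9)

    def test_cys_synonym_and_case_tolerance(self):
        assert parse_connectivity("cys2-CYS10 and c4-C11").cys_positions == \
            parse_connectivity("C2-C10, C4-C11").cys_positions

    def test_self_pair_is_an_error(self):
        with pytest.raises(ValueError, match="self-pair"):
            parse_connectivity("C1-C1")

    def test_duplicate_position_is_an_error(self):
        with pytest.raises(ValueError, match="more than one pair"):
            parse_connectivity("C2-C10, C2-C11")

    def test_garbage_is_an_error(self):
        with pytest.raises(ValueError, match="no 'Cn-Cm' pairs"):
            parse_connectivity("hello world")


class TestClassifyTopology:
    def test_loop_within_loop_is_nested(self):
        assert classify_topology(parse_connectivity("C11-C32, C15-C28")) == "nested"

    def test_interleaved_loops_are_interlocked(self):
        assert classify_topology(parse_connectivity("C2-C10, C4-C11")) == "interlocked"

    def test_disjoint_loops_are_independent(self):
        assert classify_topology(parse_connectivity("C2-C8, C12-C20")) == "independent"

    def test_single_bridge_is_independent(self):
        assert classify_topology(parse_connectivity("C3-C9")) == "independent"

    def test_three_bridge_pattern_against_brute_force(self):
        pat = parse_connectivity("C4-C19, C9-C21, C14-C26")
        assert classify_topology(pat) == brute_force_topology(pat.pairing)

    def test_agrees_with_brute_force_oracle_on_random_patterns(self):
        rng = random.Random(99)
        for _ in range(3000):
            n_bridges = rng.randint(1, 4)
            positions = rng.sample(range(1, 31), 2 * n_bridges)
            rng.shuffle(positions)
            pairing = [tuple(sorted(positions[2 * k:2 * k + 2]))
                       for k in range(n_bridges)]
            pat = ConnectivityPattern(tuple(sorted(positions)), tuple(pairing))
            assert classify_topology(pat) == brute_force_topology(pairing)

    def test_exhaustive_two_bridge_patterns(self):
        for positions in itertools.combinations(range(1, 13), 4):
            for pairing in ([(positions[0], positions[1]), (positions[2], positions[3])],
                            [(positions[0], positions[2]), (positions[1], positions[3])],
                            [(positions[0], positions[3]), (positions[1], positions[2])]):
                pat = ConnectivityPattern(positions, tuple(pairing))
                assert classify_topology(pat) == brute_force_topology(pairing)


class TestPercentIdentity:
    def test_identical_and_single_mismatch(self):
        assert percent_identity("ACDE", "ACDE") == 100.0
        assert percent_identity("ACDE", "ACDF") == 75.0

    def test_matches_character_counting_oracle(self):
        rng = random.Random(5)
        alphabet = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(300):
            n = rng.randint(1, 40)
            a = "".join(rng.choice(alphabet) for _ in range(n))
            b = "".join(rng.choice(alphabet) for _ in range(n))
            expected = 100.0 * sum(x == y for x, y in zip(a, b)) / n
            assert percent_identity(a, b) == pytest.approx(expected)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length mismatch"):
            percent_identity("AA", "AAA")


class TestBuildDatabase:
    def test_one_native_record_per_planted_bridge(self):
        structures = [make_disulphide_fixture(FixtureSpec(seed=s, positions=(3, 9)))
                      for s in range(5)]
        for k, st in enumerate(structures):
            st.id = f"FX{k}"
        db = build_loop_database(structures, include_modelled=False)
        native = [r for r in db.records if r.provenance == "native"]
        assert len(native) == 5
        assert all(r.loop_size == 7 for r in native)

    def test_loop_size_is_inclusive_span(self, toy_db):
        structures, _ = toy_db
        db = build_loop_database([structures[1]], include_modelled=False)
        sizes = sorted(r.loop_size for r in db.records)
        assert sizes == [14, 22]  # bridges (15,28) and (11,32)

    def test_grade_filter_monotone_in_record_count(self, toy_db):
        structures, _ = toy_db
        counts = []
        for grades in ("A", "AB", "ABC", "ABCD"):
            db = build_loop_database(structures[:2], frozenset(grades))
            counts.append(len(db.records))
        assert counts == sorted(counts)

    def test_unreadable_structure_is_skipped_with_warning(self, toy_db):
        structures, _ = toy_db
        with pytest.warns(UserWarning, match="skipping structure"):
            db = build_loop_database([object(), structures[0]],
                                     include_modelled=False)
        assert len(db.records) == 2


class TestSearch:
    def search_hits(self, db, pattern_text, **kw):
        return search(db, parse_connectivity(pattern_text), **kw)

    def test_planted_patterns_found_with_perfect_precision_recall(self, toy_db):
        structures, truth = toy_db
        db = build_loop_database(structures, include_modelled=False)
        for name, text in CASE_PATTERNS.items():
            hits = self.search_hits(db, text)
            got = {(h.source_id, h.chain, h.window_start) for h in hits}
            want = {(r.source_id, r.chain, r.window_start)
                    for r in truth[truth.pattern_name == name].itertuples()}
            assert got == want
            assert len(hits) == len(want)

    def test_never_planted_spacing_gives_zero_hits(self, toy_db):
        structures, _ = toy_db
        db = build_loop_database(structures, include_modelled=False)
        assert self.search_hits(db, "C2-C9, C4-C11") == []

    def test_hits_reproduce_query_offsets(self, toy_db):
        structures, _ = toy_db
        db = build_loop_database(structures, include_modelled=False)
        pat = parse_connectivity(CASE_PATTERNS["three-bridge"])
        for h in self.search_hits(db, CASE_PATTERNS["three-bridge"]):
            offsets = sorted({o for r in h.records
                              for o in (r.start_index - h.window_start,
                                        r.end_index - h.window_start)})
            assert tuple(offsets) == pat.canonical_offsets

    def test_identical_query_sequence_scores_100(self, toy_db):
        structures, _ = toy_db
        db = build_loop_database(structures, include_modelled=False)
        hits = self.search_hits(db, CASE_PATTERNS["nested-2b"])
        seq = hits[0].sequence
        query = "A" * 10 + seq  # window origin = first cysteine at position 11
        hits2 = self.search_hits(db, CASE_PATTERNS["nested-2b"],
                                 query_sequence=query)
        assert hits2[0].identity_pct == 100.0

    def test_insertion_order_invariance(self, toy_db):
        structures, _ = toy_db
        db1 = build_loop_database(structures, include_modelled=False)
        db2 = build_loop_database(structures[::-1], include_modelled=False)
        for text in CASE_PATTERNS.values():
            k1 = [h.rank_key for h in self.search_hits(db1, text)]
            k2 = [h.rank_key for h in self.search_hits(db2, text)]
            assert k1 == k2

    def test_persistence_round_trip_gives_identical_hits(self, toy_db, tmp_path):
        structures, _ = toy_db
        db = build_loop_database(structures, include_modelled=False)
        save_database(db, tmp_path / "db")
        db2 = load_database(tmp_path / "db")
        for text in CASE_PATTERNS.values():
            h1 = [(h.source_id, h.chain, h.window_start, tuple(h.grades))
                  for h in self.search_hits(db, text)]
            h2 = [(h.source_id, h.chain, h.window_start, tuple(h.grades))
                  for h in self.search_hits(db2, text)]
            assert h1 == h2

    def test_empty_database_returns_no_hits(self):
        from ssforge.loopdb import DatabaseIndex
        assert search(DatabaseIndex(), parse_connectivity("C2-C10, C4-C11")) == []

    def test_mismatched_query_sequence_warns(self, toy_db):
        structures, _ = toy_db
        db = build_loop_database(structures, include_modelled=False)
        with pytest.warns(UserWarning, match="authoritative"):
            self.search_hits(db, CASE_PATTERNS["interlocked-2b"],
                             query_sequence="AAAA")
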