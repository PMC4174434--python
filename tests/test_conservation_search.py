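"""Trimming and pairing, checked against a brute-force definition oracle."""

import itertools

import numpy as np
import pytest

from ccfind.core_model import Relation, SpeciesTable, WEIGHT_TOL
from ccfind.conservation_search import pair_and_trim, trim_index
from ccfind.seed_index import (
    SeedKey,
    build_index,
    enumerate_seeds,
    wobble_complements,
)

from conftest import make_collection, make_config, random_collection


def brute_force_hits(collection, relation, config):
    """Independent oracle: test every (key, segment pair) directly against
    the definitions — no hash tables, no merge-based trimming.

    The single-word conservation weight w(word, j) is the summed weight of
    species whose s_ij contains the word anywhere; occurrences below t0 are
    deleted, and — matching the two-threshold scheme — that deletion happens
    per partner word *before* the union over the wobble set.  A species then
    supports (omega, j, j') iff omega occurs in its s_ij and some surviving
    wobble complement occurs in its s_ij'; the pair is a hit iff (j, j') is
    allowed and the summed support weight reaches t.
    Returns {(key word, j, j') : support weight}.
    """
    table = collection.species_table
    seqs = {
        (seg.species, seg.segment_id): seg.sequence
        for seg in collection.segments
    }
    words_in: dict = {}
    for (sp, j), seq in seqs.items():
        words_in[(sp, j)] = {
            key.word for key, _, _ in enumerate_seeds(seq, config.k, config.gamma)
        }
    word_weight: dict = {}
    for (sp, j), words in words_in.items():
        for word in words:
            word_weight[(word, j)] = word_weight.get((word, j), 0.0) + table.weight(sp)

    def retained(word, j):
        return word_weight.get((word, j), 0.0) >= config.t0 - WEIGHT_TOL

    out = {}
    all_words = set().union(*words_in.values()) if words_in else set()
    for word in sorted(all_words):
        omega = SeedKey.from_word(word, config.gamma > 0)
        chi_words = {
            c.word for c in wobble_complements(omega, config.G, config.h)
        }
        if not chi_words:
            continue
        for ja, jb in relation.pairs:
            if not retained(word, ja):
                continue
            w = 0.0
            for sp in table.species_ids:
                left = words_in.get((sp, ja), set())
                right = words_in.get((sp, jb), set())
                if word in left and any(
                    c in right and retained(c, jb) for c in chi_words
                ):
                    w += table.weight(sp)
            if w >= config.t - WEIGHT_TOL:
                out[(word, ja, jb)] = w
    return out


class TestTrimIndex:
    def test_weight_sum_thresholding(self):
        # omega in segment s07 of species 0 and 1 only (weights 1/3 each)
        seqs = {
            "sp0": {"s07": "AAGGGCAA", "s08": "TTTTTTTT"},
            "sp1": {"s07": "CCGGGCTT", "s08": "TTTTTTTT"},
            "sp2": {"s07": "ACACACAC", "s08": "TTTTTTTT"},
        }
        coll = make_collection(seqs)
        cfg = make_config(k=4, L=4, M=16)
        index = build_index(coll, cfg)
        key = SeedKey("GGGC")
        kept = trim_index(index, coll.species_table, 0.6)
        assert len(kept.occurrences("sp0", key)) == 1
        dropped = trim_index(index, coll.species_table, 0.7)
        assert len(dropped.occurrences("sp0", key)) == 0

    def test_t0_zero_is_identity(self, rng):
        coll = random_collection(rng, m=2, n=3, length=30)
        cfg = make_config(k=4, L=4, M=32)
        index = build_index(coll, cfg)
        trimmed = trim_index(index, coll.species_table, 0.0)
        assert trimmed.n_occurrences() == index.n_occurrences()

    def test_simultaneity_across_species(self):
        # "boxes" occur in the same segment in all 3 species; "circles" in
        # only two -> at t0 = 1.0 boxes survive, circles do not
        box, circle = "GGGCGG", "ATATCC"
        seqs = {
            "sp0": {"s1": "TTAA" + box + "TT" + circle},
            "sp1": {"s1": circle + "AATT" + box + "AA"},
            "sp2": {"s1": "CACA" + box + "CACACACA"},
        }
        coll = make_collection(seqs)
        cfg = make_config(k=6, L=6, M=32)
        index = build_index(coll, cfg)
        trimmed = trim_index(index, coll.species_table, 1.0)
        assert len(trimmed.occurrences("sp0", SeedKey(box))) == 1
        assert len(trimmed.occurrences("sp0", SeedKey(circle))) == 0

    def test_idempotent(self, rng):
        coll = random_collection(rng, m=3, n=3, length=40)
        cfg = make_config(k=4, L=4, M=64)
        index = build_index(coll, cfg)
        once = trim_index(index, coll.species_table, 0.6)
        twice = trim_index(once, coll.species_table, 0.6)
        for sp in once.species_ids:
            for name in ("key", "seg", "pos", "gap"):
                np.testing.assert_array_equal(
                    once.tables[sp][name], twice.tables[sp][name]
                )

    def test_antitone_in_t0(self, rng):
        coll = random_collection(rng, m=3, n=3, length=40)
        cfg = make_config(k=4, L=4, M=64)
        index = build_index(coll, cfg)
        sizes = [
            trim_index(index, coll.species_table, t0).n_occurrences()
            for t0 in (0.0, 0.3, 0.6, 0.9, 1.0)
        ]
        assert sizes == sorted(sizes, reverse=True)
        # subset relation, not just size
        lo = trim_index(index, coll.species_table, 0.3)
        hi = trim_index(index, coll.species_table, 0.9)
        for sp in index.species_ids:
            lo_rows = {
                tuple(r)
                for r in zip(
                    lo.tables[sp]["key"], lo.tables[sp]["seg"],
                    lo.tables[sp]["pos"], lo.tables[sp]["gap"],
                )
            }
            hi_rows = {
                tuple(r)
                for r in zip(
                    hi.tables[sp]["key"], hi.tables[sp]["seg"],
                    hi.tables[sp]["pos"], hi.tables[sp]["gap"],
                )
            }
            assert hi_rows <= lo_rows

    def test_delta_restricts_positionally_divergent_support(self):
        # sp0 and sp1 share GGGC in s1, but 20 nt apart; with delta=5 the
        # lower-weight species no longer contributes
        seqs = {
            "sp0": {"s1": "GGGC" + "A" * 24},
            "sp1": {"s1": "A" * 20 + "GGGC" + "AAAA"},
        }
        coll = make_collection(seqs)
        cfg = make_config(k=4, L=4, M=32)
        index = build_index(coll, cfg)
        loose = trim_index(index, coll.species_table, 1.0, delta=None)
        assert len(loose.occurrences("sp0", SeedKey("GGGC"))) == 1
        tight = trim_index(index, coll.species_table, 1.0, delta=5)
        assert len(tight.occurrences("sp0", SeedKey("GGGC"))) == 0


class TestPairAndTrim:
    def run(self, coll, relation, cfg, t0=None):
        table = coll.species_table
        index = build_index(coll, cfg)
        trimmed = trim_index(index, table, cfg.t0 if t0 is None else t0)
        return pair_and_trim(trimmed, trimmed, relation, table, cfg)

    def test_tiny_planted_fixture_single_hit(self, tiny_hit_fixture):
        cfg = make_config(
            k=4, t0=0.6, t=0.6, G=0, L=4, M=16, unique_flag=True
        )
        rel = Relation(frozenset({("s1", "s2")}))
        hits = self.run(tiny_hit_fixture, rel, cfg)
        planted = [h for h in hits if h.key.word == "GGGC"]
        assert len(planted) == 1
        h = planted[0]
        assert h.left[0] == "s1" and h.right[0] == "s2"
        assert h.support_weight == pytest.approx(2 / 3)
        assert h.support_species == frozenset({"sp0", "sp1"})

    def test_empty_relation_empty_output(self, tiny_hit_fixture):
        cfg = make_config(k=4, t0=0.0, t=0.0, L=4, M=16)
        assert self.run(tiny_hit_fixture, Relation(frozenset()), cfg) == []

    def test_t_below_t0_rejected(self, tiny_hit_fixture):
        cfg = make_config(k=4, t0=0.0, t=0.5, L=4, M=16)
        index = build_index(tiny_hit_fixture, cfg)
        bad = make_config(k=4, t0=0.5, t=0.5, L=4, M=16)
        trimmed = trim_index(index, tiny_hit_fixture.species_table, 0.6)
        cfg_low_t = make_config(k=4, t0=0.3, t=0.3, L=4, M=16)
        with pytest.raises(ValueError, match="key-space|t must"):
            pair_and_trim(
                trimmed,
                build_index(tiny_hit_fixture, make_config(k=5, L=5, M=16)),
                Relation(frozenset()),
                tiny_hit_fixture.species_table,
                cfg_low_t,
            )

    def test_relation_restriction_always_holds(self, rng):
        coll = random_collection(rng, m=3, n=5, length=40)
        rel = Relation(frozenset({("s00", "s01"), ("s02", "s03")}))
        cfg = make_config(k=4, t0=0.3, t=0.3, G=1, L=4, M=64)
        for h in self.run(coll, rel, cfg):
            assert (h.left[0], h.right[0]) in rel.pairs

    def test_symmetry_without_unique_flag(self, rng):
        coll = random_collection(rng, m=2, n=4, length=36)
        ids = coll.segment_ids()
        rel = Relation(frozenset(itertools.product(ids, ids)))
        cfg = make_config(
            k=4, t0=0.5, t=0.5, G=0, L=4, M=64, unique_flag=False
        )
        hits = self.run(coll, rel, cfg)
        found = {
            (h.key.word, h.left[0], h.left[1], h.right[0], h.right[1])
            for h in hits
        }
        from ccfind.core_model import reverse_complement

        for word, ja, pa, jb, pb in found:
            mirror = (reverse_complement(word), jb, pb, ja, pa)
            assert mirror in found

    def test_raising_t_shrinks_output(self, rng):
        coll = random_collection(rng, m=3, n=4, length=40)
        ids = coll.segment_ids()
        rel = Relation(frozenset(itertools.product(ids, ids)))
        sizes = []
        for t in (0.3, 0.6, 1.0):
            cfg = make_config(
                k=4, t0=0.3, t=t, G=1, L=4, M=64, unique_flag=False
            )
            sizes.append(len(self.run(coll, rel, cfg, t0=0.3)))
        assert sizes == sorted(sizes, reverse=True)

    @pytest.mark.parametrize("k,G,h", [(4, 0, 0), (4, 1, 0), (5, 1, 2)])
    def test_oracle_equivalence_random_instances(self, rng, k, G, h):
        """Full trim+pair pipeline equals the brute-force definition oracle
        on random instances (support sets and weights at pair level)."""
        for trial in range(4):
            m = int(rng.integers(2, 4))
            n = int(rng.integers(2, 7))
            coll = random_collection(rng, m=m, n=n, length=60)
            ids = coll.segment_ids()
            rel = Relation(frozenset(itertools.product(ids, ids)))
            cfg = make_config(
                k=k, t0=0.4, t=0.4, G=G, h=h, L=k, gamma=0, M=128,
                unique_flag=False,
            )
            hits = self.run(coll, rel, cfg)
            got = {
                (h.key.word, h.left[0], h.right[0]): h.support_weight
                for h in hits
            }
            expected = brute_force_hits(coll, rel, cfg)
            assert got.keys() == expected.keys()
            for key in got:
                assert got[key] == pytest.approx(expected[key])

    def test_oracle_equivalence_gapped(self, rng):
        for trial in range(3):
            coll = random_collection(rng, m=2, n=3, length=50)
            ids = coll.segment_ids()
            rel = Relation(frozenset(itertools.product(ids, ids)))
            cfg = make_config(
                k=4, t0=0.5, t=0.5, G=1, h=0, L=4, gamma=1, M=128,
                unique_flag=False,
            )
            hits = self.run(coll, rel, cfg)
            got = {
                (h.key.word, h.left[0], h.right[0]): h.support_weight
                for h in hits
            }
            expected = brute_force_hits(coll, rel, cfg)
            assert got.keys() == expected.keys()
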