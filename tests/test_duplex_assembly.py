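"""Cluster merging geometry, the L filter, scoring, and naive alignment."""

import itertools
import math

import numpy as np
import pytest

from ccfind.core_model import (
    Relation,
    SpeciesTable,
    WEIGHT_TOL,
    reverse_complement,
)
from ccfind.conservation_search import (
    ConservedPairHit,
    pair_and_trim,
    trim_index,
)
from ccfind.duplex_assembly import (
    Duplex,
    cluster_hits,
    merge_clusters,
    naive_alignment,
    render_alignment,
    score_duplex,
    select_duplexes,
    star_align,
)
from ccfind.seed_index import SeedKey, build_index, wobble_complements
from ccfind.pipeline import run_search

from conftest import make_collection, make_config, random_collection


def make_hit(word, ja, pa, jb, pb, ga=0, gb=0, weight=1.0, sp="sp0"):
    return ConservedPairHit(
        key=SeedKey(word),
        left=(ja, pa, ga),
        right=(jb, pb, gb),
        support_species=frozenset({sp}),
        support_weight=weight,
        ref_species=sp,
        instances={sp: ((pa, ga, pb, gb),)},
    )


W8 = "ACGTACGT"


class TestMergeClusters:
    def test_antidiagonal_overlap_merges(self):
        hits = [
            make_hit(W8, "s1", 10, "s2", 50),
            make_hit(W8, "s1", 11, "s2", 49),
        ]
        cfg = make_config(k=8, L=9, M=128)
        (d,) = merge_clusters(hits, cfg)
        assert d.left_span == ("s1", 10, 19)
        assert d.right_span == ("s2", 49, 58)
        assert d.matched_length == 9

    def test_length_filter_threshold(self):
        hits = [
            make_hit(W8, "s1", 10, "s2", 50),
            make_hit(W8, "s1", 11, "s2", 49),
        ]
        assert merge_clusters(hits, make_config(k=8, L=12, M=128)) == []
        assert len(merge_clusters(hits, make_config(k=8, L=9, M=128))) == 1

    def test_disjoint_spans_stay_separate(self):
        hits = [
            make_hit(W8, "s1", 0, "s2", 60),
            make_hit(W8, "s1", 20, "s2", 40),  # same anti-diagonal, far apart
        ]
        cfg = make_config(k=8, L=8, M=128)
        duplexes = merge_clusters(hits, cfg)
        assert len(duplexes) == 2
        assert all(d.matched_length == 8 for d in duplexes)

    def test_different_antidiagonals_do_not_merge_ungapped(self):
        hits = [
            make_hit(W8, "s1", 10, "s2", 50),
            make_hit(W8, "s1", 12, "s2", 49),  # diagonal shifted by 1
        ]
        cfg = make_config(k=8, L=8, gamma=0, M=128)
        assert len(merge_clusters(hits, cfg)) == 2

    def test_partition_property(self, rng):
        # every input hit belongs to exactly one cluster before L filtering
        hits = []
        for _ in range(40):
            pa = int(rng.integers(0, 60))
            pb = int(rng.integers(0, 60))
            ja = f"s{int(rng.integers(1, 4))}"
            jb = f"t{int(rng.integers(1, 4))}"
            hits.append(make_hit(W8, ja, pa, jb, pb))
        cfg = make_config(k=8, L=8, M=128)
        clusters = cluster_hits(hits, cfg)
        members = [h for d in clusters for h in d.member_hits]
        assert len(members) == len(hits)
        assert {id(h) for h in members} == {id(h) for h in hits}

    def test_raising_L_never_increases_count(self, rng):
        hits = [
            make_hit(
                W8,
                "s1",
                int(rng.integers(0, 40)),
                "s2",
                int(rng.integers(0, 40)),
            )
            for _ in range(30)
        ]
        counts = [
            len(merge_clusters(hits, make_config(k=8, L=L, M=128)))
            for L in (8, 10, 12, 16)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_support_weight_is_min_over_members(self):
        hits = [
            make_hit(W8, "s1", 10, "s2", 50, weight=0.9),
            make_hit(W8, "s1", 11, "s2", 49, weight=0.75),
        ]
        (d,) = merge_clusters(hits, make_config(k=8, L=8, M=128))
        assert d.support_weight == pytest.approx(0.75)

    def test_inconsistent_k_rejected(self):
        hits = [make_hit(W8, "s1", 0, "s2", 0), make_hit("ACGT", "s1", 0, "s2", 0)]
        with pytest.raises(ValueError, match="inconsistent k"):
            merge_clusters(hits, make_config(k=8, L=8, M=128))


class TestSelectDuplexes:
    def dupl(self, ml, pa, pb):
        h = make_hit(W8, "s1", pa, "s2", pb)
        return Duplex(
            left_span=("s1", pa, pa + ml),
            right_span=("s2", pb, pb + ml),
            matched_length=ml,
            support_weight=1.0,
            member_hits=(h,),
            ref_species="sp0",
        )

    def test_longest_wins(self):
        d14, d12 = self.dupl(14, 30, 60), self.dupl(12, 5, 90)
        cfg = make_config(k=8, L=8, M=128)
        assert select_duplexes([d12, d14], cfg) == [d14]

    def test_tie_broken_by_first_occurrence(self):
        early, late = self.dupl(12, 5, 90), self.dupl(12, 40, 50)
        cfg = make_config(k=8, L=8, M=128)
        assert select_duplexes([late, early], cfg) == [early]

    def test_report_all_keeps_everything(self):
        ds = [self.dupl(12, 5, 90), self.dupl(12, 40, 50)]
        cfg = make_config(k=8, L=8, M=128, report_all=True)
        assert select_duplexes(ds, cfg) == ds


class TestScoring:
    def search(self, coll, rel, cfg):
        return run_search(coll, None, rel, coll.species_table, cfg)

    def test_scores_match_hand_computed_formula(self, tiny_hit_fixture):
        cfg = make_config(k=4, t0=0.6, t=0.6, G=0, L=4, M=16)
        rel = Relation(frozenset({("s1", "s2")}))
        res = self.search(tiny_hit_fixture, rel, cfg)
        (d,) = res.duplexes
        # independent recomputation of rho: fraction of 4-mer starts whose
        # word occurs in >= 2 of 3 species' copy of the segment
        def rho(seg_id):
            seqs = {
                seg.species: seg.sequence
                for seg in tiny_hit_fixture.segments
                if seg.segment_id == seg_id
            }
            ref = seqs["sp0"]
            n_starts = len(ref) - 4 + 1
            count = 0
            for p in range(n_starts):
                w = ref[p : p + 4]
                support = sum(w in s for s in seqs.values()) / 3
                count += support >= 2 / 3 - WEIGHT_TOL
            return max(count / n_starts, 1 / (n_starts + 1))

        ja, lo, hi = d.left_span
        jb, lo2, hi2 = d.right_span
        exp_c1_left = -(hi - lo - 4 + 1) * math.log10(rho(ja))
        exp_c1_right = -(hi2 - lo2 - 4 + 1) * math.log10(rho(jb))
        assert d.scores.c1_left == pytest.approx(exp_c1_left)
        assert d.scores.c1_right == pytest.approx(exp_c1_right)
        # single partner, complement present -> C2 = -log10(1/1) = 0
        assert d.scores.c2 == pytest.approx(0.0)
        assert d.scores.total == pytest.approx(
            exp_c1_left + exp_c1_right
        )

    def test_c2_counts_partners_with_conserved_complement(self):
        # s1 pairs with 4 partners; the complement word occurs (conserved)
        # in exactly one of them -> C2 = -log10(1/4)
        base = "ATATATATAT"
        seqs = {}
        for sp in ("sp0", "sp1"):
            seqs[sp] = {
                "s1": "AAGGGGCAAA",
                "t1": "TTGCCCCTTT",  # contains rc(GGGGC...) word
                "t2": base,
                "t3": base,
                "t4": base,
            }
        coll = make_collection(seqs)
        cfg = make_config(k=5, t0=1.0, t=1.0, G=0, L=5, M=16)
        rel = Relation(
            frozenset({("s1", t) for t in ("t1", "t2", "t3", "t4")})
        )
        res = self.search(coll, rel, cfg)
        assert res.duplexes, "expected the planted duplex"
        d = res.duplexes[0]
        assert d.scores.c2 == pytest.approx(-math.log10(1 / 4))

    def test_scores_invariant_under_species_relabeling(self, rng):
        coll = random_collection(rng, m=3, n=4, length=40)
        ids = coll.segment_ids()
        rel = Relation(frozenset(itertools.product(ids, ids)))
        cfg = make_config(k=4, t0=0.3, t=0.3, L=4, M=64, report_all=True)
        res1 = self.search(coll, rel, cfg)
        relabeled = make_collection(
            {
                f"zz{sp}": {
                    seg.segment_id: seg.sequence
                    for seg in coll.segments
                    if seg.species == sp
                }
                for sp in ("sp0", "sp1", "sp2")
            }
        )
        res2 = self.search(relabeled, rel, cfg)
        s1 = sorted(
            (d.left_span, d.right_span, round(d.scores.total, 9))
            for d in res1.duplexes
        )
        s2 = sorted(
            (d.left_span, d.right_span, round(d.scores.total, 9))
            for d in res2.duplexes
        )
        assert s1 == s2


class TestDuplexPairingReverification:
    def test_reported_spans_pair_under_wobble_rules(self, rng):
        """Independent re-check: member words read from the sequences pair
        with <= G wobbles and >= h G-C pairs."""
        wc = {"A": "T", "T": "A", "C": "G", "G": "C"}
        for trial in range(3):
            coll = random_collection(rng, m=2, n=4, length=50)
            ids = coll.segment_ids()
            rel = Relation(frozenset(itertools.product(ids, ids)))
            cfg = make_config(
                k=4, t0=0.5, t=0.5, G=1, h=1, L=4, M=64, report_all=True
            )
            res = run_search(coll, None, rel, coll.species_table, cfg, score=False)
            for d in res.duplexes:
                for h in d.member_hits:
                    for sp in h.support_species:
                        seq_a = next(
                            s.sequence
                            for s in coll.segments
                            if s.species == sp and s.segment_id == h.left[0]
                        )
                        seq_b = next(
                            s.sequence
                            for s in coll.segments
                            if s.species == sp and s.segment_id == h.right[0]
                        )
                        for p, g, p2, g2 in h.instances[sp]:
                            wa = seq_a[p : p + 4]
                            wb = seq_b[p2 : p2 + 4]
                            wob = gc = 0
                            for u in range(4):
                                a, b = wa[u], wb[3 - u]
                                if wc[a] == b:
                                    gc += a in "GC"
                                elif (a, b) in (("G", "T"), ("T", "G")):
                                    wob += 1
                                else:
                                    pytest.fail(f"non-pairing {wa} vs {wb}")
                            assert wob <= 1 and gc >= 1


class TestNaiveAlignment:
    def test_star_align_identical_rows_have_no_gaps(self):
        rows = star_align({"a": "ACGTACGT", "b": "ACGTACGT"}, "a")
        assert rows == {"a": "ACGTACGT", "b": "ACGTACGT"}

    def test_star_align_handles_indel(self):
        rows = star_align({"a": "ACGTACGT", "b": "ACGACGT"}, "a")
        assert len(set(len(r) for r in rows.values())) == 1
        assert rows["a"].replace("-", "") == "ACGTACGT"
        assert rows["b"].replace("-", "") == "ACGACGT"

    def test_alignment_blocks_mark_boxes(self, tiny_hit_fixture):
        cfg = make_config(
            k=4, t0=0.6, t=0.6, G=0, L=4, M=16, report_all=True
        )
        rel = Relation(frozenset({("s1", "s2")}))
        res = run_search(
            tiny_hit_fixture, None, rel,
            tiny_hit_fixture.species_table, cfg, score=False,
        )
        d = next(
            d
            for d in res.duplexes
            if any(h.key.word == "GGGC" for h in d.member_hits)
        )
        blocks = naive_alignment(d, res.collections)
        kinds = [(b.side, b.kind) for b in blocks]
        assert ("left", "box") in kinds and ("right", "box") in kinds
        box = next(b for b in blocks if b.side == "left" and b.kind == "box")
        assert "GGGC" in box.rows["sp0"]
        text = render_alignment(blocks)
        assert "^" in text and "sp0" in text
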