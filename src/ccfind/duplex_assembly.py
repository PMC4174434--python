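"""Merge overlapping complementary k-mer hits into duplexes, score, align.

Overlapping complementary k-mers form helices longer than k.  Hits sharing a
segment pair are sorted by their reference-species quadruple (p, p') and
merged when their spans overlap or abut on a common anti-diagonal
(p + p' constant for ungapped hits; gapped members may shift the diagonal
by up to gamma).  A merged cluster is reported as a duplex when it covers
at least L paired nucleotides (gap positions excluded).

Each duplex gets a significance score with two components, both -log10
scaled so they add:

*   C1 (one per side) measures how surprising the conserved box is against
    its segment's background: conserved k-mer starts are treated as
    independent Bernoulli(rho) events over the box's ell - k + 1 starts,
    where rho is the fraction of k-mer starts in the segment whose
    conservation weight reaches t, so C1 = -(ell - k + 1) * log10(rho).
    Highly conserved surrounding sequence drives rho toward 1 and C1
    toward 0.
*   C2 penalizes promiscuous complements: the fraction of relation partners
    of the left segment that contain a conserved complement of the duplex,
    C2 = -log10(occurrences / partners).

The naive display alignment anchors the selected duplex (the longest per
segment pair, first occurring on ties), aligning the complementary boxes
and the flanking intervals separately across supporting species with a
star alignment centered on the reference species, then concatenating the
blocks.  Flanks longer than 150 nt are middle-trimmed before alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio import Align

from .core_model import (
    Relation,
    SearchConfig,
    SegmentCollection,
    SpeciesTable,
    WEIGHT_TOL,
)
from .conservation_search import ConservedPairHit, segment_start_weights
from .seed_index import KmerIndex, SeedKey, wobble_complements

__all__ = [
    "Duplex",
    "DuplexScores",
    "merge_clusters",
    "cluster_hits",
    "score_duplex",
    "select_duplexes",
    "naive_alignment",
    "AlignmentBlock",
]

FLANK_TRIM = 150  # nt; longer flanks are middle-trimmed before alignment


@dataclass(frozen=True)
class DuplexScores:
    c1_left: float
    c1_right: float
    c2: float

    @property
    def total(self) -> float:
        return self.c1_left + self.c1_right + self.c2


@dataclass(frozen=True)
class Duplex:
    """A maximal cluster of overlapping conserved complementary k-mer hits."""

    left_span: tuple[str, int, int]  # (segment id, start, end) half-open
    right_span: tuple[str, int, int]
    matched_length: int  # paired nucleotides, gaps excluded
    support_weight: float  # min over member hits
    member_hits: tuple[ConservedPairHit, ...]
    ref_species: str
    scores: Optional[DuplexScores] = None

    @property
    def segment_pair(self) -> tuple[str, str]:
        return (self.left_span[0], self.right_span[0])

    @property
    def anchor(self) -> tuple[int, int]:
        """Reference (p, p') of the first member, for tie-breaking."""
        first = min((h.left[1], h.right[1]) for h in self.member_hits)
        return first


def _paired_left_positions(hit: ConservedPairHit, k: int) -> set[int]:
    """Left-segment positions actually paired by a hit (gap excluded)."""
    _, p, g = hit.left
    if g == 0:
        return set(range(p, p + k))
    a = (k + 1) // 2
    return set(range(p, p + a)) | set(range(p + a + g, p + k + g))


def _spans_touch(lo1: int, hi1: int, lo2: int, hi2: int) -> bool:
    """Half-open intervals overlap or abut."""
    return lo2 <= hi1 and lo1 <= hi2


def cluster_hits(
    hits: Sequence[ConservedPairHit], config: SearchConfig
) -> list[Duplex]:
    """Partition hits into maximal overlap clusters (no length filter).

    Every input hit belongs to exactly one returned duplex.
    """
    k = config.k
    groups: dict[tuple[str, str], list[ConservedPairHit]] = {}
    for h in hits:
        groups.setdefault(h.segment_pair, []).append(h)

    duplexes: list[Duplex] = []
    for pair in sorted(groups):
        members = sorted(
            groups[pair], key=lambda h: (h.left[1], h.right[1], str(h.key))
        )
        n = len(members)
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        def union(i: int, j: int) -> None:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[rj] = ri

        def diag(h: ConservedPairHit) -> int:
            return h.left[1] + h.right[1]

        for i in range(n):
            hi = members[i]
            li = (hi.left[1], hi.left[1] + k + hi.left[2])
            ri = (hi.right[1], hi.right[1] + k + hi.right[2])
            for j in range(i + 1, n):
                hj = members[j]
                if hj.left[1] > li[1]:  # sorted by p: no later overlap with i
                    break
                shift = config.gamma if (hi.left[2] or hj.left[2] or hi.right[2] or hj.right[2]) else 0
                if abs(diag(hi) - diag(hj)) > shift:
                    continue
                lj = (hj.left[1], hj.left[1] + k + hj.left[2])
                rj = (hj.right[1], hj.right[1] + k + hj.right[2])
                if _spans_touch(*li, *lj) and _spans_touch(*ri, *rj):
                    union(i, j)

        clusters: dict[int, list[ConservedPairHit]] = {}
        for i, h in enumerate(members):
            clusters.setdefault(find(i), []).append(h)

        for root in sorted(clusters):
            mem = clusters[root]
            paired: set[int] = set()
            for h in mem:
                paired |= _paired_left_positions(h, k)
            left_lo = min(h.left[1] for h in mem)
            left_hi = max(h.left[1] + k + h.left[2] for h in mem)
            right_lo = min(h.right[1] for h in mem)
            right_hi = max(h.right[1] + k + h.right[2] for h in mem)
            duplexes.append(
                Duplex(
                    left_span=(pair[0], left_lo, left_hi),
                    right_span=(pair[1], right_lo, right_hi),
                    matched_length=len(paired),
                    support_weight=min(h.support_weight for h in mem),
                    member_hits=tuple(mem),
                    ref_species=mem[0].ref_species,
                )
            )
    return duplexes


def merge_clusters(
    hits: Sequence[ConservedPairHit], config: SearchConfig
) -> list[Duplex]:
    """Cluster overlapping hits and keep duplexes with >= L paired nt."""
    ks = {h.key.k for h in hits}
    if len(ks) > 1:
        raise ValueError(f"hits with inconsistent k: {sorted(ks)}")
    return [
        d
        for d in cluster_hits(hits, config)
        if d.matched_length >= config.L
    ]


def select_duplexes(
    duplexes: Sequence[Duplex], config: SearchConfig
) -> list[Duplex]:
    """Default reporting: one duplex per segment pair.

    The longest matched_length wins; ties go to the first occurring region
    (smallest reference (p, p')).  With ``config.report_all`` every cluster
    is kept.
    """
    if config.report_all:
        return list(duplexes)
    best: dict[tuple[str, str], Duplex] = {}
    for d in duplexes:
        cur = best.get(d.segment_pair)
        if (
            cur is None
            or d.matched_length > cur.matched_length
            or (d.matched_length == cur.matched_length and d.anchor < cur.anchor)
        ):
            best[d.segment_pair] = d
    return [best[p] for p in sorted(best)]


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def _background_rate(
    index: KmerIndex,
    weights: SpeciesTable,
    collection: SegmentCollection,
    seg_id: str,
    t: float,
    ref_species: str,
) -> float:
    """rho_j: fraction of k-mer starts with conservation weight >= t."""
    seg = collection.get(ref_species, seg_id)
    if seg is None:
        for sp in sorted(
            collection.species_table.species_ids,
            key=lambda s: -collection.species_table.weight(s),
        ):
            seg = collection.get(sp, seg_id)
            if seg is not None:
                break
    if seg is None:
        raise KeyError(f"segment {seg_id!r} absent from collection")
    w = segment_start_weights(
        index, weights, seg.sequence, index.seg_index(seg_id)
    )
    n_starts = w.size
    if n_starts == 0:
        return 1.0
    rho = float((w >= t - WEIGHT_TOL).sum()) / n_starts
    return max(rho, 1.0 / (n_starts + 1))  # floor guards C1 < +inf


def score_duplex(
    duplex: Duplex,
    collections: tuple[SegmentCollection, SegmentCollection],
    indexes: tuple[KmerIndex, KmerIndex],
    relation: Relation,
    weights: SpeciesTable,
    config: SearchConfig,
) -> Duplex:
    """Attach C1/C2 significance components to a duplex.

    ``indexes`` are the *untrimmed* side indexes, needed for background
    rates.  Scores are invariant under relabeling of species.
    """
    coll_a, coll_b = collections
    index_a, index_b = indexes
    ja, left_lo, left_hi = duplex.left_span
    jb, right_lo, right_hi = duplex.right_span

    rho_l = _background_rate(
        index_a, weights, coll_a, ja, config.t, duplex.ref_species
    )
    rho_r = _background_rate(
        index_b, weights, coll_b, jb, config.t, duplex.ref_species
    )
    ell_l = left_hi - left_lo
    ell_r = right_hi - right_lo
    c1_l = -(ell_l - config.k + 1) * math.log10(rho_l)
    c1_r = -(ell_r - config.k + 1) * math.log10(rho_r)

    partners = relation.partners_of().get(ja, frozenset())
    if not partners:
        raise ValueError(f"segment {ja!r} has no relation partners")
    partner_codes: set[int] = set()
    for hit in duplex.member_hits:
        for chi in wobble_complements(hit.key, config.G, config.h):
            partner_codes.add(chi.encode())
    occurrences = 0
    for jb2 in partners:
        seg_idx = index_b.seg_index(jb2)
        found = False
        for code in partner_codes:
            w = sum(
                weights.weight(sp)
                for sp in index_b.species_ids
                if index_b.has_pair(sp, code, seg_idx)
            )
            if w >= config.t - WEIGHT_TOL:
                found = True
                break
        occurrences += found
    occurrences = max(occurrences, 1)
    c2 = -math.log10(occurrences / len(partners))

    return replace(
        duplex, scores=DuplexScores(c1_left=c1_l, c1_right=c1_r, c2=c2)
    )


# ---------------------------------------------------------------------------
# Naive structure-anchored alignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignmentBlock:
    """One aligned block: a complementary box or a flanking interval."""

    kind: str  # "flank" | "box"
    side: str  # "left" | "right"
    rows: Mapping[str, str]  # species -> aligned (gapped) sequence

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


def star_align(seqs: Mapping[str, str], center: str) -> dict[str, str]:
    """Star multiple alignment: pairwise-align every row to the center and
    project onto a common gap pattern (once a gap, always a gap)."""
    if center not in seqs:
        raise KeyError(f"center species {center!r} missing")
    others = [sp for sp in seqs if sp != center]
    center_seq = seqs[center]
    if not center_seq:
        width = max((len(s) for s in seqs.values()), default=0)
        return {sp: s + "-" * (width - len(s)) for sp, s in seqs.items()}
    aligner = _make_aligner()

    # master gap structure: list of center positions; gaps inserted as counts
    master: list[str] = [center_seq]
    rows: dict[str, str] = {center: center_seq}
    for sp in others:
        seq = seqs[sp]
        if not seq:
            rows[sp] = ""
            continue
        aln = aligner.align(center_seq, seq)[0]
        a_center, a_other = str(aln[0]), str(aln[1])
        # merge the new gap pattern into all existing rows
        merged_center = rows[center]
        new_rows: dict[str, str] = {}
        ci = ni = 0
        out: dict[str, list[str]] = {k: [] for k in rows}
        out[sp] = []
        while ci < len(merged_center) or ni < len(a_center):
            c_char = merged_center[ci] if ci < len(merged_center) else None
            n_char = a_center[ni] if ni < len(a_center) else None
            if c_char == "-" and n_char != "-":
                for k in rows:
                    out[k].append(rows[k][ci])
                out[sp].append("-")
                ci += 1
            elif n_char == "-" and c_char != "-":
                for k in rows:
                    out[k].append("-" if k != center else "-")
                # center gap introduced by new pairwise alignment
                out[center][-1] = "-"
                out[sp].append(a_other[ni])
                ni += 1
            else:
                for k in rows:
                    out[k].append(rows[k][ci])
                out[sp].append(a_other[ni] if ni < len(a_other) else "-")
                ci += 1
                ni += 1
        rows = {k: "".join(v) for k, v in out.items()}
    width = max((len(r) for r in rows.values()), default=0)
    return {sp: r.ljust(width, "-") for sp, r in rows.items()}


def _middle_trim(seq: str, limit: int = FLANK_TRIM) -> str:
    if len(seq) <= limit:
        return seq
    half = limit // 2
    return seq[:half] + seq[len(seq) - (limit - half) :]


def naive_alignment(
    duplex: Duplex,
    collections: tuple[SegmentCollection, SegmentCollection],
) -> list[AlignmentBlock]:
    """Structure-anchored display alignment of one duplex.

    For each side, the segment is cut at the duplex span into left flank,
    box, right flank; each piece is star-aligned across the supporting
    species (center = reference species) and the blocks are emitted in
    order, box columns marked by ``kind == "box"``.
    """
    coll_a, coll_b = collections
    ref = duplex.ref_species
    support = sorted(
        set.union(*[set(h.support_species) for h in duplex.member_hits])
    )

    # per-species anchor: first instance of the first member hit
    first_hit = min(
        duplex.member_hits, key=lambda h: (h.left[1], h.right[1])
    )
    k = first_hit.key.k
    blocks: list[AlignmentBlock] = []
    for side, coll, span in (
        ("left", coll_a, duplex.left_span),
        ("right", coll_b, duplex.right_span),
    ):
        seg_id, ref_lo, ref_hi = span
        width = ref_hi - ref_lo
        pre: dict[str, str] = {}
        box: dict[str, str] = {}
        post: dict[str, str] = {}
        for sp in support:
            seg = coll.get(sp, seg_id)
            if seg is None:
                continue
            inst = first_hit.instances.get(sp)
            if not inst:
                continue
            p, g, p2, g2 = inst[0]
            start = p if side == "left" else p2
            gap = g if side == "left" else g2
            # this species' box occupies [start - offset_into_cluster ...];
            # anchor the cluster by the first hit's offset within the span
            offset = (
                first_hit.left[1] - ref_lo
                if side == "left"
                else first_hit.right[1] - ref_lo
            )
            lo = max(start - offset, 0)
            hi = min(lo + width + (gap - first_hit.left[2] if side == "left" else gap - first_hit.right[2]), len(seg.sequence))
            hi = max(hi, lo)
            pre[sp] = _middle_trim(seg.sequence[:lo])
            box[sp] = seg.sequence[lo:hi]
            post[sp] = _middle_trim(seg.sequence[hi:])
        if ref not in box:
            continue
        blocks.append(
            AlignmentBlock("flank", side, star_align(pre, ref))
        )
        blocks.append(AlignmentBlock("box", side, star_align(box, ref)))
        blocks.append(
            AlignmentBlock("flank", side, star_align(post, ref))
        )
    return blocks


def render_alignment(blocks: Sequence[AlignmentBlock]) -> str:
    """Plain-text block alignment report with box columns marked by ^."""
    lines: list[str] = []
    for side in ("left", "right"):
        side_blocks = [b for b in blocks if b.side == side]
        if not side_blocks:
            continue
        species = sorted(
            {sp for b in side_blocks for sp in b.rows}
        )
        lines.append(f"# {side} segment")
        for sp in species:
            row = "".join(b.rows.get(sp, "-" * b.width) for b in side_blocks)
            lines.append(f"{sp:<12s} {row}")
        marker = "".join(
            ("^" if b.kind == "box" else " ") * b.width for b in side_blocks
        )
        lines.append(f"{'':<12s} {marker}")
    return "\n".join(lines) + "\n"
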