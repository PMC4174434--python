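"""The search core: conservation trimming and complementary-pair detection.

Trimming sparsifies the hash tables before any pairing: for a key omega and
segment id j, the conservation weight w(omega, j) is the sum of weights f_i
over species whose table contains omega *anywhere* in s_ij (each species
counted once — positions are forgotten, since unaligned sequences cannot be
compared by position).  Occurrences with w(omega, j) below t0 are deleted.
Trimming first is what keeps the subsequent Cartesian product tractable.

Pairing then forms, per key omega of side A, the relation-restricted product
of its occurrences with the occurrences of its wobble-complement set in side
B, and retains segment pairs whose joint conservation weight reaches t: a
species supports (j, j') iff omega occurs in its s_ij AND some chi in the
wobble set occurs in its s_ij'.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .core_model import (
    Relation,
    SearchConfig,
    SpeciesTable,
    WEIGHT_TOL,
)
from .seed_index import KmerIndex, SeedKey, wobble_complements

__all__ = [
    "ConservedPairHit",
    "trim_index",
    "pair_and_trim",
    "conservation_weight",
    "segment_start_weights",
]

# Threshold comparisons are >= throughout, with WEIGHT_TOL absorbing float
# error in weight sums (so t = 1.0 accepts weight sum 0.999999999...).


@dataclass(frozen=True)
class ConservedPairHit:
    """A conserved complementary k-mer pair localized in segments (j, j').

    ``left``/``right`` are the reference-species instances (segment id,
    position, gap size); ``instances`` carries every supporting species'
    positional instances as (p, g, p', g') tuples.
    """

    key: SeedKey
    left: tuple[str, int, int]
    right: tuple[str, int, int]
    support_species: frozenset[str]
    support_weight: float
    ref_species: str
    instances: Mapping[str, tuple[tuple[int, int, int, int], ...]]

    @property
    def segment_pair(self) -> tuple[str, str]:
        return (self.left[0], self.right[0])


def _check_sorted(index: KmerIndex) -> None:
    if not index.is_sorted():
        raise ValueError("index arrays are not sorted by (key, segment, position)")


def conservation_weight(
    index: KmerIndex, weights: SpeciesTable, key_code: int, seg_idx: int
) -> float:
    """w(omega, j): summed weight of species containing the key in segment j."""
    return sum(
        weights.weight(sp)
        for sp in index.species_ids
        if index.has_pair(sp, key_code, seg_idx)
    )


def _pass_pair_weights(
    index: KmerIndex, weights: SpeciesTable, t0: float
) -> np.ndarray:
    """Sorted packed (key * nseg + seg) values whose weight passes t0."""
    nseg = index.n_segments
    parts = []
    wparts = []
    for sp in index.species_ids:
        packed = index.packed_pairs(sp)
        parts.append(packed)
        wparts.append(np.full(packed.size, weights.weight(sp)))
    if not parts:
        return np.empty(0, np.int64)
    packed = np.concatenate(parts)
    w = np.concatenate(wparts)
    order = np.argsort(packed, kind="stable")
    packed = packed[order]
    w = w[order]
    uniq, start = np.unique(packed, return_index=True)
    sums = np.add.reduceat(w, start)
    return uniq[sums >= t0 - WEIGHT_TOL]


def trim_index(
    index: KmerIndex,
    weights: SpeciesTable,
    t0: float,
    delta: Optional[int] = None,
) -> KmerIndex:
    """Weight-threshold sparsification of the hash tables.

    Retains an occurrence (j, p) of key omega in species i iff the
    conservation weight w(omega, j) reaches t0.  With a finite ``delta``,
    a species contributes to w (and survives trimming) only if one of its
    occurrence positions lies within delta of an occurrence in the
    designated reference species — the highest-weight species holding the
    key in that segment.  Output arrays stay sorted; output is a subset of
    the input; the operation is idempotent and antitone in t0.
    """
    _check_sorted(index)
    if not (0.0 <= t0 <= 1.0):
        raise ValueError("t0 must be in [0, 1]")
    if delta is None:
        passing = _pass_pair_weights(index, weights, t0)
        nseg = np.int64(index.n_segments)
        tables = {}
        for sp in index.species_ids:
            t = index.tables[sp]
            packed = t["key"] * nseg + t["seg"]
            if passing.size:
                idx = np.searchsorted(passing, packed).clip(max=passing.size - 1)
                keep = passing[idx] == packed
            else:
                keep = np.zeros(packed.size, bool)
            tables[sp] = {name: arr[keep] for name, arr in t.items()}
        return KmerIndex(
            k=index.k,
            gamma=index.gamma,
            species_ids=index.species_ids,
            seg_ids=index.seg_ids,
            tables=tables,
        )
    return _trim_index_delta(index, weights, t0, delta)


def _trim_index_delta(
    index: KmerIndex, weights: SpeciesTable, t0: float, delta: int
) -> KmerIndex:
    """Reference (non-vectorized) trimming path with the positional bound."""
    keep_masks = {
        sp: np.zeros(index.tables[sp]["key"].size, bool)
        for sp in index.species_ids
    }
    # iterate (key, seg) groups across species
    all_pairs = np.unique(
        np.concatenate([index.packed_pairs(sp) for sp in index.species_ids])
    )
    nseg = index.n_segments
    order_by_weight = sorted(
        index.species_ids, key=lambda s: (-weights.weight(s), index.species_ids.index(s))
    )
    for packed in all_pairs:
        key_code = int(packed) // nseg
        seg_idx = int(packed) % nseg
        present: dict[str, np.ndarray] = {}
        for sp in index.species_ids:
            t = index.tables[sp]
            lo = np.searchsorted(t["key"], key_code, "left")
            hi = np.searchsorted(t["key"], key_code, "right")
            s_lo = lo + np.searchsorted(t["seg"][lo:hi], seg_idx, "left")
            s_hi = lo + np.searchsorted(t["seg"][lo:hi], seg_idx, "right")
            if s_hi > s_lo:
                present[sp] = np.arange(s_lo, s_hi)
        if not present:
            continue
        ref = next(sp for sp in order_by_weight if sp in present)
        ref_pos = index.tables[ref]["pos"][present[ref]]
        contributing: dict[str, np.ndarray] = {}
        for sp, rows in present.items():
            if sp == ref:
                contributing[sp] = rows
                continue
            pos = index.tables[sp]["pos"][rows]
            near = np.abs(pos[:, None] - ref_pos[None, :]).min(axis=1) <= delta
            if near.any():
                contributing[sp] = rows[near]
        w = sum(weights.weight(sp) for sp in contributing)
        if w >= t0 - WEIGHT_TOL:
            for sp, rows in contributing.items():
                keep_masks[sp][rows] = True
    tables = {
        sp: {name: arr[keep_masks[sp]] for name, arr in index.tables[sp].items()}
        for sp in index.species_ids
    }
    return KmerIndex(
        k=index.k,
        gamma=index.gamma,
        species_ids=index.species_ids,
        seg_ids=index.seg_ids,
        tables=tables,
    )


def _ref_instances(
    index_a: KmerIndex,
    index_b: KmerIndex,
    species: str,
    key_code: int,
    partner_codes: Sequence[int],
    seg_a: int,
    seg_b: int,
) -> tuple[tuple[int, int, int, int], ...]:
    """(p, g, p', g') combos of a species for key/partner occurrences."""
    rows_a = index_a.get(species, key_code)
    rows_a = rows_a[rows_a[:, 0] == seg_a]
    rights = []
    for code in partner_codes:
        rows_b = index_b.get(species, code)
        rows_b = rows_b[rows_b[:, 0] == seg_b]
        rights.append(rows_b)
    rows_b = np.concatenate(rights) if rights else np.empty((0, 3), np.int64)
    combos = []
    for _, p, g in rows_a:
        for _, p2, g2 in rows_b:
            combos.append((int(p), int(g), int(p2), int(g2)))
    return tuple(sorted(set(combos)))


def pair_and_trim(
    index_a: KmerIndex,
    index_b: KmerIndex,
    relation: Relation,
    weights: SpeciesTable,
    config: SearchConfig,
) -> list[ConservedPairHit]:
    """Relation-restricted Cartesian pairing of conserved complementary keys.

    Both indexes must already be trimmed at t0 <= t.  For every key omega
    present in side A, a species i supports the segment pair (j, j') iff
    omega occurs in its s_ij and some chi in wobble_complements(omega, G, h)
    occurs in its s_ij'; the pair is emitted iff (j, j') is allowed by the
    relation and the summed support weight reaches t.  With
    ``config.unique_flag`` only pairs with left < right in lexicographic
    (segment, position) order are reported, and overlapping self-pairs are
    dropped (non-overlapping self-complementarity is a legitimate hairpin).
    """
    if config.t < config.t0:
        raise ValueError("t must be >= t0")
    if index_a.k != index_b.k or index_a.gamma != index_b.gamma:
        raise ValueError("key-space mismatch between indexes (k or gamma differ)")
    _check_sorted(index_a)
    _check_sorted(index_b)

    partners = relation.partners_of()
    partner_idx: dict[int, np.ndarray] = {}
    seg_a_ids = index_a.seg_ids
    seg_b_ids = index_b.seg_ids
    seg_b_lookup = {s: i for i, s in enumerate(seg_b_ids)}
    for a_idx, a_id in enumerate(seg_a_ids):
        allowed = partners.get(a_id)
        if allowed:
            partner_idx[a_idx] = np.array(
                sorted(seg_b_lookup[b] for b in allowed if b in seg_b_lookup),
                dtype=np.int64,
            )

    species_order = sorted(
        weights.species_ids,
        key=lambda s: (-weights.weight(s), weights.species_ids.index(s)),
    )

    hits: list[ConservedPairHit] = []
    gapped = index_a.gapped
    for key_code in index_a.all_keys():
        key_code = int(key_code)
        omega = SeedKey.from_code(key_code, index_a.k, gapped)
        chi_set = wobble_complements(omega, config.G, config.h)
        if not chi_set:
            continue
        partner_codes = sorted(chi.encode() for chi in chi_set)
        # accumulate support per (seg_a, seg_b)
        support: dict[tuple[int, int], list[str]] = {}
        for sp in weights.species_ids:
            segs_a = index_a.segs_with_key(sp, key_code)
            if segs_a.size == 0:
                continue
            segs_b_parts = [
                index_b.segs_with_key(sp, code) for code in partner_codes
            ]
            segs_b = np.unique(np.concatenate(segs_b_parts))
            if segs_b.size == 0:
                continue
            segs_b_set = set(int(s) for s in segs_b)
            for ja in segs_a:
                allowed = partner_idx.get(int(ja))
                if allowed is None:
                    continue
                for jb in allowed:
                    if int(jb) in segs_b_set:
                        support.setdefault((int(ja), int(jb)), []).append(sp)
        for (ja, jb), sp_list in sorted(support.items()):
            w = sum(weights.weight(sp) for sp in sp_list)
            if w < config.t - WEIGHT_TOL:
                continue
            sp_set = frozenset(sp_list)
            ref = next(sp for sp in species_order if sp in sp_set)
            instances = {
                sp: _ref_instances(
                    index_a, index_b, sp, key_code, partner_codes, ja, jb
                )
                for sp in sorted(sp_set)
            }
            ja_id = seg_a_ids[ja]
            jb_id = seg_b_ids[jb]
            for p, g, p2, g2 in instances[ref]:
                if config.unique_flag:
                    if (ja_id, p) >= (jb_id, p2):
                        continue
                    if ja_id == jb_id:
                        # overlapping self-pair: the two words share sequence
                        span_a = (p, p + config.k + g)
                        span_b = (p2, p2 + config.k + g2)
                        if span_a[0] < span_b[1] and span_b[0] < span_a[1]:
                            continue
                hits.append(
                    ConservedPairHit(
                        key=omega,
                        left=(ja_id, p, g),
                        right=(jb_id, p2, g2),
                        support_species=sp_set,
                        support_weight=w,
                        ref_species=ref,
                        instances=instances,
                    )
                )
    return hits


def segment_start_weights(
    index: KmerIndex,
    weights: SpeciesTable,
    sequence: str,
    seg_idx: int,
) -> np.ndarray:
    """Conservation weight of the k-mer starting at every position of a segment.

    Uses the ungapped k-mer at each start of ``sequence`` (the reference
    species' copy of the segment) and the position-forgetting weight
    w(key, j) computed from the (untrimmed) index.
    """
    from .seed_index import seed_codes_of_sequence

    k = index.k
    n_starts = len(sequence) - k + 1
    out = np.zeros(max(n_starts, 0))
    if n_starts <= 0:
        return out
    codes, poss, gaps = seed_codes_of_sequence(sequence, k, 0)
    ungapped = gaps == 0
    codes, poss = codes[ungapped], poss[ungapped]
    nseg = np.int64(index.n_segments)
    packed = codes * nseg + seg_idx
    for sp in index.species_ids:
        pairs = index.packed_pairs(sp)
        if pairs.size == 0:
            continue
        idx = np.searchsorted(pairs, packed)
        idx[idx >= pairs.size] = 0
        present = pairs[idx] == packed
        out[poss[present]] += weights.weight(sp)
    return out
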