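"""False-discovery-rate estimation by block-preserving relation rewiring.

The null model re-pairs segments across genes ("hybrid transcripts") while
preserving each segment's conservation and composition profile: segments
are binned into blocks on a quantile grid of (conservation score, GC
content), and the right endpoints of the relation are permuted uniformly at
random within blocks, re-drawing any pair that lands on its own gene.  The
search is re-run on each rewired relation; FDR is the mean control count
divided by the reference count, with the standard error estimated over the
repeats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import (
    Relation,
    SearchConfig,
    SegmentCollection,
    SpeciesTable,
)
from .conservation_search import (
    pair_and_trim,
    segment_start_weights,
    trim_index,
)
from .duplex_assembly import merge_clusters, select_duplexes
from .seed_index import KmerIndex, build_index

__all__ = [
    "BlockAssignment",
    "FDRReport",
    "SearchTask",
    "block_segments",
    "rewire_relation",
    "estimate_fdr",
]


@dataclass(frozen=True)
class BlockAssignment:
    """Segment -> block index, with the covariates the blocks were built on."""

    assignment: Mapping[str, int]
    conservation: Mapping[str, float]
    gc: Mapping[str, float]
    n_blocks: int

    def block_of(self, segment_id: str) -> int:
        return self.assignment[segment_id]


@dataclass(frozen=True)
class FDRReport:
    reference_count: int
    control_counts: tuple[int, ...]
    fdr_mean: Optional[float]
    fdr_se: Optional[float]
    ci95: Optional[tuple[float, float]]

    def summary(self) -> str:
        if self.fdr_mean is None:
            return (
                f"reference pairs: {self.reference_count}; FDR undefined "
                "(no reference detections)"
            )
        lo, hi = self.ci95
        return (
            f"reference pairs: {self.reference_count}; control mean "
            f"{np.mean(self.control_counts):.2f} over "
            f"{len(self.control_counts)} repeats; FDR = "
            f"{self.fdr_mean:.3f} +- {self.fdr_se:.3f} "
            f"(95% CI {lo:.3f}-{hi:.3f})"
        )


def _quantile_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Quantile bin labels in [0, n_bins); degenerate values share a bin."""
    if n_bins <= 1 or np.unique(values).size == 1:
        return np.zeros(values.size, dtype=int)
    try:
        codes = pd.qcut(values, q=n_bins, labels=False, duplicates="drop")
    except ValueError:
        return np.zeros(values.size, dtype=int)
    return np.asarray(codes, dtype=int)


def block_segments(
    collection: SegmentCollection,
    index: KmerIndex,
    weights: SpeciesTable,
    n_blocks: int = 500,
    q: Optional[int] = None,
    r: Optional[int] = None,
) -> BlockAssignment:
    """Bin segments on a quantile grid of conservation score x GC content.

    The conservation score of a segment is the mean, over the reference
    species' k-mer starts, of the cross-species conservation weight; GC is
    the simple fraction.  The grid is q conservation quantiles by r GC
    quantiles with q*r ~= n_blocks (default 25 x 20 for 500).  Empty cells
    are allowed — a small collection simply occupies few of them.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if q is None or r is None:
        if n_blocks == 500:
            q, r = 25, 20
        else:
            r = max(int(np.sqrt(n_blocks)), 1)
            q = max(int(np.ceil(n_blocks / r)), 1)
    ref = weights.reference_species
    seg_ids = collection.segment_ids()
    cons = np.zeros(len(seg_ids))
    gc = np.zeros(len(seg_ids))
    for idx_j, j in enumerate(seg_ids):
        seg = collection.get(ref, j)
        if seg is None:  # fall back to any species holding the segment
            for sp in weights.species_ids:
                seg = collection.get(sp, j)
                if seg is not None:
                    break
        seq = seg.sequence
        w = segment_start_weights(index, weights, seq, index.seg_index(j))
        cons[idx_j] = float(w.mean()) if w.size else 0.0
        gc[idx_j] = (seq.count("G") + seq.count("C")) / len(seq)
    cons_bin = _quantile_bins(cons, q)
    gc_bin = _quantile_bins(gc, r)
    assignment = {
        j: int(cb) * r + int(gb)
        for j, cb, gb in zip(seg_ids, cons_bin, gc_bin)
    }
    return BlockAssignment(
        assignment=assignment,
        conservation=dict(zip(seg_ids, cons.tolist())),
        gc=dict(zip(seg_ids, gc.tolist())),
        n_blocks=q * r,
    )


def rewire_relation(
    relation: Relation,
    blocks: BlockAssignment,
    rng_seed: int,
    genes: Optional[Mapping[str, str]] = None,
    max_retries: int = 100,
) -> Relation:
    """Permute right endpoints within blocks, avoiding same-gene pairs.

    The per-block multiset of right endpoints and the left-endpoint multiset
    are preserved exactly; pairs that land on the same gene as their left
    endpoint are re-drawn by bounded swapping within the block and dropped
    (with a warning) when no admissible swap exists.  Deterministic given
    ``rng_seed``.
    """
    rng = np.random.default_rng(rng_seed)
    pairs = sorted(relation.pairs)
    lefts = [a for a, _ in pairs]
    rights = [b for _, b in pairs]
    for b in rights:
        if b not in blocks.assignment:
            raise ValueError(f"right endpoint {b!r} has no block assignment")
    genes = genes or {}

    by_block: dict[int, list[int]] = {}
    for i, b in enumerate(rights):
        by_block.setdefault(blocks.block_of(b), []).append(i)

    new_rights: list[Optional[str]] = [None] * len(pairs)
    for block in sorted(by_block):
        rows = by_block[block]
        perm = rng.permutation(len(rows))
        for slot, src in zip(rows, perm):
            new_rights[slot] = rights[rows[src]]

    def same_gene(i: int) -> bool:
        ga = genes.get(lefts[i])
        gb = genes.get(new_rights[i])
        return ga is not None and ga == gb

    dropped: list[int] = []
    for block in sorted(by_block):
        rows = by_block[block]
        for i in rows:
            if not same_gene(i):
                continue
            fixed = False
            for _ in range(max_retries):
                j = int(rng.integers(0, len(rows)))
                other = rows[j]
                if other == i:
                    continue
                # swap right endpoints i <-> other if both become admissible
                ri, ro = new_rights[i], new_rights[other]
                new_rights[i], new_rights[other] = ro, ri
                if not same_gene(i) and not same_gene(other):
                    fixed = True
                    break
                new_rights[i], new_rights[other] = ri, ro
            if not fixed:
                dropped.append(i)
    if dropped:
        warnings.warn(
            f"rewiring dropped {len(dropped)} pair(s) that could not avoid "
            "a same-gene pairing",
            stacklevel=2,
        )
    dropped_set = set(dropped)
    kept = frozenset(
        (lefts[i], new_rights[i])
        for i in range(len(pairs))
        if i not in dropped_set
    )
    return Relation(kept)


@dataclass
class SearchTask:
    """A configured search whose indexes are built and trimmed once.

    ``count_pairs(relation)`` reruns only the relation-dependent stages
    (pairing, clustering, length filter) and returns the number of distinct
    segment pairs carrying at least one reported duplex.
    """

    collection_a: SegmentCollection
    collection_b: SegmentCollection
    weights: SpeciesTable
    config: SearchConfig
    index_a: KmerIndex = field(init=False, repr=False)
    index_b: KmerIndex = field(init=False, repr=False)
    trimmed_a: KmerIndex = field(init=False, repr=False)
    trimmed_b: KmerIndex = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.index_a = build_index(self.collection_a, self.config)
        if self.collection_b is self.collection_a:
            self.index_b = self.index_a
        else:
            self.index_b = build_index(self.collection_b, self.config)
        self.trimmed_a = trim_index(
            self.index_a, self.weights, self.config.t0, self.config.delta
        )
        self.trimmed_b = (
            self.trimmed_a
            if self.index_b is self.index_a
            else trim_index(
                self.index_b, self.weights, self.config.t0, self.config.delta
            )
        )

    def duplexes(self, relation: Relation):
        hits = pair_and_trim(
            self.trimmed_a, self.trimmed_b, relation, self.weights, self.config
        )
        duplexes = merge_clusters(hits, self.config)
        return select_duplexes(duplexes, self.config)

    def count_pairs(self, relation: Relation) -> int:
        return len({d.segment_pair for d in self.duplexes(relation)})


def estimate_fdr(
    task: SearchTask,
    relation: Relation,
    blocks: BlockAssignment,
    repeats: int = 20,
    rng_seed: int = 0,
) -> FDRReport:
    """FDR = mean duplex-pair count under rewired relations / reference count.

    Runs the search once on the true relation and ``repeats`` times on
    independently rewired relations (all runs share the same SearchConfig),
    reporting the mean ratio with its standard error and 95% CI over the
    repeats.  A reference count of zero leaves the FDR undefined.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    genes = task.collection_b.gene_map()
    reference_count = task.count_pairs(relation)
    rng = np.random.default_rng(rng_seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=repeats)
    control_counts = []
    for seed in child_seeds:
        rewired = rewire_relation(relation, blocks, int(seed), genes=genes)
        control_counts.append(task.count_pairs(rewired))
    control_counts = tuple(control_counts)
    if reference_count == 0:
        return FDRReport(0, control_counts, None, None, None)
    mean_control = float(np.mean(control_counts))
    fdr_mean = mean_control / reference_count
    if repeats > 1:
        se_control = float(np.std(control_counts, ddof=1)) / np.sqrt(repeats)
        fdr_se = se_control / reference_count
        tcrit = float(stats.t.ppf(0.975, repeats - 1))
        ci = (fdr_mean - tcrit * fdr_se, fdr_mean + tcrit * fdr_se)
    else:
        fdr_se = float("nan")
        ci = (float("nan"), float("nan"))
    return FDRReport(reference_count, control_counts, fdr_mean, fdr_se, ci)
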