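"""Benchmark instance generators with ground truth, and the external-tool
post-filter harness.

Two designs:

*   **Seed insertion** — unalignable orthologs.  Each species gets n
    independent i.i.d. uniform-nucleotide segments; a random k-mer seed q is
    written into segment 2q-1 of every species and its reverse complement
    into segment 2q, each copy at an independent uniform position and split
    by a central gap of random size <= max_gap filled with random
    nucleotides.  Segments of a group share no ancestry, so no aligner can
    recover the pairs — only simultaneous complementarity can.

*   **Tree evolution** — alignable orthologs.  Random ancestral sequences
    evolve down a balanced binary tree by independent per-site substitution;
    the leaves become the orthologous group.  The substitution rate is, by
    default, the total root-to-leaf divergence ("per-path"), apportioned
    evenly across the branches of the tree; ``rate_mode="per-branch"``
    instead applies the rate on every branch.

The post-filter harness turns any external tool's base-pair predictions into
the benchmark's filtered pair set: a segment pair is kept iff it has a run
of at least 8 consecutive complementary nucleotides with at most one G.T
pair per 8 nt, whose words co-occur (position-forgetting) in at least the
required number of species.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .core_model import (
    Segment,
    SegmentCollection,
    SpeciesTable,
    reverse_complement,
)

__all__ = [
    "PlantedTruth",
    "TreeSimConfig",
    "TreeSimResult",
    "seed_insertion_benchmark",
    "evolve_on_tree",
    "duplex_post_filter",
    "rnaplex_predictions",
    "find_rnaplex",
    "recovered_planted_pairs",
]

_NT = "ACGT"
_WC_OK = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_GT_OK = {("G", "T"), ("T", "G")}


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_NT[i] for i in rng.integers(0, 4, size=length))


# ---------------------------------------------------------------------------
# Seed-insertion benchmark
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of the seed-insertion benchmark."""

    seeds: tuple[str, ...]  # seed words, length k
    #: (species, segment_id) -> (position, gap size) of the planted copy
    placements: Mapping[tuple[str, str], tuple[int, int]]
    #: intended complementary segment pairs (odd j with j+1)
    pairs: tuple[tuple[str, str], ...]
    k: int
    max_gap: int


def seed_insertion_benchmark(
    n: int = 200,
    length: int = 1000,
    m: int = 16,
    n_seeds: int = 100,
    k: int = 8,
    max_gap: int = 2,
    rng_seed: int = 0,
) -> tuple[SegmentCollection, PlantedTruth]:
    """Generate the seed-insertion benchmark with ground truth.

    Defaults are the benchmark's study conditions: m=16 species, n=200
    segments of 1000 nt with equal nucleotide probabilities, 100 planted
    8-mer seed pairs, central gaps up to 2 nt.  Segments 2q-1 and 2q share
    gene identifier q, so the same-gene relation links exactly the planted
    pairs (plus self-pairs).  Deterministic given ``rng_seed``.
    """
    if n % 2 != 0:
        raise ValueError("n must be even")
    if n_seeds > n // 2:
        raise ValueError("n_seeds must be <= n/2")
    if length < k + max_gap:
        raise ValueError("segment too short for seed insertion")
    rng = np.random.default_rng(rng_seed)

    species_ids = tuple(f"sp{i:02d}" for i in range(m))
    seg_ids = tuple(f"s{j:04d}" for j in range(1, n + 1))
    gene_ids = tuple(f"g{(j - 1) // 2 + 1:04d}" for j in range(1, n + 1))

    # distinct random seeds
    seed_codes = rng.choice(4**k, size=n_seeds, replace=False)
    seeds = tuple(
        "".join(_NT[(int(c) >> (2 * (k - 1 - u))) & 3] for u in range(k))
        for c in seed_codes
    )

    a = (k + 1) // 2
    placements: dict[tuple[str, str], tuple[int, int]] = {}
    segments: list[Segment] = []
    for sp in species_ids:
        for j0 in range(n):
            seq = list(_random_dna(rng, length))
            q, is_even = divmod(j0, 2)
            if q < n_seeds:
                word = seeds[q] if not is_even else reverse_complement(seeds[q])
                g = int(rng.integers(0, max_gap + 1))
                insert = word[:a] + _random_dna(rng, g) + word[a:]
                pos = int(rng.integers(0, length - len(insert) + 1))
                seq[pos : pos + len(insert)] = insert
                placements[(sp, seg_ids[j0])] = (pos, g)
            segments.append(
                Segment(
                    species=sp,
                    segment_id=seg_ids[j0],
                    gene_id=gene_ids[j0],
                    sequence="".join(seq),
                )
            )
    collection = SegmentCollection(
        "A", tuple(segments), SpeciesTable.uniform(species_ids)
    )
    truth = PlantedTruth(
        seeds=seeds,
        placements=placements,
        pairs=tuple(
            (seg_ids[2 * q], seg_ids[2 * q + 1]) for q in range(n_seeds)
        ),
        k=k,
        max_gap=max_gap,
    )
    return collection, truth


def recovered_planted_pairs(
    duplexes: Sequence, truth: PlantedTruth
) -> set[tuple[str, str]]:
    """Planted pairs recovered by reported duplexes at their coordinates.

    A planted pair counts as recovered when some duplex links its two
    segments (either orientation) with spans overlapping the planted copy
    in the duplex's reference species.
    """
    recovered: set[tuple[str, str]] = set()
    by_pair: dict[frozenset, list] = {}
    for d in duplexes:
        ja, jb = d.segment_pair
        by_pair.setdefault(frozenset((ja, jb)), []).append(d)
    span = truth.k + truth.max_gap
    for pair in truth.pairs:
        for d in by_pair.get(frozenset(pair), ()):
            ok = True
            for seg_id, (lo, hi) in (
                (d.left_span[0], (d.left_span[1], d.left_span[2])),
                (d.right_span[0], (d.right_span[1], d.right_span[2])),
            ):
                planted = truth.placements.get((d.ref_species, seg_id))
                if planted is None:
                    ok = False
                    break
                p, g = planted
                if not (lo < p + truth.k + g and p < hi):
                    ok = False
                    break
            if ok:
                recovered.add(pair)
                break
    return recovered


# ---------------------------------------------------------------------------
# Tree-evolution benchmark
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TreeSimConfig:
    """Evolution of random ancestors down a balanced binary tree.

    ``rate`` is the per-site substitution probability; with
    ``rate_mode="per-path"`` (default) it is the total root-to-leaf
    divergence, spread evenly over the ``log2(n_species)`` branches of each
    root-to-leaf path; with ``"per-branch"`` it applies on every branch.
    """

    n_groups: int = 100
    ancestor_length: int = 150
    n_species: int = 16
    rate: float = 0.03
    rate_mode: str = "per-path"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2 or self.n_species & (self.n_species - 1):
            raise ValueError("n_species must be a power of two >= 2")
        if not (0.0 <= self.rate <= 1.0):
            raise ValueError("rate must be in [0, 1]")
        if self.rate_mode not in ("per-path", "per-branch"):
            raise ValueError("rate_mode must be 'per-path' or 'per-branch'")

    @property
    def depth(self) -> int:
        return int(math.log2(self.n_species))

    @property
    def branch_rate(self) -> float:
        if self.rate_mode == "per-branch":
            return self.rate
        return 1.0 - (1.0 - self.rate) ** (1.0 / self.depth)


@dataclass(frozen=True)
class TreeSimResult:
    collection: SegmentCollection
    ancestors: tuple[str, ...]  # one ancestral sequence per group
    config: TreeSimConfig


def _mutate(
    codes: np.ndarray, q: float, rng: np.random.Generator
) -> np.ndarray:
    """Substitute each site with probability q to one of the 3 other bases."""
    mask = rng.random(codes.size) < q
    shift = rng.integers(1, 4, size=codes.size)
    out = codes.copy()
    out[mask] = (out[mask] + shift[mask]) % 4
    return out


def evolve_on_tree(config: TreeSimConfig) -> TreeSimResult:
    """Evolve random ancestors down the balanced tree; leaves become the
    orthologous segments of each group."""
    rng = np.random.default_rng(config.rng_seed)
    q = config.branch_rate
    m = config.n_species
    species_ids = tuple(f"sp{i:02d}" for i in range(m))
    seg_ids = tuple(f"s{j:04d}" for j in range(1, config.n_groups + 1))

    segments: list[Segment] = []
    ancestors: list[str] = []
    for j, seg_id in enumerate(seg_ids):
        root = rng.integers(0, 4, size=config.ancestor_length)
        ancestors.append("".join(_NT[c] for c in root))
        level = [root]
        for _ in range(config.depth):
            level = [_mutate(node, q, rng) for node in level for _ in range(2)]
        for sp, leaf in zip(species_ids, level):
            segments.append(
                Segment(
                    species=sp,
                    segment_id=seg_id,
                    gene_id=seg_id,
                    sequence="".join(_NT[c] for c in leaf),
                )
            )
    collection = SegmentCollection(
        "A", tuple(segments), SpeciesTable.uniform(species_ids)
    )
    return TreeSimResult(collection, tuple(ancestors), config)


# ---------------------------------------------------------------------------
# External-prediction post-filter
# ---------------------------------------------------------------------------


def duplex_post_filter(
    predictions: Mapping[tuple[str, str], Sequence[tuple[int, int]]],
    collection: SegmentCollection,
    min_run: int = 8,
    max_gt_per_window: int = 1,
    min_species: int = 12,
    ref_species: Optional[str] = None,
) -> set[tuple[str, str]]:
    """Filter external base-pair predictions down to conserved duplex pairs.

    ``predictions`` maps a segment pair (j, j') to a list of paired
    positions (p in s_j, p' in s_j'), 0-based, in the reference species'
    coordinates.  A pair is kept iff some window of ``min_run`` consecutive
    paired positions exists in which every base pair is Watson-Crick or G.T
    with at most ``max_gt_per_window`` G.T pairs, and the two window words
    co-occur (anywhere — the position-forgetting rule) in at least
    ``min_species`` species' copies of the two segments.
    """
    if ref_species is None:
        ref_species = collection.species_table.reference_species
    species = collection.species_table.species_ids
    kept: set[tuple[str, str]] = set()
    for (ja, jb), bps in predictions.items():
        seg_a = collection.get(ref_species, ja)
        seg_b = collection.get(ref_species, jb)
        if seg_a is None or seg_b is None:
            raise ValueError(f"pair ({ja}, {jb}) missing in reference species")
        sa, sb = seg_a.sequence, seg_b.sequence
        try:
            bps_sorted = sorted((int(p), int(p2)) for p, p2 in bps)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed pairing list for ({ja}, {jb})") from exc
        # split into antidiagonal runs of consecutive complementary pairs
        runs: list[list[tuple[int, int]]] = []
        cur: list[tuple[int, int]] = []
        for p, p2 in bps_sorted:
            if p >= len(sa) or p2 >= len(sb) or p < 0 or p2 < 0:
                raise ValueError(f"pairing position out of range for ({ja}, {jb})")
            pairing = (sa[p], sb[p2])
            complementary = pairing in _WC_OK or pairing in _GT_OK
            if cur and (p != cur[-1][0] + 1 or p2 != cur[-1][1] - 1):
                runs.append(cur)
                cur = []
            if complementary:
                cur.append((p, p2))
            elif cur:
                runs.append(cur)
                cur = []
        if cur:
            runs.append(cur)
        if _any_window_passes(
            runs, sa, sb, collection, species, ja, jb,
            min_run, max_gt_per_window, min_species,
        ):
            kept.add((ja, jb))
    return kept


def _any_window_passes(
    runs, sa, sb, collection, species, ja, jb,
    min_run, max_gt, min_species,
) -> bool:
    for run in runs:
        if len(run) < min_run:
            continue
        for start in range(len(run) - min_run + 1):
            window = run[start : start + min_run]
            gt = sum(
                1 for p, p2 in window if (sa[p], sb[p2]) in _GT_OK
            )
            if gt > max_gt:
                continue
            word_a = sa[window[0][0] : window[0][0] + min_run]
            word_b = sb[window[-1][1] : window[-1][1] + min_run]
            n_cons = 0
            for sp in species:
                seg_a = collection.get(sp, ja)
                seg_b = collection.get(sp, jb)
                if (
                    seg_a is not None
                    and seg_b is not None
                    and word_a in seg_a.sequence
                    and word_b in seg_b.sequence
                ):
                    n_cons += 1
            if n_cons >= min_species:
                return True
    return False


# ---------------------------------------------------------------------------
# RNAplex harness (optional external tool)
# ---------------------------------------------------------------------------


def find_rnaplex() -> Optional[str]:
    """Path to the RNAplex executable, or None when not installed."""
    return shutil.which("RNAplex")


def rnaplex_predictions(
    collection: SegmentCollection,
    ref_species: Optional[str] = None,
    executable: Optional[str] = None,
) -> dict[tuple[str, str], list[tuple[int, int]]]:
    """Best RNAplex duplex per unordered segment pair, as base-pair lists.

    Runs RNAplex all-vs-all on the reference species' segment sequences and
    parses each reported duplex into 0-based paired positions, keyed by the
    lexicographically ordered segment pair.  Requires the RNAplex
    executable; callers should check :func:`find_rnaplex` first.
    """
    exe = executable or find_rnaplex()
    if exe is None:
        raise RuntimeError("RNAplex executable not found on PATH")
    if ref_species is None:
        ref_species = collection.species_table.reference_species
    seg_ids = collection.segment_ids()
    seqs = {}
    for j in seg_ids:
        seg = collection.get(ref_species, j)
        if seg is None:
            raise ValueError(f"segment {j!r} missing in reference species")
        seqs[j] = seg.sequence

    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "segs.fa"
        with open(fasta, "w") as fh:
            for j, s in seqs.items():
                fh.write(f">{j}\n{s}\n")
        proc = subprocess.run(
            [exe, "-q", str(fasta), "-t", str(fasta)],
            capture_output=True,
            text=True,
            check=True,
        )
    out: dict[tuple[str, str], list[tuple[int, int]]] = {}
    best_energy: dict[tuple[str, str], float] = {}
    lines = [ln for ln in proc.stdout.splitlines() if ln.strip()]
    i = 0
    while i + 2 < len(lines) or (i + 2 <= len(lines) - 1):
        if not lines[i].startswith(">"):
            i += 1
            continue
        target = lines[i][1:].strip()
        query = lines[i + 1][1:].strip()
        hitline = lines[i + 2]
        i += 3
        if target == query:
            continue
        pair = tuple(sorted((target, query)))
        parsed = _parse_rnaplex_line(hitline)
        if parsed is None:
            continue
        structure, (t_lo, t_hi), (q_lo, q_hi), energy = parsed
        if pair in best_energy and best_energy[pair] <= energy:
            continue
        bps = _structure_to_pairs(
            structure, (t_lo, t_hi), (q_lo, q_hi)
        )
        # orient to (pair[0], pair[1])
        if target == pair[0]:
            out[pair] = [(pt, pq) for pt, pq in bps]
        else:
            out[pair] = sorted((pq, pt) for pt, pq in bps)
        best_energy[pair] = energy
    return out


def _parse_rnaplex_line(line: str):
    # e.g. ".((((((((&))))....)))).   8,16  :   1,13  (-13.30) i:16,j:1 <-14.10>"
    parts = line.split()
    if not parts or "&" not in parts[0]:
        return None
    structure = parts[0]
    try:
        t_lo, t_hi = (int(x) for x in parts[1].split(","))
        q_lo, q_hi = (int(x) for x in parts[3].split(","))
        energy = float(parts[4].strip("()"))
    except (IndexError, ValueError):
        return None
    return structure, (t_lo, t_hi), (q_lo, q_hi), energy


def _structure_to_pairs(
    structure: str, t_range: tuple[int, int], q_range: tuple[int, int]
) -> list[tuple[int, int]]:
    """Dot-bracket duplex (left&right) -> 0-based (target, query) pairs."""
    left, right = structure.split("&", 1)
    t_positions = [
        t_range[0] - 1 + i for i, ch in enumerate(left) if ch == "("
    ]
    q_positions = [
        q_range[0] - 1 + i for i, ch in enumerate(right) if ch == ")"
    ]
    # stack pairing: first '(' pairs last ')'
    return [
        (tp, qp) for tp, qp in zip(t_positions, reversed(q_positions))
    ]
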