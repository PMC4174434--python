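"""Data model and I/O for species-weighted collections of orthologous segments.

The search operates on a collection of unaligned orthologous sequence
segments ``s_ij`` indexed by species ``i = 1..m`` and segment identifier
``j = 1..n``: orthologous segments in different species carry the same
segment identifier, but no base-level alignment between them is assumed.
Species carry weight factors ``f_i`` summing to one, used to quantify how
widely a k-mer is conserved.

Segments are grouped into two (not necessarily disjoint) sides A and B, and
the pairs of segments that may interact are restricted by a relation R
between the segment identifier sets of the two sides (for intramolecular
structure, R links segments of the same gene; for trans-target scans,
R = A x B).
"""

from __future__ import annotations

import csv
import io
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Optional, Sequence

import dendropy
from Bio import SeqIO

__all__ = [
    "SpeciesTable",
    "Segment",
    "SegmentCollection",
    "Relation",
    "SearchConfig",
    "load_segments",
    "cap_segment",
    "opposite_strand_control",
    "compute_species_weights",
    "build_relation",
    "reverse_complement",
    "WEIGHT_TOL",
]

#: Tolerance used in every weighted-threshold comparison.  Weights such as
#: sixteen copies of 1/16 do not sum to exactly 1.0 in floating point; the
#: tolerance makes thresholds like t = 1.0 meaningful.
WEIGHT_TOL = 1e-9

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_ALPHABET = frozenset("ACGTN")


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return sequence.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Species table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpeciesTable:
    """Ordered species identifiers with weight factors ``f_i`` summing to one."""

    species_ids: tuple[str, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.species_ids) != len(self.weights):
            raise ValueError("species_ids and weights differ in length")
        if len(set(self.species_ids)) != len(self.species_ids):
            raise ValueError("species ids are not unique")
        if not self.species_ids:
            raise ValueError("empty species table")
        if any(w <= 0 for w in self.weights):
            raise ValueError("every species weight must be > 0")
        total = sum(self.weights)
        if abs(total - 1.0) > WEIGHT_TOL:
            raise ValueError(f"species weights sum to {total!r}, not 1")

    @classmethod
    def uniform(cls, species_ids: Sequence[str]) -> "SpeciesTable":
        m = len(species_ids)
        return cls(tuple(species_ids), tuple(1.0 / m for _ in range(m)))

    def weight(self, species: str) -> float:
        try:
            return self.weights[self.species_ids.index(species)]
        except ValueError:
            raise KeyError(f"unknown species {species!r}") from None

    @property
    def reference_species(self) -> str:
        """The highest-weight species (ties broken by table order)."""
        best = max(range(len(self.weights)), key=lambda i: (self.weights[i], -i))
        return self.species_ids[best]

    def __len__(self) -> int:
        return len(self.species_ids)


# ---------------------------------------------------------------------------
# Segments and collections
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Segment:
    """One orthologous segment ``s_ij``.

    ``strand_flag`` is "+" for input-strand sequence and "-" after the
    opposite-strand control transformation.
    """

    species: str
    segment_id: str
    gene_id: str
    sequence: str
    strand_flag: str = "+"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(
                f"empty sequence for segment {self.species}|{self.segment_id}"
            )
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise ValueError(
                f"segment {self.species}|{self.segment_id} contains characters "
                f"outside ACGTN: {sorted(bad)}"
            )
        if self.strand_flag not in ("+", "-"):
            raise ValueError("strand_flag must be '+' or '-'")

    @property
    def key(self) -> tuple[str, str]:
        return (self.species, self.segment_id)


def _clean_sequence(raw: str) -> str:
    """Uppercase and map RNA U to DNA T."""
    return raw.upper().replace("U", "T")


@dataclass(frozen=True)
class SegmentCollection:
    """A side (A or B) of the search: segments plus the species table."""

    side_label: str
    segments: tuple[Segment, ...]
    species_table: SpeciesTable

    def __post_init__(self) -> None:
        known = set(self.species_table.species_ids)
        seen: set[tuple[str, str]] = set()
        for seg in self.segments:
            if seg.species not in known:
                raise ValueError(
                    f"segment {seg.segment_id} references unknown species "
                    f"{seg.species!r}"
                )
            if seg.key in seen:
                raise ValueError(
                    f"duplicate segment ({seg.species}, {seg.segment_id})"
                )
            seen.add(seg.key)

    # -- lookups -----------------------------------------------------------

    def get(self, species: str, segment_id: str) -> Optional[Segment]:
        return self._by_key.get((species, segment_id))

    @property
    def _by_key(self) -> dict[tuple[str, str], Segment]:
        cache = self.__dict__.get("_by_key_cache")
        if cache is None:
            cache = {seg.key: seg for seg in self.segments}
            self.__dict__["_by_key_cache"] = cache
        return cache

    def segment_ids(self) -> tuple[str, ...]:
        """Sorted distinct segment identifiers (the j axis)."""
        return tuple(sorted({seg.segment_id for seg in self.segments}))

    def gene_of(self, segment_id: str) -> str:
        genes = {
            seg.gene_id for seg in self.segments if seg.segment_id == segment_id
        }
        if not genes:
            raise KeyError(f"unknown segment id {segment_id!r}")
        if len(genes) > 1:
            raise ValueError(
                f"segment id {segment_id!r} maps to several genes: {sorted(genes)}"
            )
        return genes.pop()

    def gene_map(self) -> dict[str, str]:
        """segment_id -> gene_id (validated one gene per segment id)."""
        out: dict[str, str] = {}
        for seg in self.segments:
            prev = out.setdefault(seg.segment_id, seg.gene_id)
            if prev != seg.gene_id:
                raise ValueError(
                    f"segment id {seg.segment_id!r} maps to several genes"
                )
        return out

    def species_present(self) -> tuple[str, ...]:
        return tuple(
            sp
            for sp in self.species_table.species_ids
            if any(seg.species == sp for seg in self.segments)
        )

    def __len__(self) -> int:
        return len(self.segments)


# ---------------------------------------------------------------------------
# Relations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Relation:
    """Allowed (left segment id, right segment id) combinations."""

    pairs: frozenset[tuple[str, str]]

    def validate(
        self, left: SegmentCollection, right: SegmentCollection
    ) -> None:
        left_ids = set(left.segment_ids())
        right_ids = set(right.segment_ids())
        for a, b in self.pairs:
            if a not in left_ids:
                raise ValueError(f"relation references unknown left segment {a!r}")
            if b not in right_ids:
                raise ValueError(f"relation references unknown right segment {b!r}")

    def partners_of(self) -> dict[str, frozenset[str]]:
        """Adjacency: left segment id -> set of allowed right partners."""
        adj: dict[str, set[str]] = {}
        for a, b in self.pairs:
            adj.setdefault(a, set()).add(b)
        return {a: frozenset(bs) for a, bs in adj.items()}

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)


def build_relation(
    collection_a: SegmentCollection,
    collection_b: SegmentCollection,
    mode: Literal["same-gene", "all-pairs", "from-file"],
    path: Optional[str | Path] = None,
) -> Relation:
    """Build the relation R restricting which segment pairs are searched.

    ``same-gene`` pairs every segment of A with every segment of B sharing its
    gene identifier (including self-pairs; deduplication of symmetric pairs
    is handled downstream).  ``all-pairs`` is the full Cartesian product.
    ``from-file`` loads a two-column TSV of (left id, right id) verbatim.
    """
    left_ids = collection_a.segment_ids()
    right_ids = collection_b.segment_ids()
    if mode == "same-gene":
        genes_a = collection_a.gene_map()
        genes_b = collection_b.gene_map()
        by_gene: dict[str, list[str]] = {}
        for j in right_ids:
            by_gene.setdefault(genes_b[j], []).append(j)
        pairs = frozenset(
            (a, b) for a in left_ids for b in by_gene.get(genes_a[a], ())
        )
        return Relation(pairs)
    if mode == "all-pairs":
        return Relation(frozenset((a, b) for a in left_ids for b in right_ids))
    if mode == "from-file":
        if path is None:
            raise ValueError("from-file mode requires a path")
        pairs = set()
        with open(path, newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                if len(row) < 2:
                    raise ValueError(f"malformed relation row: {row!r}")
                pairs.add((row[0], row[1]))
        relation = Relation(frozenset(pairs))
        relation.validate(collection_a, collection_b)
        return relation
    raise ValueError(f"unknown relation mode {mode!r}")


# ---------------------------------------------------------------------------
# Search configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SearchConfig:
    """Tunable parameters of the search.

    k       seed length (nt); feasible range 8-11, default 8
    t0      trimming threshold on single-k-mer conservation weight
    t       intersection threshold on complementary-pair conservation weight
            (t >= t0: meta-data trimmed at t0 can only be re-trimmed higher)
    G       maximum wobble G.T pairs allowed per k-mer duplex
    h       minimum G-C pairs required per k-mer duplex
    L       minimum complementary nucleotides per merged cluster
    gamma   maximum central gap size in a gapped seed (0 = ungapped seeds)
    delta   optional positional-divergence bound (None = unlimited)
    M       segment length cap: longer segments keep first M/2 + last M/2 nt
    unique_flag  report only ordered pairs alpha < beta (dedup when A == B)
    report_all   report every cluster per segment pair instead of one
    """

    k: int = 8
    t0: float = 0.5
    t: float = 0.8
    G: int = 1
    h: int = 0
    L: int = 8
    gamma: int = 0
    delta: Optional[int] = None
    M: int = 10000
    unique_flag: bool = True
    report_all: bool = False

    def __post_init__(self) -> None:
        if not (4 <= self.k <= 15):
            raise ValueError("k must be in [4, 15]")
        if not (8 <= self.k <= 11):
            warnings.warn(
                f"k={self.k} is outside the feasible range 8-11 nt",
                stacklevel=3,
            )
        if not (0.0 <= self.t0 <= self.t <= 1.0):
            raise ValueError("thresholds must satisfy 0 <= t0 <= t <= 1")
        if not (0 <= self.G <= self.k):
            raise ValueError("G must be in [0, k]")
        if not (0 <= self.h <= self.k):
            raise ValueError("h must be in [0, k]")
        if self.L < self.k:
            raise ValueError("L must be >= k")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.delta is not None and self.delta < 0:
            raise ValueError("delta must be >= 0 or None")
        if self.M % 2 != 0 or self.M < 2 * self.k:
            raise ValueError("M must be even and >= 2k")

    def as_dict(self) -> dict:
        return {
            "k": self.k,
            "t0": self.t0,
            "t": self.t,
            "G": self.G,
            "h": self.h,
            "L": self.L,
            "gamma": self.gamma,
            "delta": self.delta,
            "M": self.M,
            "unique_flag": self.unique_flag,
            "report_all": self.report_all,
        }


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def load_segments(
    fasta_path: str | Path,
    side_label: str,
    species_table: SpeciesTable,
) -> SegmentCollection:
    """Load a FASTA of orthologous segments into a collection.

    Headers follow the ``species|gene|segment_id`` dialect (pipe-separated),
    which makes same-gene relation building possible without annotation
    files.  RNA U is mapped to T; sequences are uppercased.
    """
    segments: list[Segment] = []
    seen: set[tuple[str, str]] = set()
    known = set(species_table.species_ids)
    with open(fasta_path) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            parts = record.id.split("|")
            if len(parts) != 3:
                raise ValueError(
                    f"malformed header {record.id!r}: expected "
                    "'species|gene|segment_id'"
                )
            species, gene, segment_id = parts
            if species not in known:
                raise ValueError(f"unknown species id {species!r} in header")
            key = (species, segment_id)
            if key in seen:
                raise ValueError(f"duplicate segment ({species}, {segment_id})")
            seen.add(key)
            segments.append(
                Segment(
                    species=species,
                    segment_id=segment_id,
                    gene_id=gene,
                    sequence=_clean_sequence(str(record.seq)),
                )
            )
    if not segments:
        raise ValueError(f"no FASTA records in {fasta_path}")
    return SegmentCollection(side_label, tuple(segments), species_table)


def write_segments(collection: SegmentCollection, path: str | Path) -> None:
    """Write a collection back to FASTA in the header dialect of load_segments."""
    with open(path, "w") as fh:
        for seg in collection.segments:
            fh.write(f">{seg.species}|{seg.gene_id}|{seg.segment_id}\n")
            for i in range(0, len(seg.sequence), 70):
                fh.write(seg.sequence[i : i + 70] + "\n")


def cap_segment(sequence: str, M: int) -> str:
    """Length cap: keep the first M/2 and last M/2 nt, discarding the middle.

    Prevents pathologically long segments from blowing up the hash tables.
    """
    if M < 2 or M % 2 != 0:
        raise ValueError("M must be even and >= 2")
    if len(sequence) <= M:
        return sequence
    half = M // 2
    return sequence[:half] + sequence[-half:]


def apply_cap(collection: SegmentCollection, M: int) -> SegmentCollection:
    """Apply the segment length cap to every segment of a collection."""
    return replace(
        collection,
        segments=tuple(
            replace(seg, sequence=cap_segment(seg.sequence, M))
            for seg in collection.segments
        ),
    )


def opposite_strand_control(collection: SegmentCollection) -> SegmentCollection:
    """Matched null set B': every sequence replaced by its reverse complement.

    Per-segment nucleotide conservation rate, length and GC content are
    identical to the input by construction; applying the control twice
    returns the original collection.
    """
    flipped = tuple(
        replace(
            seg,
            sequence=reverse_complement(seg.sequence),
            strand_flag="-" if seg.strand_flag == "+" else "+",
        )
        for seg in collection.segments
    )
    return replace(collection, segments=flipped)


def compute_species_weights(newick: str | Path) -> SpeciesTable:
    """Gerstein-Sonnhammer-Chothia species weights from a newick tree.

    Each branch length is apportioned among the leaves below it in
    proportion to the weight they have already accumulated (equally when
    all are zero); the leaf totals are normalized to sum to one.  A tree
    with zero total branch length yields uniform weights.

    ``newick`` may be a newick string or a path to a newick file.
    """
    text = str(newick)
    p = Path(text) if len(text) < 4096 and "(" not in text else None
    if p is not None and p.exists():
        text = p.read_text()
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"unparseable newick tree: {exc}") from exc

    leaf_names = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(leaf_names)) != len(leaf_names):
        raise ValueError("duplicate leaf names in tree")
    if any(
        e.length is not None and e.length < 0
        for e in tree.preorder_edge_iter()
    ):
        raise ValueError("negative branch length in tree")

    def gsc(node) -> dict[str, float]:
        if node.is_leaf():
            return {node.taxon.label: float(node.edge.length or 0.0)}
        acc: dict[str, float] = {}
        for child in node.child_nodes():
            acc.update(gsc(child))
        length = float(node.edge.length or 0.0)
        if length > 0.0 and node.parent_node is not None:
            total = sum(acc.values())
            if total > 0.0:
                for name in acc:
                    acc[name] += length * acc[name] / total
            else:
                share = length / len(acc)
                for name in acc:
                    acc[name] += share
        return acc

    raw = gsc(tree.seed_node)
    total = sum(raw.values())
    names = sorted(raw)
    if total <= 0.0:
        return SpeciesTable.uniform(names)
    return SpeciesTable(tuple(names), tuple(raw[n] / total for n in names))
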