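"""Gapped k-mer seed enumeration, per-species hash tables, wobble complements.

Every species gets a hash table H_i mapping a seed key omega to the sorted
array of its occurrences (j, p): omega occurs at position p of segment s_ij.
Seeds may carry a central gap of up to ``gamma`` nucleotides; the gap sits
strictly between a left half of ceil(k/2) and a right half of floor(k/2)
letters, and the gap *content* is forgotten — windows with different gap
sizes but identical halves share one key, which is what lets gapped seeds
tolerate both short internal loops and point mutations inside conserved
words.  Each occurrence records its own gap size.

Wobble G.T pairs are introduced by widening the reverse complement: the
complement of a key is not a single word but the set of all words pairing
against it antiparallel with Watson-Crick pairs plus at most G wobbles and
at least h G-C pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np

from .core_model import SearchConfig, SegmentCollection, SpeciesTable

__all__ = [
    "SeedKey",
    "SeedOccurrence",
    "KmerIndex",
    "enumerate_seeds",
    "wobble_complements",
    "build_index",
    "encode_word",
    "decode_word",
]

_NT2I = {"A": 0, "C": 1, "G": 2, "T": 3}
_I2NT = "ACGT"
_WC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def encode_word(word: str) -> int:
    """Base-4 integer encoding of a gap-free DNA word (A=0,C=1,G=2,T=3)."""
    code = 0
    for ch in word:
        code = code * 4 + _NT2I[ch]
    return code


def decode_word(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_I2NT[code & 3])
        code >>= 2
    return "".join(reversed(out))


@dataclass(frozen=True)
class SeedKey:
    """A (possibly gapped) seed key.

    Ungapped seeds have ``right == ""`` and ``left`` of length k.  Gapped
    seeds split the k letters into halves of ceil(k/2) and floor(k/2); the
    gap between them is not part of the key.
    """

    left: str
    right: str = ""

    def __post_init__(self) -> None:
        if self.right:
            k = self.k
            a = (k + 1) // 2
            if len(self.left) != a:
                raise ValueError(
                    f"gapped key halves must be {a}+{k - a} letters, got "
                    f"{len(self.left)}+{len(self.right)}"
                )

    @property
    def k(self) -> int:
        return len(self.left) + len(self.right)

    @property
    def word(self) -> str:
        """The k letters of the key, halves concatenated."""
        return self.left + self.right

    @property
    def gapped(self) -> bool:
        return bool(self.right)

    def __str__(self) -> str:
        return f"{self.left}.{self.right}" if self.right else self.left

    @classmethod
    def parse(cls, text: str) -> "SeedKey":
        if "." in text:
            left, right = text.split(".", 1)
            return cls(left, right)
        return cls(text)

    @classmethod
    def from_word(cls, word: str, gapped: bool) -> "SeedKey":
        if not gapped:
            return cls(word)
        a = (len(word) + 1) // 2
        return cls(word[:a], word[a:])

    def encode(self) -> int:
        return encode_word(self.word)

    @classmethod
    def from_code(cls, code: int, k: int, gapped: bool) -> "SeedKey":
        return cls.from_word(decode_word(code, k), gapped)


@dataclass(frozen=True)
class SeedOccurrence:
    """One occurrence of a seed: segment, 0-based start, gap size.

    The occupied extent on the sequence is ``k + gap_size`` nucleotides.
    """

    segment_id: str
    position: int
    gap_size: int = 0


def enumerate_seeds(
    sequence: str, k: int, gamma: int
) -> list[tuple[SeedKey, int, int]]:
    """All (key, position, gap_size) seeds of a sequence.

    Emits every ungapped k-window and, for each gap size g in 1..gamma,
    every window of span k+g with g letters skipped between the halves.
    Windows overlapping N are skipped.  Reference implementation; the
    index builder uses a vectorized equivalent.
    """
    if k < 4:
        raise ValueError("k must be >= 4")
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    gapped = gamma > 0
    a = (k + 1) // 2
    out: list[tuple[SeedKey, int, int]] = []
    n = len(sequence)
    for g in range(gamma + 1):
        span = k + g
        for p in range(n - span + 1):
            left = sequence[p : p + a]
            right = sequence[p + a + g : p + span]
            word = left + right
            if "N" in word:
                continue
            out.append((SeedKey.from_word(word, gapped), p, g))
    return out


def wobble_complements(omega: SeedKey, G: int, h: int) -> set[SeedKey]:
    """All keys chi that pair with omega antiparallel under the wobble rules.

    The pairing matches omega[u] with chi[k-1-u] (indices over the
    concatenated letters); every position must be a Watson-Crick pair or a
    G.T wobble, with at most ``G`` wobbles in total and at least ``h`` G-C
    pairs.  For gapped keys this pairs the left half of omega against the
    right half of chi and vice versa, forming an internal loop of up to
    gamma nt on either side.  The set may be empty (the h filter can be
    unsatisfiable); a key containing N has no complements.
    """
    word = omega.word
    k = len(word)
    if G < 0 or h < 0 or G > k or h > k:
        raise ValueError("G and h must be in [0, k]")
    if "N" in word:
        return set()

    # options per omega position: (partner letter, is_gc, is_wobble)
    options: list[list[tuple[str, int, int]]] = []
    for ch in word:
        opts = [(_WC[ch], 1 if ch in "GC" else 0, 0)]
        if ch == "G":
            opts.append(("T", 0, 1))
        elif ch == "T":
            opts.append(("G", 0, 1))
        options.append(opts)

    results: set[SeedKey] = set()
    partner = [""] * k

    def rec(u: int, wobbles: int, gc: int) -> None:
        if wobbles > G:
            return
        # even if every remaining position is G-C, can h still be reached?
        if gc + (k - u) < h:
            return
        if u == k:
            if gc >= h:
                results.add(
                    SeedKey.from_word("".join(reversed(partner)), omega.gapped)
                )
            return
        for letter, is_gc, is_wob in options[u]:
            partner[u] = letter
            rec(u + 1, wobbles + is_wob, gc + is_gc)

    rec(0, 0, 0)
    return results


# ---------------------------------------------------------------------------
# Index
# ---------------------------------------------------------------------------


@dataclass
class KmerIndex:
    """Per-species sorted seed-occurrence tables H_i.

    Internally each species holds parallel numpy arrays (key, seg, pos, gap)
    sorted lexicographically by (key, seg, pos), where ``seg`` indexes the
    sorted tuple ``seg_ids``; the per-key occurrence arrays H_i(omega) are
    then contiguous slices, themselves sorted by (segment, position).
    """

    k: int
    gamma: int
    species_ids: tuple[str, ...]
    seg_ids: tuple[str, ...]
    tables: dict[str, dict[str, np.ndarray]]

    # lazily built: per species, sorted unique packed (key * nseg + seg)
    _pair_cache: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def gapped(self) -> bool:
        return self.gamma > 0

    @property
    def n_segments(self) -> int:
        return len(self.seg_ids)

    def seg_index(self, segment_id: str) -> int:
        from bisect import bisect_left

        i = bisect_left(self.seg_ids, segment_id)
        if i == len(self.seg_ids) or self.seg_ids[i] != segment_id:
            raise KeyError(f"unknown segment id {segment_id!r}")
        return i

    def n_occurrences(self, species: Optional[str] = None) -> int:
        if species is not None:
            return int(self.tables[species]["key"].size)
        return sum(int(t["key"].size) for t in self.tables.values())

    def keys(self, species: str) -> np.ndarray:
        """Sorted distinct key codes present in a species' table."""
        return np.unique(self.tables[species]["key"])

    def all_keys(self) -> np.ndarray:
        """Sorted distinct key codes present in any species."""
        parts = [self.keys(sp) for sp in self.species_ids]
        return (
            np.unique(np.concatenate(parts)) if parts else np.empty(0, np.int64)
        )

    def get(self, species: str, key: SeedKey | int) -> np.ndarray:
        """Occurrence rows of a key: structured view (seg, pos, gap).

        Returns an (n, 3) int array of (seg index, position, gap size),
        sorted by (seg, pos).
        """
        code = key if isinstance(key, int) else key.encode()
        t = self.tables[species]
        lo = np.searchsorted(t["key"], code, side="left")
        hi = np.searchsorted(t["key"], code, side="right")
        return np.stack(
            [t["seg"][lo:hi], t["pos"][lo:hi], t["gap"][lo:hi]], axis=1
        )

    def occurrences(self, species: str, key: SeedKey | int) -> list[SeedOccurrence]:
        return [
            SeedOccurrence(self.seg_ids[int(s)], int(p), int(g))
            for s, p, g in self.get(species, key)
        ]

    def segs_with_key(self, species: str, key_code: int) -> np.ndarray:
        """Distinct segment indices of a species containing the key."""
        t = self.tables[species]
        lo = np.searchsorted(t["key"], key_code, side="left")
        hi = np.searchsorted(t["key"], key_code, side="right")
        return np.unique(t["seg"][lo:hi])

    def packed_pairs(self, species: str) -> np.ndarray:
        """Sorted unique packed (key * n_segments + seg) pairs of a species."""
        cached = self._pair_cache.get(species)
        if cached is None:
            t = self.tables[species]
            packed = t["key"] * np.int64(self.n_segments) + t["seg"]
            cached = np.unique(packed)
            self._pair_cache[species] = cached
        return cached

    def has_pair(self, species: str, key_code: int, seg_idx: int) -> bool:
        packed = self.packed_pairs(species)
        target = np.int64(key_code) * self.n_segments + seg_idx
        i = np.searchsorted(packed, target)
        return bool(i < packed.size and packed[i] == target)

    def is_sorted(self) -> bool:
        for t in self.tables.values():
            key, seg, pos = t["key"], t["seg"], t["pos"]
            if key.size < 2:
                continue
            order = np.lexsort((pos, seg, key))
            if not np.array_equal(order, np.arange(key.size)):
                return False
        return True

    # -- meta-data serialization ------------------------------------------

    def to_tsv(self, path: str | Path, t0: Optional[float] = None) -> None:
        """Write the (possibly trimmed) index as a sorted text meta-data file."""
        with open(path, "w") as fh:
            fh.write(
                f"#k={self.k}\tgamma={self.gamma}"
                + (f"\tt0={t0}" if t0 is not None else "")
                + "\n"
            )
            fh.write("#species\tkey\tsegment\tposition\tgap\n")
            for sp in self.species_ids:
                t = self.tables[sp]
                for key, seg, pos, gap in zip(
                    t["key"], t["seg"], t["pos"], t["gap"]
                ):
                    key_str = str(
                        SeedKey.from_code(int(key), self.k, self.gapped)
                    )
                    fh.write(
                        f"{sp}\t{key_str}\t{self.seg_ids[int(seg)]}\t"
                        f"{int(pos)}\t{int(gap)}\n"
                    )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KmerIndex":
        k = gamma = None
        rows: dict[str, list[tuple[int, str, int, int]]] = {}
        seg_ids: set[str] = set()
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    for fieldspec in line[1:].split("\t"):
                        if fieldspec.startswith("k="):
                            k = int(fieldspec[2:])
                        elif fieldspec.startswith("gamma="):
                            gamma = int(fieldspec[6:])
                    continue
                sp, key_str, seg, pos, gap = line.split("\t")
                rows.setdefault(sp, []).append(
                    (SeedKey.parse(key_str).encode(), seg, int(pos), int(gap))
                )
                seg_ids.add(seg)
        if k is None or gamma is None:
            raise ValueError("meta-data file lacks a #k=...\tgamma=... header")
        seg_tuple = tuple(sorted(seg_ids))
        seg_lookup = {s: i for i, s in enumerate(seg_tuple)}
        tables = {}
        for sp, entries in rows.items():
            arr = np.array(
                [(c, seg_lookup[s], p, g) for c, s, p, g in entries],
                dtype=np.int64,
            ).reshape(-1, 4)
            order = np.lexsort((arr[:, 2], arr[:, 1], arr[:, 0]))
            arr = arr[order]
            tables[sp] = {
                "key": arr[:, 0],
                "seg": arr[:, 1].astype(np.int32),
                "pos": arr[:, 2].astype(np.int32),
                "gap": arr[:, 3].astype(np.int8),
            }
        return cls(
            k=k,
            gamma=gamma,
            species_ids=tuple(sorted(rows)),
            seg_ids=seg_tuple,
            tables=tables,
        )


def _encode_sequence(seq: str) -> np.ndarray:
    """Sequence -> int8 codes; N (or anything else) becomes -1."""
    lut = np.full(256, -1, dtype=np.int8)
    for ch, v in _NT2I.items():
        lut[ord(ch)] = v
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_codes(codes: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-4 values of all w-windows and a validity mask (no N inside)."""
    n = codes.size
    if n < w:
        return np.empty(0, np.int64), np.empty(0, bool)
    win = np.lib.stride_tricks.sliding_window_view(codes, w)
    valid = (win >= 0).all(axis=1)
    pow4 = (4 ** np.arange(w - 1, -1, -1)).astype(np.int64)
    vals = (win.astype(np.int64) * pow4).sum(axis=1)
    return vals, valid


def seed_codes_of_sequence(
    seq: str, k: int, gamma: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized seed enumeration: (key codes, positions, gap sizes)."""
    codes = _encode_sequence(seq)
    a = (k + 1) // 2
    b = k - a
    keys: list[np.ndarray] = []
    poss: list[np.ndarray] = []
    gaps: list[np.ndarray] = []
    if b == 0:
        gamma = 0  # degenerate: no right half, gaps meaningless
    left_vals, left_ok = _window_codes(codes, a)
    right_vals, right_ok = (
        _window_codes(codes, b) if b else (np.zeros(1, np.int64), np.ones(1, bool))
    )
    for g in range(gamma + 1):
        span = k + g
        n_win = codes.size - span + 1
        if n_win <= 0:
            continue
        p = np.arange(n_win)
        if b:
            kv = left_vals[p] * (4**b) + right_vals[p + a + g]
            ok = left_ok[p] & right_ok[p + a + g]
        else:
            kv = left_vals[p]
            ok = left_ok[p]
        keys.append(kv[ok])
        poss.append(p[ok])
        gaps.append(np.full(int(ok.sum()), g, dtype=np.int8))
    if not keys:
        return (
            np.empty(0, np.int64),
            np.empty(0, np.int32),
            np.empty(0, np.int8),
        )
    return (
        np.concatenate(keys),
        np.concatenate(poss).astype(np.int32),
        np.concatenate(gaps),
    )


def build_index(
    collection: SegmentCollection, config: SearchConfig
) -> KmerIndex:
    """Build the per-species hash tables H_i for a collection.

    Segments are expected to be capped at M already (see
    :func:`ccfind.core_model.apply_cap`).  Output arrays are sorted by
    (key, segment, position); the result is independent of species
    processing order.
    """
    seg_ids = collection.segment_ids()
    seg_lookup = {s: i for i, s in enumerate(seg_ids)}
    tables: dict[str, dict[str, np.ndarray]] = {}
    for sp in collection.species_table.species_ids:
        key_parts: list[np.ndarray] = []
        seg_parts: list[np.ndarray] = []
        pos_parts: list[np.ndarray] = []
        gap_parts: list[np.ndarray] = []
        for seg in collection.segments:
            if seg.species != sp:
                continue
            kv, pv, gv = seed_codes_of_sequence(
                seg.sequence, config.k, config.gamma
            )
            key_parts.append(kv)
            seg_parts.append(
                np.full(kv.size, seg_lookup[seg.segment_id], dtype=np.int32)
            )
            pos_parts.append(pv)
            gap_parts.append(gv)
        if key_parts:
            key = np.concatenate(key_parts)
            segarr = np.concatenate(seg_parts)
            pos = np.concatenate(pos_parts)
            gap = np.concatenate(gap_parts)
        else:
            key = np.empty(0, np.int64)
            segarr = np.empty(0, np.int32)
            pos = np.empty(0, np.int32)
            gap = np.empty(0, np.int8)
        order = np.lexsort((pos, segarr, key))
        tables[sp] = {
            "key": key[order],
            "seg": segarr[order],
            "pos": pos[order],
            "gap": gap[order],
        }
    return KmerIndex(
        k=config.k,
        gamma=config.gamma,
        species_ids=collection.species_table.species_ids,
        seg_ids=seg_ids,
        tables=tables,
    )
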