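"""End-to-end orchestration: index -> trim -> pair -> assemble -> score.

The search path contains no randomness: rerunning on identical inputs and
configuration produces byte-identical reports.  Stage counts are collected
in a run manifest so every reported duplex is traceable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .core_model import (
    Relation,
    SearchConfig,
    SegmentCollection,
    SpeciesTable,
    apply_cap,
)
from .conservation_search import ConservedPairHit, pair_and_trim, trim_index
from .duplex_assembly import (
    Duplex,
    merge_clusters,
    naive_alignment,
    render_alignment,
    score_duplex,
    select_duplexes,
)
from .seed_index import KmerIndex, build_index

__all__ = ["RunManifest", "SearchResult", "run_search", "write_duplex_tsv", "write_hits_tsv"]


@dataclass
class RunManifest:
    """Config snapshot, input digests and per-stage counts of one run."""

    config: dict
    input_digests: dict[str, str] = field(default_factory=dict)
    rng_seeds: dict[str, int] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def to_json(self, path: Optional[str | Path] = None) -> str:
        text = json.dumps(
            {
                "config": self.config,
                "input_digests": self.input_digests,
                "rng_seeds": self.rng_seeds,
                "counts": self.counts,
                "notes": self.notes,
            },
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


@dataclass
class SearchResult:
    duplexes: list[Duplex]
    hits: list[ConservedPairHit]
    manifest: RunManifest
    indexes: tuple[KmerIndex, KmerIndex]
    collections: tuple[SegmentCollection, SegmentCollection]


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_search(
    collection_a: SegmentCollection,
    collection_b: Optional[SegmentCollection],
    relation: Relation,
    weights: SpeciesTable,
    config: SearchConfig,
    score: bool = True,
) -> SearchResult:
    """Run the full search on two collections under a relation.

    ``collection_b=None`` searches A against itself.  Validation failures
    (e.g. t < t0, unknown relation endpoints) raise before any work.
    """
    if config.t < config.t0:  # also enforced by SearchConfig
        raise ValueError("t must be >= t0")
    coll_b = collection_b if collection_b is not None else collection_a
    relation.validate(collection_a, coll_b)

    manifest = RunManifest(config=config.as_dict())
    capped_a = apply_cap(collection_a, config.M)
    capped_b = (
        capped_a if coll_b is collection_a else apply_cap(coll_b, config.M)
    )
    manifest.counts["segments_a"] = len(capped_a)
    manifest.counts["segments_b"] = len(capped_b)
    manifest.counts["relation_pairs"] = len(relation)

    index_a = build_index(capped_a, config)
    index_b = index_a if capped_b is capped_a else build_index(capped_b, config)
    manifest.counts["occurrences_a"] = index_a.n_occurrences()
    manifest.counts["occurrences_b"] = index_b.n_occurrences()

    trimmed_a = trim_index(index_a, weights, config.t0, config.delta)
    trimmed_b = (
        trimmed_a
        if index_b is index_a
        else trim_index(index_b, weights, config.t0, config.delta)
    )
    manifest.counts["occurrences_a_trimmed"] = trimmed_a.n_occurrences()
    manifest.counts["occurrences_b_trimmed"] = trimmed_b.n_occurrences()
    manifest.counts["keys_a_trimmed"] = int(trimmed_a.all_keys().size)

    hits = pair_and_trim(trimmed_a, trimmed_b, relation, weights, config)
    manifest.counts["hits"] = len(hits)

    duplexes = merge_clusters(hits, config)
    manifest.counts["clusters"] = len(duplexes)
    duplexes = select_duplexes(duplexes, config)
    manifest.counts["duplexes_reported"] = len(duplexes)

    if score:
        duplexes = [
            score_duplex(
                d,
                (capped_a, capped_b),
                (index_a, index_b),
                relation,
                weights,
                config,
            )
            for d in duplexes
        ]
        duplexes.sort(
            key=lambda d: (-(d.scores.total if d.scores else 0.0), d.segment_pair)
        )
    return SearchResult(
        duplexes=duplexes,
        hits=hits,
        manifest=manifest,
        indexes=(index_a, index_b),
        collections=(capped_a, capped_b),
    )


def write_hits_tsv(hits: Sequence[ConservedPairHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "key\tleft_segment\tleft_pos\tleft_gap\tright_segment\t"
            "right_pos\tright_gap\tsupport_weight\tsupport_species\n"
        )
        for h in sorted(
            hits, key=lambda h: (h.left, h.right, str(h.key))
        ):
            fh.write(
                f"{h.key}\t{h.left[0]}\t{h.left[1]}\t{h.left[2]}\t"
                f"{h.right[0]}\t{h.right[1]}\t{h.right[2]}\t"
                f"{h.support_weight:.6f}\t"
                f"{','.join(sorted(h.support_species))}\n"
            )


def write_duplex_tsv(duplexes: Sequence[Duplex], path: str | Path) -> None:
    """BED-like TSV: two anchored 0-based half-open spans per line."""
    with open(path, "w") as fh:
        fh.write(
            "left_segment\tleft_start\tleft_end\tright_segment\t"
            "right_start\tright_end\tmatched_length\tsupport_weight\t"
            "C1_left\tC1_right\tC2\ttotal_score\n"
        )
        for d in duplexes:
            s = d.scores
            fh.write(
                f"{d.left_span[0]}\t{d.left_span[1]}\t{d.left_span[2]}\t"
                f"{d.right_span[0]}\t{d.right_span[1]}\t{d.right_span[2]}\t"
                f"{d.matched_length}\t{d.support_weight:.6f}\t"
                + (
                    f"{s.c1_left:.4f}\t{s.c1_right:.4f}\t{s.c2:.4f}\t"
                    f"{s.total:.4f}\n"
                    if s
                    else "NA\tNA\tNA\tNA\n"
                )
            )


def write_alignment_report(
    result: SearchResult, path: str | Path
) -> None:
    with open(path, "w") as fh:
        for d in result.duplexes:
            fh.write(
                f"## duplex {d.left_span[0]}:{d.left_span[1]}-{d.left_span[2]}"
                f" / {d.right_span[0]}:{d.right_span[1]}-{d.right_span[2]}"
                f" matched={d.matched_length}\n"
            )
            blocks = naive_alignment(d, result.collections)
            fh.write(render_alignment(blocks))
            fh.write("\n")
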