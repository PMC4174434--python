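# ccfind — conserved complementarity in unaligned orthologous segments

`ccfind` is a search tool and Python library for detecting pairs of
complementary nucleotide regions that are simultaneously conserved across
many species — long-range RNA secondary structure in introns, snoRNA or
lncRNA target sites, or any RNA–RNA interaction signal — in orthologous
sequence segments that **cannot be aligned**.  It is aimed at comparative
genomicists working on splicing regulation and RNA–RNA interactions, where
the interesting complementary "islands" often sit in diverged intronic
background for which no multiple sequence alignment exists.

## The method in brief

The input is a collection of segments *s<sub>ij</sub>* indexed by species
*i* = 1…*m* (with weights *f<sub>i</sub>* summing to 1) and segment
identifier *j* = 1…*n*; orthologous segments share *j*.  The search is
*first-fold-then-align*:

1. each species' segments are hashed into tables *H<sub>i</sub>(ω)* of
   occurrences of every (optionally gapped) k-mer ω;
2. **trimming** deletes occurrences whose conservation weight
   *w*(ω, *j*) = Σ *f<sub>i</sub>* [ω occurs anywhere in *s<sub>ij</sub>*]
   falls below *t₀* — position inside the segment is deliberately
   forgotten;
3. for each surviving ω, its occurrences are paired with occurrences of
   its **wobble complement set** ω\* (all words pairing with ω with at most
   *G* G·T wobbles and at least *h* G–C pairs), restricted to segment
   pairs allowed by a relation ℛ (same gene, all-to-all, or a TSV), and
   kept when the joint support weight reaches *t*;
4. overlapping hits on a common anti-diagonal merge into duplexes, which
   must cover at least *L* paired nucleotides;
5. duplexes are ranked by a significance score
   C1<sub>left</sub> + C1<sub>right</sub> + C2, where
   C1 = −(ℓ−k+1)·log₁₀ρ measures surprise of the conserved box against the
   segment's background conservation rate ρ and C2 = −log₁₀(occurrences /
   partners) penalizes complements shared by many partner segments.

A rewiring control estimates the FDR: segments are binned into blocks by
conservation score and GC content, the relation's right endpoints are
permuted within blocks (avoiding same-gene pairs), and the search is
re-run; FDR = mean control count / reference count over repeated rewirings.
Two built-in simulators generate benchmark instances with ground truth:
planted complementary seeds in unalignable random segments, and orthologous
groups evolved down a binary tree.  See `docs/methods.md` for the full
model, parameter semantics, and design decisions.

## Worked example

Generate a small planted benchmark (6 species, 10 segments of 300 nt,
5 complementary 8-mer seed pairs with central gaps ≤ 2) and search it:

```sh
ccfind simulate seeds --n 10 --length 300 --m 6 --n-seeds 5 \
    --k 8 --max-gap 2 --seed 4 --out bench
ccfind search --left bench.fa --relation-mode same-gene \
    --k 8 --t0 0.95 --t 0.95 --G 1 --L 8 --gap 2 --M 1000 --out run
```

The log reports the stage counts (52 560 seed occurrences hashed, 61 left
after trimming at t₀ = 0.95, 5 hits, 5 duplexes), and `run.duplexes.tsv`
contains one duplex per planted pair:

```
left_segment  left_start  left_end  right_segment  right_start  right_end  matched_length  support_weight  C1_left  C1_right  C2      total_score
s0001         99          109       s0002          21           30         8               1.000000        7.4050   4.9367    0.3010  12.6428
s0009         184         193       s0010          232          241        8               1.000000        4.9367   4.9367    0.3010  10.1744
...
```

Reading the first line: a duplex pairs segment `s0001` (span 99–109,
0-based half-open — 10 nt because the planted copy carries a 2-nt internal
gap) with `s0002` (21–30), 8 paired nucleotides, supported by species of
total weight 1.0 (all six).  The truth file confirms the coordinates: seed
`TTACCGGC` was planted in `s0001` at position 99 with gap 2.  The score
components say the boxes are ~10⁷ and ~10⁵ times denser in conserved
k-mers than their segment backgrounds (C1), while C2 = 0.30 reflects that
the complement was found in 1 of the 2 same-gene partners scanned.

The FDR control and the tree benchmark are exposed the same way
(`ccfind fdr`, `ccfind simulate tree`, `ccfind filter-external`); run any
subcommand with `--help` for the full flag list.

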