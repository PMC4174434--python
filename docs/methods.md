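# Methods

## Problem and model

`ccfind` detects pairs of complementary nucleotide regions that are
*simultaneously conserved* across a set of species, in sequence segments
that are orthologous but **unaligned**.  The input is a collection of
segments `s_ij` indexed by species `i = 1..m` and segment identifier
`j = 1..n`; orthologous segments share `j` across species.  Species carry
weights `f_i` (summing to 1), either uniform or Gerstein–Sonnhammer–Chothia
weights computed from a newick tree, so that clusters of closely related
genomes do not dominate the conservation count.

The guiding idea is *first-fold-then-align*: instead of building a multiple
sequence alignment and then folding it, the method detects base-pairing
complementarity directly from k-mer content, with conservation defined by
the **position-forgetting rule** — a k-mer counts as conserved in segment j
when it occurs *anywhere* in `s_ij` of enough species, because unaligned
sequences cannot be meaningfully compared by position.  This is what makes
the method applicable where no alignment exists at all (diverged introns,
lncRNA targets, any synteny-extended orthology).

## Pipeline

1.  **Hashing.**  Each species gets a table `H_i` mapping a seed key to the
    sorted array of its occurrences `(j, p)`.  Seeds are k-mers (default
    `k = 8`; the feasible range is 8–11 nt) optionally carrying a central
    gap of `g <= gamma` nucleotides between a left half of `ceil(k/2)` and a
    right half of `floor(k/2)` letters.  The gap content is *not* part of
    the key: windows with different gap sizes but identical halves share
    one key, which lets gapped seeds model both short internal loops and
    isolated point mutations inside conserved words.  Segments longer than
    `M` keep only their first and last `M/2` nucleotides (memory guard for
    pathological inputs).  K-mers overlapping `N` are skipped.

2.  **Trimming.**  For a key ω and segment j the conservation weight
    `w(ω, j)` is the sum of `f_i` over species whose `s_ij` contains ω
    (each species once).  Occurrences with `w(ω, j) < t0` are deleted.
    Trimming happens *before* any pairing: the Cartesian product of
    untrimmed occurrence lists is intractably large, and trimming is
    idempotent and antitone in the threshold, so tables trimmed at an
    intermediate `t0` can be stored as meta-data and re-trimmed in memory
    at any `t >= t0`.  An optional positional bound Δ makes a species
    count only when its occurrence lies within Δ of the highest-weight
    species' occurrence; the default is unlimited, consistent with the
    position-forgetting rationale.

3.  **Wobble complements.**  The reverse complement of a key is widened to
    the set of all words pairing antiparallel against it with Watson–Crick
    pairs plus at most `G` G·T wobbles and at least `h` G–C pairs.  Wobble
    sets are symmetric (χ ∈ W(ω) ⇔ ω ∈ W(χ)) and `|W(ω, G=1, h=0)| =
    1 + #G + #T`.  For gapped keys complementarity is evaluated half-wise
    (left half of ω against right half of χ and vice versa), forming an
    internal loop of up to `gamma` nt on either side.

4.  **Pairing.**  For every key ω of side A, species i supports the segment
    pair `(j, j')` iff ω occurs in its `s_ij` and some χ in the wobble set
    occurs in its `s_ij'` (after trimming, i.e. each partner word must
    itself clear `t0`).  A pair is emitted iff `(j, j')` is allowed by the
    relation ℛ (same-gene, all-pairs, or explicit TSV) and the summed
    support weight reaches `t`.  With the uniqueness option only ordered
    pairs `(j, p) < (j', p')` are reported, and overlapping self-pairs are
    dropped while non-overlapping self-complementarity (a hairpin) is kept.
    All threshold comparisons are `>=` with a `1e-9` tolerance absorbing
    floating-point error in weight sums, so `t = 1.0` accepts a support
    weight of sixteen sixteenths.

5.  **Duplex assembly.**  Hits sharing a segment pair are sorted by their
    reference-species quadruple `(p, p')` (reference = highest-weight
    supporting species, a single frame that makes cluster maximality
    well-defined) and merged when their spans overlap or abut on a common
    anti-diagonal `p + p'` (gapped members may shift the diagonal by up to
    `gamma`).  A cluster's matched length counts paired positions only
    (gaps excluded); clusters below `L` are discarded.  By default one
    duplex is reported per segment pair — the longest cluster, the first
    occurring on ties — with `report_all` exposing every cluster.

6.  **Scoring.**  Each reported duplex gets a two-component significance
    score, both −log10-scaled so they add.  C1 (one per side) models
    conserved k-mer starts as independent Bernoulli(ρ) events over the
    box's `ell − k + 1` start positions, where ρ is the fraction of k-mer
    starts in the whole segment whose conservation weight reaches `t`
    (floored at `1/(starts + 1)` to keep the score finite):
    `C1 = −(ell − k + 1)·log10(ρ)`.  A conserved island in a nonconserved
    background scores high; a uniformly conserved segment drives ρ → 1 and
    C1 → 0, which is the expected behaviour — conservation alone is not
    evidence of base-pairing.  C2 penalizes promiscuous complements:
    `C2 = −log10(partners with a conserved complement / partners scanned)`.
    These formulas are this package's own definitions of the two named
    score components; they are deliberately simple and are not expected to
    reproduce any externally reported P-values.

7.  **Naive alignment.**  For display, the selected duplex anchors a
    block alignment: the complementary boxes and the flanking intervals
    are aligned separately across supporting species and concatenated,
    with box columns marked.  Flanks longer than 150 nt are middle-trimmed
    first.  The aligner is a star alignment centred on the reference
    species (pairwise global alignments at match +1 / mismatch −1 /
    gap −2, projected onto the centre's gap pattern).  The alignment is
    presentational: detection never depends on it.

## FDR by rewiring

The null model re-pairs segments across genes while preserving each
segment's conservation and composition profile.  Segments are binned on a
quantile grid of (conservation score, GC fraction) — conservation score of
a segment being the mean conservation weight over its k-mer starts — with
`q × r ≈ 500` cells by default (25 × 20; both factors configurable; empty
cells are fine on small inputs).  The right endpoints of the relation are
then permuted uniformly at random within blocks; pairs landing on their own
gene are re-drawn by bounded swapping (100 attempts) and dropped with a
warning when no admissible swap exists.  The search is re-run on each of
`repeats` (default 20) rewired relations under the identical configuration;
`FDR = mean control count / reference count`, with the SE and a 95%
t-interval over repeats.  Rewiring preserves the relation cardinality, the
left-endpoint multiset, and the per-block right-endpoint multiset exactly.

A subtlety worth recording: on *i.i.d.* synthetic segments, blocking by
composition makes control pairs composition-matched while the true pairs
are not, and composition-matched pairs have a slightly elevated chance of
chance complementarity.  The null-model exchangeability tests therefore use
a single block; on real data the blocking is precisely what keeps the
control honest, because same-gene pairs are composition-correlated.

## Benchmark generators

*Seed insertion* (unalignable orthologs): `m = 16` species each receive
`n = 200` independent uniform-random 1000-nt segments; 100 distinct random
8-mer seeds are drawn; seed q overwrites a uniform random position of
segment `2q−1` in every species and its reverse complement of segment
`2q`, each copy split by a central gap of uniform size 0–2 filled with
random nucleotides.  Segments of a group share no ancestry, so no aligner
can pair them — only simultaneous complementarity can.  Segments `2q−1`
and `2q` share a gene identifier, so the same-gene relation links exactly
the planted pairs.  Recovery is counted at the recorded coordinates
against the exhaustive cluster output.

*Tree evolution* (alignable orthologs): random 150-nt ancestors evolve down
a balanced binary tree to 16 leaves by independent per-site substitution.
The substitution rate (default 3%) is interpreted, by default, as the total
root-to-leaf divergence, spread evenly over the four branches of each
root-to-leaf path (`rate_mode="per-path"`); `"per-branch"` applies the rate
on every branch instead.  The choice matters enormously: the number of
complementary 8-mer pairs co-conserved in 12 of 16 species is
tail-sensitive to divergence (expected counts drop from ~1500 through ~20
to ~0 as root-to-leaf divergence goes 3% → 6% → 11%), so per-branch 3%
(≈11% root-to-leaf) yields an empty benchmark in which both the hash search
and any alignment-based tool find nothing.  Per-path keeps the benchmark
populated and the tool comparison meaningful; absolute pair counts should
be read as properties of this generator, not as universal constants.

*External-tool post-filter*: predictions from any base-pair predictor are
reduced to the benchmark's filtered pair set — a segment pair survives iff
it contains a window of ≥ 8 consecutive paired positions, each Watson–Crick
or G·T with at most one G·T per 8 nt, whose two words co-occur
(position-forgetting) in at least 12 of 16 species.  An optional harness
runs RNAplex all-vs-all on the reference species' sequences when the
executable is on PATH and parses its duplexes into such pair lists; every
pair surviving the filter is, by construction of the thresholds, also
discoverable by the hash search at `k = 8, G = 1, t = 0.75`, and the
containment is asserted exactly in the acceptance suite.  The tests never
require the external tool for the core claims.

## What the synthetic data does and does not show

The generators emulate the two regimes the method must handle — total
unalignability with planted signal, and alignable divergence — with
uniform base composition, independent sites, and substitution-only
evolution.  They do not emulate indels, composition heterogeneity (CpG,
isochores), repeats, paralogy, or strand-symmetric conserved DNA elements
(e.g. transcription-factor binding sites), the latter being a documented
confounder of complementarity searches on real genomes.  Passing tests
therefore demonstrate correctness of the machinery and the statistical
behaviour of the estimator under controlled conditions, not genome-scale
error rates.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere; output follows the BED
  convention (identical).
- DNA alphabet; `U` silently mapped to `T` on input; `N` kept in sequences
  but excluded from seeds.
- FASTA headers are `species|gene|segment_id`, making same-gene relation
  building possible without annotation files.
- GSC weights: each branch length is apportioned among the leaves below in
  proportion to already-accumulated weights (equally at zero), then
  normalized to sum 1; a zero-length tree yields uniform weights.  Uniform
  weights are the default when no tree is given.
- Trimming is vectorized as a grouped weight sum over packed
  (key, segment) pairs, never materializing untrimmed Cartesian products;
  correctness, not strategy, is the contract, and the brute-force oracle
  tests pin it down.
- One duplex per segment pair is the default report; ties in matched
  length break to the smallest reference (p, p').
- The test suite and acceptance script use reduced problem sizes where the
  full-scale run would add nothing but time: the seed-insertion benchmark
  runs at its full stated size (3200 segments); the tree benchmark harness
  runs at 40 groups per trial; FDR simulations use 4 species × 40 segments
  of 250 nt with 6–10 rewiring repeats.

## Known limitations

- The per-pair report hides secondary structures unless `report_all` is
  set; segment pairs with several distinct conserved duplexes get only the
  longest in the default view.
- C1/C2 assume independence of k-mer starts, which overlapping windows
  violate; scores are comparable within a run, not calibrated P-values.
- The star alignment is a display device; it does not attempt joint
  fold-and-align of the inter-box intervals.
- Rewiring operates at pair level within blocks; relations whose rewired
  pairs collide (same left, same right drawn twice) lose the duplicate,
  which is negligible for the sparse relations used here.
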