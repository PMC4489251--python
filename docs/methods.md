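# Methods

This note records the matching model, the algorithms, the parameter choices
and the known limitations of `affixpat`.

## 1. Matching model

### Query

A query is a pair of equal-length patterns over *elements*:

- **sequence pattern** — IUPAC nucleotide codes (`A C G U R Y S W K M B D H V
  N`; `T` is accepted as `U` on input) and bounded gaps `[x]` with
  `x ≥ 1`;
- **structure pattern** — `.` (unpaired), `(`/`)` (paired, properly nested)
  and gaps `[x]`, which must appear at the same element with the same bound
  in both patterns. Gap elements are unpaired by construction.

Pairs are read off the bracket nesting. Internally the query is a list of
typed elements (`code`, `gap`) plus the pair set, the gap-slot indices, the
fixed length (number of non-gap elements) and the maximal span
(fixed length + sum of gap bounds).

### Target

Targets are nucleotide FASTA records. Sequences are uppercased, `T` becomes
`U`, and **every other character** (ambiguity codes, `-`, whitespace
artefacts) becomes the internal wildcard `#`. The design decision here is
that a target wildcard matches *nothing*: a window containing `#` anywhere —
including at gap-filled positions — is not a match, even against a query `N`.
Ambiguous database characters assert uncertainty, not permission, so treating
them as free matches would manufacture unverifiable hits.

### Match semantics

An occurrence is a pair (window, gap vector): a 0-based window start plus one
realized length `g_k ∈ [0, x_k]` per gap slot, such that

1. every fixed element's target base is in the IUPAC expansion of its code,
2. every target base in the window (gap positions included) is a concrete
   `A/C/G/U`, and
3. for every structural pair `(i, j)`, the cost matrix entry for the ordered
   target bases at `i` and `j` is finite.

The match **cost** is the sum of the matrix entries over all pairs. Reporting
is *assignment-level*: distinct gap vectors over the same window are distinct
matches. An optional collapse step keeps, per `(target, start, end)` span,
the single match with the lexicographically smallest `(gap_total,
gap_vector)`. Reported coordinates are 1-based inclusive. Only the forward
strand is searched; to scan the reverse strand, search the
reverse-complemented target.

### Pairing cost matrix

A 4×4 table of non-negative floats or `inf`, read as whitespace-separated
text with a header row/column. `inf` (also accepted: `x`, `-`) forbids the
ordered pair; any finite value allows it at that cost. The matrix need not be
symmetric — rows index the 5′ partner. The default allows the four
Watson–Crick orientations and both G–U wobble orientations at cost 0 and
forbids everything else. An all-`inf` matrix is rejected at construction. No
thermodynamic meaning is attached to costs; they are a user-defined
admissibility/ranking device.

## 2. Index structures

### Enhanced suffix array (ESA)

Over the encoded text (sentinel `$` = 0 < `A` < `C` < `G` < `U` < `#` = 5;
wildcards are indexed like ordinary characters and rejected only at match
time) we build:

- the **suffix array** by prefix doubling over `numpy.lexsort` —
  O(n log n) passes of O(n log n) sorting, chosen because it is a few dozen
  lines of vectorized NumPy with no compiled dependency, and fast enough
  (a 2.6 Mb text indexes in roughly ten seconds, far inside any interactive
  budget). Any correct construction would do; correctness is defined by
  agreement with a naive sort, which the tests enforce on hundreds of random
  strings;
- the **LCP array** by Kasai's algorithm over the byte codes;
- the **child table** (up/down/next-ℓ-index) so that lcp-interval trees can
  be traversed top-down: `interval_extend(interval, c)` finds the
  sub-interval of words extending the current word by character `c` in
  O(σ) time.

### Affix array

The bidirectional index is the pair of ESAs of the text and of the reversed
text, plus **affix links**: given an lcp-interval for word `w` in one array,
the link is the interval of `reverse(w)` in the other array, which represents
the same set of text positions viewed from the other end. Links are computed
**lazily** — by descending the opposite array with the reversed word, O(|w|)
— and memoized per (direction, interval, depth) in a bounded cache, rather
than precomputed for all intervals. Searches touch a vanishing fraction of
all intervals, so lazy evaluation trades a negligible per-search cost for
not paying an O(n)-sized precomputation and storage on every index build.

Position translation: an occurrence at suffix position `p` in the reverse
array with depth `d` corresponds to text position `n − p − d` in the forward
orientation.

### Persistence

`save_index`/`load_index` write a small binary container: magic `AFXIDX`, a
format version, a SHA-256 digest of the normalized text, then the four
little-endian arrays (SA and LCP for both directions). Child tables are
recomputed on load (linear time, cheaper than storing them) and affix links
are never persisted (they are lazy). Loading verifies magic, version, digest
against the supplied text, and exact length — a cache can therefore never be
silently applied to the wrong target.

## 3. Search algorithm

### Decomposition

The pair set is parsed into a forest; each maximal **unbranched stem–loop**
(a chain of nested pairs with exactly one innermost loop, interior bulges
allowed) becomes a *hairpin section*. Everything else — unpaired linkers,
tails and multiloop-closing stems whose children branch — is the
*remainder*, kept as plain element ranges.

### Bidirectional section search

Each section is matched loop-outward on the affix array. The unpaired loop
is first matched left-to-right (forward array); then pairs are closed from
the innermost outward: extend left by a candidate opening base `b1`
(switching to the reverse array via an affix link if needed), then
immediately extend right by each closing base `b2` with finite
`matrix[b1][b2]`. A stem position thus never survives longer than one step
without its partner being checked — this early pairing test is the point of
bidirectionality.

The traversal is a depth-first search over tasks `(left element, right
element, array state)`. Interval states are memoized per task key so that
repeated subproblems (common under degenerate codes) are expanded once; gap
length assignments are carried alongside, outside the memo key's matched-word
identity, so distinct gap splits reaching the same interval are still
reported separately — required by assignment-level semantics. Interior gaps
inside a section branch over each feasible length.

### Merging and remainder verification

Sections are searched in **specificity order**: fewest expected occurrences
first (ranked by the number of degenerate sequence positions plus gap slack;
ties broken toward longer sections). The most specific section's hits seed
the candidate set; each further section is joined by exact distance windows
derived from prefix sums of fixed lengths and gap bounds between the
sections, located by binary search over the sorted hit starts/ends. A
candidate surviving all sections is then verified against the remainder: for
every feasible composition of the not-yet-fixed gap slots, the lead, linker
and tail ranges are checked for wildcards and IUPAC membership, and
remainder pairs (multiloop-closing stems) are scored with the matrix.
Queries with no pairs at all skip the index and use a direct forward scan.

### Reference matcher

`affixpat.oracle` shares only the query model and the match record with the
engine. It enumerates every window start and every gap vector and checks the
three match conditions literally, with a work-limit guard against
accidentally enormous enumerations. It exists to be obviously correct, and
the test suite requires the engine to agree with it exactly on hundreds of
randomized instances per run.

## 4. Synthetic data

`generate_fixture` plants a known number of non-overlapping query instances
into an i.i.d. background with a chosen GC fraction (P(G)=P(C)=gc/2). For
each instance it draws a gap vector uniformly within bounds, rejects
overlapping placements, instantiates each fixed code uniformly from its
IUPAC expansion, and overwrites each paired position pair with a draw from
the allowed pairs *compatible with both positions' codes* (an incompatible
combination raises rather than planting an invalid instance). The ground
truth (1-based start, gap vector, planted subsequence) is returned so recall
is measurable exactly.

What this emulates: motif density and composition bias of a genomic
background, and length-variable motif instances. What it does **not**
emulate: repeat structure, local compositional heterogeneity, correlated
neighbours, or true biological motif variability beyond the descriptor — so
measured false-positive behaviour on these fixtures does not predict
specificity on real genomes.

`random_query`, `random_target` and `random_matrix` produce bounded-complexity
randomized instances (≤3 hairpins with 1–3 bp stems, ≤3 gap slots with bounds
≤3, 25% ambiguous codes, 2% target wildcards, 50%-dense random matrices) for
engine-versus-reference equivalence testing. The bounds keep the reference
matcher's enumeration tractable while still exercising every code path:
branching, bulges, gaps at section boundaries, pair-free queries, empty
results.

## 5. Parameters and defaults

| Parameter | Default | Rationale |
| --- | --- | --- |
| gap bound cap | 10 000 | rejects absurd `[x]` bounds early; any realistic loop variability is orders of magnitude smaller |
| affix-link cache limit | 100 000 entries | bounds memory on adversarial queries; far above what realistic searches touch |
| oracle work limit | 2×10⁷ window×gap checks | keeps the reference matcher from silently running for hours; raised explicitly where needed |
| FASTA size guard | 100 MB | the in-memory index is ~20 bytes/nt; beyond this the user should shard |
| fixture packing guard | plants × max span ≤ length/2 | leaves enough background for rejection placement to terminate |
| default matrix | WC + G–U at cost 0 | standard RNA pairing admissibility |

Problem sizes used in the acceptance tests and reproduction script (500
equivalence trials at ≤200 nt, 200 index trials at ≤2000 nt, 50 plants in
100 kb, 25 plants in 2.6 Mb) were chosen to finish in tens of seconds while
being large enough that any systematic disagreement between the engine and
its oracles would be essentially certain to surface; the 2.6 Mb target is a
bacterial-genome-scale sanity check of the indexed path end to end.

## 6. Limitations

- Pseudoknots cannot be expressed: structure patterns must be properly
  nested.
- No mismatches or insertions in fixed elements: variability must be encoded
  with IUPAC codes and `[x]` gaps.
- Costs rank admissible matches; there is no thresholded "soft" pairing
  search beyond what finite-versus-`inf` expresses.
- Forward strand only; the reverse strand needs a second pass on the
  reverse complement.
- The index is held in memory; very large databases must be processed per
  record or sharded.
- Assignment-level reporting can produce many rows for highly gapped queries
  over low-complexity regions (by design; use `--collapse` for one row per
  span).
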