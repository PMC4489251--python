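# affixpat

Affix-array-indexed search for RNA sequence–structure motifs in nucleotide
databases.

## The problem

Many functional RNAs — riboswitch aptamers, snoRNAs, IRES elements — are
conserved more in their *secondary structure* than in their sequence. A useful
motif descriptor therefore combines three things:

1. an **IUPAC sequence pattern** (`A C G U` plus ambiguity codes such as `R`,
   `Y`, `N`) constraining what each position may be;
2. a **dot-bracket structure pattern** (`(`, `)`, `.`) declaring which
   positions must base-pair with each other; and
3. **bounded variable gaps** `[x]`, standing for 0–x unconstrained, unpaired
   nucleotides, which absorb the length variation of loops and linkers.

Given such a descriptor and a FASTA database, `affixpat` reports **every**
occurrence: every window and every assignment of gap lengths under which all
sequence codes match and all declared base pairs are admissible. Pair
admissibility is configurable through a 4×4 **pairing cost matrix**: a finite
cell means the ordered base pair is allowed at that cost, `inf` forbids it.
The default matrix allows Watson–Crick and G–U wobble pairs at cost 0. Each
reported match carries the total pairing cost of its realized pairs.

Scanning a genome position-by-position for such a pattern is wasteful. The
engine instead builds an **affix array** — an enhanced suffix array of the
text *and* of its reverse — which supports extending a matched word in
*either* direction in essentially constant time per character. Structure
patterns benefit enormously from bidirectional extension: starting inside a
hairpin loop and growing outward, each closing base of a stem is checked
immediately after its opening base, so the pairing constraint prunes the
search at the earliest possible moment instead of after the whole left arm
has been matched.

## How it works

- The query is decomposed into **hairpin sections** (maximal unbranched
  stem–loops) plus an unpaired/multiloop **remainder**.
- Each section is searched bidirectionally over the affix array: match the
  loop first, then grow outward pairwise, switching between the forward and
  reverse index via *affix links* whenever the extension direction flips.
- Sections are searched in order of **specificity** (fewest degenerate
  positions first), then merged by position arithmetic: prefix sums of fixed
  lengths and gap bounds give an exact feasible-distance window between
  neighbouring sections.
- Surviving candidates are verified against the remainder (including
  multiloop-closing pairs) for every feasible gap composition, and emitted as
  matches with 1-based inclusive coordinates, the matched subsequence, the
  aligned structure string, the gap vector and the pairing cost.

Matching is exact and assignment-level: two different gap-length vectors over
the same window are two matches (`--collapse` keeps one row per window, the
one with fewest gap nucleotides). A brute-force reference implementation
(`affixpat.oracle`) enumerates windows and gap vectors directly and is used
throughout the test suite to certify the engine.

See [docs/methods.md](docs/methods.md) for the full methods note.

## Worked example

A two-hairpin, aptamer-style descriptor: a 5-bp stem with a conserved 9-nt
loop, a gap of up to 3 nt, a second 5-bp stem with a conserved 7-nt loop,
another gap, and a conserved tail.

```text
seq:    NNNNNCUGUAUAAUNNNNN[3]NNNNNGGCAGUANNNNN[3]UCUACC
struct: (((((.........)))))[3](((((.......)))))[3]......
```

First plant three instances of it in 50 kb of random background (the `gen`
subcommand writes the FASTA and a ground-truth table):

```console
$ affixpat gen \
    --seq-pattern    'NNNNNCUGUAUAAUNNNNN[3]NNNNNGGCAGUANNNNN[3]UCUACC' \
    --struct-pattern '(((((.........)))))[3](((((.......)))))[3]......' \
    --n 3 --length 50000 --seed 11 --output demo
... INFO affixpat: wrote demo.fasta and demo.truth.tsv (3 planted)

$ cat demo.truth.tsv
target_id	start	gap_vector	subsequence
synthetic	17768	1,1	CUUGUCUGUAUAAUACAGGACGUAAGGCAGUAUUGUGCUCUACC
synthetic	19636	3,2	GUCUUCUGUAUAAUAAGGCGAUGAUUUGGCAGUAGGGUUUUUCUACC
synthetic	34409	2,3	UGUGUCUGUAUAAUGUGCGUCCACGGGGCAGUAUCGUGACCUCUACC
```

Then search for the motif:

```console
$ affixpat search --target demo.fasta \
    --seq-pattern    'NNNNNCUGUAUAAUNNNNN[3]NNNNNGGCAGUANNNNN[3]UCUACC' \
    --struct-pattern '(((((.........)))))[3](((((.......)))))[3]......' \
    --collapse --output -
... INFO affixpat: searching 1 record(s) with engine=affix
... INFO affixpat: 3 match(es)
target_id	start	end	matched_seq	aligned_structure	gap_total	gap_vector	cost
synthetic	17768	17811	CUUGUCUGUAUAAUACAGGACGUAAGGCAGUAUUGUGCUCUACC	(((((.........))))).(((((.......))))).......	2	1,1	0.0
synthetic	19636	19682	GUCUUCUGUAUAAUAAGGCGAUGAUUUGGCAGUAGGGUUUUUCUACC	(((((.........)))))...(((((.......)))))........	5	3,2	0.0
synthetic	34409	34455	UGUGUCUGUAUAAUGUGCGUCCACGGGGCAGUAUCGUGACCUCUACC	(((((.........)))))..(((((.......))))).........	5	2,3	0.0
```

All three planted instances are recovered at their exact positions and gap
vectors, with no false positives. `--index-cache PATH` persists the affix
array so repeated queries against the same target skip index construction;
`--engine naive` runs the brute-force reference instead, producing
byte-identical output. The same machinery is available as a library:

```python
from affixpat import parse_query, default_pairing_matrix, read_fasta, search

query = parse_query("GGNNNNNCC", "((.....))")
records = read_fasta("demo.fasta")
for m in search(records, query, default_pairing_matrix()):
    print(m.target_id, m.start, m.end, m.matched_seq, m.cost)
```

## Repository layout

| Path | Contents |
| --- | --- |
| `src/affixpat/query.py` | pattern parsing, IUPAC codes, pairing matrices |
| `src/affixpat/esa.py` | enhanced suffix array (SA, LCP, child table) |
| `src/affixpat/affix.py` | bidirectional affix array, index persistence |
| `src/affixpat/search.py` | decomposition, bidirectional search, merging |
| `src/affixpat/oracle.py` | brute-force reference matcher |
| `src/affixpat/fixtures.py` | planted-motif and randomized-instance generators |
| `src/affixpat/io.py`, `cli.py` | FASTA input, tabular output, command line |
| `tests/` | unit, property and acceptance tests |
| `scripts/acceptance.py` | end-to-end reproduction script |
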