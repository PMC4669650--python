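# Methods

## Encoding and the canonical form

K-mers are packed two bits per base, A=00, C=01, G=10, T=11, with the
5′-most base in the most significant occupied bit pair. This particular
mapping makes lexicographic order of k-mer strings coincide with numeric
order of packed words, which keeps dumps readable and lets string-based
oracles check sortedness directly. The 64-bit word bounds k at 32; counts
are 32-bit unsigned, so a k-mer (with its reverse complement) can be
counted up to 2³² − 1 times, saturating rather than wrapping beyond that.

The canonical form is the numeric minimum of a word and its reverse
complement. Reverse complement is computed by complementing every 2-bit
code (XOR with all-ones) and reversing the 2-bit groups with three
bit-parallel swap stages plus a byte swap — no per-base loop. For even k
there exist 4^(k/2) reverse-complement palindromes whose canonical class
has size 1; all other classes have size 2; odd k has no palindromes (the
middle base would have to equal its own complement). The exhaustive codec
tests assert exactly this class structure.

## Counting

`scan_sequence` slides a k-wide window: the packed words for all windows
are built with k shifted ORs over the per-base code array, and a
cumulative-sum trick marks every window that touches a non-ACGT byte.
Such windows are dropped entirely — an ambiguity code never contributes a
fabricated count, and counting resumes with the first clean window after
the offending character. Lowercase (soft-masked) bases are accepted and
treated as their uppercase forms; U is rejected rather than silently
mapped to T.

`make_list` concatenates the canonical word streams of all records of all
input files, so multiple inputs yield one list with summed counts, and
input file order cannot affect the output. Collation is `np.unique` with
counts. When `chunk_limit` caps the in-memory word table, chunks are
collated independently and merged by summing counts per word; the tests
require byte-identical output for `chunk_limit` ∈ {1, 10, unlimited}.
FASTQ quality strings are ignored; there is no quality trimming and no
probabilistic prefiltering of singletons.

## The list file

Fixed little-endian layout: 8-byte magic `KMERLST1`, u32 version, u32 k,
u64 n_unique, u64 total_count, then n_unique records of u64 word + u32
count (12 bytes, no padding). Fixed records give O(1) index arithmetic;
the reader memory-maps the payload, so opening costs only the header read
plus a file-size check, and one entry access touches one 12-byte record.
The writer streams entries in a single pass, validating strict ascending
order and positive counts, and back-patches n_unique/total_count into the
header afterwards. Corruption is diagnosed distinctly: bad magic,
truncated header, truncated or oversized payload, and (on full
validation) order violations, zero counts, non-canonical words and
header/sum mismatches. total_count is stored in the header because union
count conservation and the difference-from-union integrity check make
cheap use of it.

## Set operations

Presence in list i means stored count ≥ cutoff_i (default 1). A count
below the cutoff is invisible to the count rule as well — it enters the
rule as absence (0), not as its stored value — so cutoff semantics are
identical across rules. After the presence decision, classical set
membership picks the output words and the rule computes each count; any
rule evaluation yielding 0 (e.g. `subtract` on equal counts) omits the
word, so no list ever carries a zero count. Union forbids {subtract, min,
second} and difference forbids {add, min, max, second}: each forbidden
combination could either always or sometimes produce zeros for one-sided
words, and rejecting them up front (before any output is written) beats
silently dropping most of the output. Intersection, which always sees two
at-or-above-cutoff counts, admits all eight rules.

The merge itself is the classic two-pointer walk over both sorted inputs
— equal words are consumed from both sides simultaneously, so no
tie-break is ever needed — streaming entries to the writer. Symmetric
rules therefore commute, intersection ⊎ difference partitions A, and
add-rule union conserves total counts; all three laws are asserted on
seeded random pairs rather than assumed.

One wrinkle: the symmetric-rule commutativity law is stated here for the
rules each operation actually permits (union: one/two/add/max;
intersection: one/two/add/min/max), since `min` under union could emit a
zero for a one-sided word and is therefore excluded from union's rule
set.

## Difference-from-union and the marker recipe

If U is an add-rule union of a collection containing A, then for any word
of A, count_U ≥ count_A, with equality exactly when no other member
contributed it. `diff_from_union` walks A and U together, emits the
equal-count words with A's counts, and raises an integrity error the
moment it sees a word of A missing from U or with a smaller count — the
declared precondition is then provably false. Against U = A ∪_add B this
equals the plain first-rule difference A ∖ B, an identity the tests check
file-for-file on 100 seeded pairs.

`find_group_specific` folds the group's lists with *add-rule
intersection* — so the result carries each shared k-mer's total count
across the group — then applies difference-from-union against the
composite union of all lists. Equal counts now mean the k-mer occurs
nowhere outside the group: the output is the k-mers present in every
member and absent from every non-member.

## Mismatch search

Variant enumeration is over the probe: exactly-j-mismatch neighbors are
the C(k, j)·3^j words obtained by substituting j positions, generated by
position combinations and non-identity code offsets (+1..+3 mod 4, which
never reproduces the original base). Each variant is canonicalised before
lookup, since lists store only canonical forms; a hit therefore means the
stored word matches the variant on one of its two strands, making the
effective distance min over strand interpretations — the only definition
under which results cannot depend on which orientation happened to be
numerically smaller.

`lookup_with_mismatches` expands shells j = 0..m outward and records each
entry once, at its first (minimum) distance, so totals never double-count.
`diff_with_mismatches` starts from the exact difference and eliminates
survivors shell by shell, holding only the survivor array in memory
(O(|survivors|), never O(4^k)); survivors are emitted with A's counts.
The cost is Σ C(k, j)3^j lookups per survivor, fine for the intended
small m; indexed approximate-search structures and edit distance
(indels) are out of scope.

`merge_many` is a left-to-right fold of pairwise unions — the recursive
pairwise scheme used to build very large composite lists genome by
genome. For the permitted union rules the fold is associative, which the
tests verify on seeded triples instead of assuming.

## Synthetic data

The fixture generator emulates the *combinatorial* structure of the
problem, not the biology of real genomes: i.i.d. uniform ACGT sequences
(100–500 bp records, 1% N by default — typical short-contig sizes and a
realistic masked-base rate) have none of the repeat structure, GC skew or
long-range correlation of real DNA. That is deliberate: every operation
here is exact and combinatorial, so passing against uniform sequences
plus exhaustive oracles establishes correctness for any composition; what
it does not probe is performance at real-genome scale.

The clade fixture plants a 2 kb core shared by all nine genomes, a 600 bp
clade segment shared within each of three clades, and a 400 bp private
segment per genome, joined with k-length N spacers so no junction k-mers
arise. The expected clade-private marker set is computed from the planted
sequences with the naive dictionary oracle, so accidental k-mer
collisions between random segments are accounted for exactly, and the
marker-recipe test demands zero false positives and zero false negatives.
Segment lengths were chosen so each clade plants several hundred
markers (≫ 0, so an empty-output bug cannot pass) while the whole recipe
runs in seconds.

## Numerical and degenerate-input choices

- Counts saturate at 2³² − 1 (adds and per-k-mer tallies alike).
- Empty inputs are valid everywhere: empty FASTA sets produce valid empty
  lists, and every operation accepts them.
- Sequences shorter than k yield no windows; an all-N record likewise.
- Cutoffs below 1, k outside 1..32, m > k, rule/operation mismatches and
  k mismatches between operands are rejected before any output file is
  created.
- All randomness in fixtures flows from one integer seed through
  `numpy.random.default_rng`; identical specs give byte-identical FASTA,
  and the little-endian fixed-width format makes list files
  platform-independent.

## Known limitations

Single-threaded throughout (the determinism contract — identical output
regardless of scheduling — is what the tests pin down). Counting holds
chunk collation tables in memory; the two-pointer merges stream, but the
mismatch difference keeps its survivor set in RAM. No compression, no
quality-aware counting, no edit-distance search, and no compatibility
with any other tool's binary list layout.
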