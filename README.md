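# kmerset

Sorted canonical k-mer count lists and their set algebra, for sequence
analysis tasks that reduce to questions about k-mer content: which k-mers
does a genome contain, which are shared between samples, and which are
specific to one sample or one group — for example strain-specific marker
discovery, repeat detection with control sequences, or contamination
screening, all without assembly or alignment.

## The model

A k-mer (k ≤ 32) is packed into a 64-bit word, two bits per base (A=00,
C=01, G=10, T=11, 5′ base in the high bits). Since a k-mer and its reverse
complement name the same double-stranded word, only the *canonical* form —
the smaller of the two packed encodings — is stored, so both strands share
one entry. A **k-mer list** is a small header plus a strictly ascending
array of (canonical word, 32-bit count) pairs, stored as a fixed-record
binary file that supports O(1) random access and O(log N) binary-search
lookup.

Counting is by sort-and-collate: every valid window of every sequence is
packed, the words are sorted, and adjacent duplicates are counted.

Set operations (union A∪B, intersection A∩B, difference A∖B) are defined
over a *presence* predicate — a k-mer is present in a list only if its
count is at or above that list's cutoff — and a *count rule* decides the
output count: `one`, `two`, `add`, `subtract`, `min`, `max`, `first`,
`second` (defaults: union=`add`, intersection=`min`, difference=`first`).
All merges are single simultaneous passes over both sorted inputs, O(N),
streaming straight to disk.

Two further operations support marker discovery:

- **difference-from-union**: given A and an add-rule union U built from a
  collection containing A, the k-mers with equal counts in A and U were
  contributed by no other member — one composite list tests the
  specificity of every member.
- **mismatch difference**: the k-mers of A whose every variant within m
  substitutions (strand-aware) is absent from B, computed stepwise with
  increasing mismatch count over the shrinking survivor set.

## Worked example

```python
from kmerset import make_list, merge, open_list, decode_kmer

make_list(["sampleA.fa"], k=16, out_path="A.kml")
make_list(["sampleB.fa"], k=16, out_path="B.kml")
merge("A.kml", "B.kml", "onlyA.kml", "difference")  # rule "first"
with open_list("onlyA.kml") as h:
    print(h.n_unique, "k-mers unique to sample A")
```

The same pipeline from the shell:

```sh
kmerset make -k 3 -o toy.kml toy.fa       # toy.fa holds one record ACGTA
kmerset dump toy.kml
```

prints

```
ACG	2
GTA	1
```

three windows ACG, CGT, GTA; CGT canonicalises to ACG, giving count 2, and
TAC (the canonical form of GTA on the opposite strand) covers GTA's entry.
Querying the opposite strand finds the same entry:

```sh
kmerset query toy.kml --seq CGT      # -> CGT  2  ACG:0:2
```

The `examples/` directory holds one short narrative script per
capability: counting (`01`), set operations with rules and cutoffs (`02`),
group-specific marker discovery on a synthetic 9-genome, 3-clade fixture
(`03` — recovers all 585 planted markers per clade exactly), and
mismatch-tolerant query/difference (`04`). Each prints its numbers and
what they mean.

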