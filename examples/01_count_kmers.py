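"""Count canonical k-mers from a FASTA file into a sorted binary list.

Builds a tiny two-record FASTA, counts 5-mers, and prints the list.
"""

import tempfile
from pathlib import Path

from kmerset import decode_kmer, make_list, open_list

tmp = Path(tempfile.mkdtemp())
fasta = tmp / "toy.fa"
fasta.write_text(">chr1\nACGTACGTAC\n>chr2\nGGGACGTNNACGT\n")

header = make_list([fasta], k=5, out_path=tmp / "toy.kml")
print(f"list: k={header.k}, {header.n_unique} unique k-mers, "
      f"{header.total_count} total windows")

with open_list(tmp / "toy.kml") as handle:
    for word, count in handle:
        print(f"  {decode_kmer(word, handle.k)}\t{count}")

# Each line is a canonical 5-mer (one entry covers both strands) with its
# occurrence count; windows containing N contribute nothing.  total_count
# equals the number of valid windows across both records.
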