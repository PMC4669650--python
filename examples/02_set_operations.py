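"""Union, intersection and difference of two k-mer lists under count rules.

Two overlapping count tables are written as lists, then combined under the
default rules (union=add, intersection=min, difference=first) and with a
presence cutoff.
"""

import tempfile
from pathlib import Path

from kmerset import CutoffSpec, decode_kmer, merge, open_list, write_list

tmp = Path(tempfile.mkdtemp())
k = 3
# canonical words: 0="AAA", 6="ACG", 44="GTA" (canonical of TAC)
write_list(tmp / "A.kml", k, iter([(0, 4), (6, 1)]))
write_list(tmp / "B.kml", k, iter([(6, 3), (44, 2)]))


def show(title, path):
    with open_list(path) as h:
        entries = ", ".join(f"{decode_kmer(w, k)}:{c}" for w, c in h)
        print(f"{title:<28} {{{entries or 'empty'}}}")


merge(tmp / "A.kml", tmp / "B.kml", tmp / "u.kml", "union", rule="add")
show("A union B (add)", tmp / "u.kml")  # counts summed where shared

merge(tmp / "A.kml", tmp / "B.kml", tmp / "i.kml", "intersection", rule="min")
show("A intersect B (min)", tmp / "i.kml")  # smaller of the two counts

merge(tmp / "A.kml", tmp / "B.kml", tmp / "d.kml", "difference", rule="first")
show("A minus B (first)", tmp / "d.kml")  # A's count for A-only words

# With cutoff1=2, AAA (count 4) stays present but ACG (count 1 in A) no
# longer counts as present in A, so it leaves the intersection:
merge(tmp / "A.kml", tmp / "B.kml", tmp / "ic.kml", "intersection",
      cutoffs=CutoffSpec(cutoff1=2))
show("A intersect B, cutoff1=2", tmp / "ic.kml")
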