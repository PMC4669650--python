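"""Mismatch-tolerant lookup and mismatch difference.

Queries a small list with an increasing mismatch budget, then computes the
k-mers of one list that are at least 2 substitutions away from everything
in another list.
"""

import tempfile
from pathlib import Path

from kmerset import (canonicalize, decode_kmer, diff_with_mismatches,
                     encode_kmer, lookup_with_mismatches, open_list,
                     read_entries, write_list)

tmp = Path(tempfile.mkdtemp())
k = 6


def canon(s):
    return canonicalize(encode_kmer(s), k)


table = {canon("ACGTAC"): 5, canon("ACGTTT"): 2, canon("GGGGGG"): 1}
write_list(tmp / "ref.kml", k, iter(sorted(table.items())))

with open_list(tmp / "ref.kml") as handle:
    for m in (0, 1, 2):
        res = lookup_with_mismatches(handle, "ACGTAA", m)
        hits = ", ".join(f"{decode_kmer(w, k)}@{d}:{c}" for w, d, c in res.matches)
        print(f"probe ACGTAA, m={m}: total={res.total}  [{hits or 'no hits'}]")
# total sums the counts of every stored entry within m substitutions of the
# probe on either strand; each entry is reported once, at its minimum
# distance (the @d field).

other = {canon("ACGTAG"): 1}
write_list(tmp / "other.kml", k, iter(sorted(other.items())))
diff_with_mismatches(tmp / "ref.kml", tmp / "other.kml", tmp / "far.kml", m=2)
far = [decode_kmer(w, k) for w, _ in read_entries(tmp / "far.kml")[1]]
print(f"ref k-mers >2 mismatches from everything in other: {far}")
# Survivors differ from every k-mer of the second list at 3 or more
# positions (strand-aware) — candidates for highly specific probes.
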