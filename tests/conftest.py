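"""Shared helpers: list-file builders and independent pure-Python oracles.

The oracles here deliberately avoid the library's vectorised code paths:
counting is per-window string handling, set operations are dictionary
merges, and mismatch distances are exhaustive string comparisons, so each
test compares two independent routes to the same answer.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from kmerset import canonicalize, decode_kmer, encode_kmer, write_list

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp_str(s: str) -> str:
    return s.translate(COMPLEMENT)[::-1]


def canonical_str(s: str) -> int:
    """Canonical packed word of a k-mer string, by the string route."""
    return min(encode_kmer(s), encode_kmer(revcomp_str(s)))


def make_kml(path, table: dict[int, int], k: int):
    """Write a word->count dict (keys already canonical) as a list file."""
    write_list(path, k, iter(sorted(table.items())))
    return str(path)


def random_canonical_table(rng: np.random.Generator, k: int, n: int,
                           max_count: int = 9) -> dict[int, int]:
    """Random canonical-word count table with ~n entries."""
    words = rng.integers(0, 4**k, size=2 * n, dtype=np.uint64)
    canon = {canonicalize(int(w), k) for w in words}
    chosen = sorted(canon)[:n]
    return {w: int(rng.integers(1, max_count + 1)) for w in chosen}


def overlapping_pair(rng: np.random.Generator, k: int, n: int = 30
                     ) -> tuple[dict[int, int], dict[int, int]]:
    """Two tables sharing roughly half their words."""
    base = random_canonical_table(rng, k, 2 * n)
    words = list(base)
    rng.shuffle(words)
    third = max(1, len(words) // 3)
    only_a, shared, only_b = (words[:third], words[third:2 * third],
                              words[2 * third:])
    a = {w: int(rng.integers(1, 10)) for w in only_a + shared}
    b = {w: int(rng.integers(1, 10)) for w in shared + only_b}
    return a, b


# ---------------------------------------------------------------------------
# dictionary oracles for the set operations

def rule_oracle(rule: str, c1: int | None, c2: int | None) -> int:
    a, b = c1 or 0, c2 or 0
    return {"one": 1, "two": 2, "add": a + b, "subtract": max(a - b, 0),
            "min": min(a, b), "max": max(a, b), "first": a, "second": b}[rule]


def merge_oracle(ta: dict[int, int], tb: dict[int, int], op: str, rule: str,
                 cutoff1: int = 1, cutoff2: int = 1) -> dict[int, int]:
    """Presence-then-rule dictionary merge, the slow obvious way."""
    out = {}
    for w in sorted(set(ta) | set(tb)):
        c1 = ta.get(w)
        c2 = tb.get(w)
        if c1 is not None and c1 < cutoff1:
            c1 = None
        if c2 is not None and c2 < cutoff2:
            c2 = None
        present_a, present_b = c1 is not None, c2 is not None
        keep = {"union": present_a or present_b,
                "intersection": present_a and present_b,
                "difference": present_a and not present_b}[op]
        if not keep:
            continue
        c = rule_oracle(rule, c1, c2)
        if c > 0:
            out[w] = c
    return out


def canonical_hamming(a: int, b: int, k: int) -> int:
    """Min mismatch count over strand interpretations, via strings."""
    sa, sb = decode_kmer(a, k), decode_kmer(b, k)
    d1 = sum(x != y for x, y in zip(sa, sb))
    d2 = sum(x != y for x, y in zip(sa, revcomp_str(sb)))
    return min(d1, d2)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
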