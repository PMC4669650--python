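"""Query k-mer counts from sorted lists, exactly or within m mismatches.

Exact lookups are binary searches over the sorted word array (O(log N)
entry accesses).  Mismatch-tolerant lookups enumerate every variant of the
probe at exactly j = 0..m substituted positions, canonicalise each variant
and search it; an entry reachable at several distances is reported once,
at the smallest.  Distance is therefore strand-aware: the mismatch count
to the better-matching orientation of the stored canonical word.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Iterator

from .codec import canonicalize, decode_kmer, encode_kmer
from .listfile import ListHandle

logger = logging.getLogger(__name__)

__all__ = ["QueryResult", "lookup", "mismatch_neighbors",
           "lookup_with_mismatches", "query_stream"]


@dataclass
class QueryResult:
    """Outcome of one probe: matching entries and their summed counts."""

    query: str
    total: int = 0
    #: (canonical word, mismatch distance, count), each entry once at its
    #: smallest achieving distance
    matches: list[tuple[int, int, int]] = field(default_factory=list)
    error: str | None = None


def _binary_search(handle: ListHandle, word: int) -> int | None:
    """Index of ``word`` in the handle, or None; <= ceil(log2 n)+1 accesses."""
    lo, hi = 0, len(handle) - 1
    while lo <= hi:
        mid = (lo + hi) // 2
        w, _ = handle.get_entry(mid)
        if w == word:
            return mid
        if w < word:
            lo = mid + 1
        else:
            hi = mid - 1
    return None


def lookup(handle: ListHandle, word: int | str, k: int | None = None) -> int:
    """Stored count of a k-mer (canonicalised internally); 0 when absent.

    ``word`` may be a nucleotide string or a packed word (then ``k`` must
    equal the handle's k).
    """
    if isinstance(word, str):
        if len(word) != handle.k:
            raise ValueError(f"probe length {len(word)} != list k {handle.k}")
        word = encode_kmer(word)
    elif k is not None and k != handle.k:
        raise ValueError(f"probe k {k} != list k {handle.k}")
    canon = canonicalize(word, handle.k)
    idx = _binary_search(handle, canon)
    if idx is None:
        return 0
    return handle.get_entry(idx)[1]


def mismatch_neighbors(word: int, k: int, j: int, canonical: bool = False) -> set[int]:
    """All words differing from ``word`` at exactly j positions.

    Size is C(k, j) * 3^j; j=0 returns {word}.  With ``canonical=True``
    each variant is canonicalised first (the set may then be smaller).
    """
    if not 0 <= j <= k:
        raise ValueError(f"mismatch count j={j} outside 0..{k}")
    if j == 0:
        return {canonicalize(word, k) if canonical else word}
    out: set[int] = set()
    shifts = [2 * (k - 1 - p) for p in range(k)]  # position 0 = 5' end
    for pos in combinations(range(k), j):
        bases = [(word >> shifts[p]) & 3 for p in pos]
        for deltas in product((1, 2, 3), repeat=j):
            v = word
            for p, b, d in zip(pos, bases, deltas):
                v = (v & ~(3 << shifts[p])) | (((b + d) & 3) << shifts[p])
            out.add(canonicalize(v, k) if canonical else v)
    return out


def lookup_with_mismatches(handle: ListHandle, word: int | str, m: int) -> QueryResult:
    """All list entries within m substitutions of the probe.

    Variants are enumerated outward (j = 0, 1, .., m), so each entry is
    recorded at its minimum distance, and its count enters ``total`` once.
    """
    if isinstance(word, str):
        query_str = word.upper()
        if len(word) != handle.k:
            raise ValueError(f"probe length {len(word)} != list k {handle.k}")
        word = encode_kmer(word)
    else:
        query_str = decode_kmer(word, handle.k)
    k = handle.k
    if not 0 <= m <= k:
        raise ValueError(f"mismatch count m={m} outside 0..{k}")
    result = QueryResult(query=query_str)
    seen: set[int] = set()
    for j in range(m + 1):
        for canon in sorted(mismatch_neighbors(word, k, j, canonical=True)):
            if canon in seen:
                continue
            idx = _binary_search(handle, canon)
            if idx is not None:
                seen.add(canon)
                count = handle.get_entry(idx)[1]
                result.matches.append((canon, j, count))
                result.total += count
    return result


def _iter_probes(source_path: str | os.PathLike, source: str, k: int) -> Iterator[tuple[str, str | None]]:
    """Yield (probe string, error) pairs from a probe source."""
    if source == "text":
        with open(source_path) as fh:
            for lineno, line in enumerate(fh, 1):
                probe = line.strip()
                if not probe:
                    continue
                if len(probe) != k:
                    yield probe, f"line {lineno}: probe length {len(probe)} != k {k}"
                else:
                    yield probe, None
    elif source in ("fasta", "fastq"):
        from .maker import _iter_records
        for rid, seq in _iter_records(source_path, source):
            seq = seq.upper()
            n_skipped = 0
            for i in range(len(seq) - k + 1):
                window = seq[i : i + k]
                if any(b not in "ACGT" for b in window):
                    n_skipped += 1
                    continue
                yield window, None
            if n_skipped:
                logger.info("%s record %s: skipped %d ambiguous windows",
                            source_path, rid, n_skipped)
    elif source == "list":
        from .listfile import open_list
        with open_list(source_path) as other:
            if other.k != k:
                raise ValueError(f"probe list k {other.k} != list k {k}")
            for w, _c in other:
                yield decode_kmer(w, k), None
    else:
        raise ValueError(f"unknown probe source {source!r}")


def query_stream(handle: ListHandle, source_path: str | os.PathLike,
                 source: str = "text", m: int = 0) -> Iterator[QueryResult]:
    """One QueryResult per probe, in input order.

    Sources: ``text`` (one k-mer per line; a wrong-length line yields an
    error result and processing continues), ``fasta``/``fastq`` (sliding
    window; ambiguous windows are skipped with a logged note), ``list``
    (every entry of another list file).
    """
    for probe, err in _iter_probes(source_path, source, handle.k):
        if err is not None:
            logger.warning("%s: %s", source_path, err)
            yield QueryResult(query=probe, error=err)
            continue
        yield lookup_with_mismatches(handle, probe, m)
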