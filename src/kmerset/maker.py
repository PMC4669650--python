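"""Build k-mer count lists from FASTA/FASTQ by scan, sort and collate.

Counting works the way a sorting counter does: every valid window of every
sequence is packed to its canonical 2-bit word, the words are sorted, and
adjacent duplicates are collated into (word, count) entries.  Windows that
contain any non-ACGT character are skipped entirely — ambiguity codes
contribute no fabricated counts, and the window simply resumes past the
offending character.

Memory is bounded by ``chunk_limit``: when the word stream exceeds it, the
chunks are collated independently and merged by summing counts, which is
guaranteed (and tested) to reproduce the unchunked result byte for byte.
"""

from __future__ import annotations

import gzip
import os
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO

from .codec import MAX_K, canonicalize_array, encode_array
from .listfile import ListHeader, MAX_COUNT, write_list

__all__ = ["scan_sequence", "scan_sequence_array", "collate", "make_list"]


def scan_sequence_array(seq: str | bytes, k: int) -> np.ndarray:
    """Canonical words of every valid length-k window, in positional order.

    Returns a uint64 array; windows touching a non-ACGT character are
    dropped.  Sequences shorter than k yield an empty array.
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in 1..{MAX_K}, got {k}")
    codes = encode_array(seq)
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.uint64)
    bad = codes == 255
    codes = np.where(bad, 0, codes).astype(np.uint64)
    # words[i] = sum_j codes[i+j] << 2*(k-1-j): build with k shifted ORs
    nwin = n - k + 1
    words = np.zeros(nwin, dtype=np.uint64)
    two = np.uint64(2)
    for j in range(k):
        words = (words << two) | codes[j : j + nwin]
    if bad.any():
        # window i is valid iff no bad base in [i, i+k)
        bad_cum = np.concatenate(([0], np.cumsum(bad)))
        valid = (bad_cum[k:] - bad_cum[:-k]) == 0
        words = words[valid]
    return canonicalize_array(words, k)


def scan_sequence(seq: str, k: int) -> Iterator[int]:
    """Iterator form of :func:`scan_sequence_array` (Python ints)."""
    for w in scan_sequence_array(seq, k):
        yield int(w)


def collate(words: np.ndarray | Sequence[int]) -> list[tuple[int, int]]:
    """Sort words and count adjacent duplicates.

    Returns strictly ascending (word, multiplicity) pairs; the
    multiplicities sum to the input size regardless of input order.
    """
    arr = np.asarray(words, dtype=np.uint64)
    if arr.size == 0:
        return []
    uniq, counts = np.unique(arr, return_counts=True)
    return [(int(w), int(c)) for w, c in zip(uniq, counts)]


def _open_maybe_gzip(path: str | os.PathLike):
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _iter_records(path: str | os.PathLike, fmt: str) -> Iterator[tuple[str, str]]:
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"format must be 'fasta' or 'fastq', got {fmt!r}")
    with _open_maybe_gzip(path) as fh:
        try:
            for record in SeqIO.parse(fh, fmt):
                yield record.id, str(record.seq)
        except ValueError as exc:
            raise ValueError(f"{os.fspath(path)}: malformed {fmt}: {exc}") from exc


def _merge_chunks(chunks: list[tuple[np.ndarray, np.ndarray]]) -> tuple[np.ndarray, np.ndarray]:
    """Sum counts of per-chunk collated arrays into one sorted table."""
    if not chunks:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.uint64)
    words = np.concatenate([w for w, _ in chunks])
    counts = np.concatenate([c for _, c in chunks])
    order = np.argsort(words, kind="stable")
    words = words[order]
    counts = counts[order]
    boundary = np.concatenate(([True], words[1:] != words[:-1]))
    group = np.cumsum(boundary) - 1
    summed = np.zeros(int(group[-1]) + 1, dtype=np.uint64)
    np.add.at(summed, group, counts)
    return words[boundary], summed


def make_list(
    inputs: Sequence[str | os.PathLike],
    k: int,
    out_path: str | os.PathLike,
    fmt: str = "fasta",
    chunk_limit: int | None = None,
) -> ListHeader:
    """Count canonical k-mers across all records of all inputs into a list file.

    Counts are summed across records and files; per-k-mer counts saturate
    at 2^32 - 1.  ``chunk_limit`` caps the number of raw words held in
    memory at once and never changes the output.
    """
    if chunk_limit is not None and chunk_limit < 1:
        raise ValueError("chunk_limit must be >= 1")
    chunks: list[tuple[np.ndarray, np.ndarray]] = []
    pending: list[np.ndarray] = []
    pending_size = 0

    def flush() -> None:
        nonlocal pending, pending_size
        if not pending:
            return
        arr = np.concatenate(pending) if len(pending) > 1 else pending[0]
        uniq, counts = np.unique(arr, return_counts=True)
        chunks.append((uniq, counts.astype(np.uint64)))
        pending = []
        pending_size = 0

    for path in inputs:
        for _rid, seq in _iter_records(path, fmt):
            words = scan_sequence_array(seq, k)
            if chunk_limit is None:
                if words.size:
                    pending.append(words)
                continue
            start = 0
            while start < words.size:
                room = chunk_limit - pending_size
                take = words[start : start + room]
                pending.append(take)
                pending_size += take.size
                start += take.size
                if pending_size >= chunk_limit:
                    flush()
    flush()
    words, counts = _merge_chunks(chunks)
    counts = np.minimum(counts, MAX_COUNT)
    return write_list(out_path, k, ((int(w), int(c)) for w, c in zip(words, counts)))
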