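"""Sorted binary k-mer list files.

Layout (all integers little-endian, no padding):

==========  =======  ==========================================
offset      size     field
==========  =======  ==========================================
0           8        magic ``b"KMERLST1"``
8           4        format version (currently 1)
12          4        k (1..32)
16          8        n_unique — number of entries
24          8        total_count — sum of all entry counts
32          12 each  entries: word (u64) + count (u32)
==========  =======  ==========================================

Entries are canonical words in strictly ascending numeric order, each with
a count >= 1.  Fixed 12-byte records give O(1) index arithmetic, so a
memory-mapped handle answers random accesses without materialising the
file; writing streams entries in one pass and back-patches the header.
"""

from __future__ import annotations

import mmap
import os
import struct
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

from .codec import MAX_K, canonicalize

__all__ = [
    "MAGIC",
    "VERSION",
    "MAX_COUNT",
    "ListHeader",
    "ListFormatError",
    "write_list",
    "open_list",
    "ListHandle",
    "read_entries",
]

MAGIC = b"KMERLST1"
VERSION = 1
MAX_COUNT = 2**32 - 1

_HEADER = struct.Struct("<8sIIQQ")
_ENTRY = struct.Struct("<QI")
HEADER_SIZE = _HEADER.size  # 32
ENTRY_SIZE = _ENTRY.size  # 12

ENTRY_DTYPE = np.dtype([("word", "<u8"), ("count", "<u4")])
assert ENTRY_DTYPE.itemsize == ENTRY_SIZE


class ListFormatError(ValueError):
    """Raised for malformed list files or invalid entry streams."""


@dataclass(frozen=True)
class ListHeader:
    k: int
    n_unique: int
    total_count: int
    version: int = VERSION


def write_list(path: str | os.PathLike, k: int, entries: Iterable[tuple[int, int]]) -> ListHeader:
    """Stream ``(word, count)`` entries to a list file in one pass.

    Entries must arrive strictly ascending by word with counts >= 1; the
    header's ``n_unique`` and ``total_count`` are back-patched at the end.
    """
    if not 1 <= k <= MAX_K:
        raise ListFormatError(f"k must be in 1..{MAX_K}, got {k}")
    n_unique = 0
    total = 0
    prev = -1
    with open(path, "wb") as fh:
        fh.write(_HEADER.pack(MAGIC, VERSION, k, 0, 0))
        buf = bytearray()
        for word, count in entries:
            if word <= prev:
                raise ListFormatError(
                    f"entries out of order: word {word} follows {prev} "
                    "(must be strictly ascending)"
                )
            if not 1 <= count <= MAX_COUNT:
                raise ListFormatError(f"count {count} for word {word} outside 1..{MAX_COUNT}")
            if word >> (2 * k):
                raise ListFormatError(f"word {word:#x} does not fit k={k}")
            prev = word
            buf += _ENTRY.pack(word, count)
            n_unique += 1
            total += count
            if len(buf) >= 1 << 20:
                fh.write(buf)
                buf.clear()
        fh.write(buf)
        fh.seek(0)
        fh.write(_HEADER.pack(MAGIC, VERSION, k, n_unique, total))
    return ListHeader(k=k, n_unique=n_unique, total_count=total)


class ListHandle:
    """Random-access view of a list file.

    Opening reads only the fixed-size header and checks the payload length;
    entry access touches one 12-byte record, honouring the bounded-touch
    contract that stands in for memory mapping (and is implemented with it).
    """

    def __init__(self, path: str | os.PathLike):
        self.path = os.fspath(path)
        self._fh = open(self.path, "rb")
        try:
            head = self._fh.read(HEADER_SIZE)
            if len(head) < HEADER_SIZE:
                raise ListFormatError(f"{self.path}: truncated header ({len(head)} bytes)")
            magic, version, k, n_unique, total = _HEADER.unpack(head)
            if magic != MAGIC:
                raise ListFormatError(f"{self.path}: bad magic {magic!r}, expected {MAGIC!r}")
            if version != VERSION:
                raise ListFormatError(f"{self.path}: unsupported version {version}")
            if not 1 <= k <= MAX_K:
                raise ListFormatError(f"{self.path}: header k={k} outside 1..{MAX_K}")
            size = os.fstat(self._fh.fileno()).st_size
            expected = HEADER_SIZE + ENTRY_SIZE * n_unique
            if size != expected:
                kind = "truncated" if size < expected else "oversized"
                raise ListFormatError(
                    f"{self.path}: {kind} payload — header promises {n_unique} entries "
                    f"({expected} bytes), file has {size} bytes"
                )
            self.header = ListHeader(k=k, n_unique=n_unique, total_count=total, version=version)
            if n_unique:
                self._mm = mmap.mmap(self._fh.fileno(), 0, access=mmap.ACCESS_READ)
            else:
                self._mm = None
        except Exception:
            self._fh.close()
            raise

    # -- header conveniences -------------------------------------------------
    @property
    def k(self) -> int:
        return self.header.k

    @property
    def n_unique(self) -> int:
        return self.header.n_unique

    @property
    def total_count(self) -> int:
        return self.header.total_count

    def __len__(self) -> int:
        return self.header.n_unique

    # -- entry access --------------------------------------------------------
    def get_entry(self, index: int) -> tuple[int, int]:
        """The index-th ``(word, count)`` pair in ascending word order."""
        if not 0 <= index < self.header.n_unique:
            raise IndexError(f"entry index {index} out of range 0..{self.header.n_unique - 1}")
        off = HEADER_SIZE + ENTRY_SIZE * index
        return _ENTRY.unpack_from(self._mm, off)

    def __iter__(self) -> Iterator[tuple[int, int]]:
        for i in range(self.header.n_unique):
            yield self.get_entry(i)

    def words(self) -> np.ndarray:
        """All words as a uint64 array (a copy; empty for empty lists)."""
        return self._records()["word"].astype(np.uint64)

    def counts(self) -> np.ndarray:
        """All counts as a uint32 array."""
        return self._records()["count"].copy()

    def _records(self) -> np.ndarray:
        if self._mm is None:
            return np.empty(0, dtype=ENTRY_DTYPE)
        return np.frombuffer(self._mm, dtype=ENTRY_DTYPE, offset=HEADER_SIZE,
                             count=self.header.n_unique)

    def validate(self) -> None:
        """Full-scan integrity check: sortedness, canonical words, count sums."""
        rec = self._records()
        words = rec["word"]
        counts = rec["count"]
        if words.size:
            if not np.all(words[:-1] < words[1:]):
                i = int(np.argmin(words[:-1] < words[1:]))
                raise ListFormatError(
                    f"{self.path}: entries not strictly ascending at index {i}"
                )
            if np.any(counts == 0):
                raise ListFormatError(f"{self.path}: zero count present")
            sample = words[:: max(1, words.size // 256)]
            for w in sample:
                if canonicalize(int(w), self.header.k) != int(w):
                    raise ListFormatError(
                        f"{self.path}: non-canonical word {int(w):#x}"
                    )
        if int(counts.sum(dtype=np.uint64)) != self.header.total_count:
            raise ListFormatError(
                f"{self.path}: header total_count {self.header.total_count} != "
                f"entry sum {int(counts.sum(dtype=np.uint64))}"
            )

    def close(self) -> None:
        if self._mm is not None:
            self._mm.close()
            self._mm = None
        if not self._fh.closed:
            self._fh.close()

    def __enter__(self) -> "ListHandle":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def __repr__(self) -> str:  # pragma: no cover
        return (f"ListHandle({self.path!r}, k={self.header.k}, "
                f"n_unique={self.header.n_unique}, total_count={self.header.total_count})")


def open_list(path: str | os.PathLike) -> ListHandle:
    """Open a list file for random access; O(1) in the file size."""
    return ListHandle(path)


def read_entries(path: str | os.PathLike) -> tuple[ListHeader, list[tuple[int, int]]]:
    """Materialise a whole list (header consistency is re-checked)."""
    with open_list(path) as handle:
        entries = list(handle)
        total = sum(c for _, c in entries)
        if total != handle.header.total_count or len(entries) != handle.header.n_unique:
            raise ListFormatError(f"{path}: header/payload mismatch on full read")
        return handle.header, entries
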