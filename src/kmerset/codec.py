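"""2-bit k-mer codec: packing, reverse complement and canonical form.

A k-mer of length k (1 <= k <= 32) is packed into an unsigned 64-bit word
with two bits per nucleotide under the mapping A=00, C=01, G=10, T=11.
The 5'-most base occupies the most significant occupied bit pair, so
lexicographic order of k-mer strings coincides with numeric order of words.

Because a k-mer and its reverse complement name the same double-stranded
word, lists store only the *canonical* form: the smaller of the two packed
encodings.  All functions here are strand-aware building blocks for that
convention.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "MAX_K",
    "encode_kmer",
    "decode_kmer",
    "revcomp_word",
    "canonicalize",
    "encode_array",
    "revcomp_array",
    "canonicalize_array",
]

MAX_K = 32

_BASE_TO_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_TO_BASE = "ACGT"

# byte-indexed code table: 255 marks a non-ACGT byte (used by the scanner)
_CODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _b, _c in _BASE_TO_CODE.items():
    _CODE_TABLE[ord(_b)] = _c
    _CODE_TABLE[ord(_b.lower())] = _c


def _check_k(k: int) -> None:
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in 1..{MAX_K}, got {k}")


def _check_word(value: int, k: int) -> None:
    _check_k(k)
    if value < 0 or value >> (2 * k):
        raise ValueError(
            f"word {value:#x} has bits set above position {2 * k - 1} for k={k}"
        )


def encode_kmer(seq: str, k: int | None = None) -> int:
    """Pack a nucleotide string into a 2-bit word.

    Parameters
    ----------
    seq : str
        A/C/G/T only, case-insensitive, length 1..32.
    k : int, optional
        If given, must equal ``len(seq)``.

    Returns
    -------
    int
        The packed word; the 5'-most base sits in the high bits.
    """
    n = len(seq)
    if k is not None and k != n:
        raise ValueError(f"declared k={k} but sequence has length {n}")
    _check_k(n)
    value = 0
    for i, base in enumerate(seq):
        code = _BASE_TO_CODE.get(base.upper())
        if code is None:
            raise ValueError(
                f"invalid nucleotide {base!r} at position {i} (only A/C/G/T allowed)"
            )
        value = (value << 2) | code
    return value


def decode_kmer(value: int, k: int) -> str:
    """Unpack a 2-bit word back into an uppercase nucleotide string."""
    _check_word(value, k)
    bases = []
    for shift in range(2 * (k - 1), -2, -2):
        bases.append(_CODE_TO_BASE[(value >> shift) & 3])
    return "".join(bases)


# 64-bit bit-twiddling masks for reversing the order of 2-bit groups
_M2 = 0x3333333333333333
_M4 = 0x0F0F0F0F0F0F0F0F
_U64 = 0xFFFFFFFFFFFFFFFF


def revcomp_word(value: int, k: int) -> int:
    """Reverse complement of a packed word, same k.

    Complementing flips each 2-bit code (A<->T, C<->G is code XOR 3);
    reversal swaps 2-bit groups pairwise, then nibbles, then bytes.
    """
    _check_word(value, k)
    x = (~value) & _U64
    x = ((x & _M2) << 2) | ((x >> 2) & _M2)
    x = ((x & _M4) << 4) | ((x >> 4) & _M4)
    x = int.from_bytes(x.to_bytes(8, "little"), "big")  # byte reversal
    return x >> (64 - 2 * k)


def canonicalize(value: int, k: int) -> int:
    """The canonical form: min of the word and its reverse complement."""
    rc = revcomp_word(value, k)
    return value if value <= rc else rc


# ---------------------------------------------------------------------------
# vectorised variants over uint64 arrays (used by the scanner and merges)

def encode_array(seq: str | bytes) -> np.ndarray:
    """Map a sequence to per-base 2-bit codes; 255 flags non-ACGT bytes."""
    if isinstance(seq, str):
        seq = seq.encode("ascii", errors="replace")
    raw = np.frombuffer(seq, dtype=np.uint8)
    return _CODE_TABLE[raw]


def revcomp_array(words: np.ndarray, k: int) -> np.ndarray:
    """Vectorised :func:`revcomp_word` over a uint64 array."""
    _check_k(k)
    x = (~words.astype(np.uint64))
    m2 = np.uint64(_M2)
    m4 = np.uint64(_M4)
    two = np.uint64(2)
    four = np.uint64(4)
    x = ((x & m2) << two) | ((x >> two) & m2)
    x = ((x & m4) << four) | ((x >> four) & m4)
    x = x.byteswap()
    return x >> np.uint64(64 - 2 * k)


def canonicalize_array(words: np.ndarray, k: int) -> np.ndarray:
    """Vectorised canonical form over a uint64 array."""
    rc = revcomp_array(words, k)
    return np.minimum(words.astype(np.uint64), rc)
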