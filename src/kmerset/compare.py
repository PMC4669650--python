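"""Set algebra on sorted k-mer lists: union, intersection, difference.

Membership is classical set semantics over a *presence* predicate: a k-mer
is present in a list only if its stored count is at or above that list's
cutoff (default 1).  Once membership is decided, the output count comes
from one of eight rules:

========  ==============================================
one       set the count to 1
two       set the count to 2
add       sum of both counts
subtract  first count minus second (floored at 0)
min       smaller of the counts
max       larger of the counts
first     count in the first list
second    count in the second list
========  ==============================================

Defaults are ``add`` for union, ``min`` for intersection and ``first`` for
difference.  Union and difference admit only the subset of rules that
cannot manufacture zero counts for one-sided words; any rule evaluation
that still yields 0 (e.g. ``subtract`` on equal counts) drops the word, so
output lists never carry zero-valued entries.

All merges are single forward passes over both inputs, streaming entries
to disk in ascending word order.
"""

from __future__ import annotations

import os
from contextlib import ExitStack
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .listfile import ListHandle, ListHeader, MAX_COUNT, open_list, write_list
from .query import mismatch_neighbors

__all__ = [
    "RULES",
    "ALLOWED_RULES",
    "DEFAULT_RULES",
    "CutoffSpec",
    "apply_rule",
    "merge",
    "diff_from_union",
    "diff_with_mismatches",
]

RULES = ("one", "two", "add", "subtract", "min", "max", "first", "second")

# union/difference exclude rules that can yield 0 for words present on one
# side only; intersection always sees two positive counts so all apply
ALLOWED_RULES = {
    "union": frozenset({"one", "two", "add", "max", "first"}),
    "intersection": frozenset(RULES),
    "difference": frozenset({"one", "two", "first", "subtract"}),
}

DEFAULT_RULES = {"union": "add", "intersection": "min", "difference": "first"}


@dataclass(frozen=True)
class CutoffSpec:
    """Per-list minimum stored count for a k-mer to count as present."""

    cutoff1: int = 1
    cutoff2: int = 1

    def __post_init__(self):
        if self.cutoff1 < 1 or self.cutoff2 < 1:
            raise ValueError("cutoffs must be >= 1")


def apply_rule(rule: str, c1: int | None, c2: int | None) -> int:
    """Output count for one word; ``None`` marks absence (0 in arithmetic)."""
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}; expected one of {RULES}")
    if c1 is None and c2 is None:
        raise ValueError("at least one count must be present")
    a = c1 or 0
    b = c2 or 0
    if rule == "one":
        out = 1
    elif rule == "two":
        out = 2
    elif rule == "add":
        out = a + b
    elif rule == "subtract":
        out = max(a - b, 0)
    elif rule == "min":
        out = min(a, b)
    elif rule == "max":
        out = max(a, b)
    elif rule == "first":
        out = a
    else:  # second
        out = b
    return min(out, MAX_COUNT)


def _as_handle(obj, stack: ExitStack) -> ListHandle:
    if isinstance(obj, ListHandle):
        return obj
    return stack.enter_context(open_list(obj))


def _merged_entries(a: ListHandle, b: ListHandle, op: str, rule: str,
                    cutoffs: CutoffSpec) -> Iterator[tuple[int, int]]:
    """Two-pointer walk over both sorted lists, yielding output entries."""
    na, nb = len(a), len(b)
    i = j = 0
    wa, ca = a.get_entry(0) if na else (None, 0)
    wb, cb = b.get_entry(0) if nb else (None, 0)
    while i < na or j < nb:
        if j >= nb or (i < na and wa < wb):
            word, c1, c2 = wa, ca, None
            i += 1
            if i < na:
                wa, ca = a.get_entry(i)
        elif i >= na or wb < wa:
            word, c1, c2 = wb, None, cb
            j += 1
            if j < nb:
                wb, cb = b.get_entry(j)
        else:  # equal words consumed simultaneously
            word, c1, c2 = wa, ca, cb
            i += 1
            j += 1
            if i < na:
                wa, ca = a.get_entry(i)
            if j < nb:
                wb, cb = b.get_entry(j)
        # presence under cutoffs; sub-cutoff counts are invisible to rules
        if c1 is not None and c1 < cutoffs.cutoff1:
            c1 = None
        if c2 is not None and c2 < cutoffs.cutoff2:
            c2 = None
        in_a = c1 is not None
        in_b = c2 is not None
        if op == "union":
            keep = in_a or in_b
        elif op == "intersection":
            keep = in_a and in_b
        else:  # difference
            keep = in_a and not in_b
        if not keep:
            continue
        count = apply_rule(rule, c1, c2)
        if count > 0:
            yield word, count


def merge(list_a, list_b, out_path: str | os.PathLike, op: str,
          rule: str | None = None, cutoffs: CutoffSpec | None = None) -> ListHeader:
    """Union / intersection / difference of two lists into a new list file.

    Parameters
    ----------
    list_a, list_b : path or ListHandle
        Sorted inputs sharing one k.
    op : {"union", "intersection", "difference"}
    rule : str, optional
        Count rule; defaults to the operation's default rule.
    cutoffs : CutoffSpec, optional
        Presence thresholds (default 1/1).
    """
    if op not in ALLOWED_RULES:
        raise ValueError(f"unknown operation {op!r}")
    if rule is None:
        rule = DEFAULT_RULES[op]
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}; expected one of {RULES}")
    if rule not in ALLOWED_RULES[op]:
        raise ValueError(f"rule {rule!r} is not permitted for {op} "
                         f"(allowed: {sorted(ALLOWED_RULES[op])})")
    cutoffs = cutoffs or CutoffSpec()
    with ExitStack() as stack:
        a = _as_handle(list_a, stack)
        b = _as_handle(list_b, stack)
        if a.k != b.k:
            raise ValueError(f"k mismatch: {a.k} vs {b.k}")
        return write_list(out_path, a.k, _merged_entries(a, b, op, rule, cutoffs))


def diff_from_union(list_a, list_u, out_path: str | os.PathLike) -> ListHeader:
    """K-mers whose count in an add-rule union equals their count in A.

    When the second list is a union (rule ``add``) of a collection that
    includes A, equal counts mean no other member of the union contributed
    the k-mer — so the output is exactly A's specific k-mers, carrying A's
    counts, without needing a separate control list per member.
    """
    def entries(a: ListHandle, u: ListHandle) -> Iterator[tuple[int, int]]:
        j = 0
        nu = len(u)
        for word, count in a:
            while j < nu:
                wu, cu = u.get_entry(j)
                if wu >= word:
                    break
                j += 1
            else:
                wu = None
            if wu != word or cu < count:
                detail = ("missing from union" if wu != word
                          else f"union count {cu} below list count {count}")
                raise ValueError(
                    f"word {word} of {a.path}: {detail}; second list cannot be "
                    "an add-rule union including the first"
                )
            if cu == count:
                yield word, count

    with ExitStack() as stack:
        a = _as_handle(list_a, stack)
        u = _as_handle(list_u, stack)
        if a.k != u.k:
            raise ValueError(f"k mismatch: {a.k} vs {u.k}")
        return write_list(out_path, a.k, entries(a, u))


def diff_with_mismatches(list_a, list_b, out_path: str | os.PathLike,
                         m: int) -> ListHeader:
    """K-mers of A farther than m substitutions from every k-mer of B.

    Stepwise elimination: start from the exact difference (0 mismatches);
    at each step j = 1..m generate every variant of each survivor at
    exactly j positions, canonicalise it and look it up in B — a hit
    eliminates the survivor.  Only survivors of step j-1 are considered at
    step j, and the working set is O(number of survivors).  Distances are
    strand-aware: a variant matches if its canonical form occurs in B.
    """
    with ExitStack() as stack:
        a = _as_handle(list_a, stack)
        b = _as_handle(list_b, stack)
        k = a.k
        if b.k != k:
            raise ValueError(f"k mismatch: {k} vs {b.k}")
        if not 0 <= m <= k:
            raise ValueError(f"mismatch count m={m} outside 0..{k}")
        b_words = b.words()

        def in_b(word: int) -> bool:
            idx = int(np.searchsorted(b_words, np.uint64(word)))
            return idx < b_words.size and int(b_words[idx]) == word

        survivors = [(w, c) for w, c in a if not in_b(w)]
        for j in range(1, m + 1):
            survivors = [
                (w, c) for w, c in survivors
                if not any(in_b(v) for v in mismatch_neighbors(w, k, j, canonical=True))
            ]
        return write_list(out_path, k, iter(survivors))
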