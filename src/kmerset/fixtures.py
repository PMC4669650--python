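"""Seeded synthetic inputs, a naive counting oracle, and recipe helpers.

The generator produces deterministic FASTA files (identical spec, identical
bytes) with controllable record counts, length ranges and ambiguous-base
rates, plus an exact expected count table computed by a naive dictionary
oracle — so every pipeline test has a known answer.  The clade fixture
plants a shared core, clade-private and genome-private segments (separated
by N runs, as assembly gaps would) so marker discovery has an exact
expected marker set per clade.

Also here: ``merge_many`` (recursive pairwise union, the way very large
composite lists are built genome by genome) and ``find_group_specific``
(add-rule intersection of the group, then difference-from-union against
the composite of everything).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from tempfile import TemporaryDirectory
from typing import Sequence

import numpy as np

from .codec import canonicalize, encode_kmer
from .compare import diff_from_union, merge
from .listfile import ListHeader, write_list

__all__ = [
    "FixtureSpec",
    "generate_fixture",
    "naive_count",
    "random_sequence",
    "merge_many",
    "find_group_specific",
    "generate_clade_fixture",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def naive_count(seqs: Sequence[str], k: int) -> dict[int, int]:
    """Dictionary-counting oracle: per-window string handling throughout.

    Counts canonical k-mers of every valid window the slow, obvious way;
    used as the independent reference for the sort-and-collate counter.
    """
    counts: dict[int, int] = {}
    for seq in seqs:
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if any(b not in "ACGT" for b in window):
                continue
            rc = window.translate(_COMPLEMENT)[::-1]
            canon = min(encode_kmer(window), encode_kmer(rc))
            counts[canon] = counts.get(canon, 0) + 1
    return counts


def random_sequence(rng: np.random.Generator, length: int,
                    ambiguity_rate: float = 0.0) -> str:
    """Uniform random ACGT sequence with N substituted at the given rate."""
    bases = rng.integers(0, 4, size=length)
    seq = np.array(list("ACGT"))[bases]
    if ambiguity_rate > 0:
        mask = rng.random(length) < ambiguity_rate
        seq[mask] = "N"
    return "".join(seq)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a deterministic synthetic FASTA fixture."""

    seed: int
    n_records: int = 10
    length_range: tuple[int, int] = (100, 500)
    ambiguity_rate: float = 0.01
    k: int = 16

    def __post_init__(self):
        if not 0.0 <= self.ambiguity_rate <= 1.0:
            raise ValueError(f"ambiguity_rate {self.ambiguity_rate} outside [0, 1]")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError(f"bad length_range {self.length_range}")


def generate_fixture(spec: FixtureSpec, fasta_path: str | os.PathLike,
                     oracle_path: str | os.PathLike | None = None) -> dict[int, int]:
    """Write a deterministic FASTA; return (and optionally write) the
    exact expected canonical k-mer count table from the naive oracle.

    The oracle table, if written, is tab-separated ``word<TAB>count`` in
    ascending word order.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    seqs = []
    with open(fasta_path, "w") as fh:
        for i in range(spec.n_records):
            length = int(rng.integers(lo, hi + 1))
            seq = random_sequence(rng, length, spec.ambiguity_rate)
            seqs.append(seq)
            fh.write(f">record_{i} len={length}\n")
            for j in range(0, length, 70):
                fh.write(seq[j : j + 70] + "\n")
    table = naive_count(seqs, spec.k)
    if oracle_path is not None:
        with open(oracle_path, "w") as fh:
            for word in sorted(table):
                fh.write(f"{word}\t{table[word]}\n")
    return table


# ---------------------------------------------------------------------------
# recipe helpers

def merge_many(paths: Sequence[str | os.PathLike], out_path: str | os.PathLike,
               rule: str = "add") -> ListHeader:
    """Left-fold pairwise union of >= 2 lists under one rule.

    For the permitted union rules the fold is associative, so the
    left-to-right order is just the simplest deterministic choice.
    """
    if len(paths) < 2:
        raise ValueError("merge_many needs at least 2 lists")
    with TemporaryDirectory() as tmp:
        acc = os.fspath(paths[0])
        for i, nxt in enumerate(paths[1:]):
            target = (os.fspath(out_path) if i == len(paths) - 2
                      else os.path.join(tmp, f"acc_{i}.kml"))
            header = merge(acc, nxt, target, op="union", rule=rule)
            acc = target
    return header


def find_group_specific(target_lists: Sequence[str | os.PathLike],
                        background_union: str | os.PathLike,
                        out_path: str | os.PathLike) -> ListHeader:
    """K-mers present in every group member and in no non-member.

    The group's lists are intersected under the ``add`` rule (so the
    intersection carries the summed count across members); the result is
    then compared with the add-rule union of *all* lists: where counts are
    equal, no list outside the group contributed the k-mer.  One composite
    union thus serves for testing the specificity of any of its members.
    """
    if not target_lists:
        raise ValueError("need at least one target list")
    with TemporaryDirectory() as tmp:
        acc = os.fspath(target_lists[0])
        for i, nxt in enumerate(target_lists[1:]):
            target = os.path.join(tmp, f"isect_{i}.kml")
            merge(acc, nxt, target, op="intersection", rule="add")
            acc = target
        return diff_from_union(acc, background_union, out_path)


# ---------------------------------------------------------------------------
# planted-marker fixture

def generate_clade_fixture(seed: int, out_dir: str | os.PathLike, k: int = 16,
                           n_clades: int = 3, genomes_per_clade: int = 3,
                           core_len: int = 2000, clade_len: int = 600,
                           private_len: int = 400) -> dict:
    """Synthetic multi-clade genome set with known clade-private k-mers.

    Each genome is ``core + N*k + clade segment + N*k + private segment``:
    a core shared by everyone, a segment shared within the clade, and a
    genome-private segment.  The N spacers suppress junction k-mers, so
    clade-private markers come only from the clade segment.  The expected
    marker set per clade is computed with the naive oracle (so accidental
    k-mer collisions between random segments are accounted for exactly).

    Returns a dict with ``fasta_paths`` (clade -> list of FASTA paths),
    ``genome_seqs`` and ``expected_markers`` (clade -> set of canonical
    words present in every clade member and absent from all others).
    """
    rng = np.random.default_rng(seed)
    os.makedirs(out_dir, exist_ok=True)
    spacer = "N" * k
    core = random_sequence(rng, core_len)
    clade_segments = [random_sequence(rng, clade_len) for _ in range(n_clades)]
    fasta_paths: dict[int, list[str]] = {}
    genome_seqs: dict[int, list[str]] = {}
    for c in range(n_clades):
        fasta_paths[c] = []
        genome_seqs[c] = []
        for g in range(genomes_per_clade):
            private = random_sequence(rng, private_len)
            genome = core + spacer + clade_segments[c] + spacer + private
            path = os.path.join(out_dir, f"clade{c}_genome{g}.fa")
            with open(path, "w") as fh:
                fh.write(f">clade{c}_genome{g}\n")
                for j in range(0, len(genome), 70):
                    fh.write(genome[j : j + 70] + "\n")
            fasta_paths[c].append(path)
            genome_seqs[c].append(genome)

    per_genome_sets = {
        c: [set(naive_count([s], k)) for s in genome_seqs[c]] for c in range(n_clades)
    }
    expected: dict[int, set[int]] = {}
    for c in range(n_clades):
        shared = set.intersection(*per_genome_sets[c])
        others: set[int] = set()
        for c2 in range(n_clades):
            if c2 != c:
                others |= set.union(*per_genome_sets[c2])
        expected[c] = shared - others
    return {"fasta_paths": fasta_paths, "genome_seqs": genome_seqs,
            "expected_markers": expected, "k": k}


def write_entries(path: str | os.PathLike, k: int,
                  table: dict[int, int]) -> ListHeader:
    """Write a word->count table (canonicalised keys assumed) as a list file."""
    items = sorted((canonicalize(w, k), c) for w, c in table.items())
    return write_list(path, k, iter(items))
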