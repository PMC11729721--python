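"""Canonical k-mer extraction and counting.

A k-mer is a length-``k`` substring of a DNA sequence, taken with step 1.
Under *canonical* counting a k-mer and its reverse complement are treated as
one item: the lexicographically smaller of the two (A<C<G<T on uppercase) is
the representative. Canonical counting makes counts strand-invariant and
roughly halves the stored vocabulary.

The vocabulary size ``V`` — the number of distinct possible k-mers under the
chosen representation — is the pseudo-count mass added by Laplace smoothing
at scoring time. Closed forms:

* non-canonical: ``V = 4^k``
* canonical, even k: ``V = (4^k + 4^(k/2)) / 2`` (the ``4^(k/2)`` term counts
  the self-reverse-complementary k-mers, which have no distinct partner)
* canonical, odd k: ``V = 4^k / 2`` (no k-mer of odd length can equal its own
  reverse complement)
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "KmerSpec",
    "CountTable",
    "reverse_complement",
    "canonical_form",
    "vocabulary_size",
    "count_kmers",
    "merge_counts",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ACGT = frozenset("ACGT")
_ACGT_RUN = re.compile(r"[ACGT]+")

MAX_K = 31  # engineering ceiling: leaves 2-bit packing open to any backend


@dataclass(frozen=True)
class KmerSpec:
    """K-mer length and representation choice.

    Parameters
    ----------
    k : int
        K-mer length in bases, ``1 <= k <= 31``.
    canonical : bool
        If True, every k-mer is mapped to the lexicographically smaller of
        itself and its reverse complement before tallying.
    """

    k: int
    canonical: bool = True

    def __post_init__(self) -> None:
        if not isinstance(self.k, int) or isinstance(self.k, bool):
            raise TypeError(f"k must be an integer, got {self.k!r}")
        if not 1 <= self.k <= MAX_K:
            raise ValueError(f"k must be in [1, {MAX_K}], got {self.k}")


def _check_dna(seq: str) -> None:
    for i, base in enumerate(seq):
        if base not in _ACGT:
            raise ValueError(
                f"non-ACGT character {base!r} at position {i} (0-based)"
            )


def reverse_complement(seq: str) -> str:
    """Watson–Crick reverse complement of an ACGT-only sequence.

    Raises ``ValueError`` naming the first offending position if ``seq``
    contains a character outside {A, C, G, T}.
    """
    if not _ACGT.issuperset(seq):
        _check_dna(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_form(kmer: str) -> str:
    """The lexicographically smaller of ``kmer`` and its reverse complement.

    Lexicographic order is the natural character order A<C<G<T on uppercase.
    Idempotent: the canonical form is its own canonical form.
    """
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def vocabulary_size(spec: KmerSpec) -> int:
    """Number of distinct possible k-mers under ``spec`` (closed form)."""
    k = spec.k
    if not spec.canonical:
        return 4**k
    if k % 2 == 0:
        return (4**k + 4 ** (k // 2)) // 2
    return 4**k // 2


@dataclass
class CountTable:
    """Per-sequence (or per-genome) k-mer frequency table.

    ``counts`` maps each observed k-mer (canonicalized if the spec says so)
    to its tally; ``total`` is the number of tallied windows, i.e. the N_G
    term of the smoothed probability. Zero-count k-mers are never stored —
    smoothing supplies them at query time.
    """

    spec: KmerSpec
    counts: dict[str, int] = field(default_factory=dict)
    total: int = 0

    def validate(self) -> None:
        """Check structural invariants; raises ``ValueError`` on violation."""
        if self.total != sum(self.counts.values()):
            raise ValueError(
                f"total {self.total} != sum of counts {sum(self.counts.values())}"
            )
        for kmer, n in self.counts.items():
            if len(kmer) != self.spec.k or not _ACGT.issuperset(kmer):
                raise ValueError(f"bad k-mer key {kmer!r} for k={self.spec.k}")
            if n <= 0:
                raise ValueError(f"non-positive count for {kmer!r}: {n}")
            if self.spec.canonical and canonical_form(kmer) != kmer:
                raise ValueError(f"non-canonical key {kmer!r} in canonical table")


def count_kmers(seq: str, spec: KmerSpec) -> CountTable:
    """Count the k-mers of one sequence.

    A window of length ``spec.k`` slides with step 1; any window containing
    a character outside {A, C, G, T} (e.g. N) is skipped entirely. Input is
    uppercased. A sequence shorter than ``k`` yields an empty table.
    """
    k = spec.k
    raw: dict[str, int] = {}
    total = 0
    # splitting on non-ACGT runs implements window skipping exactly:
    # a window is valid iff it lies inside one maximal ACGT run
    for run in _ACGT_RUN.findall(seq.upper()):
        n = len(run) - k + 1
        if n <= 0:
            continue
        total += n
        for i in range(n):
            w = run[i : i + k]
            raw[w] = raw.get(w, 0) + 1
    if spec.canonical:
        folded: dict[str, int] = {}
        for w, c in raw.items():
            cw = canonical_form(w)
            folded[cw] = folded.get(cw, 0) + c
        raw = folded
    return CountTable(spec=spec, counts=raw, total=total)


def merge_counts(a: CountTable, b: CountTable) -> CountTable:
    """Key-wise sum of two tables built under the same spec.

    Commutative and associative; the empty table is the identity.
    """
    if a.spec != b.spec:
        raise ValueError(f"spec mismatch: {a.spec} vs {b.spec}")
    counts = dict(a.counts)
    for w, c in b.counts.items():
        counts[w] = counts.get(w, 0) + c
    return CountTable(spec=a.spec, counts=counts, total=a.total + b.total)
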