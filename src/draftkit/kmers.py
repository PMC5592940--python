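"""Canonical k-mer counting and depth histograms.

Counting is exact and strand-merged: each window is represented by the
lexicographic minimum of itself and its reverse complement, the behavior
of the standard k-mer counters used for genome profiling.  Windows that
contain any non-ACGT base (Ns, IUPAC ambiguity codes) are skipped
entirely, which keeps the conservation law simple: the sum of all counts
equals the number of fully unambiguous windows scanned.

For k <= 32 counting is vectorized over packed 64-bit k-mers; larger k
falls back to a plain dictionary scan, which is fine at desk scale.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from ._encode import (
    MAX_PACKED_K,
    canonical_kmers,
    decode_kmer,
    encode,
    encode_kmer,
    revcomp,
)
from .errors import EmptyInputError, InvalidParameterError

# Bases per numpy counting chunk; bounds peak memory, not correctness.
_CHUNK_BASES = 8_000_000


@dataclass
class KmerCounts:
    """Exact canonical k-mer counts.

    For k <= 32 the counts live in a pair of parallel arrays (sorted
    packed k-mers and their multiplicities); for larger k in a plain
    dict keyed by k-mer string.  Both support the same mapping-style
    access, decoding packed keys on demand.
    """

    k: int
    _keys: np.ndarray | None = None  # sorted uint64, packed
    _values: np.ndarray | None = None  # int64 multiplicities
    _dict: dict[str, int] | None = None

    @property
    def n_distinct(self) -> int:
        if self._dict is not None:
            return len(self._dict)
        return 0 if self._keys is None else int(self._keys.size)

    @property
    def total_positions(self) -> int:
        """Number of valid windows scanned (= sum of all counts)."""
        if self._dict is not None:
            return sum(self._dict.values())
        return 0 if self._values is None else int(self._values.sum())

    def __len__(self) -> int:
        return self.n_distinct

    def __getitem__(self, kmer: str) -> int:
        c = self.get(kmer)
        if c == 0:
            raise KeyError(kmer)
        return c

    def get(self, kmer: str, default: int = 0) -> int:
        canon = min(kmer, revcomp(kmer))
        if self._dict is not None:
            return self._dict.get(canon, default)
        if self._keys is None or self._keys.size == 0:
            return default
        v = np.uint64(encode_kmer(canon))
        i = int(np.searchsorted(self._keys, v))
        if i < self._keys.size and self._keys[i] == v:
            return int(self._values[i])
        return default

    def items(self) -> Iterator[tuple[str, int]]:
        if self._dict is not None:
            yield from self._dict.items()
        elif self._keys is not None:
            for key, val in zip(self._keys, self._values):
                yield decode_kmer(int(key), self.k), int(val)

    def to_dict(self) -> dict[str, int]:
        return dict(self.items())

    def depth_counts(self) -> np.ndarray:
        """bincount over depths: result[d] = number of distinct k-mers at depth d."""
        if self._dict is not None:
            vals = np.fromiter(self._dict.values(), dtype=np.int64)
        elif self._values is not None:
            vals = self._values
        else:
            vals = np.zeros(0, dtype=np.int64)
        if vals.size == 0:
            return np.zeros(1, dtype=np.int64)
        return np.bincount(vals)


@dataclass
class KmerHistogram:
    """Depth histogram of a k-mer spectrum: bins[d] = distinct k-mers seen d times."""

    k: int
    bins: dict[int, int] = field(default_factory=dict)

    @property
    def total_kmers(self) -> int:
        """Total k-mer occurrences, sum over d of d * bins[d]."""
        return sum(d * c for d, c in self.bins.items())

    @property
    def n_distinct(self) -> int:
        return sum(self.bins.values())

    @property
    def max_depth(self) -> int:
        return max(self.bins) if self.bins else 0

    def dense(self) -> np.ndarray:
        """Dense array a with a[d] = bins.get(d, 0), index 0 unused."""
        out = np.zeros(self.max_depth + 1, dtype=np.int64)
        for d, c in self.bins.items():
            out[d] = c
        return out

    def write(self, path: str | Path) -> None:
        """Two-column whitespace text, 'depth count', ascending depth."""
        with open(path, "w") as fh:
            for d in sorted(self.bins):
                fh.write(f"{d} {self.bins[d]}\n")

    @classmethod
    def read(cls, path: str | Path, k: int) -> "KmerHistogram":
        bins: dict[int, int] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                d, c = line.split()[:2]
                bins[int(d)] = int(c)
        return cls(k=k, bins=bins)


def _iter_chunks(sequences: Iterable[str], max_bases: int) -> Iterator[str]:
    """Join sequences with 'N' separators into bounded-size chunks."""
    buf: list[str] = []
    size = 0
    for seq in sequences:
        buf.append(seq)
        size += len(seq) + 1
        if size >= max_bases:
            yield "N".join(buf)
            buf, size = [], 0
    if buf:
        yield "N".join(buf)


def count_kmers(sequences: Iterable[str], k: int) -> KmerCounts:
    """Count canonical k-mers across an iterable of DNA strings.

    Windows containing any non-ACGT base are skipped.  Deterministic.
    A k longer than every sequence yields empty counts; k <= 0 is an error.
    """
    if k <= 0:
        raise InvalidParameterError(f"k must be >= 1, got {k}")
    if k > 255:
        raise InvalidParameterError(f"k must be <= 255, got {k}")

    if k <= MAX_PACKED_K:
        parts: list[np.ndarray] = []
        for chunk in _iter_chunks(sequences, _CHUNK_BASES):
            codes = encode(chunk)
            if codes.size < k:
                continue
            canon, valid = canonical_kmers(codes, k)
            parts.append(canon[valid])
        if not parts:
            return KmerCounts(k=k, _keys=np.zeros(0, np.uint64), _values=np.zeros(0, np.int64))
        allk = np.concatenate(parts)
        del parts
        keys, values = np.unique(allk, return_counts=True)
        return KmerCounts(k=k, _keys=keys, _values=values.astype(np.int64))

    counter: Counter[str] = Counter()
    for seq in sequences:
        seq = seq.upper()
        rc = revcomp(seq)
        n = len(seq)
        for i in range(n - k + 1):
            w = seq[i : i + k]
            if _is_acgt(w):
                wr = rc[n - k - i : n - i]
                counter[w if w <= wr else wr] += 1
    return KmerCounts(k=k, _dict=dict(counter))


def _is_acgt(window: str) -> bool:
    for ch in window:
        if ch not in "ACGT":
            return False
    return True


def build_histogram(counts: KmerCounts) -> KmerHistogram:
    """Collapse k-mer counts into a depth histogram.

    bins[d] = number of distinct canonical k-mers whose count is d.
    Raises EmptyInputError for empty counts.
    """
    if counts.n_distinct == 0:
        raise EmptyInputError("cannot build a histogram from empty k-mer counts")
    depth = counts.depth_counts()
    bins = {int(d): int(c) for d, c in enumerate(depth) if d > 0 and c > 0}
    return KmerHistogram(k=counts.k, bins=bins)
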