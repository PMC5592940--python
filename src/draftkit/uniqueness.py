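"""Assembly k-mer uniqueness ratio as a function of k.

For each k, the ratio is the fraction of valid k-mer start positions in
the assembly whose canonical k-mer occurs exactly once assembly-wide.
Windows covering Ns or ambiguity codes are excluded from numerator and
denominator alike.  Lower curves mean more exact repeat content; for a
fixed genome the curve is non-decreasing in k, since any window unique
at k stays unique when extended.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._encode import MAX_PACKED_K, canonical_kmers, encode, revcomp
from .errors import InvalidParameterError, UndefinedRatioError


@dataclass(frozen=True)
class UniquenessPoint:
    k: int
    ratio: float
    valid_positions: int


@dataclass
class UniquenessCurve:
    points: list[UniquenessPoint]

    def ratios(self) -> list[float]:
        return [p.ratio for p in self.points]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# canonical (strand-merged) k-mer counting\n")
            fh.write("k\tratio\tvalid_positions\n")
            for p in self.points:
                fh.write(f"{p.k}\t{p.ratio:.6f}\t{p.valid_positions}\n")


def uniqueness_ratio(assembly: Iterable[str], k: int) -> tuple[float, int]:
    """(fraction of k-mer positions occurring exactly once, valid positions).

    Raises UndefinedRatioError when no window of length k is free of
    ambiguous bases (all-N input or k longer than every sequence).
    """
    if k < 1:
        raise InvalidParameterError(f"k must be >= 1, got {k}")
    seqs = list(assembly)
    if not seqs:
        raise UndefinedRatioError("empty assembly")

    if k <= MAX_PACKED_K:
        return _ratio_packed(seqs, k)
    return _ratio_dict(seqs, k)


def _ratio_packed(seqs: Sequence[str], k: int) -> tuple[float, int]:
    per_seq: list[np.ndarray] = []
    for seq in seqs:
        codes = encode(seq)
        if codes.size < k:
            continue
        canon, valid = canonical_kmers(codes, k)
        per_seq.append(canon[valid])
    if not per_seq:
        raise UndefinedRatioError(f"no valid k-mer positions at k={k}")
    allk = np.concatenate(per_seq)
    if allk.size == 0:
        raise UndefinedRatioError(f"no valid k-mer positions at k={k}")
    _, inverse, counts = np.unique(allk, return_inverse=True, return_counts=True)
    unique_positions = int((counts[inverse] == 1).sum())
    return unique_positions / allk.size, int(allk.size)


def _ratio_dict(seqs: Sequence[str], k: int) -> tuple[float, int]:
    counter: Counter[str] = Counter()
    windows: list[str] = []
    for seq in seqs:
        seq = seq.upper()
        rc = revcomp(seq)
        n = len(seq)
        for i in range(n - k + 1):
            w = seq[i : i + k]
            if any(ch not in "ACGT" for ch in w):
                continue
            wr = rc[n - k - i : n - i]
            canon = w if w <= wr else wr
            windows.append(canon)
            counter[canon] += 1
    if not windows:
        raise UndefinedRatioError(f"no valid k-mer positions at k={k}")
    unique_positions = sum(1 for w in windows if counter[w] == 1)
    return unique_positions / len(windows), len(windows)


def uniqueness_curve(assembly: Iterable[str], k_values: Sequence[int]) -> UniquenessCurve:
    """Uniqueness ratio at each k; ks where the ratio is undefined are omitted."""
    seqs = list(assembly)
    if list(k_values) != sorted(k_values):
        raise InvalidParameterError("k_values must be sorted ascending")
    points: list[UniquenessPoint] = []
    for k in k_values:
        try:
            ratio, valid = uniqueness_ratio(seqs, k)
        except UndefinedRatioError:
            continue
        points.append(UniquenessPoint(k=k, ratio=ratio, valid_positions=valid))
    return UniquenessCurve(points=points)


def parse_k_list(spec: str) -> list[int]:
    """Parse '17,25,33' or range syntax '17:97:8' (start:stop:step, inclusive)."""
    if ":" in spec:
        parts = [int(x) for x in spec.split(":")]
        if len(parts) == 2:
            start, stop, step = parts[0], parts[1], 1
        else:
            start, stop, step = parts[:3]
        return list(range(start, stop + 1, step))
    return [int(x) for x in spec.split(",") if x]
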