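"""Nextera-style mate-pair library cleaning and QC.

Mate-pair (jumping) libraries circularize multi-kb fragments around a
junction adapter; genuine pairs therefore carry the adapter inside one
or both reads and map outward-facing, far apart.  This module
re-implements the cleaning steps such libraries need before scaffolding:

* junction categorization (A: adapter in both reads, B: read 1 only,
  C: read 2 only, D: neither) with adapter trimming, keeping the prefix
  before the first adapter occurrence;
* removal of category-D pairs, which lack evidence of circularization;
* PCR-duplicate estimation from alignment-coordinate signatures;
* "innie" detection: inward-facing, short-separation artifact pairs;
* distinct-clone (physical) coverage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._encode import encode, revcomp
from .align import DEFAULT_SEED_LEN, Placement, SeedIndex
from .errors import (
    EmptyInputError,
    InvalidParameterError,
    MalformedRecordError,
    UndefinedRateError,
)

# Nextera junction duplex: the 19-bp transposase recognition sequence
# joined to its reverse complement at the circularization point.
NEXTERA_JUNCTION_ADAPTER = "CTGTCTCTTATACACATCT" + "AGATGTGTATAAGAGACAG"

CATEGORIES = ("A", "B", "C", "D")


@dataclass
class MatePairLibrary:
    name: str
    nominal_insert_bp: int
    junction_adapter: str = NEXTERA_JUNCTION_ADAPTER
    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.nominal_insert_bp <= 0:
            raise InvalidParameterError("nominal_insert_bp must be positive")
        if len(self.junction_adapter) < 10:
            raise InvalidParameterError("junction adapter must be >= 10 bp")


@dataclass
class PairQC:
    category: str
    trimmed_lengths: tuple[int, int]
    duplicate: bool = False
    innie: bool = False
    inferred_fragment_bp: int | None = None


def find_adapter(read: str, adapter: str, max_mismatch: int = 1) -> int:
    """Position of the first occurrence of adapter or its reverse
    complement in read, allowing up to max_mismatch substitutions;
    -1 if absent."""
    best = -1
    for probe in (adapter, revcomp(adapter)):
        pos = read.find(probe)
        if pos < 0 and max_mismatch > 0 and len(read) >= len(probe):
            rc_ = encode(read)
            pc = encode(probe)
            win = np.lib.stride_tricks.sliding_window_view(rc_, len(probe))
            mism = (win != pc).sum(axis=1)
            hits = np.nonzero(mism <= max_mismatch)[0]
            pos = int(hits[0]) if hits.size else -1
        if pos >= 0 and (best < 0 or pos < best):
            best = pos
    return best


def classify_junction(
    pair: tuple[str, str],
    adapter: str = NEXTERA_JUNCTION_ADAPTER,
    max_mismatch: int = 1,
) -> PairQC:
    """Categorize a pair by junction-adapter presence and trim at it.

    A read containing the adapter is trimmed to the prefix before its
    first occurrence.  Category A = adapter in both reads, B = read 1
    only, C = read 2 only, D = neither (no circularization evidence).
    """
    r1, r2 = pair
    if not r1 or not r2:
        raise MalformedRecordError("empty read in mate pair")
    p1 = find_adapter(r1.upper(), adapter, max_mismatch)
    p2 = find_adapter(r2.upper(), adapter, max_mismatch)
    t1 = p1 if p1 >= 0 else len(r1)
    t2 = p2 if p2 >= 0 else len(r2)
    if p1 >= 0 and p2 >= 0:
        cat = "A"
    elif p1 >= 0:
        cat = "B"
    elif p2 >= 0:
        cat = "C"
    else:
        cat = "D"
    return PairQC(category=cat, trimmed_lengths=(t1, t2))


def filter_category_d(qcs: Sequence[PairQC]) -> tuple[list[int], int]:
    """Indices of pairs to keep (categories A/B/C) and the count removed."""
    kept = [i for i, qc in enumerate(qcs) if qc.category != "D"]
    return kept, len(qcs) - len(kept)


def _primary(placements: Sequence[Placement]) -> Placement | None:
    if not placements:
        return None
    return max(placements, key=lambda p: (p.matched_bp, -p.start))


def pair_signature(
    pair: tuple[str, str],
    placements1: Sequence[Placement],
    placements2: Sequence[Placement],
) -> tuple:
    """Duplicate signature: alignment coordinates of both mates, falling
    back to exact 32-bp prefixes when either mate is unaligned."""
    p1, p2 = _primary(placements1), _primary(placements2)
    if p1 is not None and p2 is not None:
        return (p1.contig, p1.start, p1.strand, p2.contig, p2.start, p2.strand)
    return ("seq", pair[0][:32], pair[1][:32])


def estimate_duplication_rate(
    pairs: Sequence[tuple[str, str]],
    alignments: Sequence[tuple[Sequence[Placement], Sequence[Placement]]],
) -> float:
    """Fraction of pairs whose both-mate coordinates repeat an earlier pair."""
    if not pairs:
        raise UndefinedRateError("no pairs to estimate a duplication rate from")
    seen: set = set()
    dups = 0
    for pair, (a1, a2) in zip(pairs, alignments):
        sig = pair_signature(pair, a1, a2)
        if sig in seen:
            dups += 1
        else:
            seen.add(sig)
    return dups / len(pairs)


def detect_innie(
    placements1: Sequence[Placement],
    placements2: Sequence[Placement],
    max_innie_sep: int,
) -> bool:
    """True iff some same-contig placement pair is inward-facing (FR)
    with outer span <= max_innie_sep."""
    for p1 in placements1:
        for p2 in placements2:
            if p1.contig != p2.contig:
                continue
            left, right = (p1, p2) if p1.start <= p2.start else (p2, p1)
            if left.strand == "+" and right.strand == "-":
                if right.end - left.start <= max_innie_sep:
                    return True
    return False


def default_max_innie_sep(nominal_insert_bp: int) -> int:
    """min(1000, 0.2 * nominal insert): 'too close together' operationalized."""
    return int(min(1000, 0.2 * nominal_insert_bp))


def infer_fragment_bp(
    placements1: Sequence[Placement],
    placements2: Sequence[Placement],
    nominal_insert_bp: int,
) -> int:
    """Fragment span from a same-contig placement pair (outer distance),
    falling back to the library's nominal insert when unplaced."""
    p1, p2 = _primary(placements1), _primary(placements2)
    if p1 is not None and p2 is not None and p1.contig == p2.contig:
        return max(p1.end, p2.end) - min(p1.start, p2.start)
    return nominal_insert_bp


def clone_coverage(qcs: Iterable[PairQC], genome_size_bp: float) -> float:
    """Physical coverage: summed fragment bp of non-duplicate pairs / genome size."""
    if genome_size_bp <= 0:
        raise InvalidParameterError("genome_size_bp must be positive")
    total = 0
    for qc in qcs:
        if qc.duplicate:
            continue
        if qc.inferred_fragment_bp is None:
            raise InvalidParameterError("pair lacks an inferred fragment size")
        total += qc.inferred_fragment_bp
    return total / genome_size_bp


@dataclass
class LibraryQCReport:
    library: str
    n_pairs: int
    category_counts: dict[str, int]
    removed_category_d: int
    duplication_rate: float
    innie_fraction: float
    clone_coverage_x: float | None
    max_innie_sep: int
    nominal_insert_bp: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tvalue\n")
            fh.write(f"library\t{self.library}\n")
            fh.write(f"n_pairs\t{self.n_pairs}\n")
            for cat in CATEGORIES:
                fh.write(f"category_{cat}\t{self.category_counts.get(cat, 0)}\n")
            fh.write(f"removed_category_d\t{self.removed_category_d}\n")
            fh.write(f"duplication_rate\t{self.duplication_rate:.6f}\n")
            fh.write(f"innie_fraction\t{self.innie_fraction:.6f}\n")
            if self.clone_coverage_x is not None:
                fh.write(f"clone_coverage_x\t{self.clone_coverage_x:.4f}\n")


def qc_library(
    library: MatePairLibrary,
    contigs: dict | Iterable[tuple[str, str]] | SeedIndex,
    genome_size_bp: float | None = None,
    max_innie_sep: int | None = None,
    max_mismatch: int = 1,
    seed_len: int = DEFAULT_SEED_LEN,
) -> tuple[LibraryQCReport, list[PairQC], list[int]]:
    """Full library QC: classify, filter D, align, flag dups/innies.

    Returns the report, per-pair QC records (all input pairs, in order),
    and the indices of kept (category A/B/C) pairs.  Duplication rate,
    innie fraction and clone coverage are computed over kept pairs, the
    set presented to downstream mate-pair processing.
    """
    pairs = library.pairs
    if not pairs:
        raise EmptyInputError("library has no read pairs")
    if max_innie_sep is None:
        max_innie_sep = default_max_innie_sep(library.nominal_insert_bp)

    qcs = [classify_junction(p, library.junction_adapter, max_mismatch) for p in pairs]
    kept, removed = filter_category_d(qcs)
    counts = {cat: 0 for cat in CATEGORIES}
    for qc in qcs:
        counts[qc.category] += 1

    index = contigs if isinstance(contigs, SeedIndex) else SeedIndex(contigs, seed_len=seed_len)
    trimmed: list[str] = []
    for i in kept:
        r1, r2 = pairs[i]
        t1, t2 = qcs[i].trimmed_lengths
        trimmed.append(r1[:t1])
        trimmed.append(r2[:t2])
    placements = index.align_batch(trimmed)

    kept_pairs = []
    kept_aligns = []
    for j, i in enumerate(kept):
        a1, a2 = placements[2 * j], placements[2 * j + 1]
        kept_pairs.append((pairs[i][0][: qcs[i].trimmed_lengths[0]], pairs[i][1][: qcs[i].trimmed_lengths[1]]))
        kept_aligns.append((a1, a2))

    seen: set = set()
    n_innie = 0
    for (pair, (a1, a2)), i in zip(zip(kept_pairs, kept_aligns), kept):
        sig = pair_signature(pair, a1, a2)
        if sig in seen:
            qcs[i].duplicate = True
        else:
            seen.add(sig)
        qcs[i].innie = detect_innie(a1, a2, max_innie_sep)
        if qcs[i].innie:
            n_innie += 1
        qcs[i].inferred_fragment_bp = infer_fragment_bp(a1, a2, library.nominal_insert_bp)

    n_kept = len(kept)
    dup_rate = sum(1 for i in kept if qcs[i].duplicate) / n_kept if n_kept else 0.0
    innie_frac = n_innie / n_kept if n_kept else 0.0
    cov = None
    if genome_size_bp is not None:
        cov = clone_coverage((qcs[i] for i in kept), genome_size_bp)

    report = LibraryQCReport(
        library=library.name,
        n_pairs=len(pairs),
        category_counts=counts,
        removed_category_d=removed,
        duplication_rate=dup_rate,
        innie_fraction=innie_frac,
        clone_coverage_x=cov,
        max_innie_sep=max_innie_sep,
        nominal_insert_bp=library.nominal_insert_bp,
    )
    return report, qcs, kept
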