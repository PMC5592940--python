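"""Scaffold N-gap closing by two complementary local algorithms.

1. Exact-span closing: look for a single read that crosses the whole
   gap and matches the flanking sequence exactly for at least k_exact
   (default 63) bases on each side; all spanning reads must agree on
   the interior.  Limited to gaps with interior + 2*k_exact <= read
   length.

2. Local mini-assembly: bin the reads whose alignments overlap a
   200-bp window on either side of the gap (plus their mates), build a
   k-mer graph from the bin, and accept a fill only when a unique,
   branch-free path connects the two flank-anchored k-mers, scanning k
   from 150 down to 19.  This closes gaps longer than a read but
   shorter than a fragment.  Any branch or dead end at a given k fails
   that k; a gap whose interior duplicates nearby sequence branches at
   every k and is safely left open.

After closure, small contigs whose sequence is contained in a newly
filled region (plus one flank on each side) are removed as redundant.

The k-mer graph never materializes node objects: bin reads (and their
reverse complements) are hashed with a rolling 64-bit multiplicative
hash, edges are the (k+1)-mers with read support >= 2, and the walk
advances by O(1) hash updates, verifying the target k-mer by string
comparison on hash match.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._encode import encode, revcomp
from .align import Placement, SeedIndex
from .errors import InvalidParameterError

DEFAULT_FLANK_BP = 200
DEFAULT_K_EXACT = 63
DEFAULT_K_MIN = 19
DEFAULT_K_MAX = 150

# Binning alignment tolerance: reads running off a flank into the gap
# mismatch every N, so the match threshold must stay permissive (a read
# anchored by one exact seed and ~30 matched bases is enough to bin).
BIN_MIN_MATCH_FRAC = 0.2

_MASK = (1 << 64) - 1
_MULT = 0x9E3779B97F4A7C15  # odd 64-bit multiplier for the rolling hash


@dataclass
class GapJob:
    """One scaffold N-gap with its flanks and assigned read bin."""

    scaffold_id: str
    start: int
    end: int
    left_flank: str
    right_flank: str
    estimated_gap_bp: int
    read_bin: list[str] = field(default_factory=list)
    short_flank: bool = False

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class ClosureResult:
    status: str  # closed_span | closed_assembly | open
    fill_sequence: str | None = None
    k_used: int | None = None
    direction: str | None = None  # left_to_right | right_to_left | both

    def __post_init__(self) -> None:
        if (self.status == "open") != (self.fill_sequence is None):
            raise InvalidParameterError("open status iff fill_sequence absent")


_N_RUN = re.compile(r"N+")


def find_gaps(scaffold_id: str, seq: str, flank_bp: int = DEFAULT_FLANK_BP) -> list[GapJob]:
    """Maximal N-runs of a scaffold as GapJobs (0-based half-open).

    Flanks are the N-free stretches immediately adjacent to the gap, up
    to flank_bp long; shorter flanks (scaffold ends, neighboring gaps)
    are allowed and flagged.
    """
    seq = seq.upper()
    jobs: list[GapJob] = []
    for m in _N_RUN.finditer(seq):
        start, end = m.start(), m.end()
        ls = max(0, start - flank_bp)
        left = seq[ls:start]
        cut = left.rfind("N")
        if cut >= 0:
            left = left[cut + 1 :]
        right = seq[end : end + flank_bp]
        cut = right.find("N")
        if cut >= 0:
            right = right[:cut]
        jobs.append(
            GapJob(
                scaffold_id=scaffold_id,
                start=start,
                end=end,
                left_flank=left,
                right_flank=right,
                estimated_gap_bp=end - start,
                short_flank=len(left) < flank_bp or len(right) < flank_bp,
            )
        )
    return jobs


def close_gap_spanning(
    job: GapJob,
    reads: Sequence[str] | None = None,
    k_exact: int = DEFAULT_K_EXACT,
) -> ClosureResult:
    """Close a gap from single reads spanning it with exact flank anchors.

    A spanning read contains the last k_exact bases of the left flank,
    then the interior, then the first k_exact bases of the right flank,
    all as one exact substring (either strand).  All spanning reads
    must agree on the interior; disagreement leaves the gap open.
    """
    if reads is None:
        reads = job.read_bin
    if len(job.left_flank) < k_exact or len(job.right_flank) < k_exact:
        return ClosureResult(status="open")
    left_anchor = job.left_flank[-k_exact:]
    right_anchor = job.right_flank[:k_exact]
    interiors: set[str] = set()
    for read in reads:
        for oriented in (read.upper(), revcomp(read.upper())):
            i = oriented.find(left_anchor)
            while i >= 0:
                j = oriented.find(right_anchor, i + k_exact)
                if j >= i + k_exact:
                    interiors.add(oriented[i + k_exact : j])
                i = oriented.find(left_anchor, i + 1)
    if len(interiors) == 1:
        return ClosureResult(
            status="closed_span", fill_sequence=interiors.pop(), k_used=k_exact
        )
    return ClosureResult(status="open")


def bin_reads_for_gap(
    job: GapJob,
    alignments: Sequence[tuple[str, Sequence[Placement]]],
    mates: dict[int, int] | None = None,
    flank_bp: int = DEFAULT_FLANK_BP,
) -> list[str]:
    """Reads whose alignments overlap the flank windows, plus their mates.

    alignments is a sequence of (read sequence, placements); mates maps
    read index -> mate read index within that sequence.  The windows
    are the flank_bp bases on each side of the gap.
    """
    lw = (max(0, job.start - flank_bp), job.start)
    rw = (job.end, job.end + flank_bp)
    chosen: set[int] = set()
    for idx, (_, placements) in enumerate(alignments):
        for p in placements:
            if p.contig != job.scaffold_id:
                continue
            if (p.start < lw[1] and p.end > lw[0]) or (p.start < rw[1] and p.end > rw[0]):
                chosen.add(idx)
                if mates and idx in mates:
                    chosen.add(mates[idx])
                break
    return [alignments[i][0] for i in sorted(chosen)]


def assign_read_bins(
    scaffolds: dict[str, str],
    jobs: Sequence[GapJob],
    pairs: Sequence[tuple[str, str]],
    flank_bp: int = DEFAULT_FLANK_BP,
    index: SeedIndex | None = None,
) -> None:
    """Align all reads to the gapped scaffolds and fill every job's read_bin.

    Pairs are interleaved (R1, R2); the mate of read 2i is 2i+1.  A pair
    joins a gap's bin when either mate's alignment overlaps a flank
    window; both mates then enter the bin.
    """
    if index is None:
        index = SeedIndex(scaffolds)
    reads = [r for pair in pairs for r in pair]
    placements = index.align_batch(reads, min_match_frac=BIN_MIN_MATCH_FRAC)

    # Per-scaffold sorted window table: window start -> (end, job index).
    by_scaffold: dict[str, list[tuple[int, int, int]]] = {}
    for ji, job in enumerate(jobs):
        wins = (
            (max(0, job.start - flank_bp), job.start, ji),
            (job.end, job.end + flank_bp, ji),
        )
        by_scaffold.setdefault(job.scaffold_id, []).extend(wins)
    starts_by_scaffold: dict[str, np.ndarray] = {}
    for sid, wins in by_scaffold.items():
        wins.sort()
        starts_by_scaffold[sid] = np.array([w[0] for w in wins], dtype=np.int64)

    bins: list[set[int]] = [set() for _ in jobs]
    for idx, places in enumerate(placements):
        for p in places:
            wins = by_scaffold.get(p.contig)
            if not wins:
                continue
            starts = starts_by_scaffold[p.contig]
            j = int(np.searchsorted(starts, p.end, side="left"))
            for wi in range(max(0, j - 2), min(len(wins), j + 1)):
                ws, we, ji = wins[wi]
                if p.start < we and p.end > ws:
                    bins[ji].add(idx)
                    bins[ji].add(idx ^ 1)  # the mate
    for ji, job in enumerate(jobs):
        job.read_bin = [reads[i] for i in sorted(bins[ji])]


class _GapGraph:
    """Rolling-hash k-mer graph over a gap's read bin (both strands)."""

    def __init__(self, reads: Sequence[str], w_min: int, w_max: int):
        text = "N".join([r.upper() for r in reads] + [revcomp(r.upper()) for r in reads])
        codes = encode(text)
        self._bad = np.concatenate(([0], np.cumsum(codes >= 4, dtype=np.int64)))
        c64 = (codes & 3).astype(np.uint64)
        self._hashes: dict[int, np.ndarray] = {}
        n = c64.size
        mult = np.uint64(_MULT)
        h = c64.copy()
        for w in range(2, w_max + 1):
            if n - w + 1 <= 0:
                break
            h = h[: n - w + 1] * mult + c64[w - 1 :]
            if w >= w_min:
                self._hashes[w] = h
        self._edge_cache: dict[tuple[int, int], set[int]] = {}

    def edge_sets(self, w: int, min_support: int) -> tuple[set[int], set[int]]:
        """(well-supported, any-support) w-mer hash sets (edges at k = w-1).

        The walk follows only well-supported edges (>= min_support) but
        treats any observed competing edge as a branch: a repeat's
        alternative continuation must not disappear just because it was
        sampled below the support floor at the current k.
        """
        key = (w, min_support)
        cached = self._edge_cache.get(key)
        if cached is not None:
            return cached
        h = self._hashes.get(w)
        if h is None:
            edges: tuple[set[int], set[int]] = (set(), set())
        else:
            valid = (self._bad[w:] - self._bad[: self._bad.size - w]) == 0
            vals, counts = np.unique(h[valid], return_counts=True)
            edges = (set(vals[counts >= min_support].tolist()), set(vals.tolist()))
        self._edge_cache[key] = edges
        return edges


def _hash_kmer(kmer: str) -> int:
    h = 0
    for c in encode(kmer):
        h = (h * _MULT + int(c & 3)) & _MASK
    return h


_BASES = "ACGT"


def _walk(
    graph: _GapGraph,
    start_kmer: str,
    target_kmer: str,
    k: int,
    min_support: int,
    max_steps: int,
) -> tuple[str | None, str]:
    """Unique branch-free path from start to target k-mer.

    Returns (fill, reason): fill is the interior between the anchors
    (possibly empty) when reason is "ok"; otherwise None with reason
    "branch" (more than one observed extension), "dead_end" (no
    extension at full support) or "overrun" (max_steps exceeded).
    """
    strong, observed = graph.edge_sets(k + 1, min_support)
    if not strong:
        return None, "dead_end"
    mk = pow(_MULT, k, 1 << 64)
    h = _hash_kmer(start_kmer)
    target_h = _hash_kmer(target_kmer)
    window = list(start_kmer)
    wpos = 0  # circular buffer head
    codes = [int(c & 3) for c in encode(start_kmer)]
    out: list[str] = []
    for _ in range(max_steps):
        base_h = (h * _MULT) & _MASK
        cand = -1
        for code in range(4):
            if (base_h + code) & _MASK in observed:
                if cand >= 0:
                    return None, "branch"
                cand = code
        if cand < 0 or (base_h + cand) & _MASK not in strong:
            return None, "dead_end"  # or sole edge below the support floor
        eh = (base_h + cand) & _MASK
        first = codes[wpos]
        h = (eh - first * mk) & _MASK
        window[wpos] = _BASES[cand]
        codes[wpos] = cand
        wpos = (wpos + 1) % k
        out.append(_BASES[cand])
        if h == target_h and len(out) >= k:
            spelled = "".join(window[wpos:] + window[:wpos])
            if spelled == target_kmer:
                return "".join(out[: len(out) - k]), "ok"
    return None, "overrun"


def close_gap_assembly(
    job: GapJob,
    k_min: int = DEFAULT_K_MIN,
    k_max: int = DEFAULT_K_MAX,
    min_support: int = 2,
    slack: int = 200,
) -> ClosureResult:
    """Close a gap by a unique path through the bin's k-mer graph.

    k scans from k_max down to k_min (largest k is most repeat
    resistant); the first k with a unique flank-to-flank path in at
    least one direction wins.  The walk is bounded by the estimated gap
    size plus 2k plus slack.
    """
    reads = job.read_bin
    if not reads:
        return ClosureResult(status="open")
    max_read = max(len(r) for r in reads)
    k_hi = min(k_max, max_read - 1, len(job.left_flank), len(job.right_flank))
    if k_hi < k_min:
        return ClosureResult(status="open")
    graph = _GapGraph(reads, w_min=k_min + 1, w_max=k_hi + 1)
    for k in range(k_hi, k_min - 1, -1):
        left_anchor = job.left_flank[-k:]
        right_anchor = job.right_flank[:k]
        if "N" in left_anchor or "N" in right_anchor:
            continue
        max_steps = job.estimated_gap_bp + 2 * k + slack
        fill_ltr, why_ltr = _walk(graph, left_anchor, right_anchor, k, min_support, max_steps)
        fill_rtl, why_rtl = _walk(
            graph, revcomp(right_anchor), revcomp(left_anchor), k, min_support, max_steps
        )
        if fill_rtl is not None:
            fill_rtl = revcomp(fill_rtl)
        if fill_ltr is not None and fill_rtl is not None:
            if fill_ltr == fill_rtl:
                return ClosureResult("closed_assembly", fill_ltr, k_used=k, direction="both")
            continue  # the two directions disagree: ambiguous at this k
        # A branch seen in either direction is positive evidence of a
        # competing continuation (a repeat), so a one-directional path
        # is only trusted when the other direction merely ran out of
        # read support.
        if fill_ltr is not None and why_rtl != "branch":
            return ClosureResult("closed_assembly", fill_ltr, k_used=k, direction="left_to_right")
        if fill_rtl is not None and why_ltr != "branch":
            return ClosureResult("closed_assembly", fill_rtl, k_used=k, direction="right_to_left")
    return ClosureResult(status="open")


def close_gap(
    job: GapJob,
    k_exact: int = DEFAULT_K_EXACT,
    k_min: int = DEFAULT_K_MIN,
    k_max: int = DEFAULT_K_MAX,
    min_support: int = 2,
) -> ClosureResult:
    """Spanning-read closure first, local mini-assembly second."""
    res = close_gap_spanning(job, k_exact=k_exact)
    if res.status != "open":
        return res
    return close_gap_assembly(job, k_min=k_min, k_max=k_max, min_support=min_support)


@dataclass
class ClosureReport:
    n_gaps: int
    n_closed_span: int
    n_closed_assembly: int
    n_open: int
    filled_bp_span: int
    filled_bp_assembly: int
    gap_bp_closed: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")


def apply_closures(
    scaffolds: dict[str, str],
    jobs: Sequence[GapJob],
    results: Sequence[ClosureResult],
) -> tuple[dict[str, str], ClosureReport, list[tuple[str, str]]]:
    """Replace closed gaps' N-runs with their fills.

    Gaps are applied right-to-left per scaffold so earlier coordinates
    stay valid.  Returns the new assembly, a summary report, and the
    filled regions (scaffold_id, left_flank + fill + right_flank) for
    redundancy screening.  Bases outside gap intervals are never
    touched.
    """
    if len(jobs) != len(results):
        raise InvalidParameterError("one result required per gap job")
    per_scaffold: dict[str, list[tuple[GapJob, ClosureResult]]] = {}
    for job, res in zip(jobs, results):
        per_scaffold.setdefault(job.scaffold_id, []).append((job, res))
    for sid, items in per_scaffold.items():
        items.sort(key=lambda jr: jr[0].start)
        for (a, _), (b, _) in zip(items, items[1:]):
            if a.end > b.start:
                raise InvalidParameterError(
                    f"overlapping gap intervals on {sid}: {a.interval} and {b.interval}"
                )

    new_assembly = dict(scaffolds)
    regions: list[tuple[str, str]] = []
    n_span = n_asm = bp_span = bp_asm = gap_bp = 0
    for sid, items in per_scaffold.items():
        seq = scaffolds[sid]
        for job, res in sorted(items, key=lambda jr: -jr[0].start):
            if res.status == "open":
                continue
            fill = res.fill_sequence or ""
            seq = seq[: job.start] + fill + seq[job.end :]
            regions.append((sid, job.left_flank + fill + job.right_flank))
            gap_bp += job.estimated_gap_bp
            if res.status == "closed_span":
                n_span += 1
                bp_span += len(fill)
            else:
                n_asm += 1
                bp_asm += len(fill)
        new_assembly[sid] = seq

    n_closed = n_span + n_asm
    report = ClosureReport(
        n_gaps=len(jobs),
        n_closed_span=n_span,
        n_closed_assembly=n_asm,
        n_open=len(jobs) - n_closed,
        filled_bp_span=bp_span,
        filled_bp_assembly=bp_asm,
        gap_bp_closed=gap_bp,
    )
    return new_assembly, report, regions


def write_gap_table(
    path: str | Path, jobs: Sequence[GapJob], results: Sequence[ClosureResult]
) -> None:
    """Per-gap TSV: scaffold, interval, status, k_used, fill length."""
    with open(path, "w") as fh:
        fh.write("scaffold\tstart\tend\tstatus\tk_used\tdirection\tfill_bp\n")
        for job, res in zip(jobs, results):
            fill_bp = len(res.fill_sequence) if res.fill_sequence is not None else ""
            fh.write(
                f"{job.scaffold_id}\t{job.start}\t{job.end}\t{res.status}\t"
                f"{res.k_used if res.k_used is not None else ''}\t"
                f"{res.direction if res.direction is not None else ''}\t{fill_bp}\n"
            )


def remove_redundant_contigs(
    assembly: dict[str, str],
    filled_regions: Sequence[tuple[str, str]],
    small_max_bp: int = 2000,
    min_identity: float = 0.98,
    min_cover: float = 0.95,
) -> tuple[dict[str, str], list[str]]:
    """Drop small contigs contained within newly closed gap regions.

    A contig shorter than small_max_bp is removed when it (or its
    reverse complement) aligns inside some filled region (fill plus one
    flank each side) at >= min_identity over >= min_cover of its
    length.  Containment is tested with infix edit-distance alignment:
    first the full contig at the identity threshold, then, failing
    that, its central min_cover core.
    """
    import edlib

    region_seqs = [seq for _, seq in filled_regions]
    removed: list[str] = []
    for name, seq in assembly.items():
        L = len(seq)
        if L >= small_max_bp or L == 0:
            continue
        if _contained(seq, region_seqs, min_identity, min_cover, edlib):
            removed.append(name)
    out = {name: seq for name, seq in assembly.items() if name not in set(removed)}
    return out, removed


def _contained(seq: str, regions: Sequence[str], min_identity: float, min_cover: float, edlib) -> bool:
    trim = int(round(len(seq) * (1 - min_cover) / 2))
    core = seq[trim : len(seq) - trim] if trim else seq
    for query in (seq, revcomp(seq), core, revcomp(core)):
        budget = int((1 - min_identity) * len(query))
        for region in regions:
            if len(region) < len(query):
                continue
            res = edlib.align(query, region, mode="HW", task="distance", k=budget)
            if res["editDistance"] != -1:
                return True
    return False
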