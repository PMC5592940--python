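"""Ground-truthed synthetic genomes, read sets and gapped assemblies.

The generators emulate the statistical structure the rest of the
toolkit assumes about a haploid, repeat-rich genome project:

* a genome of i.i.d. background sequence carrying planted multi-copy
  repeat families whose copies are diverged by per-base substitution —
  exact multi-copy families produce secondary k-mer-depth peaks at 2x
  and 3x the haploid depth, diverged ones dissolve back into unique
  k-mers at rate (1 - d)^k;
* uniform-coverage paired-end reads (FR orientation, substitution-only
  errors, constant read length);
* Nextera-style mate-pair libraries with a junction adapter at the
  circularization point, plus controlled PCR-duplicate, short-innie and
  adapter-free contamination, all recorded in a truth registry;
* gapped scaffolds whose true gap interiors are retained for
  validation, including deliberate "repeat trap" gaps whose interior
  duplicates nearby sequence and therefore must be left open by a
  branch-aware gap closer.

Everything is reproducible from an integer seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from ._encode import revcomp
from .errors import InvalidParameterError
from .matepair import NEXTERA_JUNCTION_ADAPTER

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class RepeatCopy(NamedTuple):
    family_id: int
    start: int
    end: int
    divergence: float


@dataclass
class SyntheticTruth:
    """Ground truth for one synthetic genome."""

    genome: str
    repeat_map: list[RepeatCopy] = field(default_factory=list)
    seed: int = 0

    @property
    def length(self) -> int:
        return len(self.genome)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each base independently with probability rate
    (always to a different base)."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    if hit.size:
        # map A<->C<->G<->T by a random non-zero offset in code space
        codes = np.searchsorted(_BASES, arr[hit])  # ACGT are sorted bytes
        shift = rng.integers(1, 4, size=hit.size)
        arr[hit] = _BASES[(codes + shift) % 4]
    return arr.tobytes().decode("ascii")


def _place_intervals(
    rng: np.random.Generator,
    genome_len: int,
    sizes: Sequence[int],
    occupied: list[tuple[int, int]],
    spacing: int = 0,
    max_tries: int = 2000,
) -> list[tuple[int, int]]:
    """Random non-overlapping intervals, each at least `spacing` away
    from every already-occupied interval."""
    placed: list[tuple[int, int]] = []
    taken = list(occupied)
    for size in sizes:
        ok = False
        for _ in range(max_tries):
            s = int(rng.integers(0, genome_len - size + 1))
            e = s + size
            if all(e + spacing <= ts or s >= te + spacing for ts, te in taken):
                taken.append((s, e))
                placed.append((s, e))
                ok = True
                break
        if not ok:
            raise InvalidParameterError(
                f"could not place an interval of {size} bp after {max_tries} tries"
            )
    return placed


def generate_repeat_genome(
    length_bp: int,
    repeat_fraction: float = 0.0,
    n_families: int = 1,
    copies_per_family: int = 2,
    divergence: float = 0.0,
    seed: int = 0,
) -> SyntheticTruth:
    """i.i.d. background genome with planted diverged repeat families.

    The repeat fraction is split evenly across families and copies;
    each copy is the family consensus with independent per-base
    substitutions at the divergence rate, overwriting a random
    non-overlapping stretch of the background.
    """
    if not 0 <= repeat_fraction < 1:
        raise InvalidParameterError("repeat_fraction must be in [0, 1)")
    if not 0 <= divergence <= 0.5:
        raise InvalidParameterError("divergence must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    genome = bytearray(_random_seq(rng, length_bp), "ascii")
    repeat_map: list[RepeatCopy] = []
    if repeat_fraction > 0:
        n_copies = n_families * copies_per_family
        copy_len = int(round(repeat_fraction * length_bp / n_copies))
        if copy_len < 1:
            raise InvalidParameterError("repeat_fraction too small for the copy count")
        if n_copies * copy_len >= length_bp:
            raise InvalidParameterError("repeats would exceed the genome length")
        intervals = _place_intervals(rng, length_bp, [copy_len] * n_copies, [])
        for fam in range(n_families):
            consensus = _random_seq(rng, copy_len)
            for c in range(copies_per_family):
                s, e = intervals[fam * copies_per_family + c]
                copy_seq = _mutate(rng, consensus, divergence)
                genome[s:e] = copy_seq.encode("ascii")
                repeat_map.append(RepeatCopy(fam, s, e, divergence))
    return SyntheticTruth(genome=genome.decode("ascii"), repeat_map=repeat_map, seed=seed)


@dataclass
class ReadSet:
    """Simulated paired-end reads with their true fragment registry."""

    pairs: list[tuple[str, str]]
    fragments: list[tuple[int, int]]
    read_len: int
    seed: int

    def reads(self) -> list[str]:
        return [r for pair in self.pairs for r in pair]


def simulate_paired_reads(
    truth: SyntheticTruth | str,
    coverage: float,
    read_len: int = 151,
    insert_mean: int = 400,
    insert_sd: float = 40.0,
    error_rate: float = 0.0,
    seed: int = 0,
) -> ReadSet:
    """Uniform FR paired-end reads at the requested coverage.

    Fragment lengths are normal (clipped to at least read_len); R1 is
    the fragment prefix on the forward strand, R2 the reverse
    complement of the fragment suffix.  Substitution errors only.
    """
    genome = truth.genome if isinstance(truth, SyntheticTruth) else truth
    L = len(genome)
    if coverage <= 0:
        raise InvalidParameterError("coverage must be positive")
    if insert_mean < 2 * read_len:
        warnings.warn("insert_mean below 2*read_len: mates will overlap", stacklevel=2)
    rng = np.random.default_rng(seed)
    n_pairs = int(round(coverage * L / (2 * read_len)))
    sizes = np.clip(
        np.rint(rng.normal(insert_mean, insert_sd, size=n_pairs)).astype(np.int64),
        read_len,
        L,
    )
    starts = (rng.random(n_pairs) * (L - sizes + 1)).astype(np.int64)
    pairs: list[tuple[str, str]] = []
    fragments: list[tuple[int, int]] = []
    for i in range(n_pairs):
        s = int(starts[i])
        e = s + int(sizes[i])
        r1 = genome[s : s + read_len]
        r2 = revcomp(genome[e - read_len : e])
        if error_rate > 0:
            r1 = _mutate(rng, r1, error_rate)
            r2 = _mutate(rng, r2, error_rate)
        pairs.append((r1, r2))
        fragments.append((s, e))
    return ReadSet(pairs=pairs, fragments=fragments, read_len=read_len, seed=seed)


def simulate_matepair_reads(
    truth: SyntheticTruth | str,
    n_pairs: int,
    insert_mean: int = 5000,
    insert_sd: float = 500.0,
    junction_adapter: str = NEXTERA_JUNCTION_ADAPTER,
    dup_rate: float = 0.0,
    innie_rate: float = 0.0,
    adapterless_rate: float = 0.0,
    read_len: int = 151,
    seed: int = 0,
):
    """Nextera-style mate-pair library with a truth registry.

    True pairs map outward-facing with outer span equal to the clone
    size and carry the junction adapter inside one or both reads (the
    read portion before the adapter comes from one clone end, the
    portion after it crosses the circularization junction).  Innies are
    inward-facing FR pairs at spans <= 0.2x the nominal insert;
    adapter-free pairs emulate untagged chimeras (junction category D).
    PCR duplicates re-emit a previous clone's reads verbatim.

    Returns (pairs, registry) where registry is a pandas DataFrame with
    one row per emitted pair: clone coordinates, kind, true junction
    category and duplicate flag.
    """
    import pandas as pd

    genome = truth.genome if isinstance(truth, SyntheticTruth) else truth
    L = len(genome)
    for name, rate in (("dup_rate", dup_rate), ("innie_rate", innie_rate),
                       ("adapterless_rate", adapterless_rate)):
        if not 0 <= rate < 1:
            raise InvalidParameterError(f"{name} must be in [0, 1)")
    if innie_rate + adapterless_rate >= 1:
        raise InvalidParameterError("contamination rates must sum below 1")
    if insert_mean >= L:
        raise InvalidParameterError("insert_mean must be below the genome length")
    rng = np.random.default_rng(seed)
    alen = len(junction_adapter)
    # Keep trimmed reads long enough to seed-align (>= 40 bp).
    g_lo, g_hi = 40, read_len - alen
    if g_hi <= g_lo:
        raise InvalidParameterError("read_len too short for the junction adapter")
    max_innie_span = int(0.2 * insert_mean)
    if max_innie_span <= 2 * read_len + 20:
        raise InvalidParameterError("insert_mean too small to distinguish innies")

    def true_pair() -> tuple[tuple[str, str], tuple[int, int], str]:
        size = int(np.clip(round(rng.normal(insert_mean, insert_sd)), 3 * read_len, L - 1))
        s = int(rng.integers(0, L - size))
        e = s + size
        cat = ("A", "B", "C")[rng.choice(3, p=[0.5, 0.25, 0.25])]
        if cat in ("A", "B"):
            g1 = int(rng.integers(g_lo, g_hi + 1))
            cross = genome[s : s + read_len - g1 - alen]
            r1 = genome[e - g1 : e] + junction_adapter + cross
        else:
            r1 = genome[e - read_len : e]
        if cat in ("A", "C"):
            g2 = int(rng.integers(g_lo, g_hi + 1))
            cross = revcomp(genome[e - (read_len - g2 - alen) : e])
            r2 = revcomp(genome[s : s + g2]) + junction_adapter + cross
        else:
            r2 = revcomp(genome[s : s + read_len])
        return (r1, r2), (s, e), cat

    def innie_pair() -> tuple[tuple[str, str], tuple[int, int], str]:
        span = int(rng.integers(2 * read_len + 20, max_innie_span + 1))
        s = int(rng.integers(0, L - span))
        g1 = int(rng.integers(g_lo, g_hi + 1))
        g2 = int(rng.integers(g_lo, g_hi + 1))
        r1 = genome[s : s + g1] + junction_adapter + genome[s + g1 : s + read_len - alen]
        r2_gen = revcomp(genome[s + span - g2 : s + span])
        r2 = r2_gen + junction_adapter + revcomp(genome[s + span - read_len + alen : s + span - g2])
        return (r1, r2), (s, s + span), "A"

    def adapterless_pair() -> tuple[tuple[str, str], tuple[int, int], str]:
        size = int(np.clip(round(rng.normal(insert_mean, insert_sd)), 3 * read_len, L - 1))
        s = int(rng.integers(0, L - size))
        e = s + size
        return (genome[e - read_len : e], revcomp(genome[s : s + read_len])), (s, e), "D"

    pairs: list[tuple[str, str]] = []
    rows = []
    clones: list[tuple[tuple[str, str], tuple[int, int], str, str, int]] = []
    for i in range(n_pairs):
        if clones and rng.random() < dup_rate:
            reads, frag, kind, cat, clone_id = clones[int(rng.integers(0, len(clones)))]
            is_dup = True
        else:
            u = rng.random()
            if u < innie_rate:
                reads, frag, cat = innie_pair()
                kind = "innie"
            elif u < innie_rate + adapterless_rate:
                reads, frag, cat = adapterless_pair()
                kind = "adapterless"
            else:
                reads, frag, cat = true_pair()
                kind = "true"
            clone_id = len(clones)
            clones.append((reads, frag, kind, cat, clone_id))
            is_dup = False
        pairs.append(reads)
        rows.append(
            dict(pair_id=i, clone_id=clone_id, kind=kind, category=cat,
                 start=frag[0], end=frag[1], is_dup=is_dup)
        )
    registry = pd.DataFrame(rows)
    return pairs, registry


def plant_repeat_traps(
    truth: SyntheticTruth,
    n_traps: int,
    repeat_len: int = 200,
    arm_len: int = 50,
    seed: int = 0,
) -> list[tuple[int, int]]:
    """Rewrite the genome so n_traps future gaps are unclosable.

    Each trap interval is [p, p + arm + repeat_len + arm): its middle
    repeat_len bases are made an exact copy of the sequence placed just
    left of p (inside what will become the gap's left flank).  A gap cut
    at the trap interval then branches at every k <= repeat_len during a
    flank-anchored k-mer walk, in both directions, so a sound closer
    must leave it open.  Mutates truth.genome; returns the intervals.
    """
    rng = np.random.default_rng(seed)
    interior = 2 * arm_len + repeat_len
    margin = repeat_len + 300
    sizes = [interior + 2 * margin] * n_traps
    occupied = [(s, e) for _, s, e, _ in truth.repeat_map]
    zones = _place_intervals(rng, truth.length, sizes, occupied, spacing=100)
    genome = bytearray(truth.genome, "ascii")
    intervals: list[tuple[int, int]] = []
    for zs, _ in zones:
        p = zs + margin
        repeat = _random_seq(rng, repeat_len)
        genome[p - 5 - repeat_len : p - 5] = repeat.encode("ascii")
        genome[p + arm_len : p + arm_len + repeat_len] = repeat.encode("ascii")
        intervals.append((p, p + interior))
    truth.genome = genome.decode("ascii")
    return intervals


def make_gapped_assembly(
    truth: SyntheticTruth | str,
    n_gaps: int,
    gap_len_range: tuple[int, int] = (50, 500),
    flank_bp: int = 200,
    seed: int = 0,
    scaffold_id: str = "scaffold_1",
    forced_intervals: Sequence[tuple[int, int]] = (),
) -> tuple[dict[str, str], dict[str, str]]:
    """Cut N-gaps into the genome at known positions.

    n_gaps random intervals with lengths uniform in gap_len_range are
    chosen at least 2*flank_bp apart (and away from any forced
    intervals, e.g. repeat traps, which are always cut).  Returns the
    gapped scaffold and the truth map gap_id -> true interior, with
    gap_id = "scaffold:start-end".
    """
    genome = truth.genome if isinstance(truth, SyntheticTruth) else truth
    rng = np.random.default_rng(seed)
    lo, hi = gap_len_range
    if lo < 1 or hi < lo:
        raise InvalidParameterError("bad gap_len_range")
    sizes = [int(x) for x in rng.integers(lo, hi + 1, size=n_gaps)]
    # keep clear of forced intervals by a full trap's worth of context
    occupied = [(max(0, s - (flank_bp + 300)), e + flank_bp + 300) for s, e in forced_intervals]
    random_intervals = _place_intervals(
        rng, len(genome), sizes, occupied, spacing=2 * flank_bp
    )
    intervals = sorted(list(forced_intervals) + random_intervals)
    gapped = bytearray(genome, "ascii")
    gap_truth: dict[str, str] = {}
    for s, e in intervals:
        gap_truth[f"{scaffold_id}:{s}-{e}"] = genome[s:e]
        gapped[s:e] = b"N" * (e - s)
    return {scaffold_id: gapped.decode("ascii")}, gap_truth
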