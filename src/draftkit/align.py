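"""Exact-seed, ungapped-extension read alignment against a contig set.

This is deliberately minimal plumbing: a sorted array of packed 31-mer
seeds over the contigs, exact seed lookup for a read (both strands,
stepping the seed across the read to tolerate substitutions), and an
ungapped extension that counts matching bases.  It supports duplicate
and innie detection and gap read-binning; it is not a general-purpose
mapper (no indels, no clipping across contig ends).
"""

from __future__ import annotations

from typing import Iterable, NamedTuple, Sequence

import numpy as np

from ._encode import encode, pack_forward, revcomp, valid_windows

DEFAULT_SEED_LEN = 31


class Placement(NamedTuple):
    """One ungapped placement of a read on a contig.

    start is 0-based on the contig's forward strand; strand '-' means
    the reverse complement of the read matches there.  length is the
    aligned span on the contig (= read length here).
    """

    contig: str
    start: int
    strand: str
    matched_bp: int
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length


class SeedIndex:
    """Packed-seed index over a set of contigs."""

    def __init__(self, contigs: Iterable[tuple[str, str]] | dict, seed_len: int = DEFAULT_SEED_LEN):
        if isinstance(contigs, dict):
            contigs = list(contigs.items())
        else:
            contigs = list(contigs)
        if seed_len < 8 or seed_len > 32:
            raise ValueError("seed_len must be in [8, 32]")
        self.seed_len = seed_len
        self.names = [name for name, _ in contigs]
        seqs = [seq.upper() for _, seq in contigs]
        # Global coordinate space: contigs joined by one 'N' sentinel.
        self._starts = np.zeros(len(seqs), dtype=np.int64)
        pos = 0
        for i, s in enumerate(seqs):
            self._starts[i] = pos
            pos += len(s) + 1
        self._lengths = np.array([len(s) for s in seqs], dtype=np.int64)
        self._text = "N".join(seqs).encode("ascii")

        codes = encode(self._text)
        if codes.size >= seed_len:
            vals = pack_forward(codes, seed_len)
            valid = valid_windows(codes, seed_len)
            positions = np.nonzero(valid)[0].astype(np.int64)
            vals = vals[valid]
            order = np.argsort(vals, kind="stable")
            self._seed_vals = vals[order]
            self._seed_pos = positions[order]
        else:
            self._seed_vals = np.zeros(0, dtype=np.uint64)
            self._seed_pos = np.zeros(0, dtype=np.int64)

    # -- lookups ---------------------------------------------------------
    def _hits(self, seed_val: int) -> np.ndarray:
        v = np.uint64(seed_val)
        lo = int(np.searchsorted(self._seed_vals, v, side="left"))
        hi = int(np.searchsorted(self._seed_vals, v, side="right"))
        return self._seed_pos[lo:hi]

    def _locate(self, gpos: int) -> tuple[int, int] | None:
        """Global position -> (contig index, local position)."""
        i = int(np.searchsorted(self._starts, gpos, side="right")) - 1
        local = gpos - int(self._starts[i])
        if local >= int(self._lengths[i]):
            return None
        return i, local

    def _extend(self, oriented: bytes, gstart: int) -> int | None:
        """Matched bases of an ungapped placement at global start, or None."""
        L = len(oriented)
        if gstart < 0:
            return None
        loc = self._locate(gstart)
        if loc is None:
            return None
        i, local = loc
        if local + L > int(self._lengths[i]):
            return None
        ref = self._text[gstart : gstart + L]
        if ref == oriented:
            return L
        a = np.frombuffer(ref, dtype=np.uint8)
        b = np.frombuffer(oriented, dtype=np.uint8)
        return int((a == b).sum())

    def align(
        self,
        read: str,
        min_match_frac: float = 0.9,
        max_seed_offsets: int = 5,
    ) -> list[Placement]:
        """All placements of a read with matched_bp >= min_match_frac * len.

        Seeds are tried at offsets 0, seed_len, 2*seed_len, ... on both
        strands, so any read with fewer than one substitution per
        seed_len bases in some window is found.  Placements are returned
        sorted by (contig, start, strand), deduplicated.
        """
        read = read.upper()
        L = len(read)
        if L < self.seed_len:
            return []
        min_match = int(np.ceil(min_match_frac * L))
        found: dict[tuple[str, int, str], Placement] = {}
        for strand, oriented in (("+", read), ("-", revcomp(read))):
            ob = oriented.encode("ascii")
            codes = encode(ob)
            n_off = min(max_seed_offsets, (L - self.seed_len) // self.seed_len + 1)
            offsets = [j * self.seed_len for j in range(n_off)]
            if L - self.seed_len not in offsets:
                offsets.append(L - self.seed_len)  # trailing window
            for off in offsets:
                window = codes[off : off + self.seed_len]
                if (window >= 4).any():
                    continue
                val = int(pack_forward(window, self.seed_len)[0])
                for gpos in self._hits(val):
                    gstart = int(gpos) - off
                    matched = self._extend(ob, gstart)
                    if matched is None or matched < min_match:
                        continue
                    loc = self._locate(gstart)
                    assert loc is not None
                    ci, local = loc
                    key = (self.names[ci], local, strand)
                    if key not in found or matched > found[key].matched_bp:
                        found[key] = Placement(self.names[ci], local, strand, matched, L)
        return sorted(found.values(), key=lambda p: (p.contig, p.start, p.strand))

    def align_batch(
        self,
        reads: Sequence[str],
        min_match_frac: float = 0.9,
    ) -> list[list[Placement]]:
        """align() over many reads, with the offset-0 seed lookups vectorized.

        Reads whose offset-0 seeds miss on both strands fall back to the
        full per-read seed schedule.
        """
        n = len(reads)
        out: list[list[Placement]] = [[] for _ in range(n)]
        if n == 0:
            return out
        sl = self.seed_len
        usable = [i for i, r in enumerate(reads) if len(r) >= sl]
        if not usable:
            return out

        fwd_txt = "".join(reads[i][:sl].upper() for i in usable)
        fwd_codes = encode(fwd_txt).reshape(len(usable), sl)
        # offset-0 seed of the reverse-complemented read = revcomp of the
        # read's last seed_len bases.
        rc_txt = "".join(reads[i][-sl:].upper() for i in usable)
        rc_codes = ((encode(rc_txt).reshape(len(usable), sl) & 3) ^ 3)[:, ::-1]
        rc_bad = encode(rc_txt).reshape(len(usable), sl) >= 4

        def pack_rows(codes: np.ndarray) -> np.ndarray:
            vals = codes[:, 0].astype(np.uint64) & np.uint64(3)
            for j in range(1, sl):
                vals = (vals << np.uint64(2)) | (codes[:, j].astype(np.uint64) & np.uint64(3))
            return vals

        fwd_vals = pack_rows(fwd_codes)
        rc_vals = pack_rows(rc_codes)
        fwd_ok = ~(fwd_codes >= 4).any(axis=1)
        rc_ok = ~rc_bad.any(axis=1)

        lo_f = np.searchsorted(self._seed_vals, fwd_vals, side="left")
        hi_f = np.searchsorted(self._seed_vals, fwd_vals, side="right")
        lo_r = np.searchsorted(self._seed_vals, rc_vals, side="left")
        hi_r = np.searchsorted(self._seed_vals, rc_vals, side="right")

        for row, i in enumerate(usable):
            read = reads[i].upper()
            L = len(read)
            min_match = int(np.ceil(min_match_frac * L))
            found: dict[tuple[str, int, str], Placement] = {}
            jobs = []
            if fwd_ok[row] and hi_f[row] > lo_f[row]:
                jobs.append(("+", read.encode("ascii"), 0, self._seed_pos[lo_f[row] : hi_f[row]]))
            if rc_ok[row] and hi_r[row] > lo_r[row]:
                jobs.append(("-", revcomp(read).encode("ascii"), 0, self._seed_pos[lo_r[row] : hi_r[row]]))
            for strand, ob, off, positions in jobs:
                for gpos in positions:
                    gstart = int(gpos) - off
                    matched = self._extend(ob, gstart)
                    if matched is None or matched < min_match:
                        continue
                    loc = self._locate(gstart)
                    assert loc is not None
                    ci, local = loc
                    key = (self.names[ci], local, strand)
                    if key not in found or matched > found[key].matched_bp:
                        found[key] = Placement(self.names[ci], local, strand, matched, L)
            if found:
                out[i] = sorted(found.values(), key=lambda p: (p.contig, p.start, p.strand))
            else:
                out[i] = self.align(read, min_match_frac=min_match_frac)
        return out


def align_read(
    read: str,
    contigs: Iterable[tuple[str, str]] | dict | SeedIndex,
    seed_len: int = DEFAULT_SEED_LEN,
    min_match_frac: float = 0.9,
) -> list[Placement]:
    """Convenience wrapper: build (or reuse) a SeedIndex and align one read."""
    index = contigs if isinstance(contigs, SeedIndex) else SeedIndex(contigs, seed_len=seed_len)
    return index.align(read, min_match_frac=min_match_frac)
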