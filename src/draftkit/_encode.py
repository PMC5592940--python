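"""Low-level vectorized DNA encoding and k-mer packing kernels.

Bases are encoded 2 bits each (A=0, C=1, G=2, T=3); any other byte maps
to the sentinel 4 and poisons every window that covers it.  For k <= 32
a k-mer packs exactly into a uint64, which lets counting, canonicalization
and histogramming run as a handful of numpy passes instead of a Python
loop per position.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _CODE[_b] = _i

_COMP = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

MAX_PACKED_K = 32


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N passes through)."""
    return seq.translate(_COMP)[::-1]


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a sequence to 2-bit codes (uint8), sentinel 4 for non-ACGT."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _CODE[np.frombuffer(seq, dtype=np.uint8)]


def valid_windows(codes: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask over the len(codes)-k+1 windows free of sentinel bases."""
    n = codes.size - k + 1
    if n <= 0:
        return np.zeros(0, dtype=bool)
    bad = np.concatenate(([0], np.cumsum(codes >= 4, dtype=np.int64)))
    return (bad[k:] - bad[:-k]) == 0


def pack_forward(codes: np.ndarray, k: int) -> np.ndarray:
    """uint64 2-bit packing of every forward k-mer window (k <= 32).

    Values under invalid windows are garbage; mask with valid_windows.
    """
    if not 1 <= k <= MAX_PACKED_K:
        raise ValueError(f"packed k-mers require 1 <= k <= {MAX_PACKED_K}")
    n = codes.size - k + 1
    if n <= 0:
        return np.zeros(0, dtype=np.uint64)
    c = (codes & 3).astype(np.uint64)
    val = c[:n].copy()
    for j in range(1, k):
        val <<= np.uint64(2)
        val |= c[j : j + n]
    return val


def pack_revcomp(codes: np.ndarray, k: int) -> np.ndarray:
    """uint64 packing of the reverse complement of every k-mer window."""
    if not 1 <= k <= MAX_PACKED_K:
        raise ValueError(f"packed k-mers require 1 <= k <= {MAX_PACKED_K}")
    n = codes.size - k + 1
    if n <= 0:
        return np.zeros(0, dtype=np.uint64)
    comp = ((codes & 3) ^ 3).astype(np.uint64)
    val = comp[k - 1 : k - 1 + n].copy()
    for j in range(1, k):
        val <<= np.uint64(2)
        val |= comp[k - 1 - j : k - 1 - j + n]
    return val


def canonical_kmers(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(canonical uint64 k-mers, valid mask) over every window of *codes*."""
    fwd = pack_forward(codes, k)
    rc = pack_revcomp(codes, k)
    return np.minimum(fwd, rc), valid_windows(codes, k)


_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def decode_kmer(value: int, k: int) -> str:
    """Decode a packed uint64 back to its k-mer string."""
    out = bytearray(k)
    v = int(value)
    for i in range(k - 1, -1, -1):
        out[i] = _DECODE[v & 3]
        v >>= 2
    return out.decode("ascii")


def encode_kmer(kmer: str) -> int:
    """Pack a k-mer string (ACGT only, len <= 32) into an int."""
    v = 0
    for ch in kmer.encode("ascii"):
        c = _CODE[ch]
        if c >= 4:
            raise ValueError(f"non-ACGT base in k-mer: {kmer!r}")
        v = (v << 2) | int(c)
    return v
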