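"""Vectorised k-mer encoding helpers.

Sequences are encoded 2 bits/base, so exact k-mers up to k=31 fit in a
uint64. Windows containing a non-ACGT base are masked out.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 255, dtype=np.uint8)
for i, base in enumerate("ACGT"):
    _CODE[ord(base)] = i
    _CODE[ord(base.lower())] = i


def encode(seq: str) -> np.ndarray:
    """Sequence -> uint8 codes (255 marks non-ACGT)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (codes, valid) for every k-window of ``seq``.

    ``codes[i]`` encodes seq[i:i+k]; ``valid[i]`` is False when the window
    contains a non-ACGT base.
    """
    arr = encode(seq)
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    bad = arr == 255
    safe = np.where(bad, 0, arr).astype(np.uint64)
    codes = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        codes = (codes << np.uint64(2)) | safe[j : n + j]
    if bad.any():
        bad_cum = np.concatenate([[0], np.cumsum(bad)])
        valid = (bad_cum[k:] - bad_cum[:-k]) == 0
    else:
        valid = np.ones(n, dtype=bool)
    return codes, valid


def unique_kmer_positions(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Codes occurring exactly once in ``seq`` and their positions."""
    codes, valid = kmer_codes(seq, k)
    pos = np.nonzero(valid)[0]
    codes = codes[pos]
    order = np.argsort(codes, kind="stable")
    sc, sp = codes[order], pos[order]
    uniq, counts = np.unique(sc, return_counts=True)
    keep = counts == 1
    starts = np.concatenate([[0], np.cumsum(counts)])[:-1]
    return uniq[keep], sp[starts[keep]]


class KmerIndex:
    """Sorted-array exact k-mer lookup over one genome strand."""

    def __init__(self, seq: str, k: int):
        self.k = k
        self.seq = seq
        codes, valid = kmer_codes(seq, k)
        pos = np.nonzero(valid)[0].astype(np.int64)
        codes = codes[pos]
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._pos = pos[order]

    def lookup(self, code: int) -> np.ndarray:
        lo = np.searchsorted(self._codes, code, side="left")
        hi = np.searchsorted(self._codes, code, side="right")
        return self._pos[lo:hi]

    def lookup_many(self, codes: np.ndarray) -> list[np.ndarray]:
        lo = np.searchsorted(self._codes, codes, side="left")
        hi = np.searchsorted(self._codes, codes, side="right")
        return [self._pos[a:b] for a, b in zip(lo, hi)]
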