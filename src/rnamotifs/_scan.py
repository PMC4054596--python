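"""Vectorised tetramer-scanning kernels.

All heavy per-nucleotide work (match finding, coverage, cluster heights)
runs here on pooled byte arrays so the calibration, region-enrichment and
positional-map stages can scan thousands of windows per tetramer in a
handful of numpy passes.
"""
from __future__ import annotations

import numpy as np

#: byte -> base code; A=0 C=1 G=2 T=3, anything else (incl. N) = 4
_BYTE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BYTE_CODE[ord(_b)] = _i
    _BYTE_CODE[ord(_b.lower())] = _i

#: sentinel k-mer code used for 4-mers containing a non-ACGT base
INVALID_KMER = 256


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 base codes (N and friends -> 4)."""
    return _BYTE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_codes(codes: np.ndarray) -> np.ndarray:
    """4-mer codes (base-4, 0..255) at every start; INVALID_KMER where any N."""
    n = codes.size - 3
    if n <= 0:
        return np.empty(0, dtype=np.int32)
    c = codes.astype(np.int32)
    k = (c[:-3] << 6) | (c[1:-2] << 4) | (c[2:-1] << 2) | c[3:]
    bad = (c[:-3] > 3) | (c[1:-2] > 3) | (c[2:-1] > 3) | (c[3:] > 3)
    k[bad] = INVALID_KMER
    return k


class PooledScan:
    """A pool of sequence windows concatenated for single-pass scanning.

    Windows are joined with runs of N long enough that neither tetramer
    matches nor cluster-height counting can leak between neighbouring
    windows.  ``segment(i)`` returns the slice of the pooled arrays
    holding window ``i``.
    """

    def __init__(self, seqs: list[str], window: int = 31):
        if window < 1 or window % 2 == 0:
            raise ValueError("cluster window must be a positive odd integer")
        self.window = window
        half = window // 2
        sep = "N" * (half + 1)
        parts: list[str] = []
        starts = np.empty(len(seqs), dtype=np.int64)
        lengths = np.empty(len(seqs), dtype=np.int64)
        pos = 0
        for i, s in enumerate(seqs):
            starts[i] = pos
            lengths[i] = len(s)
            parts.append(s)
            parts.append(sep)
            pos += len(s) + len(sep)
        self.starts = starts
        self.lengths = lengths
        self.half = half
        self.codes = encode("".join(parts)) if parts else np.empty(0, np.uint8)
        self.kmers = kmer_codes(self.codes)

    def __len__(self) -> int:
        return self.starts.size

    def segment(self, i: int) -> slice:
        return slice(self.starts[i], self.starts[i] + self.lengths[i])

    def covered(self, lut: np.ndarray) -> np.ndarray:
        """Boolean mask of 'tetramer nucleotides' for the tetramer LUT."""
        L = self.codes.size
        match = lut[self.kmers]
        # covered[i] = any match start in [i-3, i]; edge-padded cumsum turns
        # the clipped window sum into a plain slice difference
        cs = np.empty(match.size + 1, dtype=np.int32)
        cs[0] = 0
        np.cumsum(match, dtype=np.int32, out=cs[1:])
        csp = np.pad(cs, (3, L - match.size), mode="edge")
        return (csp[4:] - csp[:-4]) > 0

    def heights(self, covered: np.ndarray) -> np.ndarray:
        """Cluster height at every position (meaningful only where covered)."""
        half = self.half
        cs = np.empty(covered.size + 1, dtype=np.int32)
        cs[0] = 0
        np.cumsum(covered, dtype=np.int32, out=cs[1:])
        csp = np.pad(cs, (half, half), mode="edge")
        return csp[2 * half + 1 :] - csp[: -(2 * half + 1)]

    def height_histogram(self, lut: np.ndarray) -> tuple[np.ndarray, int]:
        """Histogram (length window+1) of h over covered positions.

        The denominator (total positions pooled, N separators excluded)
        is returned alongside; separators are never covered so they only
        need removing from the denominator.
        """
        cov = self.covered(lut)
        h = self.heights(cov)
        hist = np.bincount(h[cov], minlength=self.window + 1)
        return hist[: self.window + 1], int(self.lengths.sum())

    def instances(self, lut: np.ndarray, h_min: int) -> np.ndarray:
        """Boolean cluster-instance mask (covered and h >= h_min)."""
        cov = self.covered(lut)
        return cov & (self.heights(cov) >= h_min)
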