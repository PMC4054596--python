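"""The tetramer search space: 256 non-degenerate + 64 degenerate patterns.

Degenerate (DG) tetramers allow purine R = A/G or pyrimidine Y = C/T at the
two boundary positions only, with a non-degenerate (ND) core, e.g. YCAY,
which matches TCAT, TCAC, CCAT and CCAC.  Matching is case-insensitive,
overlaps are allowed, and any N inside a 4-mer kills the match.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from ._scan import INVALID_KMER, encode, kmer_codes

BASES = "ACGT"
_DEGEN = {"R": "AG", "Y": "CT"}


def expand_pattern(pattern: str) -> tuple[str, ...]:
    """All non-degenerate tetramers matched by ``pattern`` (R/Y at ends only)."""
    choices = [_DEGEN.get(c, c) for c in pattern]
    return tuple("".join(p) for p in itertools.product(*choices))


def _kmer_code(tet: str) -> int:
    return int(kmer_codes(encode(tet))[0])


@dataclass(frozen=True)
class Tetramer:
    """A 4-nt motif over {A,C,G,T} with optional R/Y at positions 1 and 4."""

    pattern: str
    expansion: tuple[str, ...] = field(init=False)

    def __post_init__(self):
        p = self.pattern.upper()
        object.__setattr__(self, "pattern", p)
        if len(p) != 4 or any(c not in "ACGTRY" for c in p):
            raise ValueError(f"invalid tetramer pattern {self.pattern!r}")
        if p[1] in "RY" or p[2] in "RY":
            raise ValueError(f"degeneracy only allowed at boundary positions: {p!r}")
        degen = p[0] in "RY" or p[3] in "RY"
        if degen and not (p[0] in "RY" and p[3] in "RY"):
            raise ValueError(f"degenerate tetramers must be degenerate at both ends: {p!r}")
        object.__setattr__(self, "expansion", expand_pattern(p))

    @property
    def is_degenerate(self) -> bool:
        return len(self.expansion) > 1

    def lut(self) -> np.ndarray:
        """Boolean lookup over 4-mer codes (index INVALID_KMER always False)."""
        lut = np.zeros(INVALID_KMER + 1, dtype=bool)
        for nd in self.expansion:
            lut[_kmer_code(nd)] = True
        return lut

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.pattern


def enumerate_tetramers() -> list[Tetramer]:
    """The full search space: 256 ND then 64 DG tetramers, lexicographic.

    The order is deterministic so every downstream table and FDR family is
    reproducible run to run.
    """
    nd = ["".join(p) for p in itertools.product(BASES, repeat=4)]
    dg = [
        b1 + "".join(mid) + b4
        for b1 in "RY"
        for mid in itertools.product(BASES, repeat=2)
        for b4 in "RY"
    ]
    return [Tetramer(p) for p in sorted(nd)] + [Tetramer(p) for p in sorted(dg)]


@dataclass
class MatchMask:
    """Match starts and the union of matched spans ('tetramer nucleotides')."""

    seq_len: int
    starts: np.ndarray  # int indices of match starts
    covered: np.ndarray  # bool per position


def match_positions(window, tet: Tetramer) -> MatchMask:
    """Locate all (possibly overlapping) matches of ``tet`` in a window.

    ``window`` may be a plain string or any object with a ``seq`` attribute.
    """
    seq = window if isinstance(window, str) else window.seq
    codes = encode(seq)
    km = kmer_codes(codes)
    lut = tet.lut()
    starts = np.flatnonzero(lut[km]) if km.size else np.empty(0, dtype=np.int64)
    covered = np.zeros(len(seq), dtype=bool)
    for s in starts:
        covered[s : s + 4] = True
    return MatchMask(seq_len=len(seq), starts=starts, covered=covered)
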