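"""Cluster heights, coverage-based h_min calibration and instance calling.

A multivalent motif is modelled as a *cluster* of tetramer matches.  The
cluster height h at a position is the number of 'tetramer nucleotides'
(positions overlapped by at least one match) inside a 31-nt window centred
on it; h is defined only at tetramer nucleotides, so 4 <= h <= 31.  Each
tetramer gets its own minimum height h_min, chosen so that the fraction of
calibration sequence carrying a cluster instance (h >= h_min) is closest
to a common target (0.5% by default).  This equalises the background
instance probability across frequent and rare tetramers.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._scan import PooledScan
from .genome_io import ExonEvent, calibration_sequences
from .motif_space import MatchMask, Tetramer, enumerate_tetramers

logger = logging.getLogger(__name__)

CLUSTER_WINDOW = 31
COVERAGE_TARGET = 0.5  # percent of calibration sequence


@dataclass
class ClusterProfile:
    """Per-position cluster heights and (optionally) the instance mask."""

    covered: np.ndarray  # bool per position
    h: np.ndarray  # int per position; meaningful only where covered
    instance: np.ndarray | None = None


@dataclass
class CoverageCurve:
    """Coverage percentage as a function of candidate h (4..31)."""

    h_values: np.ndarray
    coverage: np.ndarray  # percent, non-increasing
    total_positions: int


def cluster_height_profile(mask: MatchMask, window: int = CLUSTER_WINDOW) -> ClusterProfile:
    """Cluster heights from a match mask; truncates at sequence ends."""
    half = window // 2
    cov = mask.covered
    cs = np.concatenate(([0], np.cumsum(cov)))
    idx = np.arange(cov.size)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, cov.size)
    h = (cs[hi] - cs[lo]).astype(np.int32)
    return ClusterProfile(covered=cov.copy(), h=h)


def coverage_curve(profiles: list[ClusterProfile], window: int = CLUSTER_WINDOW) -> CoverageCurve:
    """Pool cluster profiles into a coverage-vs-h curve."""
    if not profiles:
        raise ValueError("empty calibration set")
    total = sum(p.h.size for p in profiles)
    hist = np.zeros(window + 1, dtype=np.int64)
    for p in profiles:
        vals = p.h[p.covered]
        if vals.size:
            hist += np.bincount(np.minimum(vals, window), minlength=window + 1)
    return _curve_from_hist(hist, total, window)


def _curve_from_hist(hist: np.ndarray, total: int, window: int = CLUSTER_WINDOW) -> CoverageCurve:
    if total <= 0:
        raise ValueError("empty calibration set")
    tail = np.cumsum(hist[::-1])[::-1]  # tail[h] = positions with height >= h
    hs = np.arange(4, window + 1)
    return CoverageCurve(h_values=hs, coverage=100.0 * tail[4:] / total, total_positions=total)


def select_h_min(curve: CoverageCurve, target: float = COVERAGE_TARGET) -> int | None:
    """Smallest h whose coverage is closest to the target percentage.

    Ties go to the smaller h.  Returns None when the tetramer never occurs
    (all-zero curve), in which case the tetramer is skipped.
    """
    if not np.any(curve.coverage > 0):
        return None
    i = int(np.argmin(np.abs(curve.coverage - target)))
    return int(curve.h_values[i])


def call_instances(profile: ClusterProfile, h_min: int) -> ClusterProfile:
    """Mark cluster instances: covered positions with h >= h_min."""
    profile.instance = profile.covered & (profile.h >= h_min)
    return profile


@dataclass
class HminTable:
    """Calibrated h_min per tetramer (h_min = -1 where undefined)."""

    tetramers: list[Tetramer]
    h_min: np.ndarray
    coverage_at_h_min: np.ndarray
    total_positions: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tetramer": [t.pattern for t in self.tetramers],
                "h_min": self.h_min,
                "coverage_at_h_min": self.coverage_at_h_min,
            }
        )


def calibrate_h_min(
    events: list[ExonEvent],
    genome,
    tetramers: list[Tetramer] | None = None,
    target: float = COVERAGE_TARGET,
    window: int = CLUSTER_WINDOW,
) -> HminTable:
    """Calibrate h_min for every tetramer over all monitored events.

    The calibration pool is the concatenated flanking sequence of all
    events of all three classes (see ``calibration_sequences``), so the
    background cluster-instance probability is matched across tetramers
    on the same data the enrichment test will use.
    """
    if tetramers is None:
        tetramers = enumerate_tetramers()
    if not events:
        raise ValueError("empty calibration set")
    seqs: list[str] = []
    for e in events:
        seqs.extend(w.seq for w in calibration_sequences(e, genome))
    pool = PooledScan(seqs, window=window)
    h_min = np.full(len(tetramers), -1, dtype=np.int32)
    cov_at = np.full(len(tetramers), np.nan)
    total = 0
    for i, tet in enumerate(tetramers):
        hist, total = pool.height_histogram(tet.lut())
        curve = _curve_from_hist(hist, total, window)
        hm = select_h_min(curve, target)
        if hm is None:
            logger.warning("tetramer %s absent from calibration sequence; skipped", tet)
            continue
        h_min[i] = hm
        cov_at[i] = curve.coverage[hm - 4]
    return HminTable(tetramers=tetramers, h_min=h_min, coverage_at_h_min=cov_at, total_positions=total)
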