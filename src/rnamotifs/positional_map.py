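"""Nucleotide-resolution RNA splicing maps.

Cluster-instance counts are tallied per map position (four 250-nt windows
around the exon-intron junctions, 1,000 positions in all) for enhanced,
silenced and control exons, with per-position denominators that respect
midpoint truncation of short introns/exons.  A one-tailed Fisher test per
position and exon set is combined across the two sets with Fisher's
method into the enrichment score

    ES(p, t) = -2 * (ln p_enhanced + ln p_silenced),

and the fraction (-ln p_enh) / (-ln p_enh - ln p_sil) attributes each
position's score to the enhanced (1.0, red), silenced (0.0, blue) or both
(0.5, yellow) sets.  Retained tetramers are grouped by a 3-consecutive-
nucleotide alignment rule seeded on the highest cumulative ES, and sorted
within groups by Pearson correlation with the seed's ES profile.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._scan import PooledScan
from .cluster_calling import CLUSTER_WINDOW, HminTable
from .genome_io import REG_CLASSES, ExonEvent, junction_windows
from .motif_space import Tetramer
from .region_enrichment import P_CLAMP, HypergeomTail

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# positional counts
# ---------------------------------------------------------------------------

@dataclass
class JunctionPool:
    """Pooled junction windows of all events, ready for per-tetramer scans."""

    scan: PooledScan
    core_idx: np.ndarray   # big-array index of every available map position
    map_idx: np.ndarray    # its map position (0..n_positions-1)
    ev_class: np.ndarray   # its event's class code
    n_positions: int
    denominators: np.ndarray  # (3, n_positions) events covering each position


def build_junction_pool(
    events: list[ExonEvent],
    genome,
    intronic: int = 200,
    exonic: int = 50,
    context: int = 15,
    window: int = CLUSTER_WINDOW,
) -> JunctionPool:
    n_positions = 4 * (intronic + exonic)
    seqs: list[str] = []
    core_chunks, map_chunks, cls_chunks = [], [], []
    sep_extra = window // 2 + 1  # PooledScan separator length
    pos = 0
    for e in events:
        cls = REG_CLASSES.index(e.reg_class)
        for jw in junction_windows(e, genome, intronic=intronic, exonic=exonic, context=context):
            w = jw.window
            if len(w) == 0:
                continue
            start = pos + w.pad_left
            core_chunks.append(np.arange(start, start + len(w), dtype=np.int64))
            map_chunks.append(jw.map_positions().astype(np.int64))
            cls_chunks.append(np.full(len(w), cls, dtype=np.int8))
            seqs.append(w.seq)
            pos += len(w.seq) + sep_extra
    scan = PooledScan(seqs, window=window)
    core_idx = np.concatenate(core_chunks) if core_chunks else np.empty(0, np.int64)
    map_idx = np.concatenate(map_chunks) if map_chunks else np.empty(0, np.int64)
    ev_class = np.concatenate(cls_chunks) if cls_chunks else np.empty(0, np.int8)
    denom = np.zeros((3, n_positions), dtype=np.int64)
    for c in range(3):
        denom[c] = np.bincount(map_idx[ev_class == c], minlength=n_positions)
    return JunctionPool(
        scan=scan, core_idx=core_idx, map_idx=map_idx, ev_class=ev_class,
        n_positions=n_positions, denominators=denom,
    )


def positional_occurrence(pool: JunctionPool, tet: Tetramer, h_min: int) -> np.ndarray:
    """Cluster-instance counts per (class, map position), shape (3, P)."""
    inst = pool.scan.instances(tet.lut(), h_min)
    hit = inst[pool.core_idx]
    counts = np.zeros((3, pool.n_positions), dtype=np.int64)
    for c in range(3):
        sel = hit & (pool.ev_class == c)
        counts[c] = np.bincount(pool.map_idx[sel], minlength=pool.n_positions)
    return counts


def positional_fisher(
    counts_reg: np.ndarray,
    denom_reg: np.ndarray,
    counts_ctl: np.ndarray,
    denom_ctl: np.ndarray,
    tail: HypergeomTail | None = None,
) -> np.ndarray:
    """One-tailed (greater) p per position; positions with a zero
    denominator in either group get p = 1 (nothing to test)."""
    tail = tail or HypergeomTail()
    p = np.ones(counts_reg.shape, dtype=float)
    # group positions by their (n_reg, n_ctl) so each pair hits one cached table
    pairs = np.stack([denom_reg, denom_ctl], axis=-1)
    uniq, inv = np.unique(pairs.reshape(-1, 2), axis=0, return_inverse=True)
    flat_p = p.reshape(-1)
    kr = counts_reg.reshape(-1)
    kc = counts_ctl.reshape(-1)
    for ui, (nr, nc) in enumerate(uniq):
        if nr <= 0 or nc <= 0:
            continue
        sel = inv == ui
        flat_p[sel] = tail.p_greater(kr[sel], int(nr), kc[sel], int(nc))
    return flat_p.reshape(counts_reg.shape)


# ---------------------------------------------------------------------------
# enrichment score
# ---------------------------------------------------------------------------

def enrichment_score(p_enh, p_sil, clamp: float = P_CLAMP) -> np.ndarray:
    """Fisher's method combination of the two one-sided tests (raw X^2)."""
    pe = np.clip(np.asarray(p_enh, dtype=float), clamp, 1.0)
    ps = np.clip(np.asarray(p_sil, dtype=float), clamp, 1.0)
    return -2.0 * (np.log(pe) + np.log(ps))


def contribution_fraction(p_enh, p_sil, clamp: float = P_CLAMP) -> np.ndarray:
    """Fraction of the ES attributable to the enhanced set (NaN where ES=0)."""
    pe = np.clip(np.asarray(p_enh, dtype=float), clamp, 1.0)
    ps = np.clip(np.asarray(p_sil, dtype=float), clamp, 1.0)
    le, ls = -np.log(pe), -np.log(ps)
    total = le + ls
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, le / np.where(total > 0, total, 1.0), np.nan)
    return frac


@dataclass
class ESMatrix:
    """Positions x tetramers enrichment scores with contribution fractions."""

    tetramers: list[Tetramer]
    es: np.ndarray            # (P, T') >= 0
    contribution: np.ndarray  # (P, T') in [0,1], NaN where es == 0
    p_enh: np.ndarray
    p_sil: np.ndarray

    @property
    def max_es(self) -> np.ndarray:
        return self.es.max(axis=0) if self.es.size else np.zeros(len(self.tetramers))

    @property
    def global_max(self) -> float:
        return float(self.es.max()) if self.es.size else 0.0

    def to_frame(self, intronic: int = 200, exonic: int = 50) -> pd.DataFrame:
        span = intronic + exonic
        P = self.es.shape[0]
        pos = np.arange(P)
        junction = pos // span
        # donor junctions (0, 2) start at -exonic; acceptor (1, 3) at -intronic
        lo = np.where(junction % 2 == 0, -exonic, -intronic)
        df = pd.DataFrame({"position": pos, "junction": junction, "offset": pos % span + lo})
        for i, t in enumerate(self.tetramers):
            df[f"es_{t.pattern}"] = self.es[:, i]
            df[f"frac_{t.pattern}"] = self.contribution[:, i]
        return df


def compute_es_matrix(
    pool: JunctionPool,
    hmin: HminTable,
    tetramer_names: list[str],
) -> ESMatrix:
    """Positional Fisher tests and ES for the selected tetramers."""
    name_to_idx = {t.pattern: i for i, t in enumerate(hmin.tetramers)}
    tail = HypergeomTail()
    tets = []
    es_cols, frac_cols, pe_cols, ps_cols = [], [], [], []
    for name in tetramer_names:
        ti = name_to_idx[name]
        tet = hmin.tetramers[ti]
        hm = int(hmin.h_min[ti])
        counts = positional_occurrence(pool, tet, hm)
        pe = positional_fisher(counts[0], pool.denominators[0], counts[2], pool.denominators[2], tail)
        ps = positional_fisher(counts[1], pool.denominators[1], counts[2], pool.denominators[2], tail)
        tets.append(tet)
        pe_cols.append(pe)
        ps_cols.append(ps)
        es_cols.append(enrichment_score(pe, ps))
        frac_cols.append(contribution_fraction(pe, ps))
    P = pool.n_positions
    stack = lambda cols: np.stack(cols, axis=1) if cols else np.zeros((P, 0))
    return ESMatrix(
        tetramers=tets, es=stack(es_cols), contribution=stack(frac_cols),
        p_enh=stack(pe_cols), p_sil=stack(ps_cols),
    )


# ---------------------------------------------------------------------------
# grouping and sorting
# ---------------------------------------------------------------------------

def _nd_aligned(x: str, y: str) -> bool:
    """True when two ND tetramers share >= 3 consecutive identical
    nucleotides at alignment offsets -1, 0 or +1."""
    eq = [a == b for a, b in zip(x, y)]
    if (eq[0] and eq[1] and eq[2]) or (eq[1] and eq[2] and eq[3]):
        return True
    return x[:3] == y[1:] or x[1:] == y[:3]


def tetramers_aligned(a: Tetramer, b: Tetramer) -> bool:
    """Group-membership alignment; DG motifs need >= 2 of their 4 ND
    expansions aligned."""
    a_hits = sum(any(_nd_aligned(x, y) for y in b.expansion) for x in a.expansion)
    b_hits = sum(any(_nd_aligned(y, x) for x in a.expansion) for y in b.expansion)
    need_a = 2 if a.is_degenerate else 1
    need_b = 2 if b.is_degenerate else 1
    return a_hits >= need_a and b_hits >= need_b


@dataclass
class TetramerGroup:
    seed: Tetramer
    members: list[Tetramer] = field(default_factory=list)  # ordered, seed first
    correlations: list[float] = field(default_factory=list)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def sort_within_group(
    seed: Tetramer, members: list[Tetramer], profiles: dict[str, np.ndarray]
) -> tuple[list[Tetramer], list[float]]:
    """Seed first, then decreasing Pearson correlation with the seed's ES
    profile; undefined correlations (flat profiles) last; ties lexicographic."""
    seed_prof = profiles[seed.pattern]
    scored = []
    for t in members:
        if t.pattern == seed.pattern:
            continue
        r = _pearson(seed_prof, profiles[t.pattern])
        scored.append((t, r))
    scored.sort(key=lambda tr: (-(tr[1] if not np.isnan(tr[1]) else -np.inf), tr[0].pattern))
    ordered = [seed] + [t for t, _ in scored]
    corrs = [1.0] + [r for _, r in scored]
    return ordered, corrs


def group_tetramers(es_matrix: ESMatrix) -> list[TetramerGroup]:
    """Partition retained tetramers into sequence/profile groups.

    Repeatedly seed on the ungrouped tetramer with the highest cumulative
    ES and absorb every ungrouped tetramer passing the alignment rule.
    """
    profiles = {t.pattern: es_matrix.es[:, i] for i, t in enumerate(es_matrix.tetramers)}
    remaining = list(es_matrix.tetramers)
    groups: list[TetramerGroup] = []
    while remaining:
        sums = [profiles[t.pattern].sum() for t in remaining]
        seed = remaining[int(np.argmax(sums))]
        members = [t for t in remaining if t is seed or tetramers_aligned(t, seed)]
        ordered, corrs = sort_within_group(seed, members, profiles)
        groups.append(TetramerGroup(seed=seed, members=ordered, correlations=corrs))
        taken = {t.pattern for t in ordered}
        remaining = [t for t in remaining if t.pattern not in taken]
    return groups


def groups_to_frame(groups: list[TetramerGroup]) -> pd.DataFrame:
    rows = []
    for gi, g in enumerate(groups):
        for rank, (t, r) in enumerate(zip(g.members, g.correlations)):
            rows.append(
                {
                    "group": gi, "rank": rank, "tetramer": t.pattern,
                    "is_seed": rank == 0, "correlation_with_seed": r,
                }
            )
    return pd.DataFrame(rows, columns=["group", "rank", "tetramer", "is_seed", "correlation_with_seed"])
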