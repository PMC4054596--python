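"""Region-level enrichment: occurrence matrices, Fisher tests, FDR, bootstrap.

For every tetramer and region (r1/r2/r3) each event is scored 0/1 for
carrying at least one cluster-instance position inside the region.  A
one-tailed (greater) Fisher's exact test compares the regulated proportion
(enhanced or silenced) against controls; p-values are Benjamini-Hochberg
corrected across the 320 tetramers within each (region, exon-set) stratum;
and a bootstrap achieved significance level

    p_empirical = (1 + #{p_bootstrap < p_fdr}) / (1 + B)

is computed by redoing the whole test (including FDR) on resampled event
sets.  The default resampling scheme draws each group's events with
replacement from the pooled set of all events, which severs the
label-sequence association and makes p_empirical a genuine null quantity;
``scheme="within"`` resamples within each class instead.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import hypergeom

from ._scan import PooledScan
from .cluster_calling import CLUSTER_WINDOW, HminTable
from .genome_io import REG_CLASSES, REGIONS, ExonEvent, region_intervals, splice_site_window
from .motif_space import Tetramer

logger = logging.getLogger(__name__)

#: p-values below this are clamped before taking logs
P_CLAMP = 1e-300


# ---------------------------------------------------------------------------
# Fisher's exact test (one-tailed, greater)
# ---------------------------------------------------------------------------

def fisher_region_test(k_reg: int, n_reg: int, k_ctl: int, n_ctl: int) -> float:
    """One-tailed Fisher's exact test for enrichment in the regulated set.

    Tests whether ``k_reg`` of ``n_reg`` regulated events carrying a cluster
    instance is larger than expected given ``k_ctl`` of ``n_ctl`` controls:
    the upper hypergeometric tail P(X >= k_reg).
    """
    if n_reg <= 0 or n_ctl <= 0:
        raise ValueError("both groups must be non-empty")
    if not (0 <= k_reg <= n_reg and 0 <= k_ctl <= n_ctl):
        raise ValueError("counts must satisfy 0 <= k <= n")
    return float(hypergeom.sf(k_reg - 1, n_reg + n_ctl, k_reg + k_ctl, n_reg))


class HypergeomTail:
    """Cached vectorised upper-tail hypergeometric probabilities.

    For fixed group sizes (n_reg, n_ctl) the one-tailed Fisher p depends
    only on (k_reg, k_reg + k_ctl); a full table over both is built once
    from log-gamma factorials and then read by fancy indexing, which makes
    the bootstrap inner loop ~1000x faster than calling scipy per value.
    """

    def __init__(self):
        self._tables: dict[tuple[int, int], np.ndarray] = {}

    def _build(self, n_reg: int, n_ctl: int) -> np.ndarray:
        M = n_reg + n_ctl
        gl = gammaln(np.arange(M + 2))

        def logC(a, b):
            return gl[a + 1] - gl[b + 1] - gl[a - b + 1]

        k = np.arange(n_reg + 1)[:, None]  # successes drawn in regulated set
        K = np.arange(M + 1)[None, :]      # total successes
        with np.errstate(invalid="ignore"):
            lp = logC(K, np.minimum(k, K)) + logC(M - K, n_reg - k) - logC(M, n_reg)
        valid = (k <= K) & (n_reg - k <= M - K)
        pmf = np.where(valid, np.exp(np.where(valid, lp, -np.inf)), 0.0)
        sf = np.cumsum(pmf[::-1], axis=0)[::-1]  # sf[k, K] = P(X >= k)
        return np.minimum(sf, 1.0)

    def p_greater(self, k_reg: np.ndarray, n_reg: int, k_ctl: np.ndarray, n_ctl: int) -> np.ndarray:
        key = (int(n_reg), int(n_ctl))
        if key not in self._tables:
            self._tables[key] = self._build(*key)
        table = self._tables[key]
        return table[np.asarray(k_reg, dtype=np.intp), np.asarray(k_reg + k_ctl, dtype=np.intp)]


def bh_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment along the last axis."""
    p = np.asarray(p_values, dtype=float)
    m = p.shape[-1]
    order = np.argsort(p, axis=-1, kind="stable")
    ranked = np.take_along_axis(p, order, axis=-1) * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[..., ::-1], axis=-1)[..., ::-1]
    np.minimum(adj, 1.0, out=adj)
    out = np.empty_like(adj)
    np.put_along_axis(out, order, adj, axis=-1)
    return out


# ---------------------------------------------------------------------------
# occurrence matrices
# ---------------------------------------------------------------------------

@dataclass
class RegionOccurrence:
    """Binary cluster-instance indicators per (event, region, tetramer).

    ``O[e, r, t]`` is 1 when event e has at least one instance position of
    tetramer t inside region r; ``valid[e, r]`` is False when the region's
    sequence was unavailable (event excluded from that region's test).
    """

    events: list[ExonEvent]
    tetramers: list[Tetramer]
    O: np.ndarray  # uint8 (n_events, 3, n_tets)
    valid: np.ndarray  # bool (n_events, 3)
    classes: np.ndarray  # int8: 0 enhanced, 1 silenced, 2 control

    def counts(self, class_idx: int) -> tuple[np.ndarray, np.ndarray]:
        """(M, n): instance counts (3, T) and region denominators (3,)."""
        sel = self.classes == class_idx
        M = self.O[sel].sum(axis=0).astype(np.int64)
        n = self.valid[sel].sum(axis=0).astype(np.int64)
        return M, n


def region_occurrence_matrices(
    events: list[ExonEvent],
    genome,
    hmin: HminTable,
    context: int = 15,
    window: int = CLUSTER_WINDOW,
) -> RegionOccurrence:
    """Scan every event's regions for cluster instances of every tetramer.

    Windows carry ``context`` nt of real genomic sequence on each side so a
    cluster straddling the region edge is scored with its full height; an
    instance position must still fall inside the region proper.
    """
    seqs: list[str] = []
    # per event: 4 interval slots (r1, r2a, r2b, r3); dummies point at a
    # separator position so reduceat yields 0 for them.
    n = len(events)
    slot_bounds = np.zeros((n, 4, 2), dtype=np.int64)
    valid = np.zeros((n, 3), dtype=bool)
    pos = 0

    def push(seq_len_before: int):  # big-array position of next window
        return seq_len_before

    sep_extra = window // 2 + 1
    for ei, e in enumerate(events):
        ivals = region_intervals(e)
        slots = [
            ("r1", ivals["r1"][0] if ivals["r1"] else None),
            ("r2", ivals["r2"][0] if ivals["r2"] else None),
            ("r2", ivals["r2"][1] if len(ivals["r2"]) > 1 else None),
            ("r3", ivals["r3"][0] if ivals["r3"] else None),
        ]
        for si, (rid, ival) in enumerate(slots):
            if ival is None:
                slot_bounds[ei, si] = (0, 0)  # pooled seq starts with a window; pos 0 fallback fixed below
                continue
            site, lo, hi, trunc = ival
            w = splice_site_window(genome, e, site, lo, hi, context=context, truncated=trunc)
            start = pos + w.pad_left
            end = start + len(w)
            slot_bounds[ei, si] = (start, end)
            valid[ei, REGIONS.index(rid)] = True
            seqs.append(w.seq)
            pos += len(w.seq) + sep_extra
    pool = PooledScan(seqs, window=window)
    # dummy slots: point at the final separator run (never covered)
    dummy = pool.codes.size - 1 if pool.codes.size else 0
    empty = (slot_bounds[:, :, 0] == 0) & (slot_bounds[:, :, 1] == 0)
    slot_bounds[empty] = (dummy, dummy)
    bounds = slot_bounds.reshape(-1)

    T = len(hmin.tetramers)
    O = np.zeros((n, 3, T), dtype=np.uint8)
    for ti, tet in enumerate(hmin.tetramers):
        hm = hmin.h_min[ti]
        if hm < 0:
            continue
        inst = pool.instances(tet.lut(), hm).view(np.uint8)
        vals = np.add.reduceat(inst.astype(np.int32), bounds)[::2].reshape(n, 4)
        O[:, 0, ti] = vals[:, 0] > 0
        O[:, 1, ti] = (vals[:, 1] + vals[:, 2]) > 0
        O[:, 2, ti] = vals[:, 3] > 0
    O[~valid, :] = 0
    classes = np.array([REG_CLASSES.index(e.reg_class) for e in events], dtype=np.int8)
    n_excluded = int((~valid).sum())
    if n_excluded:
        logger.info("%d (event, region) pairs had no available sequence", n_excluded)
    return RegionOccurrence(events=events, tetramers=hmin.tetramers, O=O, valid=valid, classes=classes)


def region_occurrence(event: ExonEvent, genome, tet: Tetramer, h_min: int, context: int = 15) -> dict[str, int]:
    """Single-event, single-tetramer region indicators (thin wrapper)."""
    hm = HminTable(tetramers=[tet], h_min=np.array([h_min], dtype=np.int32),
                   coverage_at_h_min=np.array([np.nan]))
    occ = region_occurrence_matrices([event], genome, hm, context=context)
    return {r: int(occ.O[0, i, 0]) for i, r in enumerate(REGIONS)}


# ---------------------------------------------------------------------------
# enrichment analysis + bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapConfig:
    n_samples: int = 10000
    seed: int = 0
    scheme: str = "pooled"  # or "within"

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.scheme not in ("pooled", "within"):
            raise ValueError(f"unknown bootstrap scheme {self.scheme!r}")


def _observed_p(occ: RegionOccurrence, tail: HypergeomTail) -> np.ndarray:
    """Raw one-tailed p-values, shape (2 sets, 3 regions, T)."""
    Mc, nc = occ.counts(2)
    T = len(occ.tetramers)
    p = np.ones((2, 3, T))
    for s in (0, 1):
        Ms, ns = occ.counts(s)
        for r in range(3):
            if ns[r] <= 0 or nc[r] <= 0:
                raise ValueError(f"empty exon set for region {REGIONS[r]}")
            p[s, r] = tail.p_greater(Ms[r], int(ns[r]), Mc[r], int(nc[r]))
    return p


def bootstrap_empirical(
    occ: RegionOccurrence,
    p_fdr_observed: np.ndarray,
    cfg: BootstrapConfig,
    tail: HypergeomTail | None = None,
    log_every: int = 1000,
) -> np.ndarray:
    """Bootstrap achieved significance level per (set, region, tetramer).

    Each replicate redraws the three exon sets with replacement (pooled
    across classes by default), recomputes the Fisher p-values and their
    BH correction, and counts replicates whose corrected p falls strictly
    below the observed one.
    """
    tail = tail or HypergeomTail()
    rng = np.random.default_rng(cfg.seed)
    n_events = len(occ.events)
    T = len(occ.tetramers)
    group_idx = [np.flatnonzero(occ.classes == c) for c in range(3)]
    sizes = [idx.size for idx in group_idx]
    # flatten for fast weighted sums: counts = w @ O_flat
    O_flat = occ.O.reshape(n_events, 3 * T).astype(np.float32)
    V_flat = occ.valid.astype(np.float32)
    exceed = np.zeros((2, 3, T), dtype=np.int64)
    B = cfg.n_samples
    for b in range(B):
        ks = []
        ns = []
        for g in range(3):
            if cfg.scheme == "pooled":
                draw = rng.integers(0, n_events, size=sizes[g])
            else:
                draw = group_idx[g][rng.integers(0, sizes[g], size=sizes[g])]
            w = np.bincount(draw, minlength=n_events).astype(np.float32)
            ks.append((w @ O_flat).reshape(3, T))
            ns.append(w @ V_flat)
        p = np.ones((2, 3, T))
        for s in (0, 1):
            for r in range(3):
                n_reg = int(round(ns[s][r]))
                n_ctl = int(round(ns[2][r]))
                if n_reg <= 0 or n_ctl <= 0:
                    continue
                k_reg = np.rint(ks[s][r]).astype(np.int64)
                k_ctl = np.rint(ks[2][r]).astype(np.int64)
                p[s, r] = tail.p_greater(k_reg, n_reg, k_ctl, n_ctl)
        p_fdr_b = bh_correct(p)
        exceed += p_fdr_b < p_fdr_observed
        if log_every and (b + 1) % log_every == 0:
            logger.info("bootstrap %d/%d", b + 1, B)
    return (1.0 + exceed) / (1.0 + B)


def enrichment_analysis(
    occ: RegionOccurrence,
    cfg: BootstrapConfig | None = None,
    fdr_threshold: float = 0.1,
    empirical_threshold: float = 0.0005,
) -> pd.DataFrame:
    """Full region-enrichment table for the enhanced and silenced sets.

    Returns one row per (exon_set, region, tetramer) with the raw p, the
    BH-corrected p_fdr, the bootstrap p_empirical and the retention flag.
    """
    cfg = cfg or BootstrapConfig()
    tail = HypergeomTail()
    p = _observed_p(occ, tail)
    p_fdr = bh_correct(p)
    p_emp = bootstrap_empirical(occ, p_fdr, cfg, tail=tail)
    Mc, nc = occ.counts(2)
    rows = []
    for s, set_name in enumerate(("enhanced", "silenced")):
        Ms, ns = occ.counts(s)
        for r, rid in enumerate(REGIONS):
            for t, tet in enumerate(occ.tetramers):
                rows.append(
                    {
                        "exon_set": set_name,
                        "region": rid,
                        "tetramer": tet.pattern,
                        "k_reg": int(Ms[r, t]),
                        "n_reg": int(ns[r]),
                        "k_ctl": int(Mc[r, t]),
                        "n_ctl": int(nc[r]),
                        "p": p[s, r, t],
                        "p_fdr": p_fdr[s, r, t],
                        "p_empirical": p_emp[s, r, t],
                    }
                )
    df = pd.DataFrame(rows)
    return retain_tetramers(df, fdr_threshold, empirical_threshold)


def retain_tetramers(
    df: pd.DataFrame,
    fdr_threshold: float = 0.1,
    empirical_threshold: float = 0.0005,
) -> pd.DataFrame:
    """Flag tetramers passing both thresholds in >= 1 region of a set.

    Both thresholds must be met within the *same* region.  The flag is
    per (exon_set, tetramer): every row of a retained pair is marked.
    """
    passes = (df["p_fdr"] <= fdr_threshold) & (df["p_empirical"] <= empirical_threshold)
    df = df.copy()
    df["passes"] = passes
    retained_pairs = df.loc[passes, ["exon_set", "tetramer"]].drop_duplicates()
    key = df["exon_set"] + ":" + df["tetramer"]
    retained_key = set(retained_pairs["exon_set"] + ":" + retained_pairs["tetramer"])
    df["retained"] = key.isin(retained_key)
    return df


def retained_tetramer_names(df: pd.DataFrame) -> list[str]:
    """Deterministically ordered union of retained tetramers over both sets."""
    return sorted(df.loc[df["retained"], "tetramer"].unique())


def cooccurrence_test(
    occ: RegionOccurrence,
    tet_a: str,
    region_a: str,
    tet_b: str,
    region_b: str,
    target_set: str = "enhanced",
) -> dict:
    """Fisher test for events carrying BOTH motif clusters vs controls.

    Counts target-set events with an instance of ``tet_a`` in ``region_a``
    AND ``tet_b`` in ``region_b``, against the same double-positive count
    among control events (one-tailed, greater).
    """
    names = [t.pattern for t in occ.tetramers]
    ta, tb = names.index(tet_a.upper()), names.index(tet_b.upper())
    ra, rb = REGIONS.index(region_a), REGIONS.index(region_b)
    both = (occ.O[:, ra, ta] > 0) & (occ.O[:, rb, tb] > 0)
    ok = occ.valid[:, ra] & occ.valid[:, rb]
    s = REG_CLASSES.index(target_set)
    in_set = (occ.classes == s) & ok
    in_ctl = (occ.classes == 2) & ok
    k_reg, n_reg = int(both[in_set].sum()), int(in_set.sum())
    k_ctl, n_ctl = int(both[in_ctl].sum()), int(in_ctl.sum())
    p = fisher_region_test(k_reg, n_reg, k_ctl, n_ctl)
    return {
        "k_reg": k_reg, "n_reg": n_reg, "k_ctl": k_ctl, "n_ctl": n_ctl, "p": p,
        "tet_a": tet_a.upper(), "region_a": region_a,
        "tet_b": tet_b.upper(), "region_b": region_b, "target_set": target_set,
    }
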