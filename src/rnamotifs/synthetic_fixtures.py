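"""Reproducible synthetic genomes + event tables with planted motif clusters.

Each event is laid out on its own stretch of a single chromosome as

    pad | upstream exon | intron | cassette exon | intron | downstream exon | pad

with i.i.d. background nucleotides (optionally a first-order Markov chain
with CpG depletion, to stress-test the h_min calibration against
composition bias).  A multivalent cluster — n_copies tetramer matches with
a fixed spacing <= 15 nt so they merge into one cluster — is planted at a
uniformly chosen offset inside the target region of a configurable
fraction of the target-class events.  Events alternate between the plus
and minus strand so exactly half of them exercise the reverse-complement
coordinate path.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .genome_io import ExonEvent, reverse_complement, write_exon_events
from .motif_space import Tetramer

_BASES = np.array(list("ACGT"))


@dataclass
class FixtureConfig:
    n_enhanced: int = 100
    n_silenced: int = 100
    n_control: int = 2000
    exon_len: int = 100
    intron_len: int = 400
    pad: int = 100
    background_gc: float = 0.45
    markov: bool = False  # first-order background with CpG depletion
    planted_tetramer: str = "YCAY"
    planted_region: str = "r3"
    planted_class: str = "enhanced"
    n_copies: int = 3
    spacing: int = 3
    plant_rate: float = 0.8
    # optional second planted motif (for co-occurrence studies)
    second_tetramer: str | None = None
    second_region: str | None = None
    second_rate: float = 0.0
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.plant_rate <= 1.0:
            raise ValueError("plant_rate must be in [0, 1]")
        if self.spacing > 15:
            raise ValueError("spacing > 15 nt would split the planted cluster")
        if self.planted_region not in ("r1", "r2", "r3"):
            raise ValueError(f"unknown region {self.planted_region!r}")


def _background(rng: np.random.Generator, n: int, gc: float, markov: bool) -> np.ndarray:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    if not markov:
        return rng.choice(4, size=n, p=probs).astype(np.int8)
    # first-order chain: stationary-ish start, CpG transitions suppressed 4x
    trans = np.tile(probs, (4, 1))
    trans[1, 2] /= 4.0  # C -> G
    trans /= trans.sum(axis=1, keepdims=True)
    out = np.empty(n, dtype=np.int8)
    out[0] = rng.choice(4, p=probs)
    cum = np.cumsum(trans, axis=1)
    u = rng.random(n)
    for i in range(1, n):
        out[i] = np.searchsorted(cum[out[i - 1]], u[i])
    return out


def plant_cluster(
    seq: str,
    tetramer: Tetramer | str,
    offset: int,
    n_copies: int,
    spacing: int,
    rng: np.random.Generator | None = None,
) -> str:
    """Write n_copies matches of ``tetramer`` into ``seq`` at ``offset``.

    Copies are separated by ``spacing`` untouched background nucleotides;
    degenerate patterns have an expansion sampled uniformly per copy.
    """
    tet = tetramer if isinstance(tetramer, Tetramer) else Tetramer(tetramer)
    rng = rng or np.random.default_rng()
    span = n_copies * 4 + (n_copies - 1) * spacing
    if offset < 0 or offset + span > len(seq):
        raise ValueError(f"planted span [{offset},{offset + span}) exceeds sequence of {len(seq)} nt")
    chars = list(seq)
    pos = offset
    for _ in range(n_copies):
        nd = tet.expansion[rng.integers(len(tet.expansion))]
        chars[pos : pos + 4] = nd
        pos += 4 + spacing
    return "".join(chars)


def _region_span_in_locus(cfg: FixtureConfig) -> tuple[int, int]:
    """Transcript-local [start, end) of the target region within a locus."""
    E, I, P = cfg.exon_len, cfg.intron_len, cfg.pad
    ce_start = P + E + I
    ce_end = ce_start + E
    if cfg.planted_region == "r1":
        return ce_start - 35, ce_start - 4
    if cfg.planted_region == "r2":
        return ce_start, ce_start + min(E, 62)
    return ce_end + 9, ce_end + 40


def _second_span_in_locus(cfg: FixtureConfig, region: str) -> tuple[int, int]:
    return _region_span_in_locus(replace(cfg, planted_region=region))


def build_dataset(cfg: FixtureConfig) -> tuple[dict[str, str], list[ExonEvent]]:
    """In-memory synthetic dataset: {chrom: sequence} plus validated events."""
    rng = np.random.default_rng(cfg.seed)
    E, I, P = cfg.exon_len, cfg.intron_len, cfg.pad
    L = 2 * P + 3 * E + 2 * I
    classes = (
        ["enhanced"] * cfg.n_enhanced
        + ["silenced"] * cfg.n_silenced
        + ["control"] * cfg.n_control
    )
    span = cfg.n_copies * 4 + (cfg.n_copies - 1) * cfg.spacing
    r_lo, r_hi = _region_span_in_locus(cfg)
    if r_hi - r_lo < span:
        raise ValueError(
            f"planted cluster ({span} nt) does not fit region "
            f"{cfg.planted_region} ({r_hi - r_lo} nt)"
        )
    tet = Tetramer(cfg.planted_tetramer)
    second = Tetramer(cfg.second_tetramer) if cfg.second_tetramer else None
    chunks: list[str] = []
    events: list[ExonEvent] = []
    offset = 0
    for i, reg_class in enumerate(classes):
        locus = "".join(_BASES[_background(rng, L, cfg.background_gc, cfg.markov)])
        if reg_class == cfg.planted_class and rng.random() < cfg.plant_rate:
            start = int(rng.integers(r_lo, r_hi - span + 1))
            locus = plant_cluster(locus, tet, start, cfg.n_copies, cfg.spacing, rng)
            if second is not None and rng.random() < cfg.second_rate:
                s_lo, s_hi = _second_span_in_locus(cfg, cfg.second_region)
                s_span = cfg.n_copies * 4 + (cfg.n_copies - 1) * cfg.spacing
                s_start = int(rng.integers(s_lo, s_hi - s_span + 1))
                locus = plant_cluster(locus, second, s_start, cfg.n_copies, cfg.spacing, rng)
        strand = "+" if i % 2 == 0 else "-"
        chunks.append(locus if strand == "+" else reverse_complement(locus))

        def g(a: int, b: int) -> tuple[int, int]:
            if strand == "+":
                return offset + a, offset + b
            return offset + L - b, offset + L - a

        up = g(P, P + E)
        ce = g(P + E + I, P + E + I + E)
        down = g(P + 2 * E + 2 * I, P + 2 * E + 2 * I + E)
        dirank = {
            "enhanced": float(rng.uniform(1.0, 5.0)),
            "silenced": float(rng.uniform(-5.0, -1.0)),
            "control": float(rng.uniform(-0.1, 0.1)),
        }[reg_class]
        events.append(
            ExonEvent(
                event_id=f"ev{i:05d}", chrom=cfg.chrom, strand=strand,
                ce_start=ce[0], ce_end=ce[1],
                up_exon_start=up[0], up_exon_end=up[1],
                down_exon_start=down[0], down_exon_end=down[1],
                reg_class=reg_class, dirank=round(dirank, 4),
            )
        )
        offset += L
    return {cfg.chrom: "".join(chunks)}, events


def write_fasta(sequences: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def generate_dataset(cfg: FixtureConfig, outdir) -> tuple[Path, Path]:
    """Write genome.fa + events.tsv for ``cfg``; deterministic under seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sequences, events = build_dataset(cfg)
    fasta = outdir / "genome.fa"
    table = outdir / "events.tsv"
    write_fasta(sequences, fasta)
    write_exon_events(events, table)
    return fasta, table
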