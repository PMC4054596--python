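"""Genome FASTA access, cassette-exon event tables and window extraction.

Coordinate conventions
----------------------
* Event tables use BED-style 0-based half-open genomic coordinates.
* Internally every window is transcript-oriented: index increases 5'->3'
  along the transcript, and minus-strand sequence is reverse-complemented.
* Offsets are measured from a splice-site boundary.  Offset 0 is the first
  nucleotide *after* the boundary in transcript direction, offset -1 the
  last nucleotide before it.  E.g. at a cassette exon's 3' splice site,
  offset 0 is the first exonic nucleotide and offset -1 the last intronic
  one.  The classic closed ranges [-35:-5], [1:31], [10:40] (1-based away
  from the boundary) therefore map to offset intervals [-35,-4), [0,31)
  and [9,40), each 31 positions wide.

The three regions of interest around a cassette exon (CE):

* r1 - intronic, 31 nt ending 5 nt upstream of the CE 3' splice site;
* r2 - exonic, the first and last 31 nt of the CE (the whole exon when it
  is shorter than 61 nt; overlapping halves are merged so no position is
  counted twice);
* r3 - intronic, 31 nt starting 10 nt downstream of the CE 5' splice site.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
import numpy as np
import pandas as pd
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

REG_CLASSES = ("enhanced", "silenced", "control")
REGIONS = ("r1", "r2", "r3")

EVENT_COLUMNS = [
    "event_id", "chrom", "strand",
    "ce_start", "ce_end",
    "up_exon_start", "up_exon_end",
    "down_exon_start", "down_exon_end",
    "reg_class", "dirank",
]

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def load_genome(path) -> Fasta:
    """Open an indexed FASTA (the .fai index is created on first use)."""
    return Fasta(str(path), sequence_always_upper=True)


@dataclass(frozen=True)
class ExonEvent:
    """One cassette exon with its flanking exons (the unit of counting).

    ``up``/``down`` are transcript-oriented: on the minus strand the
    upstream exon has *larger* genomic coordinates.
    """

    event_id: str
    chrom: str
    strand: str
    ce_start: int
    ce_end: int
    up_exon_start: int
    up_exon_end: int
    down_exon_start: int
    down_exon_end: int
    reg_class: str
    dirank: float | None = None

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.event_id}: strand must be + or -")
        if self.reg_class not in REG_CLASSES:
            raise ValueError(f"{self.event_id}: unknown reg_class {self.reg_class!r}")
        for a, b, name in (
            (self.ce_start, self.ce_end, "cassette exon"),
            (self.up_exon_start, self.up_exon_end, "upstream exon"),
            (self.down_exon_start, self.down_exon_end, "downstream exon"),
        ):
            if not a < b:
                raise ValueError(f"{self.event_id}: {name} has non-positive length")
        if self.up_intron_len <= 0 or self.down_intron_len <= 0:
            raise ValueError(
                f"{self.event_id}: introns must have positive length "
                "(flanking exons must lie 5'/3' of the CE in transcript orientation)"
            )

    # -- transcript-oriented geometry ------------------------------------
    @property
    def ce_len(self) -> int:
        return self.ce_end - self.ce_start

    @property
    def up_exon_len(self) -> int:
        return self.up_exon_end - self.up_exon_start

    @property
    def down_exon_len(self) -> int:
        return self.down_exon_end - self.down_exon_start

    @property
    def up_intron_len(self) -> int:
        if self.strand == "+":
            return self.ce_start - self.up_exon_end
        return self.up_exon_start - self.ce_end

    @property
    def down_intron_len(self) -> int:
        if self.strand == "+":
            return self.down_exon_start - self.ce_end
        return self.ce_start - self.down_exon_end

    def anchor(self, site: str) -> int:
        """Genomic anchor A of a splice-site boundary.

        Transcript offset o maps to genomic position A+o on '+' and A-o
        on '-'.  Sites: up3ss/up5ss (upstream exon), ce3ss/ce5ss (CE),
        down3ss/down5ss (downstream exon).
        """
        plus = {
            "up3ss": self.up_exon_start, "up5ss": self.up_exon_end,
            "ce3ss": self.ce_start, "ce5ss": self.ce_end,
            "down3ss": self.down_exon_start, "down5ss": self.down_exon_end,
        }
        minus = {
            "up3ss": self.up_exon_end - 1, "up5ss": self.up_exon_start - 1,
            "ce3ss": self.ce_end - 1, "ce5ss": self.ce_start - 1,
            "down3ss": self.down_exon_end - 1, "down5ss": self.down_exon_start - 1,
        }
        table = plus if self.strand == "+" else minus
        if site not in table:
            raise KeyError(f"unknown splice site {site!r}")
        return table[site]


@dataclass
class SequenceWindow:
    """A transcript-oriented sequence window anchored at a splice site.

    ``seq`` may carry ``pad_left``/``pad_right`` nt of genomic context on
    either side of the core window; ``offsets`` covers the core only.
    """

    seq: str
    chrom: str
    strand: str
    anchor: str
    offsets: np.ndarray
    pad_left: int = 0
    pad_right: int = 0
    truncated: bool = False

    def __post_init__(self):
        assert len(self.seq) == self.pad_left + self.offsets.size + self.pad_right

    @property
    def core_seq(self) -> str:
        return self.seq[self.pad_left : len(self.seq) - self.pad_right]

    def __len__(self) -> int:
        return self.offsets.size


# ---------------------------------------------------------------------------
# event tables
# ---------------------------------------------------------------------------

def load_exon_events(path) -> list[ExonEvent]:
    """Read a tab-separated event table; reject rows violating invariants.

    Any malformed row is reported with its file line number (header = line 1)
    and the whole load fails, so silent partial inputs cannot slip through.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "event_id": str})
    missing = [c for c in EVENT_COLUMNS if c != "dirank" and c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if "dirank" not in df.columns:
        df["dirank"] = np.nan
    events: list[ExonEvent] = []
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        try:
            coords = {
                c: int(getattr(row, c))
                for c in EVENT_COLUMNS
                if c.endswith(("start", "end"))
            }
        except (TypeError, ValueError):
            errors.append(f"line {line}: malformed coordinates")
            continue
        dirank = float(row.dirank) if pd.notna(row.dirank) else None
        try:
            events.append(
                ExonEvent(
                    event_id=str(row.event_id), chrom=str(row.chrom),
                    strand=str(row.strand), reg_class=str(row.reg_class),
                    dirank=dirank, **coords,
                )
            )
        except ValueError as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise ValueError(f"{path}: invalid event rows:\n" + "\n".join(errors))
    counts = Counter(e.reg_class for e in events)
    logger.info(
        "loaded %d events (%s)", len(events),
        ", ".join(f"{k}:{counts.get(k, 0)}" for k in REG_CLASSES),
    )
    return events


def write_exon_events(events: list[ExonEvent], path) -> None:
    rows = []
    for e in events:
        rows.append({c: getattr(e, c) for c in EVENT_COLUMNS})
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    df["dirank"] = df["dirank"].astype(float)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# window extraction
# ---------------------------------------------------------------------------

_CLEAN = str.maketrans(
    {chr(i): ("ACGT"[("ACGT".find(chr(i).upper()))] if chr(i).upper() in "ACGT" else "N")
     for i in range(256)}
)


def _clean(seq: str) -> str:
    return seq.translate(_CLEAN)


def _fetch(genome: Fasta, chrom: str, start: int, end: int) -> str:
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} not in FASTA")
    return _clean(str(genome[chrom][start:end]))


def extract_window(genome: Fasta, chrom: str, start: int, end: int, strand: str) -> SequenceWindow:
    """Extract [start, end) on ``strand``; minus strand is reverse-complemented."""
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} not in FASTA")
    clen = len(genome[chrom])
    if not (0 <= start < end <= clen):
        raise ValueError(f"interval [{start},{end}) out of range for {chrom} (len {clen})")
    seq = _fetch(genome, chrom, start, end)
    if strand == "-":
        seq = reverse_complement(seq)
    return SequenceWindow(
        seq=seq, chrom=chrom, strand=strand, anchor="",
        offsets=np.arange(end - start),
    )


def splice_site_window(
    genome: Fasta,
    event: ExonEvent,
    site: str,
    lo: int,
    hi: int,
    context: int = 0,
    truncated: bool = False,
) -> SequenceWindow:
    """Window of transcript offsets [lo, hi) around a splice site.

    ``context`` nt of genomic sequence are appended on each side (clamped
    at chromosome ends) for cluster-height computation; they are excluded
    from ``offsets``.
    """
    A = event.anchor(site)
    clen = len(genome[event.chrom])
    if event.strand == "+":
        gs, ge = A + lo, A + hi
    else:
        gs, ge = A - hi + 1, A - lo + 1
    if gs < 0 or ge > clen:
        raise ValueError(
            f"{event.event_id}: window [{lo},{hi}) at {site} leaves chromosome bounds"
        )
    if event.strand == "+":
        pl = min(context, gs)
        pr = min(context, clen - ge)
        seq = _fetch(genome, event.chrom, gs - pl, ge + pr)
    else:
        pl = min(context, clen - ge)  # transcript-left pad is genomic-right
        pr = min(context, gs)
        seq = reverse_complement(_fetch(genome, event.chrom, gs - pr, ge + pl))
    return SequenceWindow(
        seq=seq, chrom=event.chrom, strand=event.strand, anchor=site,
        offsets=np.arange(lo, hi), pad_left=pl, pad_right=pr, truncated=truncated,
    )


def region_intervals(event: ExonEvent) -> dict[str, list[tuple[str, int, int, bool]]]:
    """Offset intervals (site, lo, hi, truncated) for regions r1/r2/r3.

    Intervals shortened by a too-short intron are flagged truncated; fully
    unavailable regions come back as empty lists.
    """
    out: dict[str, list[tuple[str, int, int, bool]]] = {"r1": [], "r2": [], "r3": []}
    # r1: intronic offsets [-35, -4) upstream of the CE 3'ss
    i1 = event.up_intron_len
    lo = max(-35, -i1)
    if lo < -4:
        out["r1"].append(("ce3ss", lo, -4, lo != -35))
    # r3: intronic offsets [9, 40) downstream of the CE 5'ss
    i2 = event.down_intron_len
    hi = min(40, i2)
    if hi > 9:
        out["r3"].append(("ce5ss", 9, hi, hi != 40))
    # r2: first/last 31 exonic nt, whole exon when shorter than 61 nt
    e = event.ce_len
    if e < 61 or e - 31 < 31:  # halves overlap up to e=61; merged union = whole exon
        out["r2"].append(("ce3ss", 0, min(e, 62), False))
    else:
        out["r2"].append(("ce3ss", 0, 31, False))
        out["r2"].append(("ce5ss", -31, 0, False))
    return out


def region_sequences(
    event: ExonEvent, genome: Fasta, context: int = 0
) -> dict[str, list[SequenceWindow]]:
    """Sequence windows of the three regions of interest, transcript-oriented."""
    return {
        rid: [
            splice_site_window(genome, event, site, lo, hi, context=context, truncated=trunc)
            for site, lo, hi, trunc in ivals
        ]
        for rid, ivals in region_intervals(event).items()
    }


@dataclass
class JunctionWindow:
    """One of the four splicing-map windows around an exon-intron junction.

    ``lo``/``hi`` give the nominal offset range (always ``intronic + exonic``
    positions); ``window.offsets`` holds the available subrange, truncated at
    the intron/exon midpoints.  The map position of offset o is
    ``junction * (intronic + exonic) + (o - lo)``.
    """

    junction: int
    site: str
    lo: int
    hi: int
    window: SequenceWindow

    def map_positions(self) -> np.ndarray:
        span = self.hi - self.lo
        return self.junction * span + (self.window.offsets - self.lo)


def junction_windows(
    event: ExonEvent,
    genome: Fasta,
    intronic: int = 200,
    exonic: int = 50,
    context: int = 0,
) -> list[JunctionWindow]:
    """The four 250-nt splicing-map windows (1,000 nominal positions).

    Anchors: upstream exon 5'ss, CE 3'ss, CE 5'ss, downstream exon 3'ss.
    Positions beyond the midpoint of a short intron/exon are unavailable
    (they simply fall outside ``window.offsets``).
    """
    i1, i2 = event.up_intron_len, event.down_intron_len
    eu, ec, ed = event.up_exon_len, event.ce_len, event.down_exon_len
    specs = [
        # (site, exon-side avail, intron-side avail, donor?)
        ("up5ss", min(exonic, eu // 2), min(intronic, i1 // 2), True),
        ("ce3ss", min(exonic, ec // 2), min(intronic, i1 // 2), False),
        ("ce5ss", min(exonic, ec // 2), min(intronic, i2 // 2), True),
        ("down3ss", min(exonic, ed // 2), min(intronic, i2 // 2), False),
    ]
    out = []
    for j, (site, ex_av, in_av, donor) in enumerate(specs):
        if donor:  # exon then intron in transcript direction
            lo, hi = -exonic, intronic
            clo, chi = -ex_av, in_av
        else:  # intron then exon
            lo, hi = -intronic, exonic
            clo, chi = -in_av, ex_av
        trunc = (chi - clo) < (hi - lo)
        w = splice_site_window(genome, event, site, clo, chi, context=context, truncated=trunc)
        out.append(JunctionWindow(junction=j, site=site, lo=lo, hi=hi, window=w))
    return out


def calibration_sequences(event: ExonEvent, genome: Fasta) -> list[SequenceWindow]:
    """Windows pooled for h_min calibration: up to 500 nt of intron and
    100 nt of exon next to each splice site of the CE and its flanking
    exons, truncated at intron/exon midpoints.  Only sequence within the
    event span is used (the extents of the neighbouring introns beyond the
    flanking exons are unknown from the event table).
    """
    i1 = min(500, event.up_intron_len // 2)
    i2 = min(500, event.down_intron_len // 2)
    eu = min(100, event.up_exon_len // 2)
    ec = min(100, event.ce_len // 2)
    ed = min(100, event.down_exon_len // 2)
    specs = [
        ("up3ss", 0, eu), ("up5ss", -eu, 0),          # upstream exon ends
        ("up5ss", 0, i1), ("ce3ss", -i1, 0),          # upstream intron ends
        ("ce3ss", 0, ec), ("ce5ss", -ec, 0),          # cassette exon ends
        ("ce5ss", 0, i2), ("down3ss", -i2, 0),        # downstream intron ends
        ("down3ss", 0, ed), ("down5ss", -ed, 0),      # downstream exon ends
    ]
    return [
        splice_site_window(genome, event, site, lo, hi)
        for site, lo, hi in specs
        if hi > lo
    ]
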