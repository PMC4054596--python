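# Methods

## The problem

RNA-binding proteins (RBPs) that regulate alternative splicing mostly
recognise motifs of only 3–4 nucleotides, and achieve specific,
high-affinity binding through *multivalency*: several short motifs
clustered within a few nucleotides of each other on the pre-mRNA.
Consequently, single continuous motifs are weak predictors of regulation,
but clusters of short motifs at specific positions relative to a
regulated cassette exon (CE) are highly informative.  `rnamotifs`
identifies, de novo, the tetramers whose clusters are positionally
enriched around enhanced versus silenced cassette exons relative to
unregulated control exons, and renders the result as a
nucleotide-resolution RNA splicing map.

Inputs are a genome FASTA and a table of cassette-exon events (CE plus
both flanking exons, strand, and a regulation label in
{enhanced, silenced, control}, typically derived from a differential
splicing statistic such as dIRank with cutoffs > 1 / < −1 / |·| < 0.1).
The package does not compute that statistic and does not fetch
annotation; coordinates are supplied as BED-dialect (0-based half-open)
columns.

## Motif space

The search space is the 256 non-degenerate (ND) tetramers over
{A,C,G,T} plus 64 degenerate (DG) tetramers whose two central positions
are ND while the two boundary positions are purine R = A/G or pyrimidine
Y = C/T (e.g. YCAY = {TCAT, TCAC, CCAT, CCAC}), 320 patterns in all.
Matching allows overlaps, is case-insensitive, and never matches across
an N.  All 320 patterns are tested as distinct hypotheses even though DG
expansions overlap ND patterns; the multiple-testing correction is over
the full set of 320.

## Cluster calling

For one tetramer and one sequence window:

1. *Tetramer nucleotides* — every position overlapped by ≥ 1 match.
2. *Cluster height* h(p) — the number of tetramer nucleotides within the
   31-nt window centred on p, computed only at tetramer nucleotides, so
   4 ≤ h ≤ 31.  At sequence ends the window truncates (no padding).
3. *Cluster instance* — a position with h ≥ h_min.

h_min is calibrated per tetramer: over the pooled flanking sequence of
*all* monitored events (all three classes) — up to 500 nt of intron and
100 nt of exon adjacent to each splice site of the CE and its flanking
exons, truncated at intron/exon midpoints — we tabulate the *coverage
percentage* (fraction of pooled positions with h ≥ candidate, ×100) and
select the smallest h whose coverage is closest to a 0.5% target (ties
go to the smaller h).  This equalises the background instance
probability across common and rare tetramers; h_min is data-dependent
and recomputed per dataset (it is logged, not a constant).  Tetramers
absent from the calibration pool are skipped with a warning.  The
calibration pool deliberately stops at the outer edges of the flanking
exons because the event table does not say how far the neighbouring
introns extend.

When clusters are scored inside a *region* (below), the scanned window
carries 15 nt of real genomic context beyond each region edge so that a
cluster straddling the boundary receives its full height; the instance
position itself must still fall inside the region.

## Region enrichment

Three regions around each CE (offset 0 = first nucleotide after a splice
site boundary in transcript direction):

* r1: intronic offsets [−35, −5] upstream of the CE 3'ss (31 nt);
* r2: exonic — first and last 31 nt of the CE; the whole exon when it is
  shorter than 61 nt; overlapping halves are merged so |r2| =
  min(exon length, 62) and no position is double-counted;
* r3: intronic offsets [+10, +40] downstream of the CE 5'ss (31 nt).

Each (event, region, tetramer) is scored 0/1 for containing ≥ 1 instance
position.  Regions with no available sequence (e.g. an intron shorter
than the region) exclude the event from numerator and denominator for
that region only.  Enrichment of the enhanced (and, separately,
silenced) set against controls is a one-tailed Fisher's exact test —
the upper hypergeometric tail, "regulated proportion greater" — and
p-values are Benjamini–Hochberg corrected across the 320 tetramers
within each (region, exon-set) stratum.

The achieved significance level is estimated by bootstrap:

    p_empirical = (1 + #{ b : p_fdr,b < p_fdr,observed }) / (1 + B)

where each replicate redraws the three groups with replacement and
repeats the entire procedure including the BH step.  The default scheme
draws each group from the *pooled* set of all events, severing the
label–sequence association so that p_empirical measures how often a
null sample produces a corrected p at least as extreme.  A within-group
resample (`scheme="within"`) is available as an alternative reading of
the procedure, but it preserves the effect being tested and therefore
cannot produce small p_empirical for true signals; the pooled scheme is
the default for that reason.  The comparison in the counter is strict
(<) per the formula.

A tetramer is retained, separately for enhanced- and silenced-derived
evidence, when some region passes both thresholds *in the same region*:
p_fdr ≤ 0.1 and p_empirical ≤ 0.0005 (both configurable).  Note the
empirical threshold is only attainable when B ≥ 2,000
(min p_empirical = 1/(B+1)); the production default is B = 10,000,
while tests and the acceptance script use B = 2,000 — the smallest
size at which retention is possible — to keep run times at desk scale.

Two-motif co-occurrence (e.g. a YCAY cluster in r3 AND a TCTC cluster in
r1 of the same event) is tested with the same one-tailed Fisher test on
the double-positive counts in the target set versus controls.

## RNA splicing map

Four windows of 200 intronic + 50 exonic nt are anchored at the
upstream-exon 5'ss, CE 3'ss, CE 5'ss and downstream-exon 3'ss — 1,000
map positions.  Introns shorter than 400 nt and exons shorter than
100 nt contribute positions only up to their midpoint; masked positions
drop out of both the numerator and the per-position denominator.  For
each retained tetramer, instance counts per position are tested
(one-tailed, greater, per position — chosen for consistency with the
region test) for enhanced-vs-control and silenced-vs-control, and the
two p-values are combined by Fisher's method into the enrichment score

    ES(p) = −2 (ln p_enh + ln p_sil)

reported raw (no chi-square renormalisation), with natural logarithms
and p clamped at 1e-300 before the log to avoid infinities while
preserving ranking.  The fraction (−ln p_enh)/(−ln p_enh − ln p_sil)
colours each position: 1 = purely enhanced (red), 0 = purely silenced
(blue), 0.5 = both (yellow); it is undefined (uncoloured) where ES = 0.
No smoothing and no position-level multiple-testing correction are
applied; selection happens at the region level only.

Retained tetramers are grouped: the ungrouped tetramer with the highest
cumulative ES seeds a group; another tetramer joins when it aligns with
the seed — shares ≥ 3 consecutive identical nucleotides at alignment
offsets −1, 0 or +1 (the only offsets at which two 4-mers can overlap in
3 positions) — with DG motifs compared through their four ND expansions
and required to align with ≥ 2 of them.  The procedure recurses on the
remainder until all tetramers are grouped.  Within a group, members are
sorted by decreasing Pearson correlation of their ES profile with the
seed's; zero-variance profiles (undefined correlation) sort last, ties
break lexicographically.  The rendered map normalises ES to the global
maximum of the matrix and shows at most the 10 tetramers with the
highest per-tetramer maximum ES.

## Synthetic data generator

`synthetic_fixtures` emulates the statistical structure the method
assumes so the whole pipeline is testable without external data.  Each
event occupies its own locus (pad 100 | exon | intron | CE | intron |
exon | pad 100) of i.i.d. background nucleotides; defaults are
100 enhanced / 100 silenced / 2,000 control events, 100-nt exons,
400-nt introns (giving exactly full 200-nt intronic map windows) and
GC = 0.45, a typical intergenic/intronic composition.  A planted
cluster — by default 3 YCAY matches spaced 3 nt apart, one merged
cluster well above background height — is inserted at a uniform offset
inside r3 of 80% of enhanced events; controls get background only.
Events alternate strands so exactly half exercise the
reverse-complement path.  An optional first-order Markov background with
CpG depletion stress-tests the calibration against composition bias.
A second motif/region/rate can be planted for co-occurrence studies.

What the generator does *not* emulate: real splice-site consensus
sequences, composition differences between exons and introns,
length distributions, repeat structure, or correlated motif content
between neighbouring events.  Passing the recovery and null tests
therefore demonstrates the statistical machinery (calibration,
counting, testing, bootstrap) under the model's assumptions, not
performance on real genomes.

## Numerical choices and problem sizes

* Fisher tails are computed from cached log-gamma survival tables keyed
  by the (n_regulated, n_control) pair, exact to ~1e-9 relative against
  scipy's `hypergeom.sf` (cross-checked in tests); the scalar API uses
  scipy directly.  This makes the 10,000-replicate bootstrap tractable.
* BH is the standard step-up, vectorised along the last axis and
  cross-checked against statsmodels.
* All randomness flows through `numpy.random.default_rng(seed)`:
  identical seeds give byte-identical tables.
* Test/acceptance problem sizes are chosen as desk-scale versions of the
  study conditions: the planted-recovery dataset uses the full
  100/100/2,000 geometry with B = 2,000; the null calibration uses 20
  seeds of 100/100/2,000 events with 200-nt introns and 80-nt exons.

## Known limitations

* The per-position Fisher tests treat positions independently; spatial
  correlation of clusters (a single cluster spans many positions) means
  neighbouring map positions are not independent tests.  The map is a
  visualisation, not a site-level significance statement.
* The pooled bootstrap treats the three group sizes as fixed; it does
  not model uncertainty in the class assignment itself.
* With B = 1,000 or fewer bootstrap replicates the default empirical
  threshold (0.0005) is unattainable and nothing can be retained;
  configure the threshold or B accordingly.
* Calibration and region scanning share h_min but differ slightly at
  window edges (calibration windows truncate; region windows carry 15 nt
  of context), a negligible but nonzero asymmetry.
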