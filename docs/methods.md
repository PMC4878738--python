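# Methods

## Coordinate model and distance convention

All intervals are 0-based half-open `[start, end)`, BED-native; printed
output is BED. Overlap requires at least `min_bp` shared bases (default 1,
the BEDTools-intersect convention) everywhere a "common", "shared" or
"co-occupied" call is made; the threshold is a parameter because published
interval comparisons rarely state one.

Proximity ("within 1 kb") uses the coordinate gap: for two intervals
`max(0, b.start − a.end, a.start − b.end)`, for an interval and a point
`max(0, start − p, p − end)`. Overlapping *and* abutting features are at
distance 0. One consequence worth knowing: `within_distance(d=0)` accepts
abutting interval pairs that a 1-bp overlap test rejects; for the point
anchors used in boundary marking and TSS linkage the two conventions do not
diverge.

## Peak classification

Co-occupancy labels each A-peak by whether it overlaps ≥ 1 B-peak, counting
each peak once however many partners it overlaps; because one A-peak can
span two B-peaks, `n_both(A,B) ≠ n_both(B,A)` in general and both directions
are reported. Cross-cell classification counts, per target peak, how many of
K reference sets contain an overlapping interval: K ⇒ invariant, 0 ⇒
specific, else intermediate; the three classes partition the target set
exactly. Peak filtering applies strict inequalities (fold enrichment
strictly above the cutoff, p strictly below), matching how peak-caller
thresholds are normally quoted; a peak lacking a recorded p-value fails the
p filter when one is requested.

Printed percents are round-half-away-from-zero integers of
`100 × common / total`; raw values are always carried alongside. Where a
published table is ambiguous about its denominator (the shared-site count
between two cell types can be divided by either set's total), both
denominators are computed and labelled rather than guessing.

## Genome bins

Six assignable bins partition the non-gap genome by fixed precedence —
promoter (±1 kb of TSS) ▸ downstream (±1 kb of TES) ▸ genic (TSS→TES body) ▸
5′ distal (1–50 kb upstream) ▸ 3′ distal (1–50 kb downstream) ▸ intergenic —
with assembly gaps held in a seventh `unassigned_gap` bin. Overlapping gene
models are resolved by bin precedence, not gene identity. The partition is
computed by cut-point sweep and verified against a per-base bitmap oracle on
toy chromosomes; totality is also asserted by length bookkeeping
(Σ bin lengths = genome length). Peaks enter exactly one bin through a
single representative point (summit when present, else midpoint), so
fractions sum to 1 and can be compared to genome composition as an
enrichment ratio.

## Repressive domains and boundaries

The domain rule is filter → merge → filter: windows with fold enrichment
> 3 (strict), transitive merging of survivors ≤ 2000 bases apart (the
BEDTools-merge reading: chains of windows each within the gap form one
domain), then strict retention of merged regions > 2000 bases. Raising the
fold cutoff can *split* a domain into several retained pieces, so domain
count is not monotone in that threshold; the retained genomic extent is, and
that is the invariant the tests assert. Genome fraction divides total domain
length by the gap-inclusive assembly length by default (this denominator
reproduces the usual published shares; the non-gap denominator is a flag).
The hg19 total assembly length is carried as the constant 3,137,161,264 bp.

Each domain yields a left and a right boundary coordinate. A peak within
1 kb of a boundary marks it; a peak sitting between two short domains marks
two boundaries but counts once in the unique-peak tally, so both the
per-peak and per-boundary tallies are emitted. Boundary co-localization is
the fraction of one factor's marking peaks that overlap the other factor's
marking peaks.

## Randomization null

Intervals are re-placed independently and uniformly among *all* positions in
the gap-masked genome that fully contain them: placement is drawn by
indexing uniformly into the concatenation of every non-gap segment's valid
start range, so each segment is chosen with probability exactly proportional
to `max(0, segment_length − interval_length + 1)` and chromosome assignment
follows capacity. Mutual overlap among placed intervals is allowed (no
exclusion constraint is imposed). Per-chromosome restriction is available as
an option but genome-wide replacement is the default.

The empirical p-value uses the add-one rule
`p = (1 + #{null ≥ observed}) / (1 + n_iterations)` (≥ for enrichment, ≤ for
depletion; both are reported), which can never reach zero — at 1000
iterations the attainable floor is 1/1001 ≈ 0.000999. For speed the
statistic (A-intervals overlapping / within d of B) is computed against the
merged cover of B, which is exact for existence-of-overlap statistics.
Calibration is checked by testing null-generated A sets: the resulting
p-values are uniform up to the conservatism induced by the discreteness of
the count statistic and the add-one correction, which is why the
calibration test uses a Kolmogorov–Smirnov test at α = 0.001 and interval
sets large enough that the statistic takes many values.

## Expression rules

Counts are normalized to CPM against library sizes (column sums by
default). Detection keeps genes with median CPM strictly > 1 across samples;
filtering keeps genes with CPM > 1 in ≥ 3 samples; differential
classification computes `(mean CPM_B + 0.5) / (mean CPM_A + 0.5)` and calls
up/down outside the 2-fold band. The pseudocount of 0.5 guards zero means;
the fold-change rule is deliberately a plain arithmetic rule rather than a
count-model test — it implements the stated cutoff, not a dispersion
estimate. Genes are linked to peaks whose edge lies within 1 kb of the TSS;
a gene linked to several classes takes the most specific label
(cell-type-specific ▸ invariant ▸ other) while all linked classes remain
listed. "Expression level" for class comparisons is log2(mean CPM + 1) of
the designated sample group, compared across classes with a two-sided
Mann–Whitney U test (tie-corrected; exact agreement with exhaustive
permutation is verified on small inputs). Classes with fewer than two genes
are skipped with a note.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *statistical structure* the pipeline consumes,
with defaults fixed at the study conditions:

| parameter | default | rationale |
|---|---|---|
| co-occupancy fraction | 0.54 | fraction of CTCF peaks with an overlapping cohesin peak in erythroid-like maps |
| invariant / specific fractions | 0.30 / 0.40 | mid-range of reported cross-cell sharing, K = 7 references |
| peak length | log-normal, median 300 bp, σ = 0.3 | typical CTCF peak width |
| peak density | ~1 per 60–80 kb | matches ~50k peaks per 3.1 Gb genome |
| window size | 200 bp | SICER-style window grid |
| domain length | log-normal, median 8.3 kb, σ = 0.5 | reported mean domain scale |
| domain fold | 3.05 + Gamma(4), mean 5 | enriched windows always exceed the >3 cutoff, so planted edges are recoverable to one window |
| background fold | log-normal(0, 0.3) | ~30% CV window noise; false >3 windows ≈ 10⁻⁴ per window |
| boundary peak rate | 0.20 | ≈ 4800 marking sites per ~23k boundaries |
| boundary jitter | N(0, 250 bp), truncated ±500 bp | planted sites sit within the 1 kb rule |
| gap fraction | 0.05 | order of assembly-gap share |
| NB dispersion | 0.25 | typical bulk RNA-seq gene-level dispersion |
| base abundance | log-normal, ln-σ = 0.5 | moderate spread of detected transcripts within a class, so planted class effects dominate between-gene nuisance variance at the tested sample sizes |
| class shifts | specific +2 log2, in-domain −2 log2 | planted effect sizes the comparison stages must recover |

Planted domains are separated by > 2× the merge gap so they cannot fuse;
reference peak sets contain only the planted responses (no independent
background peaks), so cross-cell misclassification arises only from
accidental overlap at realistic density (~1% per reference). The generators
do **not** emulate read-level noise, fragment-size effects, copy-number or
mappability artifacts, peak-caller boundary uncertainty, correlated
replicate structure, or isoform-level expression — passing recovery tests
therefore demonstrates correctness of the interval and statistical logic,
not robustness to upstream calling errors in real data.

`dispersion = 0` short-circuits count sampling entirely (counts equal their
means), giving the deterministic limit used in exactness tests. All
generators take a seed and are bit-reproducible; `run_all` derives every
stage's stream from the single config seed by fixed offsets.

## Problem sizes and numerical choices

Recovery analyses run at: 5000 peaks on a 300 Mb / 4-chromosome genome
(co-occupancy and sharing, matching real peak density), ~1350 planted
domains on a 200 Mb / 8-chromosome genome (~2700 boundaries for the marking
rate), 1000 genes with 3 samples per group (expression shift), and 200
replicate tests × 200 iterations on a 5 Mb genome (null calibration).
Oracle-equivalence checks use ≤ 10⁵-bp chromosomes where per-base bitmaps
are exact and cheap.

Ties in ranks use midranks (scipy's tie correction); merge is a single
sorted sweep and is idempotent; degenerate inputs (empty peak sets, empty
domain lists, single-class comparisons, zero-length anchors) return explicit
empty/absent results rather than NaN arithmetic. Empirical p-values are
never 0 or exactly reported below their attainable floor.

## Known limitations

- Strand is ignored for all peak operations; gene strand is used only to
  orient TSS/TES and the distal bins.
- The published seven-bin genome partition names only five bins plus the
  TSS/TES definitions; this package implements six assignable bins plus a
  gap bin and treats the inventory as configuration rather than guessing a
  seventh feature class.
- The randomization null is length-preserving and position-uniform only; it
  is not GC-, annotation- or chromosome-matched.
- Fold-change classification is not a replacement for a count-model
  differential test; it implements a cutoff rule.
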