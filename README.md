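# chrombound

Interval-level analysis of transcription-factor occupancy and repressive
chromatin, built around the questions that arise when CTCF and
cohesin<sup>SA-1</sup> ChIP-seq maps are compared across hematopoietic cell
types: which peaks are co-occupied by both factors, which binding sites are
cell-type specific versus invariant across a panel of reference cell types,
where H3K27me3 repressive domains lie and whether CTCF/cohesin sites mark
their boundaries, and how all of these classes relate to gene expression.

It is aimed at genomicists working from called peaks (MACS narrowPeak,
SICER-style enriched windows, BED) and count tables, not raw reads.

## What it computes

All coordinates are 0-based half-open BED intervals.

- **Co-occupancy** — a peak of factor A is *co-occupied* when it overlaps
  (≥ `min_bp`, default 1 bp) at least one peak of factor B; each peak counts
  once. Counts are reported in both directions since they need not agree.
- **Cross-cell classification** — against K reference peak sets, a site with
  overlap in all K is *invariant*, in none *specific*, otherwise
  *intermediate*; shares are reported as raw and integer-rounded percents
  (common/total × 100, halves away from zero).
- **Genome bins** — each non-gap base is assigned by precedence
  promoter ▸ downstream ▸ genic ▸ 5′ distal ▸ 3′ distal ▸ intergenic, with
  promoter/downstream = ±1 kb of TSS/TES and distal = 1–50 kb; peak
  distributions (by summit or midpoint) are compared to genome composition.
- **Repressive domains** — SICER-style windows with fold enrichment > 3 are
  merged when ≤ 2000 bases apart and merged regions > 2000 bases long are
  kept; domain count, mean length and genome fraction are reported.
- **Boundary marking** — every domain contributes a left and right boundary;
  a binding site within 1 kb of a boundary coordinate marks it (overlap =
  distance 0). Tallies are kept per unique peak and per boundary.
- **Randomization null** — intervals are re-placed uniformly at random in
  the gap-masked genome (lengths preserved, chromosome free to change) and a
  co-localization statistic is recomputed for `n` iterations; the empirical
  p-value is the add-one form `(1 + #{null ≥ obs}) / (1 + n)`, whose floor
  at 1000 iterations is 1/1001 (< 0.001).
- **Expression linkage** — CPM-based detection (median CPM > 1), filtering
  (CPM > 1 in ≥ 3 samples) and > 2-fold change rules; genes are linked to
  peaks within 1 kb of the TSS and expression distributions across classes
  are compared with a two-sided Wilcoxon rank-sum test.
- **Synthetic data** — generators that plant known co-occupancy fractions,
  sharing classes, domain coordinates, boundary peaks and expression shifts,
  so every stage can be validated by recovering the planted truth.

## Worked example

```python
from chrombound.synthetic_data import make_genome, make_peak_panel, make_h3k27me3_track
from chrombound.peak_occupancy import classify_cooccupancy, percent_common
from chrombound.repressive_domains import call_domains, domain_stats
from chrombound.boundary_analysis import extract_boundaries, mark_boundaries

assembly = make_genome(n_chrom=2, chrom_length=5_000_000, gap_fraction=0.05, seed=42)
panel = make_peak_panel(assembly, n_peaks=1_000, seed=42)
co = classify_cooccupancy(panel.target, panel.partner)
raw, pct = percent_common(co.n_both, co.n_a)
print(f"co-occupied: {co.n_both}  CTCF alone: {co.n_a_only}  ({pct}%)")

track, planted = make_h3k27me3_track(assembly, seed=42, domain_genome_fraction=0.05)
domains = call_domains(track.windows)
stats = domain_stats(domains, assembly)
print(f"domains: {stats.n_domains}  mean length: {stats.mean_length:.0f} bp  "
      f"genome share: {stats.genome_pct:.1f}%")

boundaries = extract_boundaries(domains)
marking = mark_boundaries(track.boundary_peaks, boundaries, d=1_000)
print(f"boundaries: {len(boundaries)}  marked: {marking.n_marked_boundaries}  "
      f"marking peaks: {marking.n_marking_peaks}")
```

prints

```
co-occupied: 566  CTCF alone: 434  (57%)
domains: 57  mean length: 8428 bp  genome share: 4.8%
boundaries: 114  marked: 15  marking peaks: 15
```

566/1000 peaks recover the generator's planted 54% co-occupancy within
sampling error at this size; the 57 domains average ~8.4 kb and cover 4.8%
of the 10 Mb toy genome (5% planted), and 15 of the 114 domain boundaries
carry a planted CTCF-like site within 1 kb.

A command-line interface mirrors the library
(`chrombound {simulate,filter,cooccupancy,crosscell,bins,domains,boundaries,shuffletest,expression,run-all}`);
`chrombound run-all --seed 7 --out-dir out/` executes every stage on a
synthetic dataset and writes `summary.json` plus per-stage tables, and is
bit-reproducible for a given seed.

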