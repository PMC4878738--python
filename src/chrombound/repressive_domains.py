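"""H3K27me3 repressive chromatin domain construction and statistics.

Domains are built from SICER-style enriched windows by the three-step rule:
keep windows with fold enrichment strictly > 3, merge surviving windows whose
gaps are <= 2000 bases (transitively, as BEDTools merge does), and keep merged
regions strictly larger than 2000 bases. All three thresholds are parameters.

The genome fraction occupied by domains is reported against the total
(gap-inclusive) assembly length by default, switchable to the non-gap length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_intervals import GenomeAssembly, GenomicInterval, IntervalSet, merge_within

__all__ = [
    "RepressiveDomain",
    "DomainStats",
    "HG19_ASSEMBLY_LENGTH",
    "call_domains",
    "domain_stats",
    "genome_fraction_pct",
    "celltype_specific_domains",
    "domains_to_interval_set",
]

#: Total gap-inclusive length of the hg19 reference assembly (bases).
HG19_ASSEMBLY_LENGTH = 3_137_161_264


@dataclass(frozen=True)
class RepressiveDomain:
    """A merged H3K27me3-enriched region."""

    interval: GenomicInterval
    source_window_count: int = 1

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class DomainStats:
    n_domains: int
    mean_length: float | None
    genome_fraction: float | None

    @property
    def genome_pct(self) -> float | None:
        return None if self.genome_fraction is None else 100.0 * self.genome_fraction


def call_domains(
    windows: IntervalSet,
    min_fold: float = 3.0,
    merge_gap: int = 2_000,
    min_length: int = 2_000,
) -> list[RepressiveDomain]:
    """Filter, merge and length-filter enriched windows into domains.

    All inequalities are strict: windows must exceed ``min_fold``, merged
    regions must exceed ``min_length`` bases. Output is sorted and
    non-overlapping.
    """
    if min_fold < 0 or merge_gap < 0 or min_length < 0:
        raise ValueError("parameters must be >= 0")
    fold = windows.df["fold_enrichment"].to_numpy(dtype=float)
    enriched = windows.subset(np.where(np.isnan(fold), False, fold > min_fold))
    merged = merge_within(enriched, merge_gap)
    out: list[RepressiveDomain] = []
    for row in merged.df.itertuples(index=False):
        if row.end - row.start > min_length:
            out.append(
                RepressiveDomain(
                    GenomicInterval(row.chrom, int(row.start), int(row.end)),
                    source_window_count=int(row.name),
                )
            )
    return out


def domains_to_interval_set(domains: list[RepressiveDomain], label: str = "domains") -> IntervalSet:
    return IntervalSet.from_intervals([d.interval for d in domains], label=label)


def domain_stats(
    domains: list[RepressiveDomain],
    assembly: GenomeAssembly | None = None,
    *,
    assembly_length: int | None = None,
    gap_inclusive: bool = True,
) -> DomainStats:
    """Count, mean length and genome fraction of a domain set.

    The denominator is the assembly's total (gap-inclusive) length by default;
    pass ``gap_inclusive=False`` for the non-gap length, or supply
    ``assembly_length`` directly (e.g. :data:`HG19_ASSEMBLY_LENGTH`).
    """
    n = len(domains)
    total = sum(d.length for d in domains)
    mean = total / n if n else None
    if assembly_length is None and assembly is not None:
        assembly_length = assembly.total_length if gap_inclusive else assembly.non_gap_length
    fraction = total / assembly_length if assembly_length else None
    return DomainStats(n_domains=n, mean_length=mean, genome_fraction=fraction)


def genome_fraction_pct(total_domain_length: float, assembly_length: int) -> float:
    """Percent of the assembly covered by a total domain length."""
    if assembly_length <= 0:
        raise ValueError("assembly_length must be > 0")
    return 100.0 * total_domain_length / assembly_length


def celltype_specific_domains(
    a: list[RepressiveDomain], b: list[RepressiveDomain], min_bp: int = 1
) -> list[RepressiveDomain]:
    """Domains of A with no overlap (>= min_bp) against any domain of B."""
    if not a:
        return []
    if not b:
        return list(a)
    a_set = domains_to_interval_set(a)
    b_set = domains_to_interval_set(b)
    hit = a_set.overlap_mask(b_set, min_bp=min_bp)
    # a_set is sorted; map back through the same ordering
    order = sorted(range(len(a)), key=lambda i: (a[i].interval.chrom, a[i].interval.start, a[i].interval.end))
    return [a[order[i]] for i in range(len(a)) if not hit[i]]
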