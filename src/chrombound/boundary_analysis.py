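"""Domain boundaries and the peaks that mark them.

Every repressive domain contributes a left boundary (its start coordinate) and
a right boundary (its end coordinate). A binding site within 1 kb of a
boundary coordinate — overlap counting as distance zero — marks that boundary.
Counts are reported both per unique marking peak and per marked boundary: a
peak flanked by two short domains can mark two boundaries but is one marking
site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_intervals import IntervalSet, within_distance
from .peak_occupancy import round_half_away
from .repressive_domains import RepressiveDomain

__all__ = [
    "DomainBoundary",
    "BoundaryMarking",
    "extract_boundaries",
    "mark_boundaries",
    "boundary_colocalization",
    "shared_boundary_sites",
]


@dataclass(frozen=True)
class DomainBoundary:
    chrom: str
    position: int
    side: str  # "left" | "right"
    domain_id: int


@dataclass
class BoundaryMarking:
    """Result of the 1 kb boundary-marking rule."""

    n_marking_peaks: int
    n_marked_boundaries: int
    marking_peaks: IntervalSet
    peak_marks: np.ndarray  # bool per peak
    boundary_marked: np.ndarray  # bool per boundary
    d: int


def extract_boundaries(domains: list[RepressiveDomain]) -> list[DomainBoundary]:
    """Two boundaries per domain, at its start and end coordinates."""
    out: list[DomainBoundary] = []
    for i, dom in enumerate(domains):
        out.append(DomainBoundary(dom.interval.chrom, dom.interval.start, "left", i))
        out.append(DomainBoundary(dom.interval.chrom, dom.interval.end, "right", i))
    return out


def mark_boundaries(
    peaks: IntervalSet, boundaries: list[DomainBoundary], d: int = 1_000
) -> BoundaryMarking:
    """Identify peaks within ``d`` bases of a domain boundary coordinate."""
    if d < 0:
        raise ValueError("d must be >= 0")
    anchors = [(b.chrom, b.position) for b in boundaries]
    peak_hits, boundary_hits = within_distance(peaks, anchors, d)
    return BoundaryMarking(
        n_marking_peaks=int(peak_hits.sum()),
        n_marked_boundaries=int(boundary_hits.sum()),
        marking_peaks=peaks.subset(peak_hits),
        peak_marks=peak_hits,
        boundary_marked=boundary_hits,
        d=d,
    )


def boundary_colocalization(
    a_marking: IntervalSet, b_marking: IntervalSet, min_bp: int = 1
) -> dict:
    """Fraction of A's boundary-marking peaks that overlap a B-marking peak.

    Returns a dict with ``n_colocalized``, ``n_a_marking``, ``fraction`` (None
    when A is empty) and the integer ``percent``.
    """
    n_a = len(a_marking)
    if n_a == 0 or len(b_marking) == 0:
        n_co = 0
    else:
        n_co = int(a_marking.overlap_mask(b_marking, min_bp=min_bp).sum())
    fraction = n_co / n_a if n_a else None
    return {
        "n_colocalized": n_co,
        "n_a_marking": n_a,
        "fraction": fraction,
        "percent": None if fraction is None else round_half_away(100.0 * fraction),
    }


def shared_boundary_sites(
    a_cell: IntervalSet, b_cell: IntervalSet, min_bp: int = 1
) -> int:
    """Count A-cell boundary sites overlapping >= 1 B-cell boundary site."""
    if len(a_cell) == 0 or len(b_cell) == 0:
        return 0
    return int(a_cell.overlap_mask(b_cell, min_bp=min_bp).sum())
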