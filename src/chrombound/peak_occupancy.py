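"""Peak classification: factor co-occupancy and cross-cell-type sharing.

Two classifications drive the biology here. *Co-occupancy* asks, per CTCF
peak, whether a cohesin peak overlaps it in the same cell type. *Cross-cell
sharing* compares one cell type's peak set against K reference cell types and
labels each peak invariant (present, i.e. overlapping a peak, in all K),
cell-type specific (present in none) or intermediate.

"Present" defaults to >= 1 bp overlap — the BEDTools-intersect convention —
and is configurable through ``min_bp`` everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core_intervals import IntervalSet

__all__ = [
    "CooccupancyResult",
    "CrossCellClassification",
    "classify_cooccupancy",
    "classify_cross_cell",
    "percent_common",
    "round_half_away",
    "filter_peaks",
]


@dataclass
class CooccupancyResult:
    """Counts and per-peak labels for a two-factor overlap classification.

    ``n_both`` counts A-peaks overlapping >= 1 B-peak, so it need not equal
    the reciprocal count from classifying B against A; both directions are
    reported. Each peak is counted once regardless of how many partners it
    overlaps.
    """

    n_both: int
    n_a_only: int
    n_b_only: int
    a_labels: np.ndarray  # per-A-peak: "both" | "a_only"
    b_labels: np.ndarray  # per-B-peak: "both" | "b_only"
    n_b_both: int = 0

    @property
    def n_a(self) -> int:
        return self.n_both + self.n_a_only

    @property
    def n_b(self) -> int:
        return self.n_b_both + self.n_b_only


@dataclass
class CrossCellClassification:
    """Per-peak sharing against K reference cell types."""

    shared_count: np.ndarray  # int in [0, K] per peak
    labels: np.ndarray  # "specific" | "invariant" | "intermediate"
    k: int

    @property
    def n_specific(self) -> int:
        return int((self.labels == "specific").sum())

    @property
    def n_invariant(self) -> int:
        return int((self.labels == "invariant").sum())

    @property
    def n_intermediate(self) -> int:
        return int((self.labels == "intermediate").sum())

    def fractions(self) -> dict[str, float]:
        n = len(self.labels)
        if n == 0:
            return {"specific": math.nan, "invariant": math.nan, "intermediate": math.nan}
        return {
            "specific": self.n_specific / n,
            "invariant": self.n_invariant / n,
            "intermediate": self.n_intermediate / n,
        }


def classify_cooccupancy(
    a: IntervalSet, b: IntervalSet, min_bp: int = 1
) -> CooccupancyResult:
    """Label each peak of A/B by whether it overlaps the other factor's set."""
    a_hit = a.overlap_mask(b, min_bp=min_bp) if len(b) else np.zeros(len(a), bool)
    b_hit = b.overlap_mask(a, min_bp=min_bp) if len(a) else np.zeros(len(b), bool)
    a_labels = np.where(a_hit, "both", "a_only")
    b_labels = np.where(b_hit, "both", "b_only")
    return CooccupancyResult(
        n_both=int(a_hit.sum()),
        n_a_only=int((~a_hit).sum()),
        n_b_only=int((~b_hit).sum()),
        a_labels=a_labels,
        b_labels=b_labels,
        n_b_both=int(b_hit.sum()),
    )


def classify_cross_cell(
    target: IntervalSet, references: list[IntervalSet], min_bp: int = 1
) -> CrossCellClassification:
    """Count, per target peak, how many reference sets contain it.

    A peak is *invariant* when all K references hold an overlapping interval,
    *specific* when none does, *intermediate* otherwise.
    """
    k = len(references)
    if k < 1:
        raise ValueError("need at least one reference set")
    shared = np.zeros(len(target), dtype=np.int64)
    for ref in references:
        if len(ref):
            shared += target.overlap_mask(ref, min_bp=min_bp)
    labels = np.full(len(target), "intermediate", dtype=object)
    labels[shared == 0] = "specific"
    labels[shared == k] = "invariant"
    return CrossCellClassification(shared_count=shared, labels=labels.astype(str), k=k)


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (printed-table convention)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def percent_common(n_common: int, n_total: int) -> tuple[float, int]:
    """Percentage of common sites over a stated denominator.

    Returns ``(raw, rounded)`` where ``raw = 100 * n_common / n_total`` and
    ``rounded`` follows round-half-away-from-zero, the convention of printed
    integer percents.
    """
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not (0 <= n_common <= n_total):
        raise ValueError("require 0 <= n_common <= n_total")
    raw = 100.0 * n_common / n_total
    return raw, round_half_away(raw)


def filter_peaks(
    iset: IntervalSet, min_fold: float = 0.0, max_p: float | None = None
) -> IntervalSet:
    """Keep peaks with fold enrichment strictly > ``min_fold`` and p strictly
    < ``max_p``.

    p-values are carried as ``-log10 p``; when ``max_p`` is None no p filter is
    applied (peaks without a recorded p then pass). When ``max_p`` is given,
    peaks lacking a p-value are dropped.
    """
    if min_fold < 0:
        raise ValueError("min_fold must be >= 0")
    fold = iset.df["fold_enrichment"].to_numpy(dtype=float)
    keep = np.where(np.isnan(fold), False, fold > min_fold)
    if max_p is not None:
        if not (0 < max_p <= 1):
            raise ValueError("max_p must be in (0, 1]")
        nlp = iset.df["neg_log10_p"].to_numpy(dtype=float)
        keep &= np.where(np.isnan(nlp), False, nlp > -math.log10(max_p))
    return iset.subset(keep)
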