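"""Coordinate-safe genomic interval model, BED-family I/O and interval primitives.

All coordinates are 0-based, half-open ``[start, end)`` — BED-native. Every
higher-level stage (co-occupancy classification, domain calling, boundary
marking, randomization nulls) is built from the small set of primitives here:
overlap testing, gap-bounded merging, proximity queries and assembly-gap
complementation.

Distance convention
-------------------
The distance between two intervals is the coordinate gap separating them
(``max(0, b.start - a.end, a.start - b.end)``): overlapping *and* abutting
intervals are at distance 0. The distance between an interval and a point
position ``p`` is ``max(0, start - p, p - end)``, i.e. a position inside or on
the ends of the interval is at distance 0. This is the convention under which
"within 1 kb of a domain boundary" and "within 1 kb of the TSS" are evaluated
throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence, Union

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "Peak",
    "GenomeAssembly",
    "IntervalSet",
    "BedParseError",
    "read_bed",
    "read_chrom_sizes",
    "overlaps",
    "interval_distance",
    "point_distance",
    "merge_within",
    "within_distance",
    "subtract_gaps",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class Peak:
    """A called peak: an interval plus its enrichment evidence.

    ``summit`` is an absolute coordinate inside ``[start, end)`` or ``None``;
    ``neg_log10_p`` is ``-log10`` of the peak-calling p-value or ``None``.
    """

    interval: GenomicInterval
    summit: int | None = None
    fold_enrichment: float = 0.0
    neg_log10_p: float | None = None
    name: str = "."

    def __post_init__(self) -> None:
        if self.summit is not None and not (
            self.interval.start <= self.summit < self.interval.end
        ):
            raise ValueError(
                f"summit {self.summit} outside interval "
                f"[{self.interval.start},{self.interval.end})"
            )
        if not np.isfinite(self.fold_enrichment) or self.fold_enrichment < 0:
            raise ValueError("fold_enrichment must be finite and >= 0")


# DataFrame column layout shared by every IntervalSet.
_COLUMNS = ["chrom", "start", "end", "name", "fold_enrichment", "neg_log10_p", "summit"]


class IntervalSet:
    """An ordered collection of intervals/peaks on one table.

    Backed by a pandas DataFrame with columns
    ``chrom, start, end, name, fold_enrichment, neg_log10_p, summit``
    (the last four NaN/'.' when absent). Normalized sets are sorted by
    ``(chrom, start, end)``; duplicates are permitted but flagged via
    :attr:`has_duplicates`.
    """

    def __init__(self, df: pd.DataFrame, label: str = "", *, normalize: bool = True):
        df = df.copy()
        for col in _COLUMNS:
            if col not in df.columns:
                df[col] = np.nan if col != "name" else "."
        df = df[_COLUMNS]
        df["chrom"] = df["chrom"].astype(str)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
            bad = df[(df["start"] < 0) | (df["start"] >= df["end"])].iloc[0]
            raise ValueError(
                f"invalid interval {bad['chrom']}:[{bad['start']},{bad['end']})"
            )
        if normalize:
            df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
        df = df.reset_index(drop=True)
        self.df = df
        self.label = label

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_intervals(
        cls,
        intervals: Iterable[Union[GenomicInterval, Peak]],
        label: str = "",
    ) -> "IntervalSet":
        rows = []
        for item in intervals:
            if isinstance(item, Peak):
                iv = item.interval
                rows.append(
                    (iv.chrom, iv.start, iv.end, item.name, item.fold_enrichment,
                     np.nan if item.neg_log10_p is None else item.neg_log10_p,
                     np.nan if item.summit is None else item.summit)
                )
            else:
                rows.append((item.chrom, item.start, item.end, ".", np.nan, np.nan, np.nan))
        df = pd.DataFrame(rows, columns=_COLUMNS)
        if not rows:
            df = pd.DataFrame(columns=_COLUMNS)
        return cls(df, label=label)

    @classmethod
    def from_arrays(
        cls,
        chroms: Sequence[str],
        starts: Sequence[int],
        ends: Sequence[int],
        label: str = "",
        **extra,
    ) -> "IntervalSet":
        df = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})
        for key, val in extra.items():
            df[key] = val
        return cls(df, label=label)

    # -- basic protocol ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[GenomicInterval]:
        for row in self.df.itertuples(index=False):
            yield GenomicInterval(row.chrom, int(row.start), int(row.end))

    def peaks(self) -> Iterator[Peak]:
        for row in self.df.itertuples(index=False):
            yield Peak(
                GenomicInterval(row.chrom, int(row.start), int(row.end)),
                summit=None if pd.isna(row.summit) else int(row.summit),
                fold_enrichment=0.0 if pd.isna(row.fold_enrichment) else float(row.fold_enrichment),
                neg_log10_p=None if pd.isna(row.neg_log10_p) else float(row.neg_log10_p),
                name=str(row.name),
            )

    @property
    def has_duplicates(self) -> bool:
        return bool(self.df.duplicated(["chrom", "start", "end"]).any())

    @property
    def total_length(self) -> int:
        return int((self.df["end"] - self.df["start"]).sum())

    def subset(self, mask: np.ndarray) -> "IntervalSet":
        return IntervalSet(self.df[np.asarray(mask, bool)], label=self.label, normalize=False)

    # -- queries ----------------------------------------------------------
    def trees(self) -> dict[str, IntervalTree]:
        """One IntervalTree per chromosome (built lazily, cached)."""
        cached = getattr(self, "_trees", None)
        if cached is None:
            cached = {}
            for chrom, sub in self.df.groupby("chrom", sort=False):
                cached[str(chrom)] = IntervalTree.from_tuples(
                    zip(sub["start"].to_numpy(), sub["end"].to_numpy(), sub.index)
                )
            self._trees = cached
        return cached

    def overlap_mask(self, other: "IntervalSet", min_bp: int = 1) -> np.ndarray:
        """Boolean per interval of self: overlaps >= min_bp bases of >=1 other interval."""
        if min_bp < 1:
            raise ValueError("min_bp must be >= 1")
        trees = other.trees()
        out = np.zeros(len(self), dtype=bool)
        chroms = self.df["chrom"].to_numpy()
        starts = self.df["start"].to_numpy()
        ends = self.df["end"].to_numpy()
        for i in range(len(self)):
            tree = trees.get(chroms[i])
            if tree is None:
                continue
            for hit in tree.overlap(starts[i], ends[i]):
                if min(ends[i], hit.end) - max(starts[i], hit.begin) >= min_bp:
                    out[i] = True
                    break
        return out

    def overlap_counts(self, other: "IntervalSet", min_bp: int = 1) -> np.ndarray:
        """Number of reference sets is handled upstream; here: hits per self interval."""
        if min_bp < 1:
            raise ValueError("min_bp must be >= 1")
        trees = other.trees()
        out = np.zeros(len(self), dtype=np.int64)
        chroms = self.df["chrom"].to_numpy()
        starts = self.df["start"].to_numpy()
        ends = self.df["end"].to_numpy()
        for i in range(len(self)):
            tree = trees.get(chroms[i])
            if tree is None:
                continue
            n = 0
            for hit in tree.overlap(starts[i], ends[i]):
                if min(ends[i], hit.end) - max(starts[i], hit.begin) >= min_bp:
                    n += 1
            out[i] = n
        return out

    def points(self, mode: str = "summit_or_midpoint") -> np.ndarray:
        """Representative point per interval: summit when recorded, else midpoint."""
        starts = self.df["start"].to_numpy()
        ends = self.df["end"].to_numpy()
        mids = (starts + ends) // 2
        if mode == "midpoint":
            return mids
        summits = self.df["summit"].to_numpy(dtype=float)
        return np.where(np.isnan(summits), mids, summits).astype(np.int64)

    # -- I/O ---------------------------------------------------------------
    def to_bed(self, path: str | Path, *, name_field: bool = True) -> None:
        cols = ["chrom", "start", "end"] + (["name"] if name_field else [])
        self.df[cols].to_csv(path, sep="\t", header=False, index=False)


@dataclass
class GenomeAssembly:
    """Chromosome sizes plus assembly gaps (runs of unsequenced bases).

    Gaps are normalized (sorted, merged) on construction and validated to lie
    inside their chromosome. The non-gap complement is the space in which
    intervals are randomized.
    """

    chrom_sizes: dict[str, int]
    gaps: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive size")
        for gap in self.gaps:
            size = self.chrom_sizes.get(gap.chrom)
            if size is None:
                raise ValueError(f"gap on unknown chromosome {gap.chrom}")
            if gap.start < 0 or gap.end > size:
                raise ValueError(
                    f"gap {gap.chrom}:[{gap.start},{gap.end}) outside chromosome [0,{size})"
                )
        if self.gaps:
            merged = merge_within(IntervalSet.from_intervals(self.gaps), 0)
            self.gaps = list(merged)
        for chrom, size in self.chrom_sizes.items():
            gap_len = sum(g.length for g in self.gaps if g.chrom == chrom)
            if size - gap_len <= 0:
                raise ValueError(f"chromosome {chrom} has no non-gap bases")

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_sizes.values()))

    @property
    def non_gap_length(self) -> int:
        return self.total_length - sum(g.length for g in self.gaps)

    def non_gap_segments(self) -> dict[str, list[GenomicInterval]]:
        return subtract_gaps(self)


class BedParseError(ValueError):
    """Raised for malformed BED-family input, naming the offending line."""


_DIALECT_MIN_COLS = {"bed3": 3, "bed6": 6, "narrowPeak": 10, "sicer_window": 4}


def read_bed(
    path: str | Path,
    dialect: str = "bed3",
    *,
    label: str | None = None,
    sicer_fold_col: int = 6,
) -> IntervalSet:
    """Read a BED-family file into a normalized :class:`IntervalSet`.

    Dialects: ``bed3`` (chrom/start/end), ``bed6`` (+ name/score/strand),
    ``narrowPeak`` (ENCODE 10-column; signalValue → fold_enrichment, pValue →
    neg_log10_p, column 10 → summit offset, −1 meaning no summit) and
    ``sicer_window`` (interval + fold-enrichment in column ``sicer_fold_col``,
    0-based; default 6 matches SICER's islands-summary fold-change column).

    Raises :class:`BedParseError` naming the line number on malformed input.
    """
    if dialect not in _DIALECT_MIN_COLS:
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    min_cols = _DIALECT_MIN_COLS[dialect]
    if dialect == "sicer_window":
        min_cols = max(min_cols, sicer_fold_col + 1)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < min_cols:
                raise BedParseError(
                    f"{path.name}:{lineno}: expected >= {min_cols} columns for "
                    f"{dialect}, got {len(fields)}"
                )
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path.name}:{lineno}: {exc}") from None
            if start < 0 or start >= end:
                raise BedParseError(
                    f"{path.name}:{lineno}: invalid coordinates [{start},{end})"
                )
            name, fold, nlp, summit = ".", np.nan, np.nan, np.nan
            if dialect == "bed6":
                name = fields[3]
            elif dialect == "narrowPeak":
                name = fields[3]
                try:
                    fold = float(fields[6])
                    nlp = float(fields[7])
                    offset = int(fields[9])
                except ValueError as exc:
                    raise BedParseError(f"{path.name}:{lineno}: {exc}") from None
                summit = start + offset if offset >= 0 else np.nan
                if offset >= end - start:
                    raise BedParseError(
                        f"{path.name}:{lineno}: summit offset {offset} outside peak"
                    )
            elif dialect == "sicer_window":
                try:
                    fold = float(fields[sicer_fold_col])
                except ValueError as exc:
                    raise BedParseError(f"{path.name}:{lineno}: {exc}") from None
            rows.append((chrom, start, end, name, fold, nlp, summit))
    df = pd.DataFrame(rows, columns=_COLUMNS)
    if not rows:
        df = pd.DataFrame(columns=_COLUMNS)
    return IntervalSet(df, label=label if label is not None else path.stem)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column UCSC chrom.sizes file."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise BedParseError(f"chrom.sizes:{lineno}: expected 2 columns")
            sizes[fields[0]] = int(fields[1])
    return sizes


def overlaps(a: GenomicInterval, b: GenomicInterval, min_bp: int = 1) -> bool:
    """True iff *a* and *b* share at least ``min_bp`` bases."""
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    return a.overlap_length(b) >= min_bp


def interval_distance(a: GenomicInterval, b: GenomicInterval) -> int | None:
    """Coordinate gap between two intervals; 0 when they overlap or abut.

    Returns ``None`` for intervals on different chromosomes.
    """
    if a.chrom != b.chrom:
        return None
    return max(0, b.start - a.end, a.start - b.end)


def point_distance(a: GenomicInterval, chrom: str, pos: int) -> int | None:
    """Distance from interval *a* to coordinate ``pos``; 0 when pos in [start, end]."""
    if a.chrom != chrom:
        return None
    return max(0, a.start - pos, pos - a.end)


def merge_within(iset: IntervalSet, max_gap: int = 0) -> IntervalSet:
    """Merge intervals whose separating gap is <= ``max_gap`` (transitively).

    ``max_gap=0`` merges overlapping and abutting intervals. Output is sorted,
    non-overlapping and carries the number of source intervals per merged
    region in the ``name`` column. Idempotent.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if len(iset) == 0:
        return IntervalSet(pd.DataFrame(columns=_COLUMNS), label=iset.label)
    out_rows = []
    for chrom, sub in iset.df.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_start, cur_end, n_src = starts[0], ends[0], 1
        for s, e in zip(starts[1:], ends[1:]):
            if s - cur_end <= max_gap:
                cur_end = max(cur_end, e)
                n_src += 1
            else:
                out_rows.append((chrom, cur_start, cur_end, str(n_src)))
                cur_start, cur_end, n_src = s, e, 1
        out_rows.append((chrom, cur_start, cur_end, str(n_src)))
    df = pd.DataFrame(out_rows, columns=["chrom", "start", "end", "name"])
    return IntervalSet(df, label=iset.label)


AnchorLike = Union[IntervalSet, Sequence[GenomicInterval], Sequence[tuple]]


def _anchor_arrays(anchors: AnchorLike):
    """Normalize anchors to (chroms, starts, ends, is_point) arrays.

    Point anchors — ``(chrom, position)`` tuples — are encoded with
    start == end == position.
    """
    if isinstance(anchors, IntervalSet):
        return (
            anchors.df["chrom"].to_numpy(),
            anchors.df["start"].to_numpy(),
            anchors.df["end"].to_numpy(),
        )
    chroms, starts, ends = [], [], []
    for item in anchors:
        if isinstance(item, GenomicInterval):
            chroms.append(item.chrom)
            starts.append(item.start)
            ends.append(item.end)
        else:
            chrom, pos = item[0], int(item[1])
            chroms.append(chrom)
            starts.append(pos)
            ends.append(pos)
    return np.asarray(chroms, dtype=object), np.asarray(starts), np.asarray(ends)


def within_distance(
    queries: IntervalSet, anchors: AnchorLike, d: int
) -> tuple[np.ndarray, np.ndarray]:
    """Proximity query in both directions.

    Returns ``(query_hits, anchor_hits)``: ``query_hits[i]`` is True iff query
    *i* lies within distance ``d`` of at least one anchor, and symmetrically
    for anchors. Anchors may be intervals or ``(chrom, position)`` points;
    distances follow the module's coordinate-gap convention (overlap ⇒ 0).
    """
    if d < 0:
        raise ValueError("d must be >= 0")
    q_chrom = queries.df["chrom"].to_numpy()
    q_start = queries.df["start"].to_numpy()
    q_end = queries.df["end"].to_numpy()
    a_chrom, a_start, a_end = _anchor_arrays(anchors)
    query_hits = np.zeros(len(q_chrom), dtype=bool)
    anchor_hits = np.zeros(len(a_chrom), dtype=bool)
    for chrom in np.unique(np.concatenate([q_chrom, a_chrom])) if len(q_chrom) or len(a_chrom) else []:
        qi = np.flatnonzero(q_chrom == chrom)
        ai = np.flatnonzero(a_chrom == chrom)
        if len(qi) == 0 or len(ai) == 0:
            continue
        # chunked all-pairs distance; scales fine at per-chromosome set sizes
        for lo in range(0, len(qi), 2048):
            block = qi[lo : lo + 2048]
            gap = np.maximum(
                a_start[ai][None, :] - q_end[block][:, None],
                q_start[block][:, None] - a_end[ai][None, :],
            )
            near = np.maximum(gap, 0) <= d
            query_hits[block] |= near.any(axis=1)
            anchor_hits[ai] |= near.any(axis=0)
    return query_hits, anchor_hits


def subtract_gaps(assembly: GenomeAssembly) -> dict[str, list[GenomicInterval]]:
    """Per-chromosome complement of assembly gaps within ``[0, size)``."""
    by_chrom: dict[str, list[GenomicInterval]] = {c: [] for c in assembly.chrom_sizes}
    for gap in assembly.gaps:
        by_chrom[gap.chrom].append(gap)
    out: dict[str, list[GenomicInterval]] = {}
    for chrom, size in assembly.chrom_sizes.items():
        segments = []
        cursor = 0
        for gap in sorted(by_chrom[chrom], key=lambda g: g.start):
            if gap.start > cursor:
                segments.append(GenomicInterval(chrom, cursor, gap.start))
            cursor = max(cursor, gap.end)
        if cursor < size:
            segments.append(GenomicInterval(chrom, cursor, size))
        out[chrom] = segments
    return out
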