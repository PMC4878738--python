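"""Feature-bin partition of the genome relative to gene models.

Each non-gap base is assigned to exactly one bin by fixed precedence:

    promoter > downstream > genic > five_prime_distal > three_prime_distal
    > intergenic

with assembly gaps carried separately as ``unassigned_gap``. Defaults follow
the usual peak-annotation conventions: promoter = +/-1 kb around the TSS,
downstream = +/-1 kb around the TES, distal bins reach from 1 kb out to 50 kb
on the appropriate side of the gene, intergenic is everything > 50 kb from any
gene. Gene models carry strand-resolved TSS/TES (tss = transcription start,
whatever its numeric relation to tes).

Peaks are assigned to a bin by a single representative point (summit when
recorded, else midpoint) so the per-bin peak fractions sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_intervals import GenomeAssembly, GenomicInterval, IntervalSet

__all__ = [
    "GeneModel",
    "BinScheme",
    "BIN_NAMES",
    "build_bins",
    "peak_bin_distribution",
    "read_gene_models",
]

BIN_NAMES = [
    "promoter",
    "downstream",
    "genic",
    "five_prime_distal",
    "three_prime_distal",
    "intergenic",
    "unassigned_gap",
]

# precedence rank: lower wins
_RANK = {name: i for i, name in enumerate(BIN_NAMES)}


@dataclass(frozen=True)
class GeneModel:
    """A gene as a strand-resolved TSS/TES pair."""

    chrom: str
    strand: str
    tss: int
    tes: int
    gene_id: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.strand == "+" and not self.tss < self.tes:
            raise ValueError(f"gene {self.gene_id}: + strand requires tss < tes")
        if self.strand == "-" and not self.tss > self.tes:
            raise ValueError(f"gene {self.gene_id}: - strand requires tss > tes")

    @property
    def body(self) -> tuple[int, int]:
        return (min(self.tss, self.tes), max(self.tss, self.tes))


@dataclass(frozen=True)
class BinScheme:
    """Distances (bases) defining the partition."""

    promoter_d: int = 1_000
    distal_d: int = 50_000

    def __post_init__(self) -> None:
        if self.promoter_d <= 0 or self.distal_d <= self.promoter_d:
            raise ValueError("require 0 < promoter_d < distal_d")


def _candidate_windows(gene: GeneModel, scheme: BinScheme):
    """Yield (bin_name, start, end) windows for one gene, unclipped."""
    p, D = scheme.promoter_d, scheme.distal_d
    lo, hi = gene.body
    yield ("promoter", gene.tss - p, gene.tss + p)
    yield ("downstream", gene.tes - p, gene.tes + p)
    yield ("genic", lo, hi)
    if gene.strand == "+":
        yield ("five_prime_distal", gene.tss - D, gene.tss - p)
        yield ("three_prime_distal", gene.tes + p, gene.tes + D)
    else:
        yield ("five_prime_distal", gene.tss + p, gene.tss + D)
        yield ("three_prime_distal", gene.tes - D, gene.tes - p)


def build_bins(
    genes: list[GeneModel],
    assembly: GenomeAssembly,
    scheme: BinScheme = BinScheme(),
) -> dict[str, IntervalSet]:
    """Partition every base of the assembly into the feature bins.

    Overlapping gene windows are resolved by bin precedence, not gene
    identity. Returns one sorted, disjoint :class:`IntervalSet` per bin; the
    union of all bins (including ``unassigned_gap``) tiles the genome exactly.
    """
    for gene in genes:
        size = assembly.chrom_sizes.get(gene.chrom)
        if size is None:
            raise ValueError(f"gene {gene.gene_id} on unknown chromosome {gene.chrom}")
        lo, hi = gene.body
        if lo < 0 or hi > size:
            raise ValueError(f"gene {gene.gene_id} outside chromosome bounds")

    by_chrom: dict[str, list[tuple[int, int, int]]] = {c: [] for c in assembly.chrom_sizes}
    for gene in genes:
        size = assembly.chrom_sizes[gene.chrom]
        for name, start, end in _candidate_windows(gene, scheme):
            start, end = max(0, start), min(size, end)
            if start < end:
                by_chrom[gene.chrom].append((start, end, _RANK[name]))
    for gap in assembly.gaps:
        by_chrom[gap.chrom].append((gap.start, gap.end, _RANK["unassigned_gap"]))

    pieces: dict[str, list[tuple[str, int, int]]] = {name: [] for name in BIN_NAMES}
    for chrom, size in assembly.chrom_sizes.items():
        windows = by_chrom[chrom]
        cuts = np.unique(
            np.concatenate(
                [[0, size]] + [[s, e] for s, e, _ in windows] if windows else [[0, size]]
            )
        )
        cuts = cuts[(cuts >= 0) & (cuts <= size)]
        seg_start, seg_end = cuts[:-1], cuts[1:]
        rank = np.full(len(seg_start), _RANK["intergenic"], dtype=np.int8)
        for s, e, r in sorted(windows, key=lambda w: -w[2]):
            i0 = np.searchsorted(seg_start, s)
            i1 = np.searchsorted(seg_start, e)
            rank[i0:i1] = np.minimum(rank[i0:i1], r) if r != _RANK["unassigned_gap"] else rank[i0:i1]
        # gaps override everything, applied last
        for s, e, r in windows:
            if r == _RANK["unassigned_gap"]:
                i0 = np.searchsorted(seg_start, s)
                i1 = np.searchsorted(seg_start, e)
                rank[i0:i1] = r
        for name in BIN_NAMES:
            r = _RANK[name]
            idx = np.flatnonzero(rank == r)
            for i in idx:
                pieces[name].append((chrom, int(seg_start[i]), int(seg_end[i])))

    out: dict[str, IntervalSet] = {}
    for name in BIN_NAMES:
        rows = pieces[name]
        if rows:
            df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
            out[name] = merge_adjacent(IntervalSet(df, label=name))
        else:
            out[name] = IntervalSet(pd.DataFrame(columns=["chrom", "start", "end"]), label=name)
    return out


def merge_adjacent(iset: IntervalSet) -> IntervalSet:
    """Coalesce abutting segments produced by the cut-point sweep."""
    from .core_intervals import merge_within

    return merge_within(iset, 0)


def peak_bin_distribution(
    peaks: IntervalSet, bins: dict[str, IntervalSet]
) -> pd.DataFrame:
    """Tabulate the fraction of peaks vs fraction of genome per bin.

    Each peak counts once, at its summit (when recorded) or midpoint. Returns
    a DataFrame indexed by bin with columns ``n_peaks, peak_fraction,
    bin_length, genome_fraction, enrichment`` (peak fraction over genome
    fraction).
    """
    total_len = sum(bins[name].total_length for name in bins)
    points = peaks.points()
    chroms = peaks.df["chrom"].to_numpy()
    n_per_bin: dict[str, int] = {name: 0 for name in bins}
    assigned = np.zeros(len(peaks), dtype=bool)
    for name, bset in bins.items():
        if len(bset) == 0:
            continue
        for chrom, sub in bset.df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            sel = np.flatnonzero((chroms == chrom) & ~assigned)
            if len(sel) == 0:
                continue
            pos = points[sel]
            idx = np.searchsorted(starts, pos, side="right") - 1
            ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
            n_per_bin[name] += int(ok.sum())
            assigned[sel[ok]] = True
    n_total = len(peaks)
    rows = []
    for name in bins:
        blen = bins[name].total_length
        rows.append(
            {
                "bin": name,
                "n_peaks": n_per_bin[name],
                "peak_fraction": n_per_bin[name] / n_total if n_total else np.nan,
                "bin_length": blen,
                "genome_fraction": blen / total_len if total_len else np.nan,
            }
        )
    df = pd.DataFrame(rows).set_index("bin")
    with np.errstate(divide="ignore", invalid="ignore"):
        df["enrichment"] = df["peak_fraction"] / df["genome_fraction"]
    return df


def read_gene_models(path, dialect: str = "bed6") -> list[GeneModel]:
    """Read gene models from BED6 (TSS/TES from strand) or refFlat-like TSV.

    The refFlat-like dialect expects columns
    ``gene_id, chrom, strand, tx_start, tx_end`` (tab-separated, no header).
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if dialect == "bed6":
                if len(f) < 6:
                    raise ValueError(f"gene models line {lineno}: need 6 columns")
                chrom, start, end, name, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            elif dialect == "refflat":
                if len(f) < 5:
                    raise ValueError(f"gene models line {lineno}: need 5 columns")
                name, chrom, strand, start, end = f[0], f[1], f[2], int(f[3]), int(f[4])
            else:
                raise ValueError(f"unknown gene model dialect {dialect!r}")
            if strand == "+":
                genes.append(GeneModel(chrom, "+", start, end, name))
            else:
                genes.append(GeneModel(chrom, "-", end, start, name))
    return genes
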