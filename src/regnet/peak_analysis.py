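"""ChIP-chip peak screening, IgG subtraction, promoter assignment, TSS histograms.

Peaks arrive as scored intervals (BED convention: 0-based, half-open) with a
per-peak FDR from the upstream peak caller.  The screen keeps peaks at
FDR <= 0.2, removes any peak sharing >= 1 bp with an IgG-control peak, maps
survivors onto promoter windows, and summarizes binding positions relative
to the transcription start site (TSS), strand-corrected so that negative
offsets are upstream.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree


@dataclass(frozen=True)
class ScoredPeak:
    chrom: str
    start: int
    end: int
    score: float
    fdr: float
    name: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")
        if not 0.0 <= self.fdr <= 1.0:
            raise ValueError(f"fdr {self.fdr} outside [0, 1]")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class PromoterRegion:
    """Gene-anchored promoter window with its TSS and strand.

    The window is half-open; the TSS must fall inside it.  For minus-strand
    genes "upstream" lies at larger coordinates, handled at offset time.
    """

    gene_id: str
    chrom: str
    window_start: int
    window_end: int
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.window_start <= self.tss < self.window_end:
            raise ValueError(
                f"TSS {self.tss} outside window [{self.window_start}, {self.window_end})"
            )


@dataclass(frozen=True)
class BindingHistogram:
    bin_edges: tuple[int, ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValueError("counts must have one fewer entry than bin_edges")


def filter_by_fdr(peaks: Sequence[ScoredPeak], max_fdr: float) -> list[ScoredPeak]:
    """Keep peaks with fdr <= max_fdr (inclusive boundary), order preserved."""
    if not 0.0 <= max_fdr <= 1.0:
        raise ValueError(f"max_fdr {max_fdr} outside [0, 1]")
    return [p for p in peaks if p.fdr <= max_fdr]


def _build_tree(peaks: Iterable[ScoredPeak]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for p in peaks:
        trees[p.chrom].addi(p.start, p.end)
    return trees


def subtract_overlapping(
    target: Sequence[ScoredPeak], control: Sequence[ScoredPeak]
) -> list[ScoredPeak]:
    """Discard target peaks sharing at least one base with any control peak.

    Half-open adjacency (target end == control start) is zero overlap and is
    retained.  The survivors are the peaks considered positive for specific
    protein binding.
    """
    trees = _build_tree(control)
    kept = []
    for p in target:
        tree = trees.get(p.chrom)
        if tree is None or not tree.overlaps(p.start, p.end):
            kept.append(p)
    return kept


def assign_to_promoters(
    peaks: Sequence[ScoredPeak], promoters: Sequence[PromoterRegion]
) -> dict[str, list[ScoredPeak]]:
    """Map gene_id -> peaks overlapping that gene's promoter window by >= 1 bp.

    A peak spanning several promoter windows is assigned to each of them; the
    returned key set is the factor's target gene set.
    """
    seen: set[str] = set()
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for prom in promoters:
        if prom.gene_id in seen:
            raise ValueError(f"duplicate gene_id {prom.gene_id!r} in promoter annotation")
        seen.add(prom.gene_id)
        trees[prom.chrom].addi(prom.window_start, prom.window_end, prom.gene_id)
    assignment: dict[str, list[ScoredPeak]] = defaultdict(list)
    for p in peaks:
        for iv in trees.get(p.chrom, IntervalTree()).overlap(p.start, p.end):
            assignment[iv.data].append(p)
    return dict(assignment)


def tss_relative_offsets(
    assignment: Mapping[str, Sequence[ScoredPeak]],
    promoters: Sequence[PromoterRegion],
) -> list[int]:
    """Signed midpoint offsets of assigned peaks from their gene's TSS.

    Negative means upstream of the TSS in the gene's own orientation; the
    sign is flipped for minus-strand genes.
    """
    by_gene = {p.gene_id: p for p in promoters}
    offsets = []
    for gene_id, peaks in assignment.items():
        prom = by_gene[gene_id]
        for p in peaks:
            delta = p.midpoint - prom.tss
            offsets.append(delta if prom.strand == "+" else -delta)
    return offsets


def tss_relative_histogram(
    assignment: Mapping[str, Sequence[ScoredPeak]],
    promoters: Sequence[PromoterRegion],
    bin_width: int = 100,
) -> BindingHistogram:
    """Histogram of binding events by strand-corrected TSS offset.

    Bins are aligned so one bin is centered on offset 0 (edges at
    k*bin_width - bin_width//2), covering every event; counts conserve the
    number of assigned peak events.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    offsets = np.asarray(tss_relative_offsets(assignment, promoters), dtype=int)
    shift = bin_width // 2
    if offsets.size == 0:
        return BindingHistogram(bin_edges=(-shift, bin_width - shift), counts=(0,))
    lo = int(np.floor((offsets.min() + shift) / bin_width)) * bin_width - shift
    hi = (int(np.floor((offsets.max() + shift) / bin_width)) + 1) * bin_width - shift
    edges = np.arange(lo, hi + 1, bin_width)
    counts, _ = np.histogram(offsets, bins=edges)
    return BindingHistogram(bin_edges=tuple(int(e) for e in edges), counts=tuple(int(c) for c in counts))


def positive_peaks(
    target: Sequence[ScoredPeak],
    control: Sequence[ScoredPeak],
    max_fdr: float = 0.2,
) -> list[ScoredPeak]:
    """FDR screen followed by IgG-control subtraction (the full peak filter)."""
    return subtract_overlapping(filter_by_fdr(target, max_fdr), control)


# ---------------------------------------------------------------------------
# I/O: BED6+1 peaks (fdr in column 7), BED6 promoters


def read_peaks(path: str | Path) -> list[ScoredPeak]:
    """Read peaks from BED6+1 TSV: chrom start end name score strand fdr."""
    peaks = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        peaks.append(
            ScoredPeak(
                chrom=f[0], start=int(f[1]), end=int(f[2]),
                name=f[3], score=float(f[4]), fdr=float(f[6]),
            )
        )
    return peaks


def write_peaks(peaks: Sequence[ScoredPeak], path: str | Path) -> None:
    lines = [
        f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score:g}\t+\t{p.fdr:g}"
        for p in peaks
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_promoters(
    path: str | Path, upstream: int = 2200, downstream: int = 500
) -> list[PromoterRegion]:
    """Read a BED6 promoter annotation, deriving the TSS from the strand.

    The windows are assumed to span ``upstream`` bases 5' of the TSS and
    ``downstream`` bases 3' of it (defaults match a RefSeq-style promoter
    tiling design), so for + strand genes TSS = start + upstream and for
    - strand genes TSS = end - 1 - upstream.
    """
    promoters = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        chrom, start, end, gene_id, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
        tss = start + upstream if strand == "+" else end - 1 - upstream
        promoters.append(
            PromoterRegion(
                gene_id=gene_id, chrom=chrom, window_start=start,
                window_end=end, tss=tss, strand=strand,
            )
        )
    return promoters


def write_promoters(promoters: Sequence[PromoterRegion], path: str | Path) -> None:
    lines = [
        f"{p.chrom}\t{p.window_start}\t{p.window_end}\t{p.gene_id}\t0\t{p.strand}"
        for p in promoters
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
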