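"""Priority-based annotation of peak regions against the genome partition.

Each peak is reduced to a single anchor (its summit, or the interval midpoint
when no summit is reported), expanded to a +/-flank region (default +/-100 bp,
a 201 bp window), and assigned the highest-priority category — TSS > TES >
GENE_BODY — whose bases overlap the region by at least ``min_overlap``
(default 10 bp); a region meeting the threshold in no gene-linked category is
INTERGENIC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_model import (CATEGORIES, CATEGORY_CODE, ChromSizes,
                           GenomePartition, Interval)
from .io_formats import PeakRecord


@dataclass(frozen=True)
class AnnotatedPeak:
    peak: PeakRecord
    anchor: int
    region: Interval
    category: str
    overlap_bp: dict[str, int]


@dataclass(frozen=True)
class CategoryDistribution:
    counts: dict[str, int]
    percentages: dict[str, float]
    total: int
    params: dict


def peak_anchor(peak: PeakRecord) -> int:
    """Summit position when present, else floor of the interval midpoint."""
    if peak.summit_offset is not None:
        return peak.start + peak.summit_offset
    return (peak.start + peak.end) // 2


def peak_region(anchor: int, chrom: str, chrom_sizes: ChromSizes,
                flank: int = 100) -> Interval:
    """[anchor - flank, anchor + flank + 1) clipped to the chromosome."""
    length = chrom_sizes[chrom]
    if not 0 <= anchor < length:
        raise ValueError(f"anchor {anchor} outside chromosome {chrom}")
    return Interval(chrom, max(0, anchor - flank), min(length, anchor + flank + 1))


def annotate_peak(region: Interval, partition: GenomePartition,
                  min_overlap: int = 10) -> tuple[str, dict[str, int]]:
    """Assign one region to a category by base overlap and priority.

    Overlap per category is the total base count of the region falling in
    that category's intervals (summed across intervals, not the largest
    single block).
    """
    starts, ends, cats = partition.arrays(region.chrom)
    lo = int(np.searchsorted(ends, region.start, side="right"))
    hi = int(np.searchsorted(starts, region.end, side="left"))
    overlap = np.zeros(4, dtype=np.int64)
    for i in range(lo, hi):
        ov = min(region.end, ends[i]) - max(region.start, starts[i])
        if ov > 0:
            overlap[cats[i]] += ov
    overlap_bp = {CATEGORIES[c]: int(overlap[c]) for c in range(4)}
    for cat in ("TSS", "TES", "GENE_BODY"):
        if overlap_bp[cat] >= min_overlap:
            return cat, overlap_bp
    return "INTERGENIC", overlap_bp


def annotate_peaks(peaks: list[PeakRecord], partition: GenomePartition,
                   chrom_sizes: ChromSizes, flank: int = 100,
                   min_overlap: int = 10) -> list[AnnotatedPeak]:
    """Batch annotation preserving input order."""
    out = []
    for peak in peaks:
        try:
            anchor = peak_anchor(peak)
            region = peak_region(anchor, peak.chrom, chrom_sizes, flank)
            category, overlap_bp = annotate_peak(region, partition, min_overlap)
        except (KeyError, ValueError) as exc:
            raise ValueError(f"peak {peak.name} "
                             f"({peak.chrom}:{peak.start}-{peak.end}): {exc}") from exc
        out.append(AnnotatedPeak(peak, anchor, region, category, overlap_bp))
    return out


def category_distribution(annotated: list[AnnotatedPeak],
                          params: dict | None = None) -> CategoryDistribution:
    """Counts and percentages per category over an annotated peak set."""
    if not annotated:
        raise ValueError("cannot summarize an empty peak list")
    counts = {cat: 0 for cat in CATEGORIES}
    for ap in annotated:
        counts[ap.category] += 1
    total = len(annotated)
    percentages = {cat: 100.0 * c / total for cat, c in counts.items()}
    return CategoryDistribution(counts, percentages, total, params or {})


def distribution_table(dist: CategoryDistribution,
                       genome_fractions: dict[str, float] | None = None
                       ) -> pd.DataFrame:
    """Tabular form, optionally alongside genome-wide category fractions."""
    rows = []
    for cat in CATEGORIES:
        row = {"category": cat, "count": dist.counts[cat],
               "percent": round(dist.percentages[cat], 4)}
        if genome_fractions is not None:
            row["genome_percent"] = round(100.0 * genome_fractions[cat], 4)
        rows.append(row)
    return pd.DataFrame(rows)


def annotated_to_bed(annotated: list[AnnotatedPeak], stream,
                     params: dict | None = None) -> None:
    """Write regions as BED with the category in the name column."""
    if params:
        stream.write("# " + " ".join(f"{k}={v}" for k, v in params.items()) + "\n")
    for ap in annotated:
        name = f"{ap.peak.name}|{ap.category}" if ap.peak.name != "." else ap.category
        stream.write(f"{ap.region.chrom}\t{ap.region.start}\t{ap.region.end}"
                     f"\t{name}\n")
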