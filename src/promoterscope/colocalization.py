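"""Pairwise and three-way peak-set colocalization.

Two peaks are considered to colocalize when their genomic intervals share at
least ``min_overlap`` bases (default 10).  Counting is per reference peak —
each reference peak is classified by which other sets it touches — so
overlap fractions are asymmetric and both directions are reported by the
pipeline.  The interval engine is an interval tree; the quadratic all-pairs
comparison lives in the test suite as the independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome_model import Interval


@dataclass
class OverlapResult:
    """Venn-style membership counts of a reference peak set against others.

    ``region_counts`` maps a sorted tuple of set names (always containing the
    reference) to the number of reference peaks overlapping exactly those
    sets; counts sum to the reference set size.
    """

    reference: str
    queries: list[str]
    membership: np.ndarray  # (n_ref, n_query) boolean
    region_counts: dict[tuple[str, ...], int]
    fractions: dict[str, float]  # per query: fraction of reference overlapped
    min_overlap: int

    def to_frame(self) -> pd.DataFrame:
        rows = [{"sets": "&".join(k), "reference_peaks": v}
                for k, v in self.region_counts.items()]
        return pd.DataFrame(rows)


def _trees(intervals: list[Interval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def peaks_overlapping(reference: list[Interval], query: list[Interval],
                      min_overlap: int = 10) -> np.ndarray:
    """Boolean flag per reference peak: shares >= min_overlap bases with some
    query peak on the same chromosome."""
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    trees = _trees(query)
    flags = np.zeros(len(reference), dtype=bool)
    for i, iv in enumerate(reference):
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(iv.start, iv.end):
            if min(iv.end, hit.end) - max(iv.start, hit.begin) >= min_overlap:
                flags[i] = True
                break
    return flags


def overlap_fraction(reference: list[Interval], query: list[Interval],
                     min_overlap: int = 10) -> float:
    """Fraction of reference peaks overlapped by the query set (asymmetric)."""
    if not reference:
        raise ValueError("reference set is empty")
    return float(peaks_overlapping(reference, query, min_overlap).mean())


def venn_counts(sets: dict[str, list[Interval]], reference: str,
                min_overlap: int = 10) -> OverlapResult:
    """Classify each reference peak by which other sets it overlaps.

    Accepts two or three named sets; ``reference`` names the set whose peaks
    are counted.
    """
    if reference not in sets:
        raise ValueError(f"reference set {reference!r} not among {list(sets)}")
    if not 2 <= len(sets) <= 3:
        raise ValueError("venn_counts needs two or three sets")
    queries = [n for n in sets if n != reference]
    ref_ivs = sets[reference]
    membership = np.column_stack([
        peaks_overlapping(ref_ivs, sets[q], min_overlap) for q in queries
    ]) if ref_ivs else np.zeros((0, len(queries)), dtype=bool)

    region_counts: dict[tuple[str, ...], int] = {}
    for r in range(len(queries) + 1):
        for combo in combinations(range(len(queries)), r):
            key = tuple(sorted([reference] + [queries[i] for i in combo]))
            mask = np.ones(len(ref_ivs), dtype=bool)
            for i in range(len(queries)):
                mask &= membership[:, i] if i in combo else ~membership[:, i]
            region_counts[key] = int(mask.sum())

    fractions = {}
    for j, q in enumerate(queries):
        fractions[q] = float(membership[:, j].mean()) if len(ref_ivs) else 0.0
    return OverlapResult(reference, queries, membership, region_counts,
                         fractions, min_overlap)


def pairwise_fraction_table(sets: dict[str, list[Interval]],
                            min_overlap: int = 10) -> pd.DataFrame:
    """Both directions of every pairwise overlap fraction."""
    rows = []
    for a in sets:
        for b in sets:
            if a == b:
                continue
            rows.append({
                "reference": a, "query": b,
                "n_reference": len(sets[a]),
                "fraction_overlapped": overlap_fraction(sets[a], sets[b],
                                                        min_overlap),
            })
    return pd.DataFrame(rows)
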