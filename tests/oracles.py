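"""Independent brute-force oracles used to check the fast implementations.

These deliberately share no code with the package: the partition oracle
labels every base of a dense array, the annotation oracle counts bases in
that array, and the overlap oracle compares all interval pairs.
"""

from __future__ import annotations

import numpy as np

from promoterscope.genome_model import (CATEGORIES, ChromSizes, GeneModel,
                                        Interval)

TSS, TES, GENE_BODY, INTERGENIC = range(4)


def brute_partition_labels(genes, chrom_sizes: ChromSizes,
                           tss_window=(200, 200), tes_window=(200, 200)
                           ) -> dict[str, np.ndarray]:
    """Per-base highest-priority category code for every chromosome."""
    labels = {c: np.full(l, INTERGENIC, dtype=np.int8)
              for c, l in chrom_sizes.items()}
    tss_up, tss_down = tss_window
    tes_up, tes_down = tes_window
    # paint in ascending priority so the last coat (TSS) wins everywhere
    for code in (GENE_BODY, TES, TSS):
        for g in genes:
            if code == GENE_BODY:
                s, e = g.start, g.end
            elif code == TES:
                s, e = ((g.end - tes_up, g.end + tes_down) if g.strand == "+"
                        else (g.start - tes_down, g.start + tes_up))
            else:
                s, e = ((g.start - tss_up, g.start + tss_down)
                        if g.strand == "+"
                        else (g.end - tss_down, g.end + tss_up))
            arr = labels[g.chrom]
            s, e = max(0, s), min(len(arr), e)
            arr[s:e] = code
    return labels


def brute_annotate(labels: dict[str, np.ndarray], region: Interval,
                   min_overlap: int = 10) -> tuple[str, dict[str, int]]:
    """Category of a region by counting bases in the dense label array."""
    window = labels[region.chrom][region.start:region.end]
    counts = {CATEGORIES[c]: int(np.sum(window == c)) for c in range(4)}
    for cat in ("TSS", "TES", "GENE_BODY"):
        if counts[cat] >= min_overlap:
            return cat, counts
    return "INTERGENIC", counts


def brute_overlap_flags(reference, query, min_overlap: int = 10) -> np.ndarray:
    """All-pairs O(n*m) overlap flags over the reference set.

    Every reference interval is compared against every query interval; the
    inner comparison is vectorized but no index or sort is used.
    """
    q_chrom = np.array([b.chrom for b in query])
    q_start = np.array([b.start for b in query], dtype=np.int64)
    q_end = np.array([b.end for b in query], dtype=np.int64)
    flags = np.zeros(len(reference), dtype=bool)
    for i, a in enumerate(reference):
        ov = np.minimum(a.end, q_end) - np.maximum(a.start, q_start)
        flags[i] = bool(np.any((q_chrom == a.chrom) & (ov >= min_overlap)))
    return flags


def random_genes(rng: np.random.Generator, chrom_sizes: ChromSizes,
                 n: int, max_len: int = 3000) -> list[GeneModel]:
    """Random (possibly overlapping) gene models for oracle comparisons."""
    chroms = list(chrom_sizes)
    genes = []
    for i in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        length = int(rng.integers(200, max_len))
        start = int(rng.integers(0, max(1, chrom_sizes[chrom] - length)))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"g{i}", chrom, start, start + length, strand))
    return genes


def random_intervals(rng: np.random.Generator, chrom_sizes: ChromSizes,
                     n: int, max_len: int = 400) -> list[Interval]:
    chroms = list(chrom_sizes)
    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        length = int(rng.integers(1, max_len))
        start = int(rng.integers(0, max(1, chrom_sizes[chrom] - length)))
        out.append(Interval(chrom, start, start + length))
    return out
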