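"""Chromosomes, gene models and the four-way genome partition.

The genome is labeled exhaustively, per base, into four categories derived
from gene annotations: transcription start site windows (TSS), transcription
end site windows (TES), the remaining transcribed gene body (GENE_BODY), and
everything else (INTERGENIC).  Where windows from different genes (or the TSS
and TES of one short gene) overlap, each base takes the highest-priority
category in the fixed order TSS > TES > GENE_BODY > INTERGENIC.  This module
also provides the two control-site samplers used by meta-profile analyses:
random gene promoters and random genomic positions.

Coordinates are 0-based half-open throughout; converters live at the I/O
boundary (GFF/GTF and WIG are 1-based on disk).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Category names in priority order (highest first).
CATEGORIES = ("TSS", "TES", "GENE_BODY", "INTERGENIC")
TSS, TES, GENE_BODY, INTERGENIC = range(4)
CATEGORY_CODE = {name: code for code, name in enumerate(CATEGORIES)}


@dataclass(frozen=True)
class Interval:
    """Half-open genomic span ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A gene span with strand; one TSS/TES per gene record."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: invalid span "
                             f"[{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -, "
                             f"got {self.strand!r}")


class ChromSizes:
    """Mapping of chromosome name to length in bp."""

    def __init__(self, entries: Mapping[str, int]):
        for name, length in entries.items():
            if length < 1:
                raise ValueError(f"chromosome {name}: length must be >= 1")
        self.entries: dict[str, int] = dict(entries)

    def __getitem__(self, name: str) -> int:
        return self.entries[name]

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def items(self):
        return self.entries.items()

    @property
    def genome_size(self) -> int:
        return sum(self.entries.values())

    @classmethod
    def read(cls, path_or_stream) -> "ChromSizes":
        """Read the standard two-column whitespace-separated chrom.sizes text."""
        close = False
        if isinstance(path_or_stream, (str, bytes)):
            stream = open(path_or_stream)
            close = True
        else:
            stream = path_or_stream
        try:
            entries: dict[str, int] = {}
            for lineno, line in enumerate(stream, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) < 2:
                    raise ValueError(f"chrom.sizes line {lineno}: expected "
                                     f"two columns, got {line!r}")
                name, length = parts[0], int(parts[1])
                if name in entries:
                    raise ValueError(f"chrom.sizes line {lineno}: duplicate "
                                     f"chromosome {name}")
                entries[name] = length
            return cls(entries)
        finally:
            if close:
                stream.close()

    def write(self, stream) -> None:
        for name, length in self.entries.items():
            stream.write(f"{name}\t{length}\n")


@dataclass
class SiteSet:
    """A named set of single-base anchor positions.

    ``metadata`` optionally carries one record per site (a gene_id for
    promoter anchors, a planted category label for synthetic sites).
    """

    name: str
    chroms: list[str]
    positions: np.ndarray
    metadata: list | None = None
    flank: int = 100

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("SiteSet name must be non-empty")
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if len(self.chroms) != len(self.positions):
            raise ValueError("chroms and positions length mismatch")
        if self.metadata is not None and len(self.metadata) != len(self.positions):
            raise ValueError("metadata length mismatch")

    def __len__(self) -> int:
        return len(self.positions)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        for c, p in zip(self.chroms, self.positions):
            yield c, int(p)

    def regions(self, chrom_sizes: ChromSizes, flank: int | None = None) -> list[Interval]:
        """Anchor +/- flank regions, clipped to chromosome bounds."""
        flank = self.flank if flank is None else flank
        out = []
        for c, p in self:
            length = chrom_sizes[c]
            out.append(Interval(c, max(0, p - flank), min(length, p + flank + 1)))
        return out


class GenomePartition:
    """Exhaustive per-base labeling of a genome into the four categories.

    Per chromosome the partition is stored as parallel sorted arrays
    (starts, ends, categories) that tile ``[0, length)`` exactly.
    """

    def __init__(self, chrom_sizes: ChromSizes,
                 per_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
                 tss_window: tuple[int, int], tes_window: tuple[int, int]):
        self.chrom_sizes = chrom_sizes
        self._per_chrom = per_chrom
        self.tss_window = tuple(tss_window)
        self.tes_window = tuple(tes_window)
        for chrom, (starts, ends, cats) in per_chrom.items():
            if len(starts) == 0:
                raise ValueError(f"{chrom}: empty partition")
            if starts[0] != 0 or ends[-1] != chrom_sizes[chrom]:
                raise ValueError(f"{chrom}: partition does not span chromosome")
            if not np.all(starts[1:] == ends[:-1]):
                raise ValueError(f"{chrom}: partition intervals do not tile")

    @property
    def chroms(self) -> list[str]:
        return list(self._per_chrom)

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if chrom not in self._per_chrom:
            raise KeyError(f"chromosome {chrom} not in partition")
        return self._per_chrom[chrom]

    def intervals(self, chrom: str) -> Iterator[tuple[Interval, str]]:
        starts, ends, cats = self.arrays(chrom)
        for s, e, c in zip(starts, ends, cats):
            yield Interval(chrom, int(s), int(e)), CATEGORIES[int(c)]

    def label_array(self, chrom: str) -> np.ndarray:
        """Dense per-base int8 category codes (for small chromosomes)."""
        starts, ends, cats = self.arrays(chrom)
        out = np.empty(self.chrom_sizes[chrom], dtype=np.int8)
        for s, e, c in zip(starts, ends, cats):
            out[s:e] = c
        return out

    def category_intervals(self, category: str) -> list[Interval]:
        code = CATEGORY_CODE[category]
        out = []
        for chrom in self.chroms:
            starts, ends, cats = self.arrays(chrom)
            mask = cats == code
            out.extend(Interval(chrom, int(s), int(e))
                       for s, e in zip(starts[mask], ends[mask]))
        return out

    def write_bed(self, stream) -> None:
        """BED4 (chrom, start, end, category), 0-based half-open."""
        stream.write(f"# tss_window={self.tss_window} tes_window={self.tes_window}\n")
        for chrom in self.chroms:
            for iv, cat in self.intervals(chrom):
                stream.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{cat}\n")


def gene_regions(gene: GeneModel, tss_window: tuple[int, int],
                 tes_window: tuple[int, int], chrom_length: int
                 ) -> list[tuple[int, int, int]]:
    """Candidate (start, end, category_code) spans for one gene, clipped.

    The TSS window is (upstream, downstream) around the strand-aware start,
    the TES window around the strand-aware end; for minus-strand genes
    upstream points toward larger coordinates.
    """
    tss_up, tss_down = tss_window
    tes_up, tes_down = tes_window
    if gene.strand == "+":
        spans = [(gene.start - tss_up, gene.start + tss_down, TSS),
                 (gene.end - tes_up, gene.end + tes_down, TES)]
    else:
        spans = [(gene.end - tss_down, gene.end + tss_up, TSS),
                 (gene.start - tes_down, gene.start + tes_up, TES)]
    spans.append((gene.start, gene.end, GENE_BODY))
    out = []
    for s, e, c in spans:
        s, e = max(0, s), min(chrom_length, e)
        if s < e:
            out.append((s, e, c))
    return out


def build_partition(genes: Sequence[GeneModel], chrom_sizes: ChromSizes,
                    tss_window: tuple[int, int] = (200, 200),
                    tes_window: tuple[int, int] = (200, 200)) -> GenomePartition:
    """Derive the four-way genome partition from gene models.

    Each base receives the highest-priority category among all candidate
    regions covering it (TSS > TES > GENE_BODY), INTERGENIC elsewhere.
    Windows are clipped at chromosome boundaries.
    """
    if min(*tss_window, *tes_window) < 0:
        raise ValueError("tss/tes windows must be non-negative")
    by_chrom: dict[str, list[tuple[int, int, int]]] = {c: [] for c in chrom_sizes}
    for gene in genes:
        if gene.chrom not in chrom_sizes:
            raise ValueError(f"gene {gene.gene_id}: unknown chromosome {gene.chrom}")
        length = chrom_sizes[gene.chrom]
        if gene.end > length:
            raise ValueError(f"gene {gene.gene_id}: span [{gene.start}, {gene.end}) "
                             f"exceeds chromosome {gene.chrom} length {length}")
        by_chrom[gene.chrom].extend(
            gene_regions(gene, tss_window, tes_window, length))

    per_chrom = {}
    for chrom, spans in by_chrom.items():
        length = chrom_sizes[chrom]
        per_chrom[chrom] = _sweep(spans, length)
    return GenomePartition(chrom_sizes, per_chrom, tss_window, tes_window)


def _sweep(spans: list[tuple[int, int, int]], length: int
           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    # Sweep-line over span endpoints keeping active counts per category;
    # each elementary segment takes the lowest active code (highest priority).
    events: list[tuple[int, int, int]] = []
    for s, e, c in spans:
        events.append((s, c, 1))
        events.append((e, c, -1))
    events.sort()
    active = [0, 0, 0]
    starts, ends, cats = [], [], []

    def emit(s: int, e: int, cat: int) -> None:
        if s >= e:
            return
        if cats and cats[-1] == cat and ends[-1] == s:
            ends[-1] = e  # merge run of the same label
        else:
            starts.append(s)
            ends.append(e)
            cats.append(cat)

    pos = 0
    i = 0
    n = len(events)
    while i < n:
        p = events[i][0]
        label = next((c for c in (TSS, TES, GENE_BODY) if active[c] > 0),
                     INTERGENIC)
        emit(pos, min(p, length), label)
        while i < n and events[i][0] == p:
            _, c, d = events[i]
            active[c] += d
            i += 1
        pos = min(p, length)
    label = next((c for c in (TSS, TES, GENE_BODY) if active[c] > 0), INTERGENIC)
    emit(pos, length, label)
    return (np.asarray(starts, dtype=np.int64),
            np.asarray(ends, dtype=np.int64),
            np.asarray(cats, dtype=np.int8))


def genome_category_fractions(partition: GenomePartition) -> dict[str, float]:
    """Fraction of genome bases per category; sums to 1 within 1e-12."""
    totals = np.zeros(4, dtype=np.int64)
    for chrom in partition.chroms:
        starts, ends, cats = partition.arrays(chrom)
        np.add.at(totals, cats, ends - starts)
    genome = partition.chrom_sizes.genome_size
    return {CATEGORIES[c]: totals[c] / genome for c in range(4)}


def tss_anchor(gene: GeneModel) -> int:
    """Promoter anchor position: strand-aware gene start, within bounds."""
    return gene.start if gene.strand == "+" else gene.end - 1


def sample_random_promoters(genes: Sequence[GeneModel], n: int, seed: int,
                            flank: int = 100) -> SiteSet:
    """Draw ``n`` distinct gene TSS anchors uniformly without replacement."""
    if n > len(genes):
        raise ValueError(f"requested {n} promoters but only {len(genes)} genes")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(genes), size=n, replace=False)
    idx.sort()
    chroms = [genes[i].chrom for i in idx]
    positions = np.array([tss_anchor(genes[i]) for i in idx], dtype=np.int64)
    meta = [genes[i].gene_id for i in idx]
    return SiteSet("random_promoters", chroms, positions, meta, flank=flank)


def sample_random_sites(chrom_sizes: ChromSizes, n: int, seed: int,
                        margin: int = 100) -> SiteSet:
    """Draw ``n`` anchors uniformly over the genome, >= margin from chromosome
    ends; chromosomes are chosen proportional to usable length."""
    names, usable = [], []
    for name, length in chrom_sizes.items():
        u = length - 2 * margin
        if u > 0:
            names.append(name)
            usable.append(u)
        else:
            logger.warning("chromosome %s (length %d) excluded: shorter than "
                           "2*margin=%d", name, length, 2 * margin)
    if not names:
        raise ValueError(f"no chromosome admits a site with margin {margin}")
    usable_arr = np.asarray(usable, dtype=np.float64)
    rng = np.random.default_rng(seed)
    which = rng.choice(len(names), size=n, p=usable_arr / usable_arr.sum())
    offsets = rng.integers(0, np.asarray(usable)[which])
    chroms = [names[i] for i in which]
    positions = margin + offsets.astype(np.int64)
    return SiteSet("random_sites", chroms, positions, flank=margin)


def read_genes(path_or_stream, file_format: str | None = None) -> list[GeneModel]:
    """Read gene records from GFF3 or GTF (feature type ``gene``).

    Other feature types are ignored with a logged count.  Coordinates are
    converted from the on-disk 1-based closed convention to 0-based half-open.
    """
    import gffutils

    db = gffutils.create_db(
        str(path_or_stream), dbfn=":memory:", force=True,
        merge_strategy="create_unique", keep_order=True)
    genes: list[GeneModel] = []
    skipped = 0
    seen: set[str] = set()
    for feat in db.all_features(order_by=("seqid", "start")):
        if feat.featuretype != "gene":
            skipped += 1
            continue
        gene_id = feat.attributes.get("ID", [feat.id])[0] \
            if "ID" in feat.attributes else \
            feat.attributes.get("gene_id", [feat.id])[0]
        if gene_id in seen:
            raise ValueError(f"duplicate gene_id {gene_id} in annotation")
        seen.add(gene_id)
        genes.append(GeneModel(gene_id=gene_id, chrom=feat.seqid,
                               start=feat.start - 1, end=feat.end,
                               strand=feat.strand))
    if skipped:
        logger.info("ignored %d non-gene features", skipped)
    return genes


def write_genes_gff3(genes: Iterable[GeneModel], stream) -> None:
    """Write gene records as minimal GFF3 (1-based closed on disk)."""
    stream.write("##gff-version 3\n")
    for g in genes:
        stream.write(f"{g.chrom}\tpromoterscope\tgene\t{g.start + 1}\t{g.end}"
                     f"\t.\t{g.strand}\t.\tID={g.gene_id}\n")
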