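"""Text-format I/O: BED peak tables, WIG signal tracks, TSV result tables.

Internal coordinates are 0-based half-open.  BED is native; WIG is 1-based on
disk and converted on read/write.  Signal tracks are dense per-base float
arrays per chromosome with NaN marking positions that carry no data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .genome_model import ChromSizes, Interval

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PeakRecord:
    """One peak call: half-open interval, optional score and summit offset."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float | None = None
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"peak {self.name}: invalid span "
                             f"[{self.start}, {self.end})")
        if self.summit_offset is not None and not (
                0 <= self.summit_offset < self.end - self.start):
            raise ValueError(f"peak {self.name}: summit offset "
                             f"{self.summit_offset} outside interval")

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end)


class SignalTrack:
    """Per-base signal values per chromosome; NaN means "no data"."""

    def __init__(self, chrom_sizes: ChromSizes):
        self.chrom_sizes = chrom_sizes
        self._data: dict[str, np.ndarray] = {}

    def values(self, chrom: str) -> np.ndarray:
        """Dense array for ``chrom`` (allocated NaN-filled on first access)."""
        if chrom not in self.chrom_sizes:
            raise KeyError(f"chromosome {chrom} not in chrom sizes")
        if chrom not in self._data:
            self._data[chrom] = np.full(self.chrom_sizes[chrom], np.nan)
        return self._data[chrom]

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self._data

    @property
    def chroms(self) -> list[str]:
        return list(self._data)

    def set_span(self, chrom: str, start: int, end: int, value: float) -> None:
        self.values(chrom)[start:end] = value

    def spans(self, chrom: str) -> Iterable[tuple[int, int, float]]:
        """Maximal constant-value runs of defined signal, sorted."""
        arr = self.values(chrom)
        n = len(arr)
        defined = ~np.isnan(arr)
        boundary = np.ones(n, dtype=bool)
        boundary[1:] = (defined[1:] != defined[:-1]) | (
            defined[1:] & defined[:-1] & (arr[1:] != arr[:-1]))
        starts = np.flatnonzero(boundary)
        ends = np.append(starts[1:], n)
        for s, e in zip(starts, ends):
            if defined[s]:
                yield int(s), int(e), float(arr[s])


def read_bed(stream, summit_column: bool = False) -> list[PeakRecord]:
    """Read BED3+ peak records in file order.

    track/browser/comment lines are permitted and skipped.  With
    ``summit_column=True`` column 7 is interpreted as a summit offset from
    the interval start (the common narrow-peak-style dialect).
    """
    records: list[PeakRecord] = []
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"BED line {lineno}: fewer than 3 columns")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ValueError(f"BED line {lineno}: non-numeric coordinate "
                             f"in {line!r}") from exc
        if start < 0 or start >= end:
            raise ValueError(f"BED line {lineno}: invalid interval "
                             f"[{start}, {end})")
        name = fields[3] if len(fields) > 3 and fields[3] else "."
        score = None
        if len(fields) > 4 and fields[4] not in (".", ""):
            score = float(fields[4])
        summit = None
        if summit_column and len(fields) > 6 and fields[6] not in (".", ""):
            summit = int(fields[6])
        try:
            records.append(PeakRecord(chrom, start, end, name, score, summit))
        except ValueError as exc:
            raise ValueError(f"BED line {lineno}: {exc}") from exc
    return records


def _fmt_score(score: float) -> str:
    return repr(score) if score != int(score) else str(int(score))


def write_bed(records: Sequence[PeakRecord], stream) -> None:
    """Write records in input order; read_bed inverts exactly."""
    for r in records:
        cols = [r.chrom, str(r.start), str(r.end)]
        if r.name != "." or r.score is not None or r.summit_offset is not None:
            cols.append(r.name)
        if r.score is not None or r.summit_offset is not None:
            cols.append(_fmt_score(r.score) if r.score is not None else ".")
        if r.summit_offset is not None:
            cols.extend([".", str(r.summit_offset)])
        stream.write("\t".join(cols) + "\n")


def _parse_wig_keywords(fields: list[str], lineno: int) -> dict[str, str]:
    out = {}
    for f in fields:
        if "=" not in f:
            raise ValueError(f"WIG line {lineno}: malformed keyword {f!r}")
        k, v = f.split("=", 1)
        out[k] = v
    return out


def read_wig(stream, chrom_sizes: ChromSizes) -> SignalTrack:
    """Read fixedStep / variableStep WIG (1-based) into a SignalTrack.

    Positions beyond a chromosome's length, or unknown chromosomes, are
    rejected with the offending line number.
    """
    track = SignalTrack(chrom_sizes)
    mode = None  # ("fixed", chrom, next_start0, step, span) or ("variable", chrom, span)
    for lineno, raw in enumerate(stream, 1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split()
        if fields[0] == "fixedStep":
            kw = _parse_wig_keywords(fields[1:], lineno)
            chrom = kw["chrom"]
            if chrom not in chrom_sizes:
                raise ValueError(f"WIG line {lineno}: unknown chromosome {chrom}")
            start0 = int(kw["start"]) - 1
            if start0 < 0:
                raise ValueError(f"WIG line {lineno}: start must be >= 1")
            mode = ["fixed", chrom, start0, int(kw.get("step", 1)),
                    int(kw.get("span", 1))]
        elif fields[0] == "variableStep":
            kw = _parse_wig_keywords(fields[1:], lineno)
            chrom = kw["chrom"]
            if chrom not in chrom_sizes:
                raise ValueError(f"WIG line {lineno}: unknown chromosome {chrom}")
            mode = ["variable", chrom, int(kw.get("span", 1))]
        elif mode is None:
            raise ValueError(f"WIG line {lineno}: data before any declaration")
        elif mode[0] == "fixed":
            _, chrom, start0, step, span = mode
            end = start0 + span
            if end > chrom_sizes[chrom]:
                raise ValueError(f"WIG line {lineno}: span [{start0}, {end}) "
                                 f"beyond chromosome {chrom} length")
            track.set_span(chrom, start0, end, float(fields[0]))
            mode[2] = start0 + step
        else:
            _, chrom, span = mode
            start0 = int(fields[0]) - 1
            end = start0 + span
            if start0 < 0 or end > chrom_sizes[chrom]:
                raise ValueError(f"WIG line {lineno}: span [{start0}, {end}) "
                                 f"outside chromosome {chrom}")
            track.set_span(chrom, start0, end, float(fields[1]))
    return track


def write_wig(track: SignalTrack, stream) -> None:
    """Emit per-base fixedStep blocks; read_wig inverts exactly.

    Values print with repr so floats round-trip bit-exactly.
    """
    for chrom in track.chroms:
        arr = track.values(chrom)
        n = len(arr)
        defined = ~np.isnan(arr)
        if not defined.any():
            continue
        boundary = np.empty(n, dtype=bool)
        boundary[0] = True
        boundary[1:] = defined[1:] != defined[:-1]
        starts = np.flatnonzero(boundary)
        ends = np.append(starts[1:], n)
        for s, e in zip(starts, ends):
            if not defined[s]:
                continue
            stream.write(f"fixedStep chrom={chrom} start={s + 1} step=1\n")
            stream.write("\n".join(repr(float(v)) for v in arr[s:e]) + "\n")


def write_tsv(df, stream, params: dict | None = None, version: str | None = None) -> None:
    """Write a result table with a commented header recording parameters."""
    from . import __version__

    header = f"# promoterscope {version or __version__}"
    if params:
        header += " " + " ".join(f"{k}={v}" for k, v in params.items())
    stream.write(header + "\n")
    df.to_csv(stream, sep="\t", index=False)
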