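"""Genomic intervals, peak sets, BED/narrowPeak I/O and overlap arithmetic.

Coordinates are 0-based, half-open (BED convention) throughout. A ``Peak``
carries the per-library read counts needed for the background-subtracted
enrichment statistic; ``enrichment`` is ``None`` until annotated (and stays
``None`` when the statistic is undefined, i.e. ChIP signal does not exceed
input).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "Peak",
    "PeakSet",
    "RegionParseError",
    "read_regions",
    "write_regions",
    "overlap_fraction",
    "overlapping_mask",
    "quintile_overlap",
]


class RegionParseError(ValueError):
    """Malformed line in a BED/narrowPeak file (reports the line number)."""


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""
    score: float = 0.0

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class Peak:
    """A called binding site with summit and per-library read counts."""

    interval: GenomicInterval
    summit_offset: int = 0
    chip_count: int = 0
    input_count: int = 0
    chip_libsize: int = 1
    input_libsize: int = 1
    enrichment: float | None = None

    def __post_init__(self) -> None:
        if self.summit_offset < 0:
            raise ValueError("summit_offset must be >= 0")
        if self.interval.start + self.summit_offset >= self.interval.end:
            raise ValueError("summit falls outside the peak interval")
        if self.chip_libsize <= 0 or self.input_libsize <= 0:
            raise ValueError("library sizes must be positive")
        if self.chip_count > self.chip_libsize or self.input_count > self.input_libsize:
            raise ValueError("read count exceeds library size")

    @property
    def name(self) -> str:
        return self.interval.name

    @property
    def summit(self) -> int:
        """Absolute genomic position of the summit."""
        return self.interval.start + self.summit_offset


class PeakSet:
    """Ordered collection of uniquely named peaks from one sample."""

    def __init__(self, peaks: Iterable[Peak] = (), label: str = "") -> None:
        self.peaks: list[Peak] = list(peaks)
        self.label = label
        names = [p.name for p in self.peaks]
        if len(set(names)) != len(names):
            dupes = {n for n in names if names.count(n) > 1}
            raise ValueError(f"duplicate peak names in set: {sorted(dupes)[:5]}")
        self._by_name = {p.name: p for p in self.peaks}

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __getitem__(self, name: str) -> Peak:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def tree_by_chrom(self) -> dict[str, IntervalTree]:
        trees: dict[str, IntervalTree] = {}
        for p in self.peaks:
            trees.setdefault(p.interval.chrom, IntervalTree()).addi(
                p.interval.start, p.interval.end, p.name
            )
        return trees


def _parse_int(token: str, what: str, lineno: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise RegionParseError(
            f"line {lineno}: non-integer {what} {token!r}"
        ) from None


def read_regions(path, format: str = "narrowPeak", label: str = "") -> PeakSet:
    """Read a BED3/BED6 or ENCODE narrowPeak file into a :class:`PeakSet`.

    narrowPeak column 10 (0-based summit offset from start) populates the
    summit; plain BED summits default to the interval midpoint. Peaks without
    a name field are named ``peak_<lineno>``.
    """
    if format not in {"bed", "narrowPeak"}:
        raise ValueError(f"unknown format {format!r}")
    min_cols = 10 if format == "narrowPeak" else 3
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < min_cols:
                raise RegionParseError(
                    f"line {lineno}: expected >= {min_cols} columns, got {len(cols)}"
                )
            chrom = cols[0]
            start = _parse_int(cols[1], "start", lineno)
            end = _parse_int(cols[2], "end", lineno)
            if start >= end:
                raise RegionParseError(
                    f"line {lineno}: start {start} >= end {end}"
                )
            name = cols[3] if len(cols) > 3 and cols[3] not in {"", "."} else f"peak_{lineno}"
            score = float(cols[4]) if len(cols) > 4 and cols[4] != "." else 0.0
            strand = cols[5] if len(cols) > 5 and cols[5] in {"+", "-"} else "."
            if format == "narrowPeak":
                summit = _parse_int(cols[9], "summit offset", lineno)
                if summit < 0:
                    summit = (end - start) // 2
            else:
                summit = (end - start) // 2
            try:
                peaks.append(
                    Peak(
                        interval=GenomicInterval(chrom, start, end, strand, name, score),
                        summit_offset=summit,
                    )
                )
            except ValueError as exc:
                raise RegionParseError(f"line {lineno}: {exc}") from None
    return PeakSet(peaks, label=label or str(path))


def write_regions(peaks: PeakSet, path, format: str = "narrowPeak") -> None:
    """Write BED6 or 10-column narrowPeak (signalValue = enrichment)."""
    if format not in {"bed", "narrowPeak"}:
        raise ValueError(f"unknown format {format!r}")
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            base = [iv.chrom, str(iv.start), str(iv.end), iv.name,
                    str(int(iv.score)), iv.strand]
            if format == "narrowPeak":
                signal = 0.0 if p.enrichment is None else p.enrichment
                base += [f"{signal:.4f}", "-1", "-1", str(p.summit_offset)]
            fh.write("\t".join(base) + "\n")


def overlapping_mask(a: PeakSet, b: PeakSet, min_bp: int = 1) -> np.ndarray:
    """Boolean mask over ``a`` marking peaks that overlap ``b`` by >= min_bp."""
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    trees = b.tree_by_chrom()
    mask = np.zeros(len(a), dtype=bool)
    for i, p in enumerate(a):
        tree = trees.get(p.interval.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(p.interval.start, p.interval.end):
            ov = min(p.interval.end, hit.end) - max(p.interval.start, hit.begin)
            if ov >= min_bp:
                mask[i] = True
                break
    return mask


def overlap_fraction(a: PeakSet, b: PeakSet, min_bp: int = 1) -> float:
    """Fraction of peaks in ``a`` overlapping any peak in ``b`` by >= min_bp.

    Counted peak-wise: a peak of ``a`` hitting several peaks of ``b`` counts
    once. An empty ``a`` yields 0.0.
    """
    if len(a) == 0:
        return 0.0
    return float(overlapping_mask(a, b, min_bp).mean())


def quintile_overlap(a: PeakSet, b: PeakSet, min_bp: int = 1) -> np.ndarray:
    """Per-enrichment-quintile overlap fractions of ``a`` with ``b``.

    Peaks of ``a`` are ranked by enrichment ascending (ties broken by name),
    split into 5 bins Q1..Q5 whose sizes differ by at most one (any remainder
    goes to the lowest bins); Q5 holds the highest-enrichment peaks. Returns
    the fraction of each bin overlapping ``b``.
    """
    n = len(a)
    if n < 5:
        raise ValueError(f"need at least 5 peaks for quintiles, got {n}")
    for p in a:
        if p.enrichment is None:
            raise ValueError(f"peak {p.name!r} has undefined enrichment")
    order = sorted(range(n), key=lambda i: (a.peaks[i].enrichment, a.peaks[i].name))
    mask = overlapping_mask(a, b, min_bp)
    base, rem = divmod(n, 5)
    sizes = [base + 1 if q < rem else base for q in range(5)]
    out = np.empty(5)
    pos = 0
    for q, size in enumerate(sizes):
        idx = order[pos:pos + size]
        out[q] = mask[idx].mean()
        pos += size
    return out
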