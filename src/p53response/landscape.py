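"""Peak enrichment and chromatin-state classification of binding sites.

Enrichment is the log2 of the input-subtracted ChIP signal on the
reads-per-million scale: log2(rpm(ChIP) - rpm(input)). When the ChIP signal
does not exceed input the statistic is undefined and the peak is flagged
(``enrichment is None``) rather than floored, so rankings never contain
artifacts.

Binding sites are partitioned into three classes with strict precedence:
PROMOTER (overlapping a strand-aware -5 kb/+2 kb TSS window), else ENHANCER
(overlapping an H3K4me1 peak), else UNMARKED_DISTAL (everything else) — the
last being candidate "proto-enhancers" in closed chromatin.
"""

from __future__ import annotations

from enum import Enum
from typing import Mapping

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, Peak, PeakSet, overlap_fraction, overlapping_mask
from .motif import MotifClass

__all__ = [
    "PeakClass",
    "normalized_count",
    "peak_enrichment",
    "annotate_enrichment",
    "promoter_window",
    "promoter_windows_from_genes",
    "classify_peaks",
    "mark_overlap_summary",
    "motif_by_class",
    "REQUIRED_ENHANCER_MARK",
]

REQUIRED_ENHANCER_MARK = "H3K4me1"


class PeakClass(Enum):
    PROMOTER = "promoter"
    ENHANCER = "enhancer"
    UNMARKED_DISTAL = "unmarked_distal"


def normalized_count(reads: int, libsize: int) -> float:
    """Reads per million library reads."""
    if libsize <= 0:
        raise ValueError("library size must be positive")
    if reads < 0:
        raise ValueError("read count must be non-negative")
    return reads * 1e6 / libsize


def peak_enrichment(peak: Peak) -> float | None:
    """log2 of the rpm difference between ChIP and input; None if <= 0."""
    diff = normalized_count(peak.chip_count, peak.chip_libsize) - normalized_count(
        peak.input_count, peak.input_libsize
    )
    if diff <= 0:
        return None
    return float(np.log2(diff))


def annotate_enrichment(peaks: PeakSet) -> PeakSet:
    """Set ``enrichment`` on every peak in place; returns the same set."""
    for p in peaks:
        p.enrichment = peak_enrichment(p)
    return peaks


def promoter_window(
    tss: int,
    strand: str,
    up: int = 5000,
    down: int = 2000,
    chrom_len: int | None = None,
    chrom: str = "",
    name: str = "",
) -> GenomicInterval:
    """Strand-aware promoter window: -up/+down around the TSS, clamped.

    On '+' the window is [tss-up, tss+down); on '-' it is mirrored,
    [tss-down, tss+up).
    """
    if strand not in {"+", "-"}:
        raise ValueError(f"strand must be + or -, got {strand!r}")
    if tss < 0 or (chrom_len is not None and tss >= chrom_len):
        raise ValueError(f"TSS {tss} outside chromosome of length {chrom_len}")
    if strand == "+":
        start, end = tss - up, tss + down
    else:
        start, end = tss - down, tss + up
    start = max(0, start)
    if chrom_len is not None:
        end = min(end, chrom_len)
    return GenomicInterval(chrom or "chr", start, end, strand, name)


def promoter_windows_from_genes(
    genes: pd.DataFrame,
    up: int = 5000,
    down: int = 2000,
    chrom_lengths: Mapping[str, int] | None = None,
) -> PeakSet:
    """Promoter windows for a gene table with columns gene_id/chrom/strand/tss."""
    windows = []
    for row in genes.itertuples():
        clen = chrom_lengths.get(row.chrom) if chrom_lengths else None
        iv = promoter_window(
            int(row.tss), row.strand, up=up, down=down,
            chrom_len=clen, chrom=row.chrom, name=str(row.gene_id),
        )
        windows.append(Peak(interval=iv, summit_offset=len(iv) // 2))
    return PeakSet(windows, label="promoters")


def classify_peaks(
    peaks: PeakSet,
    promoters: PeakSet,
    marks: Mapping[str, PeakSet],
    min_bp: int = 1,
    summit_only: bool = False,
) -> tuple[dict[str, PeakClass], dict[PeakClass, int]]:
    """Assign each peak to PROMOTER > ENHANCER > UNMARKED_DISTAL.

    ``summit_only`` restricts the overlap test to the 1-bp summit position
    instead of the whole peak interval.
    """
    if REQUIRED_ENHANCER_MARK not in marks:
        raise ValueError(f"marks must include {REQUIRED_ENHANCER_MARK}")
    query = peaks
    if summit_only:
        query = PeakSet(
            [
                Peak(
                    interval=GenomicInterval(
                        p.interval.chrom, p.summit, p.summit + 1, name=p.name
                    )
                )
                for p in peaks
            ],
            label=peaks.label,
        )
    prom_mask = overlapping_mask(query, promoters, min_bp)
    enh_mask = overlapping_mask(query, marks[REQUIRED_ENHANCER_MARK], min_bp)
    classes: dict[str, PeakClass] = {}
    counts = {cls: 0 for cls in PeakClass}
    for i, p in enumerate(peaks):
        if prom_mask[i]:
            cls = PeakClass.PROMOTER
        elif enh_mask[i]:
            cls = PeakClass.ENHANCER
        else:
            cls = PeakClass.UNMARKED_DISTAL
        classes[p.name] = cls
        counts[cls] += 1
    return classes, counts


def mark_overlap_summary(
    peaks: PeakSet,
    classes: Mapping[str, PeakClass],
    marks: Mapping[str, PeakSet],
    min_bp: int = 1,
) -> pd.DataFrame:
    """Percent of peaks of each class overlapping each chromatin mark."""
    rows = {}
    for cls in PeakClass:
        subset = PeakSet(
            [p for p in peaks if classes[p.name] == cls], label=cls.value
        )
        rows[cls.value] = {
            mark: 100.0 * overlap_fraction(subset, mset, min_bp)
            for mark, mset in marks.items()
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def motif_by_class(
    classes: Mapping[str, PeakClass],
    motif_classes: Mapping[str, MotifClass],
) -> pd.DataFrame:
    """Percent of peaks per chromatin class carrying any p53 motif."""
    if set(classes) != set(motif_classes):
        raise ValueError("peak class and motif class assignments cover different peaks")
    rows = []
    for cls in PeakClass:
        names = [n for n, c in classes.items() if c == cls]
        with_motif = sum(
            1 for n in names if motif_classes[n] != MotifClass.NO_MOTIF
        )
        pct = 100.0 * with_motif / len(names) if names else float("nan")
        rows.append({"peak_class": cls.value, "n": len(names), "pct_with_motif": pct})
    return pd.DataFrame(rows).set_index("peak_class")
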