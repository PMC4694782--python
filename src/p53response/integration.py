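"""Joining binding, motif, chromatin and regulation layers per gene.

A gene is "p53-bound" when at least one peak overlaps its strand-aware
promoter window (-5/+2 kb around the TSS). When several peaks qualify, the
gene inherits the single peak whose best motif hit has the lowest p-value
(then highest enrichment, then name order), keeping the per-gene motif
category well defined for the regulatory cross-tabulations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .intervals import PeakSet
from .landscape import promoter_windows_from_genes
from .motif import MotifClass, MotifHit, group_compare
from .expression import RegulatoryMode

__all__ = [
    "GenePeakLink",
    "link_genes_to_peaks",
    "regulatory_crosstab",
    "fc_by_category",
    "core_response",
]


@dataclass
class GenePeakLink:
    gene_id: str
    peak_name: str | None
    motif_class: MotifClass
    best_hit: MotifHit | None

    def __post_init__(self) -> None:
        if self.peak_name is None and (
            self.motif_class != MotifClass.NO_MOTIF or self.best_hit is not None
        ):
            raise ValueError("unbound gene cannot carry a motif class or hit")

    @property
    def bound(self) -> bool:
        return self.peak_name is not None


def link_genes_to_peaks(
    genes: pd.DataFrame,
    peaks: PeakSet,
    hits: Mapping[str, MotifHit | None],
    up: int = 5000,
    down: int = 2000,
) -> dict[str, GenePeakLink]:
    """Link each gene to its best promoter-window peak (or to none)."""
    windows = promoter_windows_from_genes(genes, up=up, down=down)
    trees = peaks.tree_by_chrom()
    links: dict[str, GenePeakLink] = {}
    for win in windows:
        gene_id = win.name
        tree = trees.get(win.interval.chrom)
        overlapping = (
            sorted(tree.overlap(win.interval.start, win.interval.end),
                   key=lambda h: h.data)
            if tree is not None
            else []
        )
        if not overlapping:
            links[gene_id] = GenePeakLink(gene_id, None, MotifClass.NO_MOTIF, None)
            continue

        def rank(h):
            peak = peaks[h.data]
            hit = hits.get(h.data)
            pval = hit.pvalue if hit is not None else 2.0
            enr = peak.enrichment if peak.enrichment is not None else -np.inf
            return (pval, -enr, h.data)

        best = min(overlapping, key=rank)
        hit = hits.get(best.data)
        links[gene_id] = GenePeakLink(
            gene_id,
            best.data,
            MotifClass.NO_MOTIF if hit is None else hit.motif_class,
            hit,
        )
    return links


def regulatory_crosstab(
    links: Mapping[str, GenePeakLink],
    modes: Mapping[str, RegulatoryMode],
) -> pd.DataFrame:
    """Bound-gene counts and row percentages by regulatory mode x motif class."""
    missing = set(links) - set(modes)
    if missing:
        raise ValueError(f"genes without a regulatory mode: {sorted(missing)[:5]}")
    rows = []
    for gene_id, link in links.items():
        if link.bound:
            rows.append(
                {"mode": modes[gene_id].value, "motif_class": link.motif_class.value}
            )
    if not rows:
        return pd.DataFrame(
            columns=[m.value for m in MotifClass],
            index=pd.Index([], name="mode"),
        )
    df = pd.DataFrame(rows)
    counts = pd.crosstab(df["mode"], df["motif_class"])
    counts = counts.reindex(columns=[m.value for m in MotifClass], fill_value=0)
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    out = counts.copy()
    for col in pct.columns:
        out[f"{col}_pct"] = pct[col]
    return out


def fc_by_category(
    modes: Mapping[str, RegulatoryMode],
    motif_classes: Mapping[str, MotifClass],
    log2fc: Mapping[str, float],
) -> dict:
    """log2 fold-change summaries per (mode, motif class) group + t-tests.

    Groups with fewer than two genes are reported with their n only and
    excluded from pairwise testing.
    """
    groups: dict[tuple[str, str], list[float]] = {}
    for gene, mode in modes.items():
        if gene not in motif_classes or gene not in log2fc:
            continue
        key = (mode.value, motif_classes[gene].value)
        groups.setdefault(key, []).append(float(log2fc[gene]))
    testable = {k: v for k, v in groups.items() if len(v) >= 2}
    singletons = {k: len(v) for k, v in groups.items() if len(v) < 2}
    result = group_compare(testable) if testable else {"summaries": {}, "tests": {}}
    result["excluded_singletons"] = singletons
    return result


def core_response(set_a: set[str], set_b: set[str]) -> dict:
    """Intersection of the two cell types' dependent/bound/unsplit gene sets."""
    core = set_a & set_b
    return {
        "core": core,
        "n_core": len(core),
        "fraction_a": len(core) / len(set_a) if set_a else 0.0,
        "fraction_b": len(core) / len(set_b) if set_b else 0.0,
    }
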