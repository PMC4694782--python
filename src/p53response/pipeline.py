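"""End-to-end pipeline: enrichment -> discovery -> scan -> classify -> DE
-> dependence -> integration, with a deterministic output manifest.

Every stage writes a plain-text table into the output directory; the
manifest records the configuration hash, per-table SHA-256 digests and
record counts, and an overall manifest hash that is reproducible byte for
byte given the same inputs, seed and thresholds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import memeio
from .discovery import discover_motif, top_peaks
from .expression import assign_modes, call_degs, nb_de_test, rpkm
from .integration import link_genes_to_peaks, regulatory_crosstab
from .intervals import PeakSet, read_regions
from .landscape import (annotate_enrichment, classify_peaks,
                        mark_overlap_summary, motif_by_class)
from .motif import MotifClass, build_spaced_pwm, p53_consensus_pwm, scan_window

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Input paths and analysis thresholds for one pipeline run."""

    peaks: str
    peak_counts: str
    genome: str
    genes: str
    marks: dict[str, str]
    counts: str
    meta: str
    outdir: str
    seed: int = 0
    motif_pvalue: float = 1e-4
    deg_q: float = 0.05
    deg_lfc: float = 0.58
    dependence_ratio: float = 1.5
    promoter_up: int = 5000
    promoter_down: int = 2000
    top_n: int = 1000
    expressed_rpkm: float = 1.0
    flank: int = 300
    motif_width: int = 20
    scan_pwm: str = "discovered"  # or "consensus"

    def threshold_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # hash over thresholds/seed and input basenames, not absolute paths
        for key in ("peaks", "peak_counts", "genome", "genes", "counts", "meta"):
            d[key] = os.path.basename(d[key])
        d["marks"] = {k: os.path.basename(v) for k, v in sorted(self.marks.items())}
        d.pop("outdir")
        return d


def _sha256_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _count_records(path: str) -> int:
    with open(path) as fh:
        return max(0, sum(1 for _ in fh) - 1)


def _read_fasta(path: str) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is not None:
                seqs[name].append(line.upper())
    return {k: "".join(v) for k, v in seqs.items()}


def _summit_window(seq: str, summit: int, flank: int) -> str:
    return seq[max(0, summit - flank):summit + flank]


STAGES = ("enrich", "discover", "scan", "classify", "de", "dependence", "integrate")


def run_pipeline(cfg: RunConfig, until: str = "integrate") -> dict:
    """Execute stages in order up to ``until``; returns the manifest.

    The manifest (also written to ``outdir/manifest.json``) covers the
    outputs actually produced.
    """
    if until not in STAGES:
        raise ValueError(f"unknown stage {until!r}")
    stop_after = STAGES.index(until)
    os.makedirs(cfg.outdir, exist_ok=True)
    outputs: dict[str, str] = {}
    log: list[dict] = []

    def emit(name: str, path: str, n: int):
        outputs[name] = path
        log.append({"stage": name, "records": n})

    def out(name: str) -> str:
        return os.path.join(cfg.outdir, name)

    # --- enrichment -------------------------------------------------------
    try:
        peaks = read_regions(cfg.peaks, format="narrowPeak")
        pc = pd.read_csv(cfg.peak_counts, sep="\t").set_index("peak_name")
        for p in peaks:
            row = pc.loc[p.name]
            p.chip_count = int(row["chip_count"])
            p.input_count = int(row["input_count"])
            p.chip_libsize = int(row["chip_libsize"])
            p.input_libsize = int(row["input_libsize"])
        annotate_enrichment(peaks)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("enrich", str(exc)) from exc
    enr = pd.DataFrame({
        "peak_name": [p.name for p in peaks],
        "enrichment": [p.enrichment if p.enrichment is not None else np.nan
                       for p in peaks],
    })
    path = out("peaks_enrichment.tsv")
    enr.to_csv(path, sep="\t", index=False, float_format="%.6f")
    emit("peaks_enrichment", path, len(enr))
    if stop_after == 0:
        return _write_manifest(cfg, outputs, log)

    # --- motif discovery --------------------------------------------------
    try:
        genome = _read_fasta(cfg.genome)
        defined = PeakSet([p for p in peaks if p.enrichment is not None],
                          label=peaks.label)
        top = top_peaks(defined, n=cfg.top_n)
        seqs = [
            _summit_window(genome[p.interval.chrom], p.summit, cfg.flank)
            for p in top
        ]
        seqs = [s for s in seqs if len(s) >= cfg.motif_width]
        disc = discover_motif(
            seqs, width=cfg.motif_width, seed=cfg.seed, n_restarts=5,
        )
    except Exception as exc:
        raise PipelineError("discover", str(exc)) from exc
    path = out("motif_discovered.meme")
    memeio.write_meme({"discovered": disc.pwm}, path)
    emit("motif_discovered", path, 1)
    if stop_after == 1:
        return _write_manifest(cfg, outputs, log)

    # --- motif scanning ---------------------------------------------------
    try:
        if cfg.scan_pwm == "consensus" or disc.pwm.width != 20:
            scan_base = p53_consensus_pwm()
        else:
            scan_base = disc.pwm
        model = build_spaced_pwm(scan_base)
        hits = {}
        for p in peaks:
            window = _summit_window(genome[p.interval.chrom], p.summit, cfg.flank)
            hits[p.name] = scan_window(
                window, model, threshold=cfg.motif_pvalue, peak_name=p.name
            )
    except Exception as exc:
        raise PipelineError("scan", str(exc)) from exc
    hit_rows = []
    for name, hit in hits.items():
        if hit is None:
            hit_rows.append({"peak_name": name, "offset": -1, "strand": ".",
                             "spacer": -1, "score": np.nan, "pvalue": np.nan,
                             "matched_seq": ""})
        else:
            hit_rows.append({"peak_name": name, "offset": hit.offset,
                             "strand": hit.strand, "spacer": hit.spacer,
                             "score": round(hit.score, 4),
                             "pvalue": float(f"{hit.pvalue:.6g}"),
                             "matched_seq": hit.matched_seq})
    path = out("motif_hits.tsv")
    pd.DataFrame(hit_rows).to_csv(path, sep="\t", index=False)
    emit("motif_hits", path, len(hit_rows))
    motif_classes = {
        name: (MotifClass.NO_MOTIF if h is None else h.motif_class)
        for name, h in hits.items()
    }
    if stop_after == 2:
        return _write_manifest(cfg, outputs, log)

    # --- chromatin classification ------------------------------------------
    try:
        genes = pd.read_csv(cfg.genes, sep="\t")
        marks = {m: read_regions(pth, format="bed") for m, pth in cfg.marks.items()}
        from .landscape import promoter_windows_from_genes
        promoters = promoter_windows_from_genes(
            genes, up=cfg.promoter_up, down=cfg.promoter_down
        )
        classes, counts = classify_peaks(peaks, promoters, marks)
    except Exception as exc:
        raise PipelineError("classify", str(exc)) from exc
    path = out("peak_classes.tsv")
    pd.DataFrame({
        "peak_name": list(classes),
        "peak_class": [c.value for c in classes.values()],
        "motif_class": [motif_classes[n].value for n in classes],
    }).to_csv(path, sep="\t", index=False)
    emit("peak_classes", path, len(classes))
    path = out("mark_overlap.tsv")
    mark_overlap_summary(peaks, classes, marks).to_csv(
        path, sep="\t", float_format="%.4f"
    )
    emit("mark_overlap", path, 3)
    path = out("motif_by_class.tsv")
    motif_by_class(classes, motif_classes).to_csv(path, sep="\t", float_format="%.4f")
    emit("motif_by_class", path, 3)
    if stop_after == 3:
        return _write_manifest(cfg, outputs, log)

    # --- differential expression -------------------------------------------
    try:
        counts_df = pd.read_csv(cfg.counts, sep="\t", index_col=0)
        meta = pd.read_csv(cfg.meta, sep="\t", index_col=0)
        gene_info = genes.set_index("gene_id")
        lengths = gene_info["exon_length"].reindex(counts_df.index)
        totals = counts_df.sum(axis=0)
        rpkm_mat = rpkm(counts_df, lengths, totals)
        de_wt = nb_de_test(counts_df, meta, genotype="WT")
        de_ko = nb_de_test(counts_df, meta, genotype="KO")
    except Exception as exc:
        raise PipelineError("de", str(exc)) from exc
    for label, de in (("de_wt", de_wt), ("de_ko", de_ko)):
        path = out(f"{label}.tsv")
        de.round(6).to_csv(path, sep="\t")
        emit(label, path, len(de))
    if stop_after == 4:
        return _write_manifest(cfg, outputs, log)

    # --- dependence ---------------------------------------------------------
    try:
        modes = assign_modes(
            de_wt, de_ko, rpkm_mat,
            q_threshold=cfg.deg_q, lfc_threshold=cfg.deg_lfc,
            min_rpkm=cfg.expressed_rpkm,
        )
    except Exception as exc:
        raise PipelineError("dependence", str(exc)) from exc
    path = out("regulatory_modes.tsv")
    modes.map(lambda m: m.value).rename("mode").to_csv(path, sep="\t")
    emit("regulatory_modes", path, len(modes))
    if stop_after == 5:
        return _write_manifest(cfg, outputs, log)

    # --- integration ---------------------------------------------------------
    try:
        links = link_genes_to_peaks(
            genes, peaks, hits, up=cfg.promoter_up, down=cfg.promoter_down
        )
        crosstab = regulatory_crosstab(links, modes.to_dict())
    except Exception as exc:
        raise PipelineError("integrate", str(exc)) from exc
    path = out("gene_peak_links.tsv")
    pd.DataFrame([
        {"gene_id": l.gene_id,
         "peak_name": l.peak_name or "",
         "motif_class": l.motif_class.value}
        for l in links.values()
    ]).to_csv(path, sep="\t", index=False)
    emit("gene_peak_links", path, len(links))
    path = out("regulatory_crosstab.tsv")
    crosstab.round(4).to_csv(path, sep="\t")
    emit("regulatory_crosstab", path, len(crosstab))

    return _write_manifest(cfg, outputs, log)


def _write_manifest(cfg: RunConfig, outputs: dict[str, str], log: list[dict]) -> dict:
    config = cfg.threshold_dict()
    config_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()
    ).hexdigest()
    table = {
        name: {
            "file": os.path.basename(pth),
            "sha256": _sha256_file(pth),
            "records": _count_records(pth),
        }
        for name, pth in outputs.items()
    }
    manifest_hash = hashlib.sha256(
        json.dumps({"config": config_hash, "outputs": table}, sort_keys=True).encode()
    ).hexdigest()
    manifest = {
        "config": config,
        "config_hash": config_hash,
        "outputs": table,
        "log": log,
        "manifest_hash": manifest_hash,
    }
    with open(os.path.join(cfg.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
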