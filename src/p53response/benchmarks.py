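"""Synthetic-truth validation experiments for every pipeline stage.

Each function builds its own synthetic inputs with planted ground truth,
runs the corresponding part of the pipeline, and returns the measured
recovery/calibration quantities. These are the package's standing
correctness experiments; the test suite asserts on their outputs and the
acceptance script reports them.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd

from .discovery import discover_motif
from .expression import (RegulatoryMode, assign_modes, call_degs,
                         nb_de_test, rpkm)
from .integration import core_response, link_genes_to_peaks
from .intervals import PeakSet, quintile_overlap
from .landscape import annotate_enrichment, classify_peaks, promoter_windows_from_genes
from .motif import (MotifClass, Pwm, build_spaced_pwm, log_odds_score,
                    p53_consensus_pwm, scan_window, score_pvalue, score_pvalues,
                    group_compare, encode_sequence)
from .simulate import (SimConfig, sample_site, simulate_annotation,
                       simulate_core_pair, simulate_counts, simulate_genome,
                       simulate_peaks, simulate_study)

__all__ = [
    "pwm_pvalue_enumeration_gap",
    "planted_motif_recovery",
    "enrichment_ordering",
    "chromatin_classification_accuracy",
    "de_type1_error",
    "dependence_recovery",
    "em_discovery_recovery",
    "quintile_identity",
    "core_recovery",
    "manifest_determinism",
]

_BASES = "ACGT"


def enumerate_pvalues(pwm: Pwm, scores: np.ndarray) -> np.ndarray:
    """Brute-force P(score' >= s) by enumerating all 4^w sequences."""
    w = pwm.width
    lo = np.log2(pwm.probs / pwm.background[None, :])
    all_scores = np.zeros(1)
    all_probs = np.ones(1)
    for c in range(w):
        all_scores = (all_scores[:, None] + lo[c][None, :]).ravel()
        all_probs = (all_probs[:, None] * pwm.background[None, :]).ravel()
    order = np.argsort(all_scores)
    sorted_scores = all_scores[order]
    suffix = np.cumsum(all_probs[order][::-1])[::-1]
    idx = np.searchsorted(sorted_scores, np.asarray(scores) - 1e-9, side="left")
    out = np.where(idx < len(suffix), suffix[np.minimum(idx, len(suffix) - 1)], 0.0)
    return out


def pwm_pvalue_enumeration_gap(seed: int, n_pwms: int = 20) -> dict:
    """Max |DP - enumeration| p-value gap over random PWMs of width 4-8."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for i in range(n_pwms):
        w = int(rng.integers(4, 9))
        probs = rng.dirichlet(np.full(4, 0.5), size=w)
        probs = np.clip(probs, 1e-3, None)
        probs /= probs.sum(axis=1, keepdims=True)
        pwm = Pwm(probs=probs)
        lo = np.log2(pwm.probs / pwm.background[None, :])
        scores = np.zeros(1)
        for c in range(w):
            scores = np.unique(np.round((scores[:, None] + lo[c][None, :]).ravel(), 12))
        exact = enumerate_pvalues(pwm, scores)
        dp = score_pvalues(pwm, scores)
        worst = max(worst, float(np.abs(dp - exact).max()))
    return {"max_abs_error": worst, "n_pwms": n_pwms}


def planted_motif_recovery(
    seed: int,
    n_unsplit: int = 200,
    n_spaced: int = 100,
    n_none: int = 200,
    threshold: float = 1e-4,
    window: int = 600,
) -> dict:
    """Scan windows with planted PWM-sampled sites; measure class recovery."""
    rng = np.random.default_rng(seed)
    pwm = p53_consensus_pwm()
    model = build_spaced_pwm(pwm)
    gc = 0.42
    p_bg = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]

    def background(n):
        return "".join(_BASES[i] for i in rng.choice(4, size=n, p=p_bg))

    records = []
    spacers = list(itertools.islice(itertools.cycle(range(1, 16)), n_spaced))
    rng.shuffle(spacers)
    plan = ([(MotifClass.UNSPLIT, 0)] * n_unsplit
            + [(MotifClass.SPACED, s) for s in spacers]
            + [(MotifClass.NO_MOTIF, 0)] * n_none)
    for i, (cls, spacer) in enumerate(plan):
        seq = background(window)
        if cls != MotifClass.NO_MOTIF:
            site = sample_site(pwm, spacer, rng, gc)
            pos = window // 2 - len(site) // 2
            seq = seq[:pos] + site + seq[pos + len(site):]
        hit = scan_window(seq, model, threshold=threshold, peak_name=f"pk{i}")
        records.append({
            "truth": cls, "spacer": spacer,
            "called": MotifClass.NO_MOTIF if hit is None else hit.motif_class,
            "called_spacer": -1 if hit is None else hit.spacer,
        })
    df = pd.DataFrame(records)
    unsplit = df[df.truth == MotifClass.UNSPLIT]
    spaced = df[df.truth == MotifClass.SPACED]
    detected_spaced = spaced[spaced.called == MotifClass.SPACED]
    return {
        "unsplit_accuracy": float((unsplit.called == MotifClass.UNSPLIT).mean()),
        "spaced_accuracy": float((spaced.called == MotifClass.SPACED).mean()),
        "spacer_match": float(
            (detected_spaced.called_spacer == detected_spaced.spacer).mean()
        ) if len(detected_spaced) else float("nan"),
        "none_false_positive": float(
            (df[df.truth == MotifClass.NO_MOTIF].called != MotifClass.NO_MOTIF).mean()
        ),
        "n": len(df),
    }


def enrichment_ordering(seed: int, n_peaks: int = 500) -> dict:
    """Mean enrichment by planted motif class + pairwise Student's t."""
    cfg = SimConfig(seed=seed, n_peaks=n_peaks)
    rng = np.random.default_rng(cfg.seed)
    from .simulate import _plan_peaks
    plan = _plan_peaks(cfg, rng)
    _, registry = simulate_genome(cfg, plan, rng)
    peaks, truth = simulate_peaks(cfg, registry)
    annotate_enrichment(peaks)
    enr = {p.name: p.enrichment for p in peaks}
    groups = {
        cls: [enr[n] for n, c in zip(truth.peak_name, truth.motif_class)
              if c == cls and enr[n] is not None]
        for cls in MotifClass
    }
    res = group_compare({c.value: v for c, v in groups.items()})
    means = {c: res["summaries"][c]["mean"] for c in res["summaries"]}
    p_unsplit_spaced = res["tests"][
        _pair_key(res["tests"], "unsplit", "spaced")]["pvalue"]
    p_spaced_none = res["tests"][
        _pair_key(res["tests"], "spaced", "no_motif")]["pvalue"]
    return {
        "mean_unsplit": means["unsplit"],
        "mean_spaced": means["spaced"],
        "mean_no_motif": means["no_motif"],
        "p_unsplit_vs_spaced": float(p_unsplit_spaced),
        "p_spaced_vs_none": float(p_spaced_none),
        "ordered": means["unsplit"] > means["spaced"] > means["no_motif"],
    }


def _pair_key(tests: dict, a: str, b: str):
    for key in ((a, b), (b, a)):
        if key in tests:
            return key
    raise KeyError((a, b))


def chromatin_classification_accuracy(seed: int, n_peaks: int = 300) -> dict:
    """classify_peaks vs planted classes on the disjoint default layout."""
    cfg = SimConfig(seed=seed, n_peaks=n_peaks)
    bundle = simulate_study(cfg)
    promoters = promoter_windows_from_genes(
        bundle.genes[bundle.genes.chrom == "chrS"]
    )
    classes, _ = classify_peaks(bundle.peaks, promoters, bundle.marks)
    truth = dict(zip(bundle.peak_truth.peak_name, bundle.peak_truth.peak_class))
    agree = np.mean([classes[n] == truth[n] for n in classes])
    return {"accuracy": float(agree), "n": len(classes)}


def de_type1_error(
    seed: int, n_genes: int = 10_000, n_replicates: int = 4,
    dispersion: float = 0.1,
) -> dict:
    """Raw p < 0.05 fraction under the all-null NB simulation."""
    cfg = SimConfig(
        seed=seed, n_peaks=0, n_genes=n_genes, n_replicates=n_replicates,
        dispersion=dispersion, fraction_null=1.0, genome_length=1200,
    )
    genes = pd.DataFrame({
        "gene_id": [f"g{i:05d}" for i in range(n_genes)],
        "chrom": "chrU", "strand": "+", "tss": np.arange(n_genes) * 10 + 1000,
        "exon_length": 1000,
    })
    plan = pd.DataFrame({
        "gene_id": genes.gene_id, "mode": RegulatoryMode.UNCHANGED,
        "wt_fold": 1.0, "ko_fold": 1.0, "bound_peak": None,
        "motif_class": MotifClass.NO_MOTIF,
    })
    counts, meta = simulate_counts(cfg, genes, plan)
    de = nb_de_test(counts, meta, genotype="WT")
    pvals = de["pvalue"].dropna()
    return {"type1_rate": float((pvals < 0.05).mean()), "n_tested": int(len(pvals))}


def dependence_recovery(
    seed: int, n_per_mode: int = 200, n_null: int = 1400,
    n_replicates: int = 4, dispersion: float = 0.05,
) -> dict:
    """Sensitivity/specificity of the DEP vs INDEP call on planted modes."""
    n_genes = 4 * n_per_mode + n_null
    cfg = SimConfig(
        seed=seed, n_peaks=0, n_genes=n_genes, n_replicates=n_replicates,
        dispersion=dispersion, fraction_null=n_null / n_genes,
        genome_length=1200,
    )
    genes = pd.DataFrame({
        "gene_id": [f"g{i:05d}" for i in range(n_genes)],
        "chrom": "chrU", "strand": "+", "tss": np.arange(n_genes) * 10 + 1000,
        "exon_length": 1000,
    })
    modes = ([RegulatoryMode.UP_DEP] * n_per_mode
             + [RegulatoryMode.UP_INDEP] * n_per_mode
             + [RegulatoryMode.DOWN_DEP] * n_per_mode
             + [RegulatoryMode.DOWN_INDEP] * n_per_mode
             + [RegulatoryMode.UNCHANGED] * n_null)
    rng = np.random.default_rng(seed + 17)
    modes = list(modes)
    rng.shuffle(modes)
    plan = pd.DataFrame({
        "gene_id": genes.gene_id,
        "mode": modes,
        "wt_fold": [cfg.effects.get(m, (1.0, 1.0))[0] for m in modes],
        "ko_fold": [cfg.effects.get(m, (1.0, 1.0))[1] for m in modes],
        "bound_peak": None, "motif_class": MotifClass.NO_MOTIF,
    })
    counts, meta = simulate_counts(cfg, genes, plan)
    de_wt = nb_de_test(counts, meta, genotype="WT")
    de_ko = nb_de_test(counts, meta, genotype="KO")
    lengths = genes.set_index("gene_id")["exon_length"]
    rpkm_mat = rpkm(counts, lengths, counts.sum(axis=0))
    called = assign_modes(de_wt, de_ko, rpkm_mat)

    truth = pd.Series(modes, index=genes.gene_id)
    dep_modes = {RegulatoryMode.UP_DEP, RegulatoryMode.DOWN_DEP}
    indep_modes = {RegulatoryMode.UP_INDEP, RegulatoryMode.DOWN_INDEP}
    deg_called = called[called != RegulatoryMode.UNCHANGED]
    planted_dep = truth[truth.isin(dep_modes)].index.intersection(deg_called.index)
    planted_indep = truth[truth.isin(indep_modes)].index.intersection(deg_called.index)
    sens = float(called[planted_dep].isin(dep_modes).mean())
    spec = float(called[planted_indep].isin(indep_modes).mean())
    return {
        "sensitivity": sens,
        "specificity": spec,
        "n_dep_evaluated": int(len(planted_dep)),
        "n_indep_evaluated": int(len(planted_indep)),
    }


def em_discovery_recovery(
    seed: int, n_seqs: int = 500, site_rate: float = 0.6,
    seq_len: int = 100, width: int = 20,
) -> dict:
    """ZOOPS-EM consensus recovery on sequences with planted PWM sites."""
    rng = np.random.default_rng(seed)
    pwm = p53_consensus_pwm()
    gc = 0.42
    p_bg = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seqs = []
    n_planted = int(round(site_rate * n_seqs))
    for i in range(n_seqs):
        seq = "".join(_BASES[b] for b in rng.choice(4, size=seq_len, p=p_bg))
        if i < n_planted:
            site = sample_site(pwm, 0, rng, gc)
            pos = int(rng.integers(0, seq_len - len(site) + 1))
            seq = seq[:pos] + site + seq[pos + len(site):]
        seqs.append(seq)
    result = discover_motif(seqs, width=width, seed=seed)
    # the planted consensus is degenerate (R/W/Y are two-fold), so a
    # recovered base matches when it is among the allowed bases
    from .simulate import _DEGENERATE, _HALF_CONSENSUS
    pattern = (_HALF_CONSENSUS * 2)[:width]
    fwd = result.pwm.consensus
    rev = result.pwm.reverse_complement().consensus
    match = max(
        sum(b in _DEGENERATE[c] for b, c in zip(fwd, pattern)),
        sum(b in _DEGENERATE[c] for b, c in zip(rev, pattern)),
    )
    monotone = bool(np.all(np.diff(result.objective_trace) >= -1e-6))
    return {
        "consensus_matches": int(match),
        "width": width,
        "monotone": monotone,
        "information_content": result.information_content,
        "converged": result.converged,
    }


def quintile_identity(seed: int, n_peaks: int = 100) -> dict:
    """quintile_overlap(a, a) must be all ones on any simulated peak set."""
    cfg = SimConfig(seed=seed, n_peaks=n_peaks)
    rng = np.random.default_rng(cfg.seed)
    from .simulate import _plan_peaks
    plan = _plan_peaks(cfg, rng)
    _, registry = simulate_genome(cfg, plan, rng)
    peaks, _ = simulate_peaks(cfg, registry)
    annotate_enrichment(peaks)
    defined = PeakSet([p for p in peaks if p.enrichment is not None], label="a")
    q = quintile_overlap(defined, defined)
    return {"quintiles": q.tolist(), "min_fraction": float(q.min())}


def _core_candidate_set(bundle) -> set[str]:
    """Genes UP_DEP, promoter-bound and linked via an unsplit-motif peak."""
    model = build_spaced_pwm(p53_consensus_pwm())
    genome = bundle.sequences
    hits = {}
    for p in bundle.peaks:
        window = genome[p.interval.chrom][max(0, p.summit - 300):p.summit + 300]
        hits[p.name] = scan_window(window, model, peak_name=p.name)
    annotate_enrichment(bundle.peaks)
    links = link_genes_to_peaks(bundle.genes, bundle.peaks, hits)
    de_wt = nb_de_test(bundle.counts, bundle.meta, genotype="WT")
    de_ko = nb_de_test(bundle.counts, bundle.meta, genotype="KO")
    lengths = bundle.genes.set_index("gene_id")["exon_length"]
    rpkm_mat = rpkm(bundle.counts, lengths, bundle.counts.sum(axis=0))
    modes = assign_modes(de_wt, de_ko, rpkm_mat)
    return {
        g for g, link in links.items()
        if link.bound
        and link.motif_class == MotifClass.UNSPLIT
        and modes.get(g) == RegulatoryMode.UP_DEP
    }


def core_recovery(
    seed: int, n_core: int = 50, n_private_a: int = 20, n_private_b: int = 30,
    n_peaks: int = 120, n_genes: int = 300,
) -> dict:
    """Exact recovery of the planted shared core across two cell types."""
    cfg = SimConfig(seed=seed, n_peaks=n_peaks, n_genes=n_genes)
    bundle_a, bundle_b, truth = simulate_core_pair(
        cfg, n_core=n_core, n_private_a=n_private_a, n_private_b=n_private_b
    )
    set_a = _core_candidate_set(bundle_a)
    set_b = _core_candidate_set(bundle_b)
    result = core_response(set_a, set_b)
    core = result["core"]
    return {
        "n_recovered": len(core),
        "n_planted": n_core,
        "exact": core == truth["core"],
        "missed": sorted(truth["core"] - core),
        "extra": sorted(core - truth["core"]),
        "fraction_a": result["fraction_a"],
        "fraction_b": result["fraction_b"],
    }


def manifest_determinism(seed: int, workdir, n_peaks: int = 60,
                         n_genes: int = 150) -> dict:
    """run-all twice with the same seed/config gives the same manifest hash."""
    import os
    from .pipeline import RunConfig, run_pipeline
    from .simulate import write_bundle

    cfg = SimConfig(seed=seed, n_peaks=n_peaks, n_genes=n_genes)
    bundle = simulate_study(cfg)
    indir = os.path.join(workdir, "inputs")
    paths = write_bundle(bundle, indir)
    marks = {
        name[len("mark_"):-len(".bed")]: pth
        for name, pth in paths.items()
        if name.startswith("mark_") and name.endswith(".bed")
    }
    hashes = []
    for run in ("run1", "run2"):
        rc = RunConfig(
            peaks=paths["peaks.narrowPeak"], peak_counts=paths["peak_counts.tsv"],
            genome=paths["genome.fa"], genes=paths["genes.tsv"], marks=marks,
            counts=paths["counts.tsv"], meta=paths["meta.tsv"],
            outdir=os.path.join(workdir, run), seed=seed, top_n=50,
        )
        manifest = run_pipeline(rc)
        hashes.append(manifest["manifest_hash"])
    return {"hashes": hashes, "identical": hashes[0] == hashes[1]}
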