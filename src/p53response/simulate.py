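"""Synthetic study generator: toy genome, planted p53 sites, peaks, marks,
gene annotation and WT/KO x mock/IR count matrices with known ground truth.

Every generator is a pure function of :class:`SimConfig` (fixed seed gives
byte-identical outputs). The design emulates the structure of the real
study: binding sites fall at promoters, enhancers or unmarked distal
regions; their sequences carry the dimeric p53 response element unsplit,
with a 1-15 nt spacer, or not at all; ChIP enrichment is higher for
unsplit-motif sites than spaced than motif-free; and gene counts follow a
negative-binomial model with planted p53-dependent and -independent
responses to irradiation in wild-type and knockout animals.

Peak loci are placed on a regular grid with enough spacing that promoter
windows, enhancer marks and neighboring peaks never collide, so chromatin
classification on default output is exact by construction. Genes without a
binding site live on a separate decoy chromosome.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, Peak, PeakSet
from .landscape import PeakClass
from .motif import MotifClass, Pwm, p53_consensus_pwm
from .expression import RegulatoryMode

__all__ = [
    "SimConfig",
    "StudyBundle",
    "simulate_study",
    "simulate_genome",
    "simulate_peaks",
    "simulate_annotation",
    "simulate_counts",
    "simulate_core_pair",
    "sample_site",
    "write_bundle",
    "PEAK_SPACING",
]

PEAK_SPACING = 12_000  # grid distance guaranteeing disjoint windows/marks
_BASES = "ACGT"
_HALF_CONSENSUS = "RRRCWWGYYY"
_DEGENERATE = {"R": "AG", "W": "AT", "Y": "CT", "C": "C", "G": "G"}


@dataclass
class SimConfig:
    """Study conditions for the synthetic generators.

    Defaults reflect the structure of the modeled experiment: three
    chromatin classes with promoters and enhancers dominating, motif
    frequency highest at unmarked distal sites, enrichment decreasing from
    unsplit over spaced to motif-free sites, and a WT/KO x mock/IR design
    with four replicates per arm.
    """

    seed: int = 0
    genome_length: int | None = None
    gc_content: float = 0.42
    n_peaks: int = 500
    class_fractions: tuple[float, float, float] = (0.4, 0.4, 0.2)  # prom, enh, unmarked
    motif_rates_by_class: dict = field(default_factory=lambda: {
        PeakClass.PROMOTER: (0.30, 0.20, 0.50),       # unsplit, spaced, none
        PeakClass.ENHANCER: (0.30, 0.20, 0.50),
        PeakClass.UNMARKED_DISTAL: (0.55, 0.20, 0.25),
    })
    spacer_weights: tuple = tuple([1.0] * 15)         # spacers 1..15
    enrichment_means: dict = field(default_factory=lambda: {
        MotifClass.UNSPLIT: 120.0, MotifClass.SPACED: 80.0, MotifClass.NO_MOTIF: 40.0,
    })
    input_mean: float = 10.0
    enrichment_noise_sd: float = 0.25                 # log2 units on the chip mean
    chip_libsize: int = 1_000_000
    input_libsize: int = 1_000_000
    peak_width_range: tuple[int, int] = (300, 600)
    mark_rates: dict = field(default_factory=lambda: {
        PeakClass.PROMOTER: {"H3K4me3": 0.95, "RNApolII": 0.95, "DHS": 0.95, "H3K27ac": 0.8},
        PeakClass.ENHANCER: {"H3K4me1": 1.0, "H3K27ac": 0.7, "DHS": 0.8},
        PeakClass.UNMARKED_DISTAL: {},
    })
    n_genes: int = 2000
    n_replicates: int = 4
    ko_replicates: int | None = None                  # defaults to n_replicates
    dispersion: float = 0.05
    effects: dict = field(default_factory=lambda: {
        RegulatoryMode.UP_DEP: (4.0, 1.0),            # (WT fold, KO fold) upon IR
        RegulatoryMode.UP_INDEP: (3.0, 3.0),
        RegulatoryMode.DOWN_DEP: (0.25, 1.0),
        RegulatoryMode.DOWN_INDEP: (1 / 3, 1 / 3),
    })
    fraction_null: float = 0.7
    consensus_only: bool = False
    pwm_strength: float = 0.97
    cell_type: str = "B"

    def __post_init__(self) -> None:
        if self.n_peaks < 0 or self.n_genes < 0:
            raise ValueError("n_peaks and n_genes must be non-negative")
        if abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")
        for cls, rates in self.motif_rates_by_class.items():
            if abs(sum(rates) - 1.0) > 1e-9:
                raise ValueError(f"motif rates for {cls} must sum to 1")
        if not 0.0 <= self.fraction_null <= 1.0:
            raise ValueError("fraction_null must be in [0, 1]")
        for mode, (wt, ko) in self.effects.items():
            if wt <= 0 or ko <= 0:
                raise ValueError(f"folds must be positive ({mode})")
        if self.genome_length is None:
            self.genome_length = self.n_peaks * PEAK_SPACING
        if self.n_peaks > 0 and self.genome_length < self.n_peaks * 1200:
            raise ValueError("infeasible packing: genome too short for n_peaks")

    @property
    def spacing(self) -> int:
        return self.genome_length // max(self.n_peaks, 1)

    @property
    def planting_pwm(self) -> Pwm:
        return p53_consensus_pwm(strong=self.pwm_strength)


@dataclass
class StudyBundle:
    cfg: SimConfig
    sequences: dict[str, str]
    peaks: PeakSet
    peak_truth: pd.DataFrame
    genes: pd.DataFrame
    marks: dict[str, PeakSet]
    counts: pd.DataFrame
    meta: pd.DataFrame
    gene_truth: pd.DataFrame


def _largest_remainder(fractions, n: int) -> list[int]:
    """Integer counts summing to n, proportional to fractions."""
    raw = np.asarray(fractions, dtype=float) * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1
    return counts.tolist()


def _plan_peaks(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Planted chromatin class, motif class and spacer for every peak."""
    classes: list[PeakClass] = []
    for cls, cnt in zip(PeakClass, _largest_remainder(cfg.class_fractions, cfg.n_peaks)):
        classes += [cls] * cnt
    rng.shuffle(classes)
    motif: list[MotifClass | None] = [None] * cfg.n_peaks
    spacer = [0] * cfg.n_peaks
    for cls in PeakClass:
        idx = [i for i, c in enumerate(classes) if c == cls]
        cnt_u, cnt_s, cnt_n = _largest_remainder(cfg.motif_rates_by_class[cls], len(idx))
        labels = ([MotifClass.UNSPLIT] * cnt_u + [MotifClass.SPACED] * cnt_s
                  + [MotifClass.NO_MOTIF] * cnt_n)
        rng.shuffle(labels)
        for i, lab in zip(idx, labels):
            motif[i] = lab
            if lab == MotifClass.SPACED:
                w = np.asarray(cfg.spacer_weights, float)
                spacer[i] = int(rng.choice(np.arange(1, 16), p=w / w.sum()))
    width = cfg.n_peaks and int(np.ceil(np.log10(max(cfg.n_peaks, 2))))
    return pd.DataFrame({
        "peak_name": [f"peak_{i:0{max(width, 3)}d}" for i in range(cfg.n_peaks)],
        "peak_class": classes,
        "motif_class": motif,
        "spacer": spacer,
    })


def sample_site(
    pwm: Pwm, spacer: int, rng: np.random.Generator,
    gc_content: float = 0.42, consensus_only: bool = False,
) -> str:
    """Draw one dimeric site: two decamers with a background spacer between.

    With ``consensus_only`` the degenerate consensus RRRCWWGYYY is sampled
    uniformly over its allowed bases instead of from the PWM, so scanning
    recovers every planted site with certainty.
    """
    if consensus_only:
        half = lambda: "".join(
            _DEGENERATE[c][int(rng.integers(len(_DEGENERATE[c])))]
            for c in _HALF_CONSENSUS
        )
        h1, h2 = half(), half()
    else:
        draws = [
            "".join(_BASES[int(rng.choice(4, p=row))] for row in pwm.probs[:10]),
            "".join(_BASES[int(rng.choice(4, p=row))] for row in pwm.probs[10:]),
        ]
        h1, h2 = draws
    gap = "".join(
        _BASES[i] for i in rng.choice(
            4, size=spacer,
            p=[(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2],
        )
    ) if spacer else ""
    return h1 + gap + h2


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(4, size=length, p=p).astype(np.int8)


def simulate_genome(
    cfg: SimConfig, peak_plan: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Background genome with planted sites; returns (sequences, registry).

    Summits sit at the midpoints of a regular grid; the registry records
    the planted site location and exact sequence for every peak.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    if peak_plan is None:
        peak_plan = _plan_peaks(cfg, rng)
    codes = _random_sequence(rng, cfg.genome_length, cfg.gc_content)
    pwm = cfg.planting_pwm
    records = []
    spacing = cfg.spacing
    for i, row in enumerate(peak_plan.itertuples()):
        summit = spacing * i + spacing // 2
        site_seq, site_start = "", -1
        if row.motif_class != MotifClass.NO_MOTIF:
            site_seq = sample_site(
                pwm, row.spacer, rng, cfg.gc_content, cfg.consensus_only
            )
            site_start = summit - len(site_seq) // 2
            site_codes = np.frombuffer(site_seq.encode(), dtype=np.uint8)
            lut = np.zeros(256, dtype=np.int8)
            for j, b in enumerate(_BASES):
                lut[ord(b)] = j
            codes[site_start:site_start + len(site_seq)] = lut[site_codes]
        records.append({
            "peak_name": row.peak_name, "chrom": "chrS", "summit": summit,
            "peak_class": row.peak_class, "motif_class": row.motif_class,
            "spacer": row.spacer, "site_start": site_start, "site_seq": site_seq,
        })
    seq = "".join(_BASES[i] for i in codes) if len(codes) else ""
    registry = pd.DataFrame(
        records,
        columns=["peak_name", "chrom", "summit", "peak_class",
                 "motif_class", "spacer", "site_start", "site_seq"],
    )
    return {"chrS": seq}, registry


def simulate_peaks(
    cfg: SimConfig, registry: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[PeakSet, pd.DataFrame]:
    """Peak calls with Poisson ChIP/input counts tied to the motif class."""
    rng = rng or np.random.default_rng(cfg.seed + 1)
    peaks = []
    lo, hi = cfg.peak_width_range
    for row in registry.itertuples():
        width = int(rng.integers(lo, hi + 1))
        start = max(0, row.summit - width // 2)
        chip_rpm = cfg.enrichment_means[row.motif_class]
        chip_rpm *= 2.0 ** rng.normal(0.0, cfg.enrichment_noise_sd)
        chip = int(rng.poisson(chip_rpm * cfg.chip_libsize / 1e6))
        inp = int(rng.poisson(cfg.input_mean * cfg.input_libsize / 1e6))
        peaks.append(Peak(
            interval=GenomicInterval(row.chrom, start, start + width, name=row.peak_name),
            summit_offset=row.summit - start,
            chip_count=chip, input_count=inp,
            chip_libsize=cfg.chip_libsize, input_libsize=cfg.input_libsize,
        ))
    truth = registry.copy()
    return PeakSet(peaks, label=f"{cfg.cell_type}_IR"), truth


def simulate_annotation(
    cfg: SimConfig, registry: pd.DataFrame,
    gene_plan: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict[str, PeakSet], pd.DataFrame]:
    """Gene table and chromatin-mark peak sets consistent with the registry.

    Promoter-class peaks receive a gene whose -5/+2 kb window covers the
    summit plus active-promoter marks; enhancer-class peaks receive
    H3K4me1 (+- H3K27ac/DHS) and no gene; unmarked peaks receive nothing.
    Genes beyond the bound ones sit on a decoy chromosome without peaks.
    Returns (genes, marks, gene_plan).
    """
    rng = rng or np.random.default_rng(cfg.seed + 2)
    mark_members: dict[str, list[Peak]] = {
        m: [] for m in ("H3K4me3", "H3K4me1", "H3K27ac", "RNApolII", "DHS")
    }
    genes = []
    bound_rows = []
    k = 0
    for row in registry.itertuples():
        rates = cfg.mark_rates[row.peak_class]
        for mark, rate in rates.items():
            if rng.random() < rate:
                iv = GenomicInterval(
                    row.chrom, max(0, row.summit - 1000), row.summit + 1000,
                    name=f"{mark}_{row.peak_name}",
                )
                mark_members[mark].append(Peak(interval=iv, summit_offset=1000))
        if row.peak_class == PeakClass.PROMOTER:
            gene_id = f"gene_{k:04d}"
            k += 1
            strand = "+" if rng.random() < 0.5 else "-"
            tss = row.summit + int(rng.integers(-900, 901))
            genes.append({
                "gene_id": gene_id, "chrom": row.chrom, "strand": strand,
                "tss": tss, "exon_length": int(rng.integers(500, 5001)),
            })
            bound_rows.append({
                "gene_id": gene_id, "peak_name": row.peak_name,
                "motif_class": row.motif_class,
            })
    n_extra = max(0, cfg.n_genes - len(genes))
    for j in range(n_extra):
        genes.append({
            "gene_id": f"gene_{k + j:04d}", "chrom": "chrU",
            "strand": "+" if rng.random() < 0.5 else "-",
            "tss": 1000 + 10 * j, "exon_length": int(rng.integers(500, 5001)),
        })
    genes_df = pd.DataFrame(
        genes, columns=["gene_id", "chrom", "strand", "tss", "exon_length"]
    )
    marks = {m: PeakSet(v, label=m) for m, v in mark_members.items()}
    if gene_plan is None:
        gene_plan = _plan_gene_modes(cfg, genes_df, bound_rows, rng)
    return genes_df, marks, gene_plan


def _plan_gene_modes(
    cfg: SimConfig, genes: pd.DataFrame, bound_rows: list[dict],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Assign a planted regulatory mode (and folds) to every gene."""
    n = len(genes)
    modes = list(cfg.effects)
    n_de = int(round(n * (1.0 - cfg.fraction_null)))
    per_mode = _largest_remainder([1.0 / len(modes)] * len(modes), n_de)
    labels = [RegulatoryMode.UNCHANGED] * (n - n_de)
    for mode, cnt in zip(modes, per_mode):
        labels += [mode] * cnt
    labels = list(labels)
    rng.shuffle(labels)
    bound = {r["gene_id"]: r for r in bound_rows}
    rows = []
    for gene_id, mode in zip(genes["gene_id"], labels):
        wt, ko = cfg.effects.get(mode, (1.0, 1.0))
        link = bound.get(gene_id)
        rows.append({
            "gene_id": gene_id, "mode": mode, "wt_fold": wt, "ko_fold": ko,
            "bound_peak": link["peak_name"] if link else None,
            "motif_class": link["motif_class"] if link else MotifClass.NO_MOTIF,
        })
    return pd.DataFrame(rows)


def simulate_counts(
    cfg: SimConfig, genes: pd.DataFrame, gene_plan: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial count matrix for the WT/KO x mock/IR design.

    Null genes draw base means log-normally over the full expression range;
    planted DE genes draw from the expressed range (so that responsiveness
    is observable at all). IR samples scale the mean by the genotype fold.
    """
    rng = rng or np.random.default_rng(cfg.seed + 3)
    n_wt = cfg.n_replicates
    n_ko = cfg.ko_replicates if cfg.ko_replicates is not None else cfg.n_replicates
    if min(n_wt, n_ko) < 2:
        raise ValueError("need at least 2 replicates per genotype")
    samples = []
    for genotype, n_rep in (("WT", n_wt), ("KO", n_ko)):
        for treatment in ("mock", "IR"):
            for rep in range(1, n_rep + 1):
                samples.append({
                    "sample_id": f"{cfg.cell_type}_{genotype}_{treatment}_r{rep}",
                    "genotype": genotype, "treatment": treatment,
                    "cell_type": cfg.cell_type, "replicate": rep,
                })
    meta = pd.DataFrame(samples).set_index("sample_id")

    plan = gene_plan.set_index("gene_id").reindex(genes["gene_id"])
    null_mask = (plan["mode"] == RegulatoryMode.UNCHANGED).to_numpy()
    n = len(plan)
    base = np.empty(n)
    base[null_mask] = rng.lognormal(np.log(100.0), 1.0, size=null_mask.sum())
    base[~null_mask] = rng.lognormal(np.log(200.0), 0.5, size=(~null_mask).sum())

    wt_fold = plan["wt_fold"].to_numpy(dtype=float)
    ko_fold = plan["ko_fold"].to_numpy(dtype=float)
    counts = {}
    for sample_id, row in meta.iterrows():
        mu = base.copy()
        if row["treatment"] == "IR":
            mu = mu * (wt_fold if row["genotype"] == "WT" else ko_fold)
        if cfg.dispersion > 0:
            r = 1.0 / cfg.dispersion
            counts[sample_id] = rng.negative_binomial(r, r / (r + mu))
        else:
            counts[sample_id] = rng.poisson(mu)
    counts_df = pd.DataFrame(counts, index=genes["gene_id"])
    counts_df.index.name = "gene_id"
    return counts_df, meta


def simulate_study(
    cfg: SimConfig,
    peak_plan: pd.DataFrame | None = None,
    gene_plan: pd.DataFrame | None = None,
) -> StudyBundle:
    """Run every generator off one seed and return the full bundle."""
    rng = np.random.default_rng(cfg.seed)
    if peak_plan is None:
        peak_plan = _plan_peaks(cfg, rng)
    sequences, registry = simulate_genome(cfg, peak_plan, rng)
    peaks, peak_truth = simulate_peaks(cfg, registry)
    genes, marks, gene_plan = simulate_annotation(cfg, registry, gene_plan)
    counts, meta = simulate_counts(cfg, genes, gene_plan)
    return StudyBundle(
        cfg=cfg, sequences=sequences, peaks=peaks, peak_truth=peak_truth,
        genes=genes, marks=marks, counts=counts, meta=meta, gene_truth=gene_plan,
    )


def simulate_core_pair(
    cfg: SimConfig,
    n_core: int = 50,
    n_private_a: int = 20,
    n_private_b: int = 30,
) -> tuple[StudyBundle, StudyBundle, dict]:
    """Two cell types sharing a planted core of dependent, unsplit-bound genes.

    Core genes are UP_DEP and bound via an unsplit consensus site in both
    cell types; private genes only in their own type (they are unbound and
    unchanged in the other). Remaining peaks and genes follow the default
    plan with no planted response.
    """
    cfg = dataclasses.replace(cfg, consensus_only=True)
    shared = [f"core_{i:03d}" for i in range(n_core)]
    priv_a = [f"privA_{i:03d}" for i in range(n_private_a)]
    priv_b = [f"privB_{i:03d}" for i in range(n_private_b)]
    universe = shared + priv_a + priv_b

    def build(cell_type: str, own_private: list[str], other_private: list[str], seed: int):
        sub = dataclasses.replace(cfg, seed=seed, cell_type=cell_type)
        bound_genes = shared + own_private
        n_peaks = sub.n_peaks
        if n_peaks < len(bound_genes):
            raise ValueError("n_peaks too small for the planted core design")
        plan = pd.DataFrame({
            "peak_name": [f"{cell_type}_peak_{i:04d}" for i in range(n_peaks)],
            "peak_class": [PeakClass.PROMOTER] * len(bound_genes)
                          + [PeakClass.UNMARKED_DISTAL] * (n_peaks - len(bound_genes)),
            "motif_class": [MotifClass.UNSPLIT] * len(bound_genes)
                           + [MotifClass.NO_MOTIF] * (n_peaks - len(bound_genes)),
            "spacer": [0] * n_peaks,
        })
        rng = np.random.default_rng(sub.seed)
        sequences, registry = simulate_genome(sub, plan, rng)
        peaks, peak_truth = simulate_peaks(sub, registry)
        genes, marks, _ = simulate_annotation(sub, registry, gene_plan=pd.DataFrame())
        # rename the promoter genes to the planted gene ids (order preserved)
        prom_mask = genes["chrom"] == "chrS"
        assert prom_mask.sum() == len(bound_genes)
        renames = dict(zip(genes.loc[prom_mask, "gene_id"], bound_genes))
        genes["gene_id"] = genes["gene_id"].map(lambda g: renames.get(g, g))
        # genes of the other type exist here as unbound nulls
        extra = [g for g in other_private if g not in set(genes["gene_id"])]
        filler = genes[genes["chrom"] == "chrU"]["gene_id"].tolist()
        for gid, old in zip(extra, filler):
            genes.loc[genes["gene_id"] == old, "gene_id"] = gid
        plan_rows = []
        prom_peaks = registry[registry["peak_class"] == PeakClass.PROMOTER]
        peak_for_gene = dict(zip(bound_genes, prom_peaks["peak_name"]))
        for gid in genes["gene_id"]:
            is_de = gid in set(bound_genes)
            wt, ko = cfg.effects[RegulatoryMode.UP_DEP] if is_de else (1.0, 1.0)
            plan_rows.append({
                "gene_id": gid,
                "mode": RegulatoryMode.UP_DEP if is_de else RegulatoryMode.UNCHANGED,
                "wt_fold": wt, "ko_fold": ko,
                "bound_peak": peak_for_gene.get(gid),
                "motif_class": MotifClass.UNSPLIT if is_de else MotifClass.NO_MOTIF,
            })
        gene_plan = pd.DataFrame(plan_rows)
        counts, meta = simulate_counts(sub, genes, gene_plan)
        return StudyBundle(
            cfg=sub, sequences=sequences, peaks=peaks, peak_truth=peak_truth,
            genes=genes, marks=marks, counts=counts, meta=meta, gene_truth=gene_plan,
        )

    bundle_a = build("B", priv_a, priv_b, cfg.seed)
    bundle_b = build("nonB", priv_b, priv_a, cfg.seed + 1000)
    truth = {"core": set(shared), "private_a": set(priv_a),
             "private_b": set(priv_b), "universe": set(universe)}
    return bundle_a, bundle_b, truth


def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_bundle(bundle: StudyBundle, outdir) -> dict[str, str]:
    """Write the bundle to standard text formats; returns {name: path}."""
    import os
    from .intervals import write_regions

    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def p(name):
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    write_fasta(bundle.sequences, p("genome.fa"))
    write_regions(bundle.peaks, p("peaks.narrowPeak"), format="narrowPeak")
    pc = pd.DataFrame({
        "peak_name": [pk.name for pk in bundle.peaks],
        "chip_count": [pk.chip_count for pk in bundle.peaks],
        "input_count": [pk.input_count for pk in bundle.peaks],
        "chip_libsize": [pk.chip_libsize for pk in bundle.peaks],
        "input_libsize": [pk.input_libsize for pk in bundle.peaks],
    })
    pc.to_csv(p("peak_counts.tsv"), sep="\t", index=False)
    bundle.genes.to_csv(p("genes.tsv"), sep="\t", index=False)
    for mark, mset in bundle.marks.items():
        write_regions(mset, p(f"mark_{mark}.bed"), format="bed")
    bundle.counts.to_csv(p("counts.tsv"), sep="\t")
    bundle.meta.to_csv(p("meta.tsv"), sep="\t")
    truth = bundle.peak_truth.copy()
    for col in ("peak_class", "motif_class"):
        truth[col] = truth[col].map(lambda v: v.value)
    truth.to_csv(p("peak_truth.tsv"), sep="\t", index=False)
    gt = bundle.gene_truth.copy()
    gt["mode"] = gt["mode"].map(lambda v: v.value)
    gt["motif_class"] = gt["motif_class"].map(lambda v: v.value)
    gt.to_csv(p("gene_truth.tsv"), sep="\t", index=False)
    return paths
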