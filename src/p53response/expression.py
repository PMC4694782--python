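"""Expression quantification, differential expression and p53 dependence.

Quantification uses RPKM with the library size defined as exon-mapped reads
only. Differential expression (IR vs mock within one genotype) is a
deliberately simple negative-binomial Wald test: median-of-ratios library
normalization, method-of-moments gene-wise dispersion (floored), a delta-
method standard error for the log2 fold change, and Benjamini-Hochberg
adjustment across genes passing a mean-count filter. It is a documented
stand-in for a full shrinkage-based DE engine; externally computed DE
tables (gene_id, log2fc, qvalue) can be imported instead.

DEG calling follows strict thresholds (q < 0.05, |log2fc| > 0.58, max RPKM
> 1 in at least one replicate). A wild-type DEG is p53-dependent when its
fold response to irradiation exceeds the knockout response by a factor of
at least 1.5 (mirrored for repression).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RegulatoryMode",
    "rpkm",
    "size_factors",
    "nb_de_test",
    "import_de_table",
    "read_gmt",
    "call_degs",
    "classify_dependence",
    "assign_modes",
    "spearman_cluster",
    "geneset_enrichment",
    "DEG_Q_THRESHOLD",
    "DEG_LFC_THRESHOLD",
    "DEPENDENCE_RATIO",
    "EXPRESSED_RPKM",
]

DEG_Q_THRESHOLD = 0.05
DEG_LFC_THRESHOLD = 0.58
DEPENDENCE_RATIO = 1.5
EXPRESSED_RPKM = 1.0


class RegulatoryMode(Enum):
    UP_DEP = "up_dep"
    UP_INDEP = "up_indep"
    DOWN_DEP = "down_dep"
    DOWN_INDEP = "down_indep"
    UNCHANGED = "unchanged"


def rpkm(
    counts: pd.DataFrame,
    exon_lengths: pd.Series,
    exon_mapped_totals: pd.Series,
) -> pd.DataFrame:
    """Reads per kilobase of exon per million exon-mapped reads.

    rpkm[g, s] = counts[g, s] * 1e9 / (exon_lengths[g] * totals[s]).
    """
    lengths = exon_lengths.reindex(counts.index)
    totals = exon_mapped_totals.reindex(counts.columns)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive exon length")
    if totals.isna().any() or (totals <= 0).any():
        raise ValueError("every sample needs a positive exon-mapped total")
    return counts.mul(1e9).div(lengths, axis=0).div(totals, axis=1)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors (reference = geometric mean)."""
    log_counts = np.log(counts.where(counts > 0))
    log_ref = log_counts.mean(axis=1)
    usable = log_ref.notna() & np.isfinite(log_ref)
    if not usable.any():
        raise ValueError("no gene has positive counts in every sample")
    ratios = log_counts.loc[usable].sub(log_ref[usable], axis=0)
    sf = np.exp(ratios.median(axis=0))
    return sf


def nb_de_test(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    genotype: str,
    cell_type: str | None = None,
    min_mean_count: float = 1.0,
    dispersion_floor: float = 1e-8,
) -> pd.DataFrame:
    """Simplified NB Wald test of IR vs mock within one genotype.

    ``meta`` is indexed by sample_id with columns genotype/treatment (and
    optionally cell_type/replicate). The gene-wise NB dispersion is a
    property of the gene, so it is moment-estimated from the within-group
    variances of every (genotype, treatment) group available in ``meta``
    (within the cell type), not just the two contrasted arms; the Wald
    statistic is referred to a t distribution with the residual degrees of
    freedom of that variance estimate. Returns a frame indexed by gene with
    base_mean, log2fc, se, stat, pvalue, qvalue; genes failing the
    mean-normalized-count filter carry NaN p/q (not tested).
    """
    scope = meta
    if cell_type is not None and "cell_type" in meta.columns:
        scope = meta[meta["cell_type"] == cell_type]
    sub = scope[scope["genotype"] == genotype]
    ir_samples = sub.index[sub["treatment"] == "IR"]
    mock_samples = sub.index[sub["treatment"] == "mock"]
    if len(ir_samples) < 2 or len(mock_samples) < 2:
        raise ValueError(
            f"need >= 2 replicates per arm, got IR={len(ir_samples)} "
            f"mock={len(mock_samples)}"
        )
    mat = counts[list(scope.index)]
    sf = size_factors(mat)
    norm = mat.div(sf, axis=1)
    a = norm[mock_samples].to_numpy(dtype=float)
    b = norm[ir_samples].to_numpy(dtype=float)
    n_a, n_b = a.shape[1], b.shape[1]

    m_a, m_b = a.mean(axis=1), b.mean(axis=1)
    base_mean = (m_a + m_b) / 2.0

    # method-of-moments dispersion averaged over all replicate groups
    alpha_terms = []
    resid_df = 0
    for (_, _), group in scope.groupby(["genotype", "treatment"], sort=True):
        if len(group.index) < 2:
            continue
        g = norm[list(group.index)].to_numpy(dtype=float)
        gm = g.mean(axis=1)
        gv = g.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha_terms.append((gv - gm) / np.square(gm))
        resid_df += len(group.index) - 1
    stacked = np.vstack(alpha_terms)
    stacked = np.where(np.isfinite(stacked), stacked, np.nan)
    with np.errstate(invalid="ignore"):
        alpha = np.nanmean(stacked, axis=0)
    alpha = np.where(np.isfinite(alpha), alpha, dispersion_floor)
    alpha = np.maximum(alpha, dispersion_floor)

    pseudo = 0.5
    log2fc = np.log2(m_b + pseudo) - np.log2(m_a + pseudo)
    ln2sq = np.log(2.0) ** 2
    var_a = (m_a + alpha * m_a**2) / n_a / (np.square(m_a + pseudo) * ln2sq)
    var_b = (m_b + alpha * m_b**2) / n_b / (np.square(m_b + pseudo) * ln2sq)
    se = np.sqrt(var_a + var_b)

    tested = base_mean >= min_mean_count
    stat = np.full(len(mat), np.nan)
    pval = np.full(len(mat), np.nan)
    ok = tested & (se > 0)
    stat[ok] = log2fc[ok] / se[ok]
    pval[ok] = 2.0 * stats.t.sf(np.abs(stat[ok]), resid_df)
    # zero fold change with zero SE: no evidence against the null
    pval[tested & (se == 0)] = 1.0
    stat[tested & (se == 0)] = 0.0

    qval = np.full(len(mat), np.nan)
    tested_idx = ~np.isnan(pval)
    if tested_idx.any():
        qval[tested_idx] = multipletests(pval[tested_idx], method="fdr_bh")[1]

    out = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "stat": stat,
            "pvalue": pval,
            "qvalue": qval,
        },
        index=mat.index,
    )
    assert _bh_monotone(out)
    return out


def _bh_monotone(de: pd.DataFrame) -> bool:
    """BH q-values are non-decreasing in p-value over tested genes."""
    sub = de.dropna(subset=["pvalue", "qvalue"]).sort_values("pvalue")
    return bool((np.diff(sub["qvalue"].to_numpy()) >= -1e-12).all())


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene sets from a GMT file (set name, description, members...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 3:
                sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


def import_de_table(path) -> pd.DataFrame:
    """Load an externally computed DE table (gene_id, log2fc, qvalue)."""
    de = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2fc", "qvalue"}
    if not required.issubset(de.columns):
        raise ValueError(f"DE table must contain columns {sorted(required)}")
    return de.set_index("gene_id")


def call_degs(
    de: pd.DataFrame,
    rpkm_matrix: pd.DataFrame,
    q_threshold: float = DEG_Q_THRESHOLD,
    lfc_threshold: float = DEG_LFC_THRESHOLD,
    min_rpkm: float = EXPRESSED_RPKM,
) -> tuple[set[str], set[str]]:
    """Call up/down DEG sets with strict thresholds.

    UP: q < q_threshold and log2fc > lfc_threshold and max RPKM > min_rpkm
    in at least one sample; DOWN mirrored. All inequalities strict.
    """
    max_rpkm = rpkm_matrix.reindex(de.index).max(axis=1)
    q = de["qvalue"]
    lfc = de["log2fc"]
    expressed = max_rpkm > min_rpkm
    sig = q.notna() & (q < q_threshold) & expressed
    up = set(de.index[sig & (lfc > lfc_threshold)])
    down = set(de.index[sig & (lfc < -lfc_threshold)])
    return up, down


def classify_dependence(
    wt_log2fc: float,
    ko_log2fc: float | None,
    direction: str,
    ratio: float = DEPENDENCE_RATIO,
) -> str:
    """DEP vs INDEP for a wild-type DEG, by the knockout fold comparison.

    Up-regulated: dependent when the WT fold induction is at least ``ratio``
    times the KO induction; down-regulated mirrored on the repression side.
    A missing KO estimate is treated as no response (ko_log2fc = 0), which
    biases toward DEP.
    """
    if direction not in {"up", "down"}:
        raise ValueError("direction must be 'up' or 'down'")
    ko = 0.0 if ko_log2fc is None or np.isnan(ko_log2fc) else ko_log2fc
    if direction == "up":
        dep = 2.0 ** (wt_log2fc - ko) >= ratio
    else:
        dep = 2.0 ** (ko - wt_log2fc) >= ratio
    return "DEP" if dep else "INDEP"


def assign_modes(
    de_wt: pd.DataFrame,
    de_ko: pd.DataFrame,
    rpkm_matrix: pd.DataFrame,
    **thresholds,
) -> pd.Series:
    """Per-gene :class:`RegulatoryMode` from WT DEG calls + the KO contrast."""
    up, down = call_degs(de_wt, rpkm_matrix, **thresholds)
    modes = pd.Series(RegulatoryMode.UNCHANGED, index=de_wt.index, dtype=object)
    ko_lfc = de_ko["log2fc"] if de_ko is not None else pd.Series(dtype=float)
    for gene in up:
        dep = classify_dependence(
            de_wt.at[gene, "log2fc"], ko_lfc.get(gene), "up"
        )
        modes.at[gene] = RegulatoryMode.UP_DEP if dep == "DEP" else RegulatoryMode.UP_INDEP
    for gene in down:
        dep = classify_dependence(
            de_wt.at[gene, "log2fc"], ko_lfc.get(gene), "down"
        )
        modes.at[gene] = RegulatoryMode.DOWN_DEP if dep == "DEP" else RegulatoryMode.DOWN_INDEP
    return modes


def spearman_cluster(rpkm_matrix: pd.DataFrame, min_rpkm: float = EXPRESSED_RPKM):
    """Average-linkage clustering of samples on 1 - Spearman rho.

    Genes are restricted to those expressed (RPKM > min_rpkm in >= 1
    sample). Returns (linkage matrix, ordered sample labels); columns are
    taken in sorted sample_id order for determinism.
    """
    expressed = rpkm_matrix.max(axis=1) > min_rpkm
    mat = rpkm_matrix.loc[expressed].reindex(sorted(rpkm_matrix.columns), axis=1)
    if mat.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 expressed genes")
    ranks = mat.rank(axis=0)
    sds = ranks.std(axis=0)
    flat = sds[sds == 0]
    if len(flat):
        raise ValueError(
            f"sample {flat.index[0]!r} has constant expression (no rank variance)"
        )
    rho = np.corrcoef(ranks.to_numpy().T)
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = linkage(squareform(dist, checks=False), method="average")
    return z, list(mat.columns)


def geneset_enrichment(
    genes: set[str],
    universe: set[str],
    sets: dict[str, set[str]],
    min_size: int = 10,
    max_size: int = 2000,
) -> pd.DataFrame:
    """One-sided Fisher (hypergeometric upper tail) gene-set enrichment.

    Sets are restricted to the universe and filtered to sizes strictly
    between ``min_size`` and ``max_size``.
    """
    if not genes <= universe:
        raise ValueError("query genes must be a subset of the universe")
    m_total = len(universe)
    n_query = len(genes)
    rows = []
    for name, members in sets.items():
        in_universe = members & universe
        size = len(in_universe)
        if not (min_size < size < max_size):
            continue
        k = len(in_universe & genes)
        p = float(stats.hypergeom.sf(k - 1, m_total, size, n_query))
        rows.append({"set": name, "set_size": size, "overlap": k, "pvalue": p})
    return pd.DataFrame(rows, columns=["set", "set_size", "overlap", "pvalue"]).set_index("set")
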