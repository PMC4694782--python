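"""Synthetic-study generators: determinism, planted-truth consistency."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from p53response.landscape import PeakClass
from p53response.motif import MotifClass
from p53response.simulate import (SimConfig, _largest_remainder, sample_site,
                                  simulate_genome, simulate_peaks,
                                  simulate_study, write_bundle,
                                  _DEGENERATE, _HALF_CONSENSUS)
from p53response.motif import p53_consensus_pwm


class TestConfig:
    def test_fraction_validation(self):
        with pytest.raises(ValueError):
            SimConfig(class_fractions=(0.5, 0.6, 0.2))

    def test_infeasible_packing(self):
        with pytest.raises(ValueError, match="packing"):
            SimConfig(n_peaks=100, genome_length=10_000)

    def test_largest_remainder_sums(self):
        for n in (7, 500, 501, 502):
            counts = _largest_remainder((0.4, 0.4, 0.2), n)
            assert sum(counts) == n


class TestGenome:
    def test_seed_determinism_byte_identical(self, tmp_path):
        cfg = SimConfig(seed=9, n_peaks=20, n_genes=30)
        b1 = simulate_study(cfg)
        b2 = simulate_study(cfg)
        assert b1.sequences == b2.sequences
        pd.testing.assert_frame_equal(b1.counts, b2.counts)
        d1, d2 = tmp_path / "one", tmp_path / "two"
        write_bundle(b1, d1)
        write_bundle(b2, d2)
        for f in ("genome.fa", "counts.tsv", "peaks.narrowPeak"):
            assert (d1 / f).read_bytes() == (d2 / f).read_bytes()

    def test_registry_sites_present_in_sequence(self):
        cfg = SimConfig(seed=2, n_peaks=40, n_genes=50)
        seqs, registry = simulate_genome(cfg)
        genome = seqs["chrS"]
        planted = registry[registry.motif_class != MotifClass.NO_MOTIF]
        assert len(planted) > 0
        for row in planted.itertuples():
            assert genome[row.site_start:row.site_start + len(row.site_seq)] \
                == row.site_seq

    def test_zero_motif_rate_plants_nothing(self):
        rates = {cls: (0.0, 0.0, 1.0) for cls in PeakClass}
        cfg = SimConfig(seed=1, n_peaks=10, motif_rates_by_class=rates)
        _, registry = simulate_genome(cfg)
        assert (registry.motif_class == MotifClass.NO_MOTIF).all()
        assert (registry.site_start == -1).all()

    def test_consensus_space_has_256_half_sites(self):
        # 8 two-fold degenerate positions -> 2^8 distinct decamers
        rng = np.random.default_rng(0)
        pwm = p53_consensus_pwm()
        halves = {sample_site(pwm, 0, rng, consensus_only=True)[:10]
                  for _ in range(20_000)}
        n_possible = int(np.prod([len(_DEGENERATE[c]) for c in _HALF_CONSENSUS]))
        assert n_possible == 256
        assert halves <= self._all_halves()
        assert len(halves) > 250   # 20k draws cover nearly all 256

    @staticmethod
    def _all_halves():
        out = {""}
        for c in _HALF_CONSENSUS:
            out = {p + b for p in out for b in _DEGENERATE[c]}
        return out


class TestPeaks:
    def test_empty_config(self):
        cfg = SimConfig(seed=0, n_peaks=0, genome_length=1000, n_genes=10)
        seqs, registry = simulate_genome(cfg)
        peaks, truth = simulate_peaks(cfg, registry)
        assert len(peaks) == 0 and len(truth) == 0

    def test_planted_class_counts_exact(self):
        cfg = SimConfig(seed=3, n_peaks=500)
        _, registry = simulate_genome(cfg)
        counts = registry.peak_class.value_counts()
        assert counts[PeakClass.PROMOTER] == 200
        assert counts[PeakClass.ENHANCER] == 200
        assert counts[PeakClass.UNMARKED_DISTAL] == 100

    def test_summit_at_planted_site(self):
        cfg = SimConfig(seed=4, n_peaks=30)
        _, registry = simulate_genome(cfg)
        peaks, _ = simulate_peaks(cfg, registry)
        planted = registry[registry.motif_class != MotifClass.NO_MOTIF]
        for row in planted.itertuples():
            assert peaks[row.peak_name].summit == row.summit


class TestAnnotationAndCounts:
    def test_unmarked_only_gives_empty_marks(self):
        cfg = SimConfig(seed=5, n_peaks=10, n_genes=20,
                        class_fractions=(0.0, 0.0, 1.0))
        bundle = simulate_study(cfg)
        for mark, ps in bundle.marks.items():
            assert len(ps) == 0, mark

    def test_counts_shape_and_meta_design(self):
        cfg = SimConfig(seed=6, n_peaks=10, n_genes=40, n_replicates=3)
        bundle = simulate_study(cfg)
        assert bundle.counts.shape == (40, 12)   # 2 genotypes x 2 treatments x 3
        assert set(bundle.meta.genotype) == {"WT", "KO"}
        assert set(bundle.meta.treatment) == {"mock", "IR"}

    def test_unbalanced_ko_design(self):
        cfg = SimConfig(seed=6, n_peaks=10, n_genes=20, n_replicates=4,
                        ko_replicates=2)
        bundle = simulate_study(cfg)
        assert (bundle.meta.genotype == "KO").sum() == 4
        assert (bundle.meta.genotype == "WT").sum() == 8

    def test_low_dispersion_means_near_truth(self):
        # dispersion -> 0 with fold 1: sample means approach base means
        cfg = SimConfig(seed=7, n_peaks=0, genome_length=1200, n_genes=200,
                        n_replicates=50, dispersion=1e-8, fraction_null=1.0)
        genes = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(200)], "chrom": "chrU",
            "strand": "+", "tss": np.arange(200) * 10 + 100, "exon_length": 1000,
        })
        from p53response.expression import RegulatoryMode
        plan = pd.DataFrame({
            "gene_id": genes.gene_id, "mode": RegulatoryMode.UNCHANGED,
            "wt_fold": 1.0, "ko_fold": 1.0, "bound_peak": None,
            "motif_class": MotifClass.NO_MOTIF,
        })
        from p53response.simulate import simulate_counts
        counts, meta = simulate_counts(cfg, genes, plan)
        # all four groups share one base mean per gene; in the Poisson limit
        # their group means agree within sampling error of the mean
        groups = [counts[meta.index[(meta.genotype == g) & (meta.treatment == t)]]
                  for g in ("WT", "KO") for t in ("mock", "IR")]
        m0 = groups[0].mean(axis=1).to_numpy()
        n = groups[0].shape[1]
        for other in groups[1:]:
            m1 = other.mean(axis=1).to_numpy()
            sd = np.sqrt((m0 + m1) / (2 * n) * 2)
            assert (np.abs(m1 - m0) < 5 * sd + 1.0).mean() > 0.98
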