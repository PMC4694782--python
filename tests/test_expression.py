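"""RPKM, the NB differential-expression stand-in, DEG calling, dependence,
clustering and gene-set enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.special import comb

from p53response.expression import (call_degs, classify_dependence,
                                    geneset_enrichment, nb_de_test, rpkm,
                                    spearman_cluster)


def _matrix(values, genes=None, samples=None):
    values = np.atleast_2d(values)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


class TestRpkm:
    def test_formula(self):
        counts = _matrix([[10]])
        out = rpkm(counts, pd.Series({"g0": 1000}), pd.Series({"s0": 10**6}))
        assert out.iloc[0, 0] == pytest.approx(10.0)

    def test_zero_counts(self):
        out = rpkm(_matrix([[0]]), pd.Series({"g0": 500}), pd.Series({"s0": 100}))
        assert out.iloc[0, 0] == 0.0

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            rpkm(_matrix([[1]]), pd.Series({"g0": 0}), pd.Series({"s0": 100}))

    @given(st.integers(1, 1000), st.integers(100, 5000), st.integers(10**4, 10**7))
    def test_linear_in_counts_inverse_in_length_and_total(self, c, length, total):
        base = rpkm(_matrix([[c]]), pd.Series({"g0": length}),
                    pd.Series({"s0": total})).iloc[0, 0]
        doubled = rpkm(_matrix([[2 * c]]), pd.Series({"g0": length}),
                       pd.Series({"s0": total})).iloc[0, 0]
        halflen = rpkm(_matrix([[c]]), pd.Series({"g0": 2 * length}),
                       pd.Series({"s0": total})).iloc[0, 0]
        assert doubled == pytest.approx(2 * base)
        assert halflen == pytest.approx(base / 2)


def _meta(n=4, genotypes=("WT", "KO")):
    rows = []
    for g in genotypes:
        for t in ("mock", "IR"):
            for r in range(1, n + 1):
                rows.append({"sample_id": f"{g}_{t}_r{r}", "genotype": g,
                             "treatment": t, "cell_type": "B", "replicate": r})
    return pd.DataFrame(rows).set_index("sample_id")


class TestNbDeTest:
    def test_identical_counts_zero_fold_change(self):
        meta = _meta(n=3, genotypes=("WT",))
        counts = pd.DataFrame(
            {s: [100, 40, 7] for s in meta.index},
            index=["g0", "g1", "g2"],
        )
        de = nb_de_test(counts, meta, genotype="WT")
        assert np.allclose(de["log2fc"], 0.0)

    def test_replicate_requirement(self):
        meta = _meta(n=1, genotypes=("WT",))
        counts = pd.DataFrame({s: [10] for s in meta.index}, index=["g0"])
        with pytest.raises(ValueError, match="replicates"):
            nb_de_test(counts, meta, genotype="WT")

    def test_planted_fold_change_recovered(self):
        # 4-fold induction planted in a minority of genes (median-of-ratios
        # normalization assumes most genes are unchanged)
        rng = np.random.default_rng(42)
        meta = _meta(n=4)
        n_genes, n_de = 1000, 100
        base = rng.lognormal(np.log(100), 0.3, n_genes)
        fold = np.ones(n_genes)
        fold[:n_de] = 4.0
        r = 1 / 0.05
        cols = {}
        for s, row in meta.iterrows():
            mu = base * (fold if row.treatment == "IR" and row.genotype == "WT"
                         else 1.0)
            cols[s] = rng.negative_binomial(r, r / (r + mu))
        counts = pd.DataFrame(cols, index=[f"g{i}" for i in range(n_genes)])
        de = nb_de_test(counts, meta, genotype="WT")
        planted = de.iloc[:n_de]
        assert planted["log2fc"].median() == pytest.approx(2.0, abs=0.2)
        assert de.iloc[n_de:]["log2fc"].abs().median() < 0.2

    def test_bh_monotone_in_pvalue(self):
        rng = np.random.default_rng(0)
        meta = _meta(n=4, genotypes=("WT",))
        counts = pd.DataFrame(
            rng.poisson(50, size=(200, len(meta.index))),
            index=[f"g{i}" for i in range(200)], columns=meta.index,
        )
        de = nb_de_test(counts, meta, genotype="WT").dropna().sort_values("pvalue")
        assert (np.diff(de["qvalue"]) >= -1e-12).all()


class TestCallDegs:
    def _de(self, q, lfc):
        return pd.DataFrame({"log2fc": [lfc], "qvalue": [q]}, index=["g"])

    def _rpkm(self, v=2.0):
        return pd.DataFrame({"s1": [v]}, index=["g"])

    def test_up_call(self):
        up, down = call_degs(self._de(0.04, 0.60), self._rpkm())
        assert up == {"g"} and down == set()

    def test_lfc_boundary_strict(self):
        up, down = call_degs(self._de(0.04, 0.58), self._rpkm())
        assert up == set()

    def test_q_boundary_strict(self):
        up, _ = call_degs(self._de(0.05, 1.0), self._rpkm())
        assert up == set()

    def test_expression_floor(self):
        up, _ = call_degs(self._de(0.01, 1.0), self._rpkm(v=0.9))
        assert up == set()

    def test_down_mirrored_and_disjoint(self):
        de = pd.DataFrame({"log2fc": [1.0, -1.0], "qvalue": [0.01, 0.01]},
                          index=["u", "d"])
        rp = pd.DataFrame({"s": [5.0, 5.0]}, index=["u", "d"])
        up, down = call_degs(de, rp)
        assert up == {"u"} and down == {"d"}
        assert not (up & down)


class TestDependence:
    def test_up_dependent(self):
        # WT fold 4 vs KO fold 2 -> ratio 2 >= 1.5
        assert classify_dependence(np.log2(4), np.log2(2), "up") == "DEP"

    def test_up_independent(self):
        assert classify_dependence(np.log2(1.6), np.log2(1.5), "up") == "INDEP"

    def test_down_dependent(self):
        # WT fold 0.25 vs KO 0.5 -> repression 2x stronger
        assert classify_dependence(np.log2(0.25), np.log2(0.5), "down") == "DEP"

    def test_boundary_inclusive(self):
        assert classify_dependence(np.log2(3.0), np.log2(2.0), "up") == "DEP"

    def test_missing_ko_treated_as_no_response(self):
        assert classify_dependence(1.0, None, "up") == "DEP"
        assert classify_dependence(0.3, None, "up") == "INDEP"

    def test_direction_validated(self):
        with pytest.raises(ValueError):
            classify_dependence(1.0, 0.0, "sideways")


class TestSpearmanCluster:
    def test_duplicate_samples_merge_first_at_zero(self):
        rng = np.random.default_rng(1)
        g = rng.lognormal(2, 1, 50)
        mat = pd.DataFrame({
            "a1": g, "a2": g,
            "b1": rng.lognormal(2, 1, 50),
            "b2": rng.lognormal(2, 1, 50),
        }, index=[f"g{i}" for i in range(50)])
        z, labels = spearman_cluster(mat)
        first = z[0]
        merged = {labels[int(first[0])], labels[int(first[1])]}
        assert merged == {"a1", "a2"}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_reversed_ranks_distance_two(self):
        vals = np.arange(1.0, 21.0)
        mat = pd.DataFrame({"fwd": vals, "rev": vals[::-1]},
                           index=[f"g{i}" for i in range(20)])
        z, _ = spearman_cluster(mat)
        assert z[0][2] == pytest.approx(2.0)

    def test_constant_sample_named_in_error(self):
        mat = pd.DataFrame({"flat": [5.0] * 10,
                            "ok": np.arange(10.0) + 1},
                           index=[f"g{i}" for i in range(10)])
        with pytest.raises(ValueError, match="flat"):
            spearman_cluster(mat)


class TestGenesetEnrichment:
    def test_disjoint_set_p_one(self):
        universe = {f"g{i}" for i in range(100)}
        genes = {f"g{i}" for i in range(10)}
        sets = {"away": {f"g{i}" for i in range(50, 70)}}
        res = geneset_enrichment(genes, universe, sets)
        assert res.loc["away", "pvalue"] == pytest.approx(1.0)

    def test_size_filter(self):
        universe = {f"g{i}" for i in range(100)}
        genes = {f"g{i}" for i in range(10)}
        sets = {"tiny": {f"g{i}" for i in range(5)},
                "ok": {f"g{i}" for i in range(30)}}
        res = geneset_enrichment(genes, universe, sets)
        assert "tiny" not in res.index and "ok" in res.index

    def test_hypergeometric_closed_form(self):
        universe = {f"g{i}" for i in range(20)}
        genes = {f"g{i}" for i in range(10)}
        sets = {"exact": set(genes)}
        res = geneset_enrichment(genes, universe, sets, min_size=5)
        assert res.loc["exact", "pvalue"] == pytest.approx(
            1.0 / comb(20, 10), rel=1e-9
        )

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            geneset_enrichment({"x"}, {"a", "b"}, {})
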