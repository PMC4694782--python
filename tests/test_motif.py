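"""Spaced PWM model, log-odds scoring, exact p-values and window scanning."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from p53response.benchmarks import enumerate_pvalues
from p53response.motif import (MotifClass, MotifHit, Pwm, build_spaced_pwm,
                               classify_hits, group_compare, log_odds_score,
                               p53_consensus_pwm, reverse_complement,
                               scan_window, score_pvalue, score_pvalues,
                               spacer_distribution)


def all_a_pwm(width=4):
    """Near-deterministic all-A columns (probability 1 up to numerics)."""
    counts = np.zeros((width, 4))
    counts[:, 0] = 1.0
    return Pwm.from_counts(counts, pseudocount=1e-12)


class TestPwm:
    def test_rows_must_sum_to_one(self):
        with pytest.raises(ValueError):
            Pwm(probs=np.full((4, 4), 0.3))

    def test_zero_entries_rejected(self):
        probs = np.zeros((2, 4))
        probs[:, 0] = 1.0
        with pytest.raises(ValueError):
            Pwm(probs=probs)

    def test_consensus_and_information(self):
        pwm = p53_consensus_pwm()
        assert pwm.width == 20
        # invariant C and G positions of RRRCWWGYYY at both half sites
        assert pwm.consensus[3] == "C" and pwm.consensus[6] == "G"
        assert pwm.consensus[13] == "C" and pwm.consensus[16] == "G"
        assert pwm.information_content > 15.0

    def test_reverse_complement_involution(self):
        pwm = p53_consensus_pwm()
        rc2 = pwm.reverse_complement().reverse_complement()
        assert np.allclose(rc2.probs, pwm.probs)


class TestSpacedPwm:
    def test_variant_widths(self):
        model = build_spaced_pwm(p53_consensus_pwm())
        assert sorted(v.width for v in model.variants.values()) == list(range(20, 36))

    def test_zero_spacer_equals_input(self):
        full = p53_consensus_pwm()
        model = build_spaced_pwm(full)
        assert np.allclose(model.variants[0].probs, full.probs)

    def test_spacer_columns_equal_background(self):
        model = build_spaced_pwm(p53_consensus_pwm())
        v15 = model.variants[15]
        assert np.allclose(v15.probs[10:25], model.background[None, :])

    def test_wrong_width_rejected(self):
        with pytest.raises(ValueError, match="width 20"):
            build_spaced_pwm(all_a_pwm(width=4))


class TestScoring:
    def test_all_a_consensus_scores_eight_bits(self):
        assert log_odds_score(all_a_pwm(), "AAAA") == pytest.approx(8.0, abs=1e-6)

    def test_background_pwm_scores_zero(self):
        pwm = Pwm(probs=np.full((6, 4), 0.25))
        assert log_odds_score(pwm, "ACGTAC") == pytest.approx(0.0)

    def test_n_contributes_zero(self):
        assert log_odds_score(all_a_pwm(), "AANA") == pytest.approx(6.0, abs=1e-6)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            log_odds_score(all_a_pwm(), "AAAAA")


class TestPvalue:
    def test_minimum_score_gives_one(self):
        pwm = all_a_pwm()
        assert score_pvalue(pwm, -1e6) == 1.0

    def test_max_score_is_one_in_256(self):
        pwm = all_a_pwm()
        mx = log_odds_score(pwm, "AAAA")
        assert score_pvalue(pwm, mx) == pytest.approx(1 / 256)

    @pytest.mark.parametrize("seed", [0, 5])
    def test_dp_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        w = int(rng.integers(4, 9))
        probs = rng.dirichlet(np.full(4, 0.8), size=w)
        probs = np.clip(probs, 1e-4, None)
        probs /= probs.sum(axis=1, keepdims=True)
        pwm = Pwm(probs=probs)
        lo = np.log2(pwm.probs / pwm.background[None, :])
        scores = np.zeros(1)
        for c in range(w):
            scores = np.unique((scores[:, None] + lo[c][None, :]).ravel())
        assert np.abs(
            score_pvalues(pwm, scores) - enumerate_pvalues(pwm, scores)
        ).max() <= 1e-3

    def test_monotone_in_score(self):
        pwm = p53_consensus_pwm()
        grid = np.linspace(-40, 25, 200)
        pv = score_pvalues(pwm, grid)
        assert (np.diff(pv) <= 1e-12).all()

    def test_lattice_path_used_for_wide_model(self):
        model = build_spaced_pwm(p53_consensus_pwm())
        v = model.variants[15]           # width 35 -> lattice DP
        assert score_pvalue(v, -1e6) == 1.0
        # max score is shared by 2^16 sequences (two allowed bases at each
        # degenerate consensus position), so its exact p is 2^16 * 0.25^20
        hi = float(v.log_odds()[:, :4].max(axis=1).sum())
        assert score_pvalue(v, hi) == pytest.approx(2**16 * 0.25**20, rel=0.05)


@pytest.fixture(scope="module")
def model():
    return build_spaced_pwm(p53_consensus_pwm())


def planted_window(site, offset, length=600, seed=0):
    rng = np.random.default_rng(seed)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, length))
    return seq[:offset] + site + seq[offset + len(site):]


CONSENSUS_SITE = "AGACATGTCT" * 2  # one realization of RRRCWWGYYY x2


class TestScan:
    def test_all_n_window_has_no_hit(self, model):
        assert scan_window("N" * 600, model) is None

    def test_planted_consensus_found_at_offset(self, model):
        win = planted_window(CONSENSUS_SITE, 137)
        hit = scan_window(win, model)
        assert hit is not None
        assert hit.offset == 137
        assert hit.spacer == 0
        assert hit.pvalue < 1e-4
        assert hit.matched_seq == CONSENSUS_SITE

    def test_two_identical_sites_tie_breaks_to_smaller_offset(self, model):
        win = planted_window(CONSENSUS_SITE, 100)
        win = win[:400] + CONSENSUS_SITE + win[400 + 20:]
        hit = scan_window(win, model)
        assert hit.offset == 100

    def test_spaced_site_recovers_spacer(self, model):
        site = CONSENSUS_SITE[:10] + "TATAT" + CONSENSUS_SITE[10:]
        hit = scan_window(planted_window(site, 200), model)
        assert hit.spacer == 5
        assert hit.motif_class == MotifClass.SPACED

    def test_reverse_complement_invariance_symmetric_model(self, model):
        # the p53 RE consensus family is reverse-complement closed, so the
        # p-value and spacer are unchanged and the site is found either way
        win = planted_window(CONSENSUS_SITE, 222, seed=3)
        fwd = scan_window(win, model)
        rev = scan_window(reverse_complement(win), model)
        assert rev is not None
        assert rev.pvalue == fwd.pvalue
        assert rev.spacer == fwd.spacer
        assert rev.offset == len(win) - fwd.offset - 20

    def test_reverse_complement_flips_strand_for_asymmetric_model(self):
        word = "AAACCCGGGTTTACGTACGA"        # not RC-symmetric
        counts = np.zeros((20, 4))
        for i, b in enumerate(word):
            counts[i, "ACGT".index(b)] = 10.0
        model = build_spaced_pwm(Pwm.from_counts(counts, pseudocount=0.5))
        win = planted_window(word, 300, seed=4)
        fwd = scan_window(win, model)
        rev = scan_window(reverse_complement(win), model)
        assert fwd is not None and rev is not None
        assert rev.pvalue == fwd.pvalue
        assert {fwd.strand, rev.strand} == {"+", "-"}
        assert rev.matched_seq == fwd.matched_seq == word

    def test_invalid_characters_rejected(self, model):
        with pytest.raises(ValueError, match="invalid characters"):
            scan_window("ACGTX" * 100, model)

    def test_report_all_orders_by_pvalue(self, model):
        win = planted_window(CONSENSUS_SITE, 100)
        win = win[:400] + CONSENSUS_SITE + win[420:]
        hits = scan_window(win, model, report_all=True)
        assert len(hits) >= 2
        assert hits[0].pvalue <= hits[-1].pvalue


class TestSummaries:
    def hit(self, spacer, name="p"):
        return MotifHit(name, 0, "+", spacer, 20.0, 1e-9, "X")

    def test_all_none(self):
        classes, freq = classify_hits({"a": None, "b": None})
        assert freq[MotifClass.NO_MOTIF] == 1.0
        assert freq[MotifClass.UNSPLIT] == 0.0

    def test_counting(self):
        hits = {"a": self.hit(0), "b": self.hit(0), "c": self.hit(3)}
        classes, freq = classify_hits(hits)
        assert freq[MotifClass.UNSPLIT] == pytest.approx(2 / 3)
        assert freq[MotifClass.SPACED] == pytest.approx(1 / 3)
        assert sum(freq.values()) == pytest.approx(1.0)

    def test_spacer_distribution(self):
        hits = [self.hit(2), self.hit(2), self.hit(5), self.hit(0), None]
        counts = spacer_distribution(hits)
        assert counts[1] == 2 and counts[4] == 1
        assert counts.sum() == 3

    def test_spacer_distribution_empty(self):
        assert spacer_distribution([None, self.hit(0)]).sum() == 0


class TestGroupCompare:
    def test_identical_groups(self):
        res = group_compare({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        t = res["tests"][("a", "b")]
        assert t["t"] == pytest.approx(0.0)
        assert t["pvalue"] == pytest.approx(1.0)

    def test_textbook_pooled_t(self):
        # pooled t with 4 df: {1,2,3} vs {4,5,6}
        res = group_compare({"lo": [1, 2, 3], "hi": [4, 5, 6]})
        t = res["tests"][("lo", "hi")]
        assert t["t"] == pytest.approx(-3.674, abs=1e-3)
        assert t["pvalue"] == pytest.approx(0.0214, abs=1e-3)

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            group_compare({"a": [1.0], "b": [1.0, 2.0]})
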