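"""PWMs, k-mers, cumulative scores, Fisher/Wilcoxon with exact oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom, rankdata

import mpraloc as m
from mpraloc.motifs import signed_rank_test, wilcoxon_exact_p


def _pwm(rows, motif_id="M1"):
    return m.Pwm(motif_id, np.array(rows, dtype=float))


DETERMINISTIC6 = _pwm(
    [[1, 0, 0, 0], [0, 0, 1, 0], [0, 0, 1, 0], [0, 0, 0, 1], [1, 0, 0, 0], [1, 0, 0, 0]]
)  # AGGTAA


class TestMemeIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        mats = []
        for k, w in enumerate((6, 8)):
            raw = rng.random((w, 4)) + 0.05
            mats.append(m.Pwm(f"motif{k}", raw / raw.sum(1, keepdims=True)))
        path = tmp_path / "motifs.meme"
        m.write_meme_motifs(mats, path)
        back = m.read_meme_motifs(path)
        assert [b.motif_id for b in back] == ["motif0", "motif1"]
        for a, b in zip(mats, back):
            assert np.allclose(a.matrix, b.matrix, atol=1e-6)

    def test_bad_row_sum_rejected(self, tmp_path):
        path = tmp_path / "bad.meme"
        path.write_text(
            "MEME version 4\n\nMOTIF bad\n"
            "letter-probability matrix: alphlength= 4 w= 4\n"
            + "0.5 0.5 0.5 0.5\n" * 4
        )
        with pytest.raises(ValueError, match="bad"):
            m.read_meme_motifs(path)

    def test_invariant_enforced_on_construction(self):
        with pytest.raises(ValueError):
            _pwm([[0.5, 0.5, 0.5, 0.5]] * 4)
        with pytest.raises(ValueError):  # width < 4
            _pwm([[0.25] * 4] * 3)


class TestTopKmers:
    def test_deterministic_pwm_unique_top(self):
        assert m.top_n_kmers(DETERMINISTIC6, 1) == ["AGGTAA"]

    def test_order_matches_exhaustive_products(self):
        pwm = _pwm(
            [[0.6, 0.4, 0, 0], [0, 0, 0.7, 0.3], [1, 0, 0, 0], [0, 1, 0, 0]]
        )
        # oracle: enumerate all 4-mers, sort by probability product then lex
        probs = {}
        for kmer in map("".join, itertools.product("ACGT", repeat=4)):
            p = 1.0
            for i, b in enumerate(kmer):
                p *= pwm.matrix[i, "ACGT".index(b)]
            if p > 0:
                probs[kmer] = p
        oracle = sorted(probs, key=lambda k: (-probs[k], k))
        assert m.top_n_kmers(pwm, 4) == oracle[:4] == ["AGAC", "CGAC", "ATAC", "CTAC"]

    def test_n_larger_than_space(self):
        assert len(m.top_n_kmers(DETERMINISTIC6, 10_000)) == 4**6


class TestCumulativeScore:
    def test_no_positive_windows_is_zero(self):
        # uniform PWM: every window log-odds 0 -> positive part 0
        pwm = _pwm([[0.25] * 4] * 4)
        assert m.cumulative_score("ACGTACGTACGT", pwm) == 0.0

    def test_single_perfect_match_brute_force(self):
        seq = "C" * 40 + "AGGTAA" + "C" * 40
        # oracle: per-window sum of positive log2 odds
        lo = DETERMINISTIC6.log_odds()
        expected = 0.0
        for i in range(len(seq) - 5):
            w = sum(lo[j, "ACGT".index(seq[i + j])] for j in range(6))
            expected += max(0.0, w)
        got = m.cumulative_score(seq, DETERMINISTIC6)
        assert got == pytest.approx(expected)
        assert got == pytest.approx(12.0)  # only the match window is positive

    def test_shorter_than_motif_zero(self):
        assert m.cumulative_score("ACG", DETERMINISTIC6) == 0.0

    def test_prepending_neutral_background_leaves_score(self):
        seq = "G" * 20 + "AGGTAA" + "G" * 20
        s0 = m.cumulative_score(seq, DETERMINISTIC6)
        s1 = m.cumulative_score("C" * 30 + seq, DETERMINISTIC6)
        assert s1 >= s0
        assert s1 == pytest.approx(s0)  # C/G-only junction windows score -inf


class TestMotifEnrichment:
    def _fisher_oracle(self, a, b, c, d):
        """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
        n, K, N = a + b + c + d, a + c, a + b
        rv = hypergeom(n, K, N)
        p_obs = rv.pmf(a)
        # <= with a tiny relative slack so float noise cannot drop a tied table
        return sum(
            rv.pmf(k)
            for k in range(max(0, N + K - n), min(K, N) + 1)
            if rv.pmf(k) <= p_obs * (1 + 1e-7)
        )

    def test_matches_enumeration_oracle(self):
        fg = ["AGGTAA" + "C" * 20] * 8 + ["C" * 26] * 2
        bg = ["AGGTAA" + "C" * 20] * 10 + ["C" * 26] * 90
        res = m.motif_enrichment(fg, bg, {"M": ["AGGTAA"]}, p_threshold=0.001)
        assert res.pvalue.iloc[0] == pytest.approx(self._fisher_oracle(8, 2, 10, 90))
        assert res.fg_hits.iloc[0] == 8 and res.bg_hits.iloc[0] == 10

    def test_identical_sets_p_one(self):
        seqs = ["AGGTAACCC", "CCCCCCCCC"]
        res = m.motif_enrichment(seqs, seqs, {"M": ["AGGTAA"]})
        assert res.pvalue.iloc[0] == pytest.approx(1.0)
        assert not res.enriched.iloc[0]

    def test_absent_motif_degenerate(self):
        res = m.motif_enrichment(["CCC"] * 5, ["GGG"] * 7, {"M": ["AGGTAA"]})
        assert res.pvalue.iloc[0] == pytest.approx(1.0)

    @given(st.integers(0, 8), st.integers(0, 8), st.integers(0, 7), st.integers(0, 7))
    @settings(max_examples=40, deadline=None)
    def test_random_tables_match_oracle(self, a, b, c, d):
        fg = ["AGGTAA"] * a + ["CCCCCC"] * b
        bg = ["AGGTAA"] * c + ["CCCCCC"] * d
        if not fg or not bg:
            return
        res = m.motif_enrichment(fg, bg, {"M": ["AGGTAA"]})
        assert res.pvalue.iloc[0] == pytest.approx(
            self._fisher_oracle(a, b, c, d), rel=1e-9, abs=1e-12
        )


class TestCorrelateScores:
    def test_perfectly_linear(self):
        scores = pd.DataFrame({"M": [1.0, 2, 3, 4, 5]}, index=list("abcde"))
        logfc = pd.Series([2.0, 4, 6, 8, 10], index=list("abcde"))
        res = m.correlate_scores(scores, logfc)
        assert res.pearson_r.iloc[0] == pytest.approx(1.0)

    def test_constant_scores_nan(self):
        scores = pd.DataFrame({"M": [1.0] * 5}, index=list("abcde"))
        logfc = pd.Series([1.0, 2, 3, 4, 5], index=list("abcde"))
        assert np.isnan(m.correlate_scores(scores, logfc).pearson_r.iloc[0])

    def test_five_point_example(self):
        # direct Pearson formula gives r = 0.8 for this configuration
        x = np.array([1, 2, 3, 4, 5.0])
        y = np.array([2, 1, 4, 3, 5.0])
        r_oracle = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        scores = pd.DataFrame({"M": x}, index=list("abcde"))
        res = m.correlate_scores(scores, pd.Series(y, index=list("abcde")))
        assert res.pearson_r.iloc[0] == pytest.approx(r_oracle) == pytest.approx(0.8)

    def test_bh_qvalues_monotone(self):
        rng = np.random.default_rng(1)
        scores = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("ABCDE"))
        logfc = pd.Series(rng.normal(size=30), index=scores.index)
        res = m.correlate_scores(scores, logfc).sort_values("pvalue")
        assert (res.qvalue.to_numpy() >= res.pvalue.to_numpy() - 1e-12).all()


class TestWilcoxon:
    def brute_force_p(self, d):
        """Full 2^n enumeration of sign assignments."""
        d = np.asarray(d, float)
        d = d[d != 0]
        n = len(d)
        ranks = rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        total = ranks.sum()
        ws = []
        for mask in range(2**n):
            w = sum(ranks[i] for i in range(n) if mask >> i & 1)
            ws.append(w)
        ws = np.array(ws)
        lower = (ws <= w_obs + 1e-9).mean()
        upper = (ws >= w_obs - 1e-9).mean()
        return min(1.0, 2 * min(lower, upper))

    def test_all_identical_negative_deltas(self):
        d = np.full(10, -0.5)
        assert wilcoxon_exact_p(d) == pytest.approx(2 / 2**10)

    def test_symmetric_deltas_p_near_one(self):
        d = np.array([-2, -1, 1, 2, -0.5, 0.5])
        assert wilcoxon_exact_p(d) == pytest.approx(1.0)

    @given(
        st.lists(
            st.floats(-5, 5, allow_nan=False).filter(lambda x: abs(x) > 1e-6),
            min_size=1,
            max_size=12,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_sign_enumeration(self, deltas):
        assert wilcoxon_exact_p(np.array(deltas)) == pytest.approx(
            self.brute_force_p(deltas), abs=1e-9
        )

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(2)
        d = rng.normal(0.3, 1.0, size=60)
        from scipy.stats import wilcoxon as sp_wilcoxon

        expected = sp_wilcoxon(d, correction=True, method="approx").pvalue
        assert signed_rank_test(d) == pytest.approx(expected)


class TestPairedEffects:
    def test_planted_insertion_effect_recovered(self, insertion_study):
        sim, design_df, enrichment = insertion_study
        rec = m.paired_motif_effect(enrichment, design_df, "TCTTCT", "insertion")
        assert rec.n_pairs >= 50
        planted = sim.config.soma_motifs["TCTTCT"]
        assert rec.mean_delta_logfc == pytest.approx(planted, abs=0.1)
        assert rec.wilcoxon_pvalue < 0.05

    def test_two_copy_insertion_additive(self, insertion_study):
        sim, design_df, enrichment = insertion_study
        rec = m.paired_motif_effect(enrichment, design_df, "AGGTAA", "insertion")
        assert rec.mean_delta_logfc == pytest.approx(0.8, abs=0.15)

    def test_unknown_motif_raises(self, insertion_study):
        _, design_df, enrichment = insertion_study
        with pytest.raises(ValueError, match="no valid pairs"):
            m.paired_motif_effect(enrichment, design_df, "GGGGGG", "insertion")

    def test_dose_response_keys(self, insertion_study):
        _, design_df, enrichment = insertion_study
        per_copy, _ = m.dose_response(enrichment, design_df, "AGGTAA")
        assert set(per_copy) == {0, 2}
        assert per_copy[0] == 0.0
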