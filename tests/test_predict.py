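"""Fourmer features, dataset assembly, dual classifiers, native aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mpraloc as m
from mpraloc.predict import DEFAULT_HYPERPARAMS, FOURMERS, DualModels


class TestFourmers:
    def test_homopolymer(self):
        v = m.extract_fourmers("A" * 150)
        assert v[FOURMERS.index("AAAA")] == 147
        assert v.sum() == 147

    def test_acgtacgt_brute_force(self):
        v = m.extract_fourmers("ACGTACGT")
        expected = {"ACGT": 2, "CGTA": 2, "GTAC": 1, "TACG": 0}
        # oracle by direct scan
        s = "ACGTACGT"
        for k in FOURMERS:
            n = sum(s[i : i + 4] == k for i in range(len(s) - 3))
            assert v[FOURMERS.index(k)] == n
        assert v[FOURMERS.index("ACGT")] == expected["ACGT"]

    def test_short_sequence_zero_vector(self):
        assert m.extract_fourmers("ACG").sum() == 0

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            m.extract_fourmers("ACGTNACGT")

    @given(st.text(alphabet="ACGT", max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_sum_rule(self, seq):
        assert m.extract_fourmers(seq).sum() == max(0, len(seq) - 3)


class TestPrepareDataset:
    def _inputs(self):
        n = 60
        rng = np.random.default_rng(0)
        ids = [f"v{i}" for i in range(n)]
        region = ["".join(rng.choice(list("ACGT"), 150)) for _ in range(n)]
        lfc = rng.normal(size=n)
        enr = pd.DataFrame(
            {"variant_id": ids, "logfc": lfc, "pvalue": rng.uniform(size=n),
             "mean_count": 200.0}
        )
        design = pd.DataFrame({"variant_id": ids, "variable_region": region})
        return enr, design

    def test_read_filter(self):
        enr, design = self._inputs()
        enr2 = enr.copy()
        enr.loc[0, "mean_count"] = 499 / 6  # total 499 -> excluded
        train, test = m.prepare_dataset(enr, enr2, design, min_total_reads=500, seed=1)
        kept = set(train.variant_id) | set(test.variant_id)
        assert "v0" not in kept

    def test_duplicates_collapse_to_one(self):
        enr, design = self._inputs()
        design.loc[:2, "variable_region"] = design.variable_region.iloc[5]
        train, test = m.prepare_dataset(enr, enr.copy(), design, seed=2)
        merged = pd.concat([train, test])
        assert merged.variable_region.is_unique

    def test_label_requires_significance_in_both(self):
        enr, design = self._inputs()
        a, b = enr.copy(), enr.copy()
        a.loc[0, ["logfc", "pvalue"]] = [0.5, 0.01]
        b.loc[0, ["logfc", "pvalue"]] = [0.5, 0.20]
        a.loc[1, ["logfc", "pvalue"]] = [0.7, 0.01]
        b.loc[1, ["logfc", "pvalue"]] = [0.6, 0.02]
        train, test = m.prepare_dataset(a, b, design, seed=3, holdout_frac=0.1)
        merged = pd.concat([train, test]).set_index("variant_id")
        assert not merged.loc["v0", "neurite_positive"]
        assert merged.loc["v1", "neurite_positive"]


class TestCombinedScore:
    def test_values(self):
        assert m.combined_score(0.9, 0.2) == pytest.approx(0.7)
        assert m.combined_score(0.4, 0.4) == 0.0
        assert m.combined_score(1.0, 0.0) == 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            m.combined_score(1.2, 0.0)


class _StubModel:
    """predict_proba stub keyed on the count of a marker fourmer."""

    def __init__(self, mapping):
        self.mapping = mapping  # marker count -> probability

    def predict_proba(self, X):
        marker = X[:, FOURMERS.index("AGGT")]
        p = np.array([self.mapping(int(c)) for c in marker])
        return np.column_stack([1 - p, p])


def _stub_models(fn_neurite, fn_soma):
    return DualModels(
        model_neurite=_StubModel(fn_neurite),
        model_soma=_StubModel(fn_soma),
        feature_names=FOURMERS,
    )


class TestNativePrediction:
    def test_single_tile_is_difference(self):
        models = _stub_models(lambda c: 0.9 if c else 0.2, lambda c: 0.1)
        utr = "C" * 40 + "AGGTAA" + "C" * 104
        pred = m.predict_native(utr, models)
        assert len(pred.tile_starts) == 1
        assert pred.combined == pytest.approx(0.9 - 0.1)

    def test_median_minus_max_aggregation(self):
        # three tiles; vary probabilities through marker counts per tile
        models = _stub_models(
            lambda c: {0: 0.2, 1: 0.6, 2: 0.9}[c], lambda c: {0: 0.1, 1: 0.1, 2: 0.8}[c]
        )
        utr = "C" * 150 + "AGGTAA" * 2 + "C" * 138  # markers only past 150
        pred = m.predict_native(utr, models)
        pn, ps = pred.p_neurite, pred.p_soma
        assert list(pn) == [0.2, 0.9, 0.9, 0.9] and list(ps) == [0.1, 0.8, 0.8, 0.8]
        assert pred.combined == pytest.approx(0.9 - 0.8)

    def test_short_utr_rejected(self):
        models = _stub_models(lambda c: 0.5, lambda c: 0.5)
        with pytest.raises(ValueError):
            m.predict_native("ACGT" * 10, models)


class TestAuroc:
    def brute_force(self, scores, labels):
        pos = [s for s, y in zip(scores, labels) if y == 1]
        neg = [s for s, y in zip(scores, labels) if y == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        return wins / (len(pos) * len(neg))

    def test_examples(self):
        assert m.evaluate_auroc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
        assert m.evaluate_auroc([1, 2, 3, 4], [0, 1, 0, 1]) == 0.75
        assert m.evaluate_auroc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            m.evaluate_auroc([1, 2], [1, 1])

    @given(
        st.lists(
            st.tuples(st.integers(0, 10), st.booleans()), min_size=2, max_size=50
        ).filter(lambda xs: len({y for _, y in xs}) == 2)
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_all_pairs_oracle(self, data):
        scores = [s for s, _ in data]
        labels = [int(y) for _, y in data]
        assert m.evaluate_auroc(scores, labels) == pytest.approx(
            self.brute_force(scores, labels)
        )


class TestTraining:
    def _separable_data(self, n=240, seed=0):
        rng = np.random.default_rng(seed)
        rows, labels = [], []
        for i in range(n):
            has_n = i % 3 == 0
            has_s = i % 3 == 1
            seq = "".join(rng.choice(list("ACGT"), 150))
            if has_n:
                seq = "AGGTAA" * 2 + seq[12:]
            if has_s:
                seq = "TCTTCT" * 2 + seq[12:]
            rows.append((f"v{i}", seq))
            labels.append((has_n, has_s))
        feats = m.feature_matrix({vid: s for vid, s in rows})
        lab = pd.DataFrame(
            {
                "variant_id": [v for v, _ in rows],
                "neurite_positive": [a for a, _ in labels],
                "soma_positive": [b for _, b in labels],
            }
        )
        return feats, lab

    def test_separable_labels_high_auroc(self):
        feats, lab = self._separable_data()
        models = m.train_dual_models(feats, lab, DEFAULT_HYPERPARAMS, seed=1)
        probs = m.predict.predict_probabilities(models, feats)
        y = lab.set_index("variant_id").loc[feats.index, "neurite_positive"]
        assert m.evaluate_auroc(probs.p_neurite, y.astype(int)) >= 0.95

    def test_deterministic_given_seed(self):
        feats, lab = self._separable_data(n=120)
        p1 = m.predict.predict_probabilities(
            m.train_dual_models(feats, lab, DEFAULT_HYPERPARAMS, seed=7), feats
        )
        p2 = m.predict.predict_probabilities(
            m.train_dual_models(feats, lab, DEFAULT_HYPERPARAMS, seed=7), feats
        )
        assert np.array_equal(p1.to_numpy(), p2.to_numpy())

    def test_shuffled_labels_chance_level(self):
        feats, lab = self._separable_data(n=180, seed=2)
        rng = np.random.default_rng(3)
        lab = lab.assign(
            neurite_positive=rng.permutation(lab.neurite_positive.to_numpy()),
            soma_positive=False,
        )
        lab.loc[0, "soma_positive"] = True  # keep both classes present
        from mpraloc.predict import _cv_auroc

        auc = _cv_auroc(
            feats.to_numpy(float),
            lab.neurite_positive.to_numpy(int),
            DEFAULT_HYPERPARAMS,
            seed=4,
        )
        assert 0.35 <= auc <= 0.65

    def test_single_class_rejected(self):
        feats, lab = self._separable_data(n=60)
        lab["soma_positive"] = False
        with pytest.raises(ValueError, match="single class"):
            m.train_dual_models(feats, lab, DEFAULT_HYPERPARAMS, seed=1)

    def test_model_round_trip(self, tmp_path):
        feats, lab = self._separable_data(n=90)
        models = m.train_dual_models(feats, lab, DEFAULT_HYPERPARAMS, seed=5)
        path = tmp_path / "models.joblib"
        models.save(path)
        back = DualModels.load(path)
        assert back.feature_names == models.feature_names
        a = m.predict.predict_probabilities(models, feats)
        b = m.predict.predict_probabilities(back, feats)
        assert np.allclose(a, b)
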