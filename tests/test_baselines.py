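"""Symmetrical uncertainty, FCBF, univariate and tree-importance rankings."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from topictriage.baselines import (
    BinaryFeatureView,
    binarize,
    compare_methods,
    default_classifiers,
    fcbf_select,
    rank_tree_importance,
    rank_univariate,
    symmetrical_uncertainty,
)
from topictriage.config import OuterEvalConfig
from topictriage.errors import InputError
from topictriage.vectorize import DocTermMatrix


def su_oracle(x, y):
    """Brute-force SU from observed joint frequencies, entropies in bits."""

    def entropy(values):
        n = len(values)
        out = 0.0
        for v in set(values):
            p = values.count(v) / n
            out -= p * math.log2(p)
        return out

    x, y = list(x), list(y)
    hx, hy = entropy(x), entropy(y)
    if hx + hy == 0:
        return 0.0
    hxy = entropy(list(zip(x, y)))
    return 2.0 * (hx + hy - hxy) / (hx + hy)


class TestSymmetricalUncertainty:
    def test_identical_nonconstant_vectors(self):
        assert symmetrical_uncertainty([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0

    def test_independent_vectors(self):
        assert symmetrical_uncertainty([0, 0, 1, 1], [0, 1, 0, 1]) == 0.0

    def test_partially_dependent_value(self):
        # closed form: H(x) = 2 - (3/4) log2 3, H(y) = 1, H(x,y) = 3/2,
        # so SU = 2 (H(x) + 1 - 3/2) / (H(x) + 1) = 0.34371101848...
        h = 2.0 - 0.75 * math.log2(3.0)
        expected = 2.0 * (h - 0.5) / (h + 1.0)
        su = symmetrical_uncertainty([0, 0, 0, 1], [0, 0, 1, 1])
        assert su == pytest.approx(expected, abs=1e-12)

    def test_both_constant_defined_as_zero(self):
        assert symmetrical_uncertainty([1, 1, 1], [0, 0, 0]) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            symmetrical_uncertainty([0, 1], [0, 1, 0])

    @given(
        st.lists(st.integers(0, 2), min_size=1, max_size=12),
        st.lists(st.integers(0, 2), min_size=1, max_size=12),
    )
    def test_symmetry_and_oracle_agreement(self, x, y):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        su_xy = symmetrical_uncertainty(x, y)
        su_yx = symmetrical_uncertainty(y, x)
        assert su_xy == pytest.approx(su_yx, abs=1e-12)
        assert su_xy == pytest.approx(su_oracle(x, y), abs=1e-12)
        assert 0.0 <= su_xy <= 1.0


def fcbf_oracle(view: BinaryFeatureView, delta=0.0):
    """Exhaustive restatement of the predominance rule for tiny instances.

    SU values are quantized at 1e-12, matching the implementation's stated
    numerical contract, so mathematically tied features order identically.
    """
    su_class = {
        t: round(su_oracle(list(view.X[:, j]), list(view.y)), 12)
        for j, t in enumerate(view.terms)
    }
    candidates = sorted(
        (t for t in view.terms if su_class[t] > delta),
        key=lambda t: (-su_class[t], t),
    )
    col = {t: j for j, t in enumerate(view.terms)}
    kept = []
    for f in candidates:
        if all(
            round(su_oracle(list(view.X[:, col[f]]), list(view.X[:, col[g]])), 12)
            < su_class[f]
            for g in kept
        ):
            kept.append(f)
    return kept


class TestFcbf:
    def _view(self, X, y):
        X = np.asarray(X)
        return BinaryFeatureView(
            terms=[f"f{j}" for j in range(X.shape[1])],
            X=X,
            y=np.asarray(y, dtype=object),
        )

    def test_class_copy_selected_first(self, rng):
        y = np.asarray(["a", "b"] * 10, dtype=object)
        X = rng.integers(0, 2, size=(20, 4))
        X[:, 2] = (y == "a").astype(int)
        ranking = fcbf_select(self._view(X, y))
        assert ranking.features[0] == "f2"
        assert ranking.scores[0] == 1.0

    def test_exact_duplicate_eliminated(self, rng):
        y = np.asarray(["a", "b"] * 15, dtype=object)
        informative = (y == "a").astype(int)
        informative[:4] = 1 - informative[:4]  # imperfect but informative
        X = np.column_stack(
            [informative, informative, rng.integers(0, 2, size=30)]
        )
        ranking = fcbf_select(self._view(X, y))
        assert sum(f in ("f0", "f1") for f in ranking.features) == 1

    def test_matches_exhaustive_oracle_on_small_instances(self, rng):
        """Random instances with <= 6 binary features agree with the
        brute-force predominance oracle feature for feature."""
        for trial in range(60):
            n_feat = int(rng.integers(1, 7))
            n_rows = int(rng.integers(4, 16))
            X = rng.integers(0, 2, size=(n_rows, n_feat))
            y = rng.integers(0, 2, size=n_rows).astype(str).astype(object)
            if len(set(y)) < 2:
                continue
            view = self._view(X, y)
            assert fcbf_select(view).features == fcbf_oracle(view)

    def test_selection_subset_of_input(self, matrix):
        view = binarize(matrix)
        ranking = fcbf_select(view)
        assert set(ranking.features) <= set(view.terms)
        assert ranking.scores == sorted(ranking.scores, reverse=True)


class TestRankUnivariate:
    def _matrix(self):
        # two classes with hand-chosen group means for a closed-form F
        values = np.asarray(
            [
                [1.0, 0.0, 0.3],
                [0.9, 0.0, 0.1],
                [0.1, 0.0, 0.2],
                [0.2, 0.0, 0.4],
            ]
        )
        return DocTermMatrix(
            doc_ids=["d0", "d1", "d2", "d3"],
            terms=["sep", "flat", "noise"],
            values=values,
            labels=np.asarray(["pos", "pos", "neg", "neg"], dtype=object),
        )

    @staticmethod
    def _anova_f(column, labels):
        groups = [
            [v for v, l in zip(column, labels) if l == lab]
            for lab in sorted(set(labels))
        ]
        grand = np.mean(column)
        ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
        ss_within = sum((v - np.mean(g)) ** 2 for g in groups for v in g)
        df_b = len(groups) - 1
        df_w = len(column) - len(groups)
        return (ss_between / df_b) / (ss_within / df_w)

    def test_scores_match_closed_form_anova(self):
        m = self._matrix()
        ranking = rank_univariate(m, k=3)
        expected = {
            "sep": self._anova_f(m.values[:, 0], list(m.labels)),
            "noise": self._anova_f(m.values[:, 2], list(m.labels)),
        }
        got = dict(zip(ranking.features, ranking.scores))
        assert got["sep"] == pytest.approx(expected["sep"], rel=1e-9)
        assert got["noise"] == pytest.approx(expected["noise"], rel=1e-9)

    def test_constant_feature_scored_zero_and_last(self):
        ranking = rank_univariate(self._matrix(), k=3)
        assert ranking.features[-1] == "flat"
        assert ranking.scores[-1] == 0.0

    def test_indicator_feature_ranked_first(self):
        ranking = rank_univariate(self._matrix(), k=2)
        assert ranking.features[0] == "sep"

    def test_k_out_of_range_rejected(self):
        with pytest.raises(InputError):
            rank_univariate(self._matrix(), k=4)


class TestRankTreeImportance:
    def test_informative_feature_recovered_across_seeds(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            y = np.asarray(["pos", "neg"] * 25, dtype=object)
            X = rng.random((50, 6)) * 0.2
            X[:, 3] += (y == "pos") * 0.5
            matrix = DocTermMatrix(
                doc_ids=[f"d{i}" for i in range(50)],
                terms=[f"w{j}" for j in range(6)],
                values=X,
                labels=y,
            )
            ranking = rank_tree_importance(matrix, k=6, seed=seed)
            hits += ranking.features[0] == "w3"
        assert hits >= 18

    def test_full_k_is_permutation_with_nonnegative_scores(self, matrix):
        k = len(matrix.terms)
        ranking = rank_tree_importance(matrix, k=k, seed=0)
        assert sorted(ranking.features) == sorted(matrix.terms)
        assert all(s >= 0 for s in ranking.scores)
        assert sum(ranking.scores) > 0


class TestCompareMethods:
    def test_schema_and_row_count(self, matrix):
        selectors = {"skb": lambda m: rank_univariate(m, 20)}
        classifiers = {
            "random_forest": default_classifiers(seed=0)["random_forest"]
        }
        table = compare_methods(
            matrix, selectors, classifiers, top_n=20,
            outer=OuterEvalConfig(reps=2, n_trees=20, seed=0),
        )
        assert list(table.columns) == [
            "classifier", "fs", "accuracy", "accuracy_std",
            "recall", "precision", "f1",
        ]
        assert len(table) == 1
        assert 0 <= table.loc[0, "f1"] <= 1
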