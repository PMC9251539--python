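"""Metrics arithmetic, accumulation, outer evaluation, final model."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from topictriage.config import OuterEvalConfig
from topictriage.errors import InputError
from topictriage.io import CorpusRecord, RawCorpus
from topictriage.modeling import (
    accumulate_vocabulary,
    compute_metrics,
    evaluate_levels,
    fit_final,
    predict_corpus,
)
from topictriage.topic_model import Topic
from topictriage.vectorize import DocTermMatrix


def _topic(i, words):
    return Topic(
        topic_id=f"topic_{i}",
        words=list(words),
        weights=np.full(len(words), 1.0 / len(words)),
    )


def _labels_from_counts(tp, fp, fn, tn):
    y_true = ["pos"] * (tp + fn) + ["neg"] * (fp + tn)
    y_pred = (
        ["pos"] * tp + ["neg"] * fn + ["pos"] * fp + ["neg"] * tn
    )
    return y_true, y_pred


class TestComputeMetrics:
    def test_confusion_arithmetic(self):
        y_true, y_pred = _labels_from_counts(tp=3, fp=1, fn=1, tn=5)
        m = compute_metrics(y_true, y_pred, pos_label="pos")
        assert m.accuracy == 0.8
        assert m.precision == 0.75
        assert m.sensitivity == 0.75
        assert m.specificity == 5 / 6
        assert m.f1 == 0.75

    def test_perfect_predictions(self):
        y = ["pos", "neg", "pos", "neg"]
        m = compute_metrics(y, y, scores=[1.0, 0.0, 1.0, 0.0])
        assert (m.accuracy, m.sensitivity, m.specificity, m.precision,
                m.f1, m.auc) == (1.0,) * 6

    def test_zero_denominator_flagged_as_zero(self):
        m = compute_metrics(["neg", "neg"], ["neg", "neg"], pos_label="pos")
        assert m.precision == 0.0
        assert m.sensitivity == 0.0
        assert "precision" in m.zero_denominator_flags
        assert "auc" in m.zero_denominator_flags

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            compute_metrics([], [])

    def test_auc_ties_count_half(self):
        m = compute_metrics(
            ["pos", "neg"], ["pos", "neg"], scores=[0.5, 0.5], pos_label="pos"
        )
        assert m.auc == 0.5

    @given(
        st.lists(
            st.tuples(st.booleans(), st.booleans()), min_size=2, max_size=60
        ).filter(lambda pairs: len({t for t, _ in pairs}) == 2)
    )
    def test_agrees_with_sklearn_oracle(self, pairs):
        """Confusion-matrix metrics match scikit-learn on random labelings."""
        from sklearn.metrics import (
            accuracy_score,
            f1_score,
            precision_score,
            recall_score,
        )

        y_true = ["pos" if t else "neg" for t, _ in pairs]
        y_pred = ["pos" if p else "neg" for _, p in pairs]
        m = compute_metrics(y_true, y_pred, pos_label="pos")
        assert m.accuracy == pytest.approx(accuracy_score(y_true, y_pred))
        assert m.precision == pytest.approx(
            precision_score(y_true, y_pred, pos_label="pos", zero_division=0)
        )
        assert m.sensitivity == pytest.approx(
            recall_score(y_true, y_pred, pos_label="pos", zero_division=0)
        )
        assert m.f1 == pytest.approx(
            f1_score(y_true, y_pred, pos_label="pos", zero_division=0)
        )

    @given(
        st.lists(
            st.tuples(
                st.booleans(),
                # coarse grid keeps both s and 1-s tie-free after filtering
                st.integers(0, 10**6).map(lambda i: i / 10**6),
            ),
            min_size=2,
            max_size=40,
        ).filter(
            lambda pairs: 0 < sum(t for t, _ in pairs) < len(pairs)
            and len({s for _, s in pairs}) == len(pairs)  # tie-free scores
        )
    )
    def test_auc_matches_sklearn_and_complement_sums_to_one(self, pairs):
        from sklearn.metrics import roc_auc_score

        flags = [t for t, _ in pairs]
        y = ["pos" if f else "neg" for f in flags]
        scores = [s for _, s in pairs]
        m = compute_metrics(y, y, scores=scores, pos_label="pos")
        expected = roc_auc_score([f for f in flags], scores)
        assert m.auc == pytest.approx(expected, abs=1e-12)
        flipped = compute_metrics(
            y, y, scores=[1 - s for s in scores], pos_label="pos"
        )
        assert m.auc + flipped.auc == pytest.approx(1.0, abs=1e-12)


class TestAccumulateVocabulary:
    def test_single_topic_returns_its_words(self):
        words = [f"w{i}" for i in range(20)]
        assert accumulate_vocabulary([_topic(0, words)], 1) == words

    def test_overlapping_topics_deduplicated(self):
        a = [f"a{i}" for i in range(20)]
        b = [f"a{i}" for i in range(8)] + [f"b{i}" for i in range(12)]
        out = accumulate_vocabulary([_topic(0, a), _topic(1, b)], 2)
        assert len(out) == 32  # 20 + 20 - 8 shared
        assert out[:20] == a  # first occurrence kept, order preserved

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            accumulate_vocabulary([_topic(0, ["w"])], 2)

    def test_levels_are_nested(self, planted):
        previous: list[str] = []
        for r in range(1, len(planted) + 1):
            words = accumulate_vocabulary(planted, r)
            assert set(previous) <= set(words)
            assert len(words) <= r * 20
            previous = words


class TestEvaluateLevels:
    def test_determinism_and_shape(self, matrix, planted):
        cfg = OuterEvalConfig(reps=2, n_trees=20, seed=4)
        a = evaluate_levels(matrix, planted, levels=[1, 3], outer=cfg)
        b = evaluate_levels(matrix, planted, levels=[1, 3], outer=cfg)
        assert [l.level for l in a.levels] == [1, 3]
        for la, lb in zip(a.levels, b.levels):
            assert la == lb
        assert a.levels[0].n_words <= a.levels[1].n_words

    def test_empty_level_rejected(self):
        matrix = DocTermMatrix(
            doc_ids=["d0", "d1", "d2", "d3"],
            terms=["a"],
            values=np.ones((4, 1)),
            labels=np.asarray(["pos", "neg", "pos", "neg"], dtype=object),
        )
        with pytest.raises(InputError):
            evaluate_levels(
                matrix, [_topic(0, ["zz"])], levels=[1],
                outer=OuterEvalConfig(reps=1, n_trees=5, seed=0),
            )


class TestFinalModelAndPredict:
    @pytest.fixture()
    def separable(self):
        rng = np.random.default_rng(0)
        labels = np.asarray(
            ["pos"] * 20 + ["neg"] * 20, dtype=object
        )
        values = rng.random((40, 3)) * 0.1
        values[:20, 0] += 0.5
        return DocTermMatrix(
            doc_ids=[f"d{i:02d}" for i in range(40)],
            terms=["alpha", "beta", "gamma"],
            values=values,
            labels=labels,
        )

    def test_training_set_accuracy_near_perfect(self, separable):
        artifact = fit_final(separable, ["alpha"], n_trees=25, seed=1)
        preds = artifact.model.predict(separable.values[:, [0]])
        assert (preds == separable.labels).mean() >= 0.95

    def test_artifact_records_selection_in_order(self, separable):
        artifact = fit_final(separable, ["gamma", "alpha"], seed=1)
        assert artifact.words == ["gamma", "alpha"]

    def test_empty_selection_rejected(self, separable):
        with pytest.raises(InputError):
            fit_final(separable, [])

    def test_predict_contract(self, separable):
        artifact = fit_final(separable, ["alpha"], n_trees=25, seed=1)
        corpus = RawCorpus(
            [
                CorpusRecord("n1", "alpha alpha beta", None),
                CorpusRecord("n2", "", None),  # empty doc -> zero vector
            ]
        )
        table = predict_corpus(artifact, corpus)
        assert list(table["doc_id"]) == ["n1", "n2"]
        assert table["score"].between(0, 1).all()
        again = predict_corpus(artifact, corpus)
        assert table.equals(again)

    def test_save_load_round_trip(self, separable, tmp_path):
        artifact = fit_final(separable, ["alpha"], n_trees=10, seed=1)
        path = tmp_path / "model.joblib"
        artifact.save(path)
        from topictriage.modeling import ModelArtifact

        back = ModelArtifact.load(path)
        assert back.words == artifact.words
        assert back.pos_label == artifact.pos_label
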