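"""Word-level feature-selection baselines for comparison.

Three selectors operating on individual words rather than topics:

* **FCBF** (Fast Correlation-Based Filter), implemented from its definition:
  symmetrical uncertainty against the class ranks the features, and the
  predominance rule removes every feature more correlated with an already
  kept feature than with the class.  It runs on the binary presence/absence
  view because its information measures need discrete variables.
* **Univariate k-best** — per-feature one-way ANOVA F between classes
  (chi-squared on the binary view as an option).
* **Gradient-boosted-tree importance** — gain-based importances from an
  XGBoost model.

``compare_methods`` evaluates selector x classifier pairs at a fixed feature
budget under outer stratified MCCV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.feature_selection import chi2, f_classif
from sklearn.tree import DecisionTreeClassifier

from .config import OuterEvalConfig
from .errors import InputError
from .gsm import resolve_pos_label, stratified_split
from .modeling import compute_metrics
from .seeds import derive_seed
from .vectorize import DocTermMatrix

logger = logging.getLogger(__name__)


@dataclass
class FeatureRanking:
    """An ordered word list with aligned, non-increasing scores."""

    method: str
    features: list[str]
    scores: list[float]

    def top(self, k: int) -> list[str]:
        return self.features[:k]


@dataclass
class BinaryFeatureView:
    """Documents x vocabulary presence/absence indicators with labels."""

    terms: list[str]
    X: np.ndarray  # values in {0, 1}
    y: np.ndarray


def binarize(matrix: DocTermMatrix) -> BinaryFeatureView:
    if matrix.labels is None:
        raise InputError("matrix has no labels")
    return BinaryFeatureView(
        terms=list(matrix.terms),
        X=(matrix.values > 0).astype(int),
        y=np.asarray(matrix.labels, dtype=object),
    )


def _entropy_bits(values: np.ndarray) -> float:
    _, counts = np.unique(values, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def symmetrical_uncertainty(x: Sequence, y: Sequence) -> float:
    """SU(x, y) = 2 IG(x; y) / (H(x) + H(y)), entropies in bits.

    Returns 0 when both vectors are constant (zero total entropy).
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.size == 0:
        raise InputError("vectors must be non-empty and of equal length")
    hx = _entropy_bits(x)
    hy = _entropy_bits(y)
    if hx + hy == 0.0:
        return 0.0
    joint = np.char.add(
        np.char.add(x.astype(str), "\x1f"), y.astype(str)
    )
    hxy = _entropy_bits(joint)
    su = 2.0 * (hx + hy - hxy) / (hx + hy)
    return float(min(1.0, max(0.0, su)))


def fcbf_select(view: BinaryFeatureView, delta: float = 0.0) -> FeatureRanking:
    """FCBF: SU-with-class ranking plus the predominance rule.

    Features with ``SU(feature, class) > delta`` are ordered by that SU
    (descending; ties broken by feature name).  Walking that order, a feature
    f is discarded when some already-kept feature g satisfies
    ``SU(f, g) >= SU(f, class)``.  SU values are quantized at 1e-12 before
    ordering and comparison: entropies are float sums, so mathematically
    equal SUs can differ in the last ulp, and quantizing makes ties (e.g.
    duplicated features) exact and the selection reproducible.
    """
    if view.X.size == 0:
        raise InputError("empty feature view")
    if len({str(v) for v in view.y}) < 2:
        raise InputError("both classes must be present")
    su_class = {
        term: round(symmetrical_uncertainty(view.X[:, j], view.y), 12)
        for j, term in enumerate(view.terms)
    }
    candidates = sorted(
        (t for t in view.terms if su_class[t] > delta),
        key=lambda t: (-su_class[t], t),
    )
    col = {t: j for j, t in enumerate(view.terms)}
    kept: list[str] = []
    for f in candidates:
        predominant = True
        for g in kept:
            su_fg = round(
                symmetrical_uncertainty(view.X[:, col[f]], view.X[:, col[g]]),
                12,
            )
            if su_fg >= su_class[f]:
                predominant = False
                break
        if predominant:
            kept.append(f)
    return FeatureRanking(
        method="fcbf",
        features=kept,
        scores=[su_class[t] for t in kept],
    )


def rank_univariate(
    matrix: DocTermMatrix, k: int, scorer: str = "anova_f"
) -> FeatureRanking:
    """Top-k words by a univariate score against the class label.

    Constant features receive score 0 and rank last; ties break
    lexicographically.
    """
    if matrix.labels is None:
        raise InputError("matrix has no labels")
    if not 1 <= k <= len(matrix.terms):
        raise InputError(f"k={k} out of range 1..{len(matrix.terms)}")
    y = np.asarray([str(v) for v in matrix.labels])
    if scorer == "anova_f":
        with np.errstate(divide="ignore", invalid="ignore"):
            scores, _ = f_classif(matrix.values, y)
    elif scorer == "chi2":
        scores, _ = chi2((matrix.values > 0).astype(float), y)
    else:
        raise InputError(f"unknown scorer {scorer!r}")
    scores = np.nan_to_num(np.asarray(scores, dtype=float), nan=0.0)
    order = sorted(
        range(len(matrix.terms)),
        key=lambda j: (-scores[j], matrix.terms[j]),
    )[:k]
    return FeatureRanking(
        method=f"univariate_{scorer}",
        features=[matrix.terms[j] for j in order],
        scores=[float(scores[j]) for j in order],
    )


def rank_tree_importance(
    matrix: DocTermMatrix, k: int, seed: int = 0
) -> FeatureRanking:
    """Top-k words by gain-based gradient-boosted-tree importance."""
    from xgboost import XGBClassifier

    if matrix.labels is None:
        raise InputError("matrix has no labels")
    if not 1 <= k <= len(matrix.terms):
        raise InputError(f"k={k} out of range 1..{len(matrix.terms)}")
    pos = resolve_pos_label(np.asarray(matrix.labels, dtype=object), None)
    y = np.asarray([1 if str(v) == pos else 0 for v in matrix.labels])
    model = XGBClassifier(
        n_estimators=100,
        max_depth=4,
        importance_type="gain",
        random_state=seed,
        n_jobs=1,
        verbosity=0,
    )
    model.fit(matrix.values, y)
    importances = np.asarray(model.feature_importances_, dtype=float)
    order = sorted(
        range(len(matrix.terms)),
        key=lambda j: (-importances[j], matrix.terms[j]),
    )[:k]
    return FeatureRanking(
        method="tree_importance",
        features=[matrix.terms[j] for j in order],
        scores=[float(importances[j]) for j in order],
    )


def default_classifiers(seed: int = 0) -> dict[str, Callable[[], object]]:
    """Classifier factories behind one interface: RF, DT, two boosters."""
    return {
        "random_forest": lambda: RandomForestClassifier(
            n_estimators=100, random_state=seed, n_jobs=1
        ),
        "decision_tree": lambda: DecisionTreeClassifier(random_state=seed),
        "adaboost": lambda: AdaBoostClassifier(random_state=seed),
        "gradient_boosting": lambda: GradientBoostingClassifier(
            random_state=seed
        ),
    }


def compare_methods(
    matrix: DocTermMatrix,
    selectors: Mapping[str, Callable[[DocTermMatrix], FeatureRanking]],
    classifiers: Mapping[str, Callable[[], object]] | None = None,
    top_n: int = 100,
    outer: OuterEvalConfig | None = None,
    pos_label: str | None = None,
) -> pd.DataFrame:
    """Evaluate selector x classifier pairs at a fixed feature budget.

    Each selector runs once on the full matrix; each pair is then evaluated
    by outer stratified MCCV restricted to the selector's top ``top_n``
    words.  Returns a table with columns: classifier, fs, accuracy,
    accuracy_std, recall, precision, f1.
    """
    if matrix.labels is None:
        raise InputError("matrix has no labels")
    cfg = outer or OuterEvalConfig()
    classifiers = classifiers or default_classifiers(cfg.seed)

    order = np.argsort(np.asarray(matrix.doc_ids, dtype=object), kind="stable")
    X_all = matrix.values[order]
    y_all = np.asarray(matrix.labels, dtype=object)[order]
    pos = resolve_pos_label(y_all, pos_label)
    term_idx = matrix.term_index()

    rows = []
    for sel_name, selector in selectors.items():
        ranking = selector(matrix)
        words = ranking.top(top_n)
        if not words:
            logger.warning(
                "[baselines] selector %s yielded no features; skipped", sel_name
            )
            continue
        cols = [term_idx[w] for w in words if w in term_idx]
        for clf_name, factory in classifiers.items():
            accs, recs, precs, f1s = [], [], [], []
            for rep in range(cfg.reps):
                rng = np.random.default_rng(
                    derive_seed(cfg.seed, f"compare-{sel_name}-{clf_name}", rep)
                )
                train, test = stratified_split(y_all, cfg.test_fraction, rng)
                model = factory()
                model.fit(X_all[np.ix_(train, cols)], y_all[train])
                y_pred = model.predict(X_all[np.ix_(test, cols)])
                m = compute_metrics(y_all[test], y_pred, pos_label=pos)
                accs.append(m.accuracy)
                recs.append(m.sensitivity)
                precs.append(m.precision)
                f1s.append(m.f1)
            rows.append(
                {
                    "classifier": clf_name,
                    "fs": sel_name,
                    "accuracy": float(np.mean(accs)),
                    "accuracy_std": float(np.std(accs)),
                    "recall": float(np.mean(recs)),
                    "precision": float(np.mean(precs)),
                    "f1": float(np.mean(f1s)),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["classifier", "fs", "accuracy", "accuracy_std",
                 "recall", "precision", "f1"],
    )
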