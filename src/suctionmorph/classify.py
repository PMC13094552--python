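"""Predictive-power stage: can morphology alone identify suction feeders?

The labeled taxa are split once into stratified training (75%) and
testing (25%) subsets. Separate two-class logistic models are fitted for
each single character, for the composite indices (CharSum, CharMean/SSI,
adjusted SSI), and for two multivariate models (all ten characters;
the eight osteology/dentition characters only). Each model is scored on
the held-out set with a confusion matrix, accuracy, precision, recall
and F1 (positive class Suction), and accuracy is compared against the
no-information rate (NIR, the majority-class share of the test set) with
an exact one-sided binomial test and a Clopper-Pearson 95% interval.

Stratified test counts use round-half-down per class: with 42 Other and
26 Suction taxa at a 0.25 test fraction this yields a 16-taxon test set
(10 + 6) and NIR = 0.625.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .data_io import (
    AnalysisConfig,
    CharacterMatrix,
    LabelTable,
    OTHER_LABEL,
    SUCTION_LABEL,
)

#: inverse of the ridge strength applied to logistic weights; the best
#: suction predictors separate the classes perfectly, where unpenalized
#: maximum likelihood diverges. At 1e-8 the penalty is invisible in the
#: predictions and, for overlapping classes, in the weights to ~1e-4.
_RIDGE = 1e-8


@dataclass
class Partition:
    """One stratified train/test split of the labeled taxa."""

    train: list[str]
    test: list[str]
    seed: int
    class_counts: dict[str, dict[str, int]]


@dataclass
class FittedClassifier:
    """Two-class logistic model: predict Suction iff the linear score > 0."""

    predictors: list[str]
    intercept: float
    weights: np.ndarray
    converged: bool
    ridge: float = _RIDGE

    def decision(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + X @ self.weights

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision(X) > 0, SUCTION_LABEL, OTHER_LABEL)


@dataclass
class ClassificationReport:
    """Test-set evaluation of one model (positive class = Suction)."""

    confusion: list[list[int]]  # rows truth [Other, Suction], cols prediction
    accuracy: float
    precision: float | None  # None when no positive predictions were made
    recall: float
    f1: float | None
    nir: float
    ci_low: float
    ci_high: float
    p_vs_nir: float
    n_test: int


def _round_half_down(x: float) -> int:
    return math.ceil(x - 0.5)


def stratified_partition(
    labels: LabelTable, test_fraction: float = 0.25, seed: int = 0
) -> Partition:
    """Stratified split preserving class proportions.

    Per class, the test count is round-half-down(class size * fraction);
    members are sampled uniformly without replacement with the given seed.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[str]] = {}
    for taxon, lab in labels.items():
        by_class.setdefault(lab, []).append(taxon)
    if len(by_class) < 2 or any(len(v) < 2 for v in by_class.values()):
        raise ValueError("both classes need at least 2 members")
    train: list[str] = []
    test: list[str] = []
    counts: dict[str, dict[str, int]] = {}
    for lab in sorted(by_class):
        members = sorted(by_class[lab])
        n_test = _round_half_down(len(members) * test_fraction)
        if n_test < 1:
            raise ValueError(
                f"class {lab!r} ({len(members)} members) gets no test "
                f"representation at fraction {test_fraction}")
        picked = rng.choice(len(members), size=n_test, replace=False)
        mask = np.zeros(len(members), dtype=bool)
        mask[picked] = True
        test += [m for m, t in zip(members, mask) if t]
        train += [m for m, t in zip(members, mask) if not t]
        counts[lab] = {"train": len(members) - n_test, "test": n_test}
    return Partition(train, test, seed, counts)


def no_information_rate(labels: LabelTable, test: list[str]) -> float:
    """Majority-class share of the test set."""
    y = labels.labels_for(test)
    return max((y == lvl).mean() for lvl in (SUCTION_LABEL, OTHER_LABEL))


def _predictor_grid(
    matrix: CharacterMatrix, predictors: list[str], taxa: list[str],
    extra: dict[str, dict[str, float]] | None = None,
) -> np.ndarray:
    extra = extra or {}
    cols = []
    for p in predictors:
        if p in matrix.character_names:
            cols.append([matrix.row(t)[matrix.character_names.index(p)]
                         for t in taxa])
        elif p in extra:
            cols.append([extra[p][t] for t in taxa])
        else:
            raise KeyError(f"unknown predictor {p!r}")
    X = np.array(cols, dtype=float).T
    if not np.isfinite(X).all():
        raise ValueError("missing scores among the requested predictors")
    return X


def fit_logistic(
    matrix: CharacterMatrix,
    labels: LabelTable,
    predictors: list[str],
    train: list[str],
    extra: dict[str, dict[str, float]] | None = None,
) -> FittedClassifier:
    """Maximum-likelihood logistic fit with a vanishing ridge term."""
    y = labels.labels_for(train)
    if len(set(y)) < 2:
        raise ValueError("training set contains a single class")
    X = _predictor_grid(matrix, predictors, train, extra)
    const = X.std(axis=0) == 0
    if const.all():
        # intercept-only model: predict the majority training class
        p1 = (y == SUCTION_LABEL).mean()
        b0 = math.log(p1 / (1 - p1)) if 0 < p1 < 1 else math.copysign(50, p1 - 0.5)
        return FittedClassifier(predictors, b0, np.zeros(X.shape[1]), True)
    clf = LogisticRegression(
        C=1.0 / _RIDGE, solver="lbfgs", max_iter=20000, tol=1e-12,
    )
    clf.fit(X, (y == SUCTION_LABEL).astype(int))
    return FittedClassifier(
        predictors,
        float(clf.intercept_[0]),
        clf.coef_[0].astype(float),
        int(clf.n_iter_[0]) < clf.max_iter,
    )


def nir_test(correct: int, n_test: int, nir: float) -> tuple[float, float, float]:
    """Exact accuracy-vs-NIR machinery.

    Returns the two-sided 95% Clopper-Pearson interval for the accuracy
    correct/n_test and the one-sided exact binomial tail
    P(X >= correct | n_test, NIR).
    """
    if not 0 <= correct <= n_test:
        raise ValueError("correct must lie in [0, n_test]")
    if not 0 < nir < 1:
        raise ValueError("nir must lie in (0, 1)")
    lo = 0.0 if correct == 0 else float(
        stats.beta.ppf(0.025, correct, n_test - correct + 1))
    hi = 1.0 if correct == n_test else float(
        stats.beta.ppf(0.975, correct + 1, n_test - correct))
    p = float(stats.binom.sf(correct - 1, n_test, nir))
    return lo, hi, p


def evaluate(
    model: FittedClassifier,
    matrix: CharacterMatrix,
    labels: LabelTable,
    test: list[str],
    extra: dict[str, dict[str, float]] | None = None,
) -> ClassificationReport:
    """Score a fitted model on the held-out taxa."""
    if not test:
        raise ValueError("test set is empty")
    X = _predictor_grid(matrix, model.predictors, test, extra)
    y = labels.labels_for(test)
    pred = model.predict(X)
    lvls = (OTHER_LABEL, SUCTION_LABEL)
    conf = [[int(((y == a) & (pred == b)).sum()) for b in lvls] for a in lvls]
    n = len(test)
    correct = conf[0][0] + conf[1][1]
    tp = conf[1][1]
    fp = conf[0][1]
    fn = conf[1][0]
    precision = None if tp + fp == 0 else tp / (tp + fp)
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (None if precision is None or precision + recall == 0
          else 2 * precision * recall / (precision + recall))
    nir = no_information_rate(labels, test)
    lo, hi, p = nir_test(correct, n, nir)
    return ClassificationReport(
        confusion=conf, accuracy=correct / n, precision=precision,
        recall=recall, f1=f1, nir=nir, ci_low=lo, ci_high=hi,
        p_vs_nir=p, n_test=n,
    )


#: composite-index rows of the battery report
BATTERY_COMPOSITES = ("CharSum", "CharMean", "adjusted_SSI")
BATTERY_MULTIVARIATE = ("all_characters", "osteo_dental_characters")


def run_predictor_battery(
    matrix: CharacterMatrix,
    labels: LabelTable,
    ssi_table,
    config: AnalysisConfig | None = None,
    resplit_per_model: bool = False,
) -> dict:
    """Fit and evaluate the full predictor battery on one shared split.

    Rows: each single character, the three composite indices, and the two
    multivariate models. All models share the same stratified partition
    unless ``resplit_per_model`` draws a fresh split (same seed sequence)
    per row.
    """
    config = config or AnalysisConfig()
    taxa = [t for t in matrix.taxa if t in labels]
    sub_labels = LabelTable({t: labels[t] for t in taxa})
    extra = {
        "CharSum": ssi_table["char_sum"].to_dict(),
        "CharMean": ssi_table["char_mean"].to_dict(),
        "adjusted_SSI": ssi_table["adjusted_ssi"].to_dict(),
    }
    osteo = [c.name for c in matrix.characters if c.char_class == "osteo_dental"]
    rows: list[tuple[str, list[str]]] = (
        [(c, [c]) for c in matrix.character_names]
        + [(name, [name]) for name in BATTERY_COMPOSITES]
        + [("all_characters", list(matrix.character_names)),
           ("osteo_dental_characters", osteo)]
    )
    base = stratified_partition(sub_labels, config.test_fraction, config.seed)
    out: dict = {"partition": base, "reports": {}}
    for i, (name, preds) in enumerate(rows):
        part = (stratified_partition(sub_labels, config.test_fraction,
                                     config.seed + 1 + i)
                if resplit_per_model else base)
        model = fit_logistic(matrix, sub_labels, preds, part.train, extra)
        out["reports"][name] = evaluate(model, matrix, sub_labels,
                                        part.test, extra)
    return out
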