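import math

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import minimize

from suctionmorph.classify import (
    ClassificationReport,
    evaluate,
    fit_logistic,
    nir_test,
    no_information_rate,
    run_predictor_battery,
    stratified_partition,
)
from suctionmorph.data_io import (
    AnalysisConfig,
    Character,
    CharacterMatrix,
    LabelTable,
)
from suctionmorph.ssi import compute_ssi


def make_labels(n_other: int, n_suction: int) -> LabelTable:
    return LabelTable(
        {f"o{i:02d}": "Other" for i in range(n_other)}
        | {f"s{i:02d}": "Suction" for i in range(n_suction)})


class TestStratifiedPartition:
    def test_study_class_sizes_give_nir_0625(self):
        """42 Other + 26 Suction at 25% -> 10 + 6 test taxa, NIR 0.625."""
        labels = make_labels(42, 26)
        part = stratified_partition(labels, 0.25, seed=0)
        assert part.class_counts["Other"]["test"] == 10
        assert part.class_counts["Suction"]["test"] == 6
        assert len(part.test) == 16
        assert no_information_rate(labels, part.test) == pytest.approx(0.625)

    def test_seed_determinism(self):
        labels = make_labels(20, 12)
        a = stratified_partition(labels, 0.25, seed=5)
        b = stratified_partition(labels, 0.25, seed=5)
        c = stratified_partition(labels, 0.25, seed=6)
        assert a.test == b.test and a.train == b.train
        assert a.test != c.test

    def test_partition_is_disjoint_cover(self):
        labels = make_labels(17, 9)
        part = stratified_partition(labels, 0.3, seed=1)
        assert set(part.train) | set(part.test) == {t for t, _ in labels.items()}
        assert not set(part.train) & set(part.test)

    def test_proportions_preserved(self):
        labels = make_labels(40, 24)
        for seed in range(5):
            part = stratified_partition(labels, 0.25, seed=seed)
            full = 24 / 64
            test_frac = sum(labels[t] == "Suction" for t in part.test) / len(part.test)
            assert abs(test_frac - full) <= 1 / len(part.test)

    def test_tiny_class_error(self):
        with pytest.raises(ValueError):
            stratified_partition(make_labels(30, 1), 0.25, seed=0)


def two_char_matrix(values: dict[str, list[float]]) -> CharacterMatrix:
    k = len(next(iter(values.values())))
    return CharacterMatrix(list(values), [Character(f"c{j}") for j in range(k)],
                           np.array(list(values.values())))


class TestFitLogistic:
    def test_separating_predictor_perfect_on_train(self):
        rows = {f"o{i}": [float(i % 3) / 2] for i in range(6)}
        rows |= {f"s{i}": [2.5 + 0.5 * (i % 2)] for i in range(4)}
        m = two_char_matrix(rows)
        labels = LabelTable({t: ("Suction" if t[0] == "s" else "Other")
                             for t in rows})
        model = fit_logistic(m, labels, ["c0"], list(rows))
        X = np.array([rows[t] for t in rows])
        pred = model.predict(X)
        truth = np.array([labels[t] for t in rows], dtype=object)
        assert (pred == truth).all()

    def test_constant_predictor_predicts_majority(self):
        rows = {f"o{i}": [1.0] for i in range(7)} | {f"s{i}": [1.0] for i in range(3)}
        m = two_char_matrix(rows)
        labels = LabelTable({t: ("Suction" if t[0] == "s" else "Other")
                             for t in rows})
        model = fit_logistic(m, labels, ["c0"], list(rows))
        assert (model.predict(np.array([[1.0]])) == ["Other"]).all()

    def test_single_class_training_error(self):
        rows = {f"o{i}": [float(i) / 2] for i in range(5)}
        m = two_char_matrix(rows | {"s0": [3.0], "s1": [2.8]})
        labels = LabelTable({t: ("Suction" if t[0] == "s" else "Other")
                             for t in rows} | {"s0": "Suction", "s1": "Suction"})
        with pytest.raises(ValueError, match="single class"):
            fit_logistic(m, labels, ["c0"], list(rows))

    def test_overlapping_classes_match_brute_force_mle(self):
        """With class overlap the near-unpenalized fit reproduces the
        unregularized maximum-likelihood weights to ~1e-4."""
        x = np.array([0.2, 0.8, 1.1, 1.9, 2.4, 0.5, 1.4, 2.8, 3.0, 2.2])
        y = np.array([0, 0, 0, 0, 1, 0, 1, 1, 1, 0])
        rows = {f"{'s' if yi else 'o'}{i}": [xi]
                for i, (xi, yi) in enumerate(zip(x, y))}
        m = two_char_matrix(rows)
        labels = LabelTable({t: ("Suction" if t[0] == "s" else "Other")
                             for t in rows})
        model = fit_logistic(m, labels, ["c0"], list(rows))

        def nll(b):
            z = b[0] + b[1] * x
            return np.sum(np.log1p(np.exp(z)) - y * z)

        res = minimize(nll, [0.0, 0.0], method="BFGS", options={"gtol": 1e-12})
        assert model.intercept == pytest.approx(res.x[0], abs=1e-4)
        assert model.weights[0] == pytest.approx(res.x[1], abs=1e-4)


class TestNIRTest:
    @pytest.mark.parametrize(
        "correct,n,nir,ci,p",
        [
            (16, 16, 0.625, (0.7941, 1.0), 0.0005421),
            (15, 16, 0.625, (0.6977, 0.9984), 0.005746),
            (0, 16, 0.625, (0.0, 0.2059), 1.0),
        ],
    )
    def test_table_values(self, correct, n, nir, ci, p):
        lo, hi, pv = nir_test(correct, n, nir)
        assert lo == pytest.approx(ci[0], abs=5e-5)
        assert hi == pytest.approx(ci[1], abs=5e-5)
        assert pv == pytest.approx(p, rel=1e-3)

    def test_exact_binomial_enumeration_all_n(self):
        """p and the CI endpoints agree with direct binomial enumeration
        for every n <= 30 and several accuracies."""
        for n in range(1, 31):
            for correct in {0, 1, n // 2, n - 1, n}:
                lo, hi, p = nir_test(correct, n, 0.625)
                exact = sum(math.comb(n, j) * 0.625**j * 0.375 ** (n - j)
                            for j in range(correct, n + 1))
                assert p == pytest.approx(exact, rel=1e-12)
                # Clopper-Pearson: tail probabilities hit 2.5% at the bounds
                if correct > 0:
                    tail = stats.binom.sf(correct - 1, n, lo)
                    assert tail == pytest.approx(0.025, rel=1e-6)
                if correct < n:
                    tail = stats.binom.cdf(correct, n, hi)
                    assert tail == pytest.approx(0.025, rel=1e-6)

    def test_exact_coverage_at_least_95(self):
        """Clopper-Pearson coverage, computed exactly over the binomial
        pmf at n=16, is >= 95% across the probability range."""
        n = 16
        bounds = [nir_test(x, n, 0.5)[:2] for x in range(n + 1)]
        for p in np.linspace(0.05, 0.95, 19):
            pmf = stats.binom.pmf(np.arange(n + 1), n, p)
            cover = sum(pmf[x] for x in range(n + 1)
                        if bounds[x][0] <= p <= bounds[x][1])
            assert cover >= 0.95


class TestEvaluate:
    def _report(self, conf) -> ClassificationReport:
        # build a dataset realizing the requested confusion matrix via a
        # predictor the model can fit exactly
        (tn, fp), (fn, tp) = conf
        rows = {}
        labels = {}
        for i in range(tn):
            rows[f"tn{i}"] = [0.0]; labels[f"tn{i}"] = "Other"
        for i in range(fp):
            rows[f"fp{i}"] = [1.0]; labels[f"fp{i}"] = "Other"
        for i in range(fn):
            rows[f"fn{i}"] = [0.0]; labels[f"fn{i}"] = "Suction"
        for i in range(tp):
            rows[f"tp{i}"] = [1.0]; labels[f"tp{i}"] = "Suction"
        m = two_char_matrix(rows)
        lt = LabelTable(labels)
        train = {"a": [0.0], "b": [1.0]}
        m_train = two_char_matrix(rows | train)
        lt_train = LabelTable(labels | {"a": "Other", "b": "Suction"})
        model = fit_logistic(m_train, lt_train, ["c0"],
                             ["a", "b"] + list(rows))
        return evaluate(model, m, lt, list(rows))

    def test_perfect_classifier(self):
        r = self._report([[10, 0], [0, 6]])
        assert (r.accuracy, r.precision, r.recall, r.f1) == (1.0, 1.0, 1.0, 1.0)
        assert r.confusion == [[10, 0], [0, 6]]

    def test_hand_formula_metrics(self):
        """Confusion [[10,0],[1,5]]: accuracy 15/16, recall 5/6, F1 10/11."""
        r = self._report([[10, 0], [1, 5]])
        assert r.accuracy == pytest.approx(15 / 16)
        assert r.precision == pytest.approx(1.0)
        assert r.recall == pytest.approx(5 / 6)
        assert r.f1 == pytest.approx(10 / 11)
        assert r.nir == pytest.approx(0.625)

    def test_all_majority_equals_nir(self):
        r = self._report([[10, 0], [6, 0]])
        assert r.accuracy == pytest.approx(r.nir)
        assert r.precision is None  # no positive predictions
        assert r.f1 is None


class TestBattery:
    def test_perfect_separator_row(self, default_dataset):
        """A character carrying the full planted shift reaches accuracy 1
        with the Clopper-Pearson lower bound 0.025^(1/n)."""
        ds = default_dataset
        table = compute_ssi(ds.suction_matrix)
        bat = run_predictor_battery(ds.suction_matrix, ds.labels, table,
                                    AnalysisConfig(seed=3))
        r = bat["reports"]["CharMean"]
        assert r.accuracy == 1.0
        assert r.ci_low == pytest.approx(0.025 ** (1 / r.n_test), abs=1e-6)

    def test_reports_shape(self, default_dataset):
        ds = default_dataset
        table = compute_ssi(ds.suction_matrix)
        bat = run_predictor_battery(ds.suction_matrix, ds.labels, table,
                                    AnalysisConfig(seed=3))
        names = set(bat["reports"])
        assert names == set(ds.suction_matrix.character_names) | {
            "CharSum", "CharMean", "adjusted_SSI",
            "all_characters", "osteo_dental_characters"}

    def test_bit_reproducible(self, default_dataset):
        ds = default_dataset
        table = compute_ssi(ds.suction_matrix)
        a = run_predictor_battery(ds.suction_matrix, ds.labels, table,
                                  AnalysisConfig(seed=4))
        b = run_predictor_battery(ds.suction_matrix, ds.labels, table,
                                  AnalysisConfig(seed=4))
        for k in a["reports"]:
            assert a["reports"][k] == b["reports"][k]

    def test_shuffled_labels_accuracy_near_nir(self, default_dataset):
        """Breaking the label/phylogeny link, battery accuracies
        concentrate near the no-information rate."""
        ds = default_dataset
        table = compute_ssi(ds.suction_matrix)
        rng = np.random.default_rng(12)
        taxa = list(ds.suction_matrix.taxa)
        deltas = []
        for seed in range(100):
            perm = rng.permutation([ds.labels[t] for t in taxa])
            labels = LabelTable(dict(zip(taxa, perm)))
            bat = run_predictor_battery(ds.suction_matrix, labels, table,
                                        AnalysisConfig(seed=seed))
            accs = [r.accuracy for r in bat["reports"].values()]
            deltas.append(np.mean(accs) - bat["reports"]["CharMean"].nir)
        assert abs(np.mean(deltas)) < 0.1

    def test_all_zero_matrix_intercept_only(self):
        labels = make_labels(12, 8)
        taxa = [t for t, _ in labels.items()]
        m = two_char_matrix({t: [0.0, 0.0] for t in taxa})
        table = compute_ssi(m)
        bat = run_predictor_battery(m, labels, table, AnalysisConfig(seed=0))
        for r in bat["reports"].values():
            assert r.accuracy == pytest.approx(r.nir)
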