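"""Feature assembly, subspace ensemble, cross-validation and metrics."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from paglucose.ensemble import (
    EnsembleConfig,
    FeatureTable,
    PredictionSet,
    SubspaceEnsemble,
    assemble_feature_table,
    classification_metrics,
    kfold_cross_validate,
    predict,
    preprocess_feature_table,
    train_subspace_ensemble,
)
from paglucose.synthetic import generate_study


@pytest.fixture(scope="module")
def default_table(default_study):
    return assemble_feature_table(default_study)


class TestAssembleFeatureTable:
    def test_default_study_gives_300_by_134_with_30_rows_per_class(
        self, default_table
    ):
        assert default_table.features.shape == (300, 134)
        labels, counts = np.unique(default_table.labels, return_counts=True)
        assert len(labels) == 10
        assert all(c == 30 for c in counts)

    def test_row_order_is_day_class_round(self, default_table):
        meta = default_table.meta
        keys = list(zip(meta["day"], default_table.labels, meta["round"]))
        assert keys == sorted(keys)

    def test_single_record(self, default_study):
        table = assemble_feature_table(default_study[:1])
        assert table.features.shape == (1, 134)

    def test_csv_round_trip(self, default_table, tmp_path):
        path = tmp_path / "table.csv"
        default_table.to_frame().to_csv(path, index=False)
        back = FeatureTable.from_frame(pd.read_csv(path))
        assert np.allclose(back.features.to_numpy(), default_table.features.to_numpy())
        assert np.array_equal(back.labels, default_table.labels)

    def test_mixed_grids_rejected(self, default_study):
        from paglucose.spectra import SpectrumRecord, make_frequency_grid

        other = make_frequency_grid(10_000.0, 30_000.0, 300.0)
        odd = SpectrumRecord(
            other, np.ones(len(other)), default_study[0].meta
        )
        with pytest.raises(ValueError):
            assemble_feature_table([default_study[0], odd])


def _toy_table(n_per_class=10, n_features=6, gap=5.0, seed=0):
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for i, label in enumerate((100.0, 200.0)):
        centre = np.full(n_features, gap * i)
        rows.append(centre + 0.1 * rng.normal(size=(n_per_class, n_features)))
        labels += [label] * n_per_class
    X = np.vstack(rows)
    return FeatureTable(
        features=pd.DataFrame(X, columns=[f"{i}" for i in range(n_features)]),
        labels=np.array(labels),
        meta=pd.DataFrame({"day": [1] * len(labels), "sample_id": [1] * len(labels),
                           "round": list(range(len(labels)))}),
    )


class TestSubspaceEnsemble:
    def test_same_seed_reproduces_subspaces_and_predictions(self, default_table):
        cfg = EnsembleConfig(n_learners=5, subspace_dim=40, seed=3)
        m1 = train_subspace_ensemble(default_table, cfg)
        m2 = train_subspace_ensemble(default_table, cfg)
        for a, b in zip(m1.subspaces_, m2.subspaces_):
            assert np.array_equal(a, b)
        X = default_table.features.to_numpy(float)
        assert np.array_equal(m1.predict(X), m2.predict(X))

    def test_degenerate_ensemble_equals_plain_base_learner(self, default_table):
        from sklearn.neighbors import KNeighborsClassifier

        cfg = EnsembleConfig(n_learners=1, subspace_dim=134, seed=0)
        model = train_subspace_ensemble(default_table, cfg)
        X = default_table.features.to_numpy(float)
        plain = KNeighborsClassifier(n_neighbors=1).fit(X, default_table.labels)
        assert np.array_equal(model.predict(X), plain.predict(X))

    def test_separable_toy_reaches_perfect_training_accuracy(self):
        table = _toy_table()
        cfg = EnsembleConfig(n_learners=7, subspace_dim=3, seed=1)
        model = train_subspace_ensemble(table, cfg)
        X = table.features.to_numpy(float)
        assert np.array_equal(model.predict(X), table.labels)
        # independent nearest-neighbour hand check on ten points
        for i in range(10):
            d = np.linalg.norm(X - X[i], axis=1)
            d[i] = np.inf
            assert table.labels[int(np.argmin(d))] == table.labels[i]

    def test_subspace_dim_larger_than_feature_count_rejected(self, default_table):
        cfg = EnsembleConfig(n_learners=2, subspace_dim=200)
        with pytest.raises(ValueError):
            train_subspace_ensemble(default_table, cfg)

    def test_vote_tie_breaks_to_lowest_concentration(self):
        # two learners trained on disjoint single features that disagree on
        # the probe row: the plurality tie resolves to the lower label
        X = np.array([[0.0, 10.0], [10.0, 0.0]])
        y = np.array([100.0, 125.0])
        model = SubspaceEnsemble(EnsembleConfig(n_learners=2, subspace_dim=1, seed=0))
        model.fit(X, y)
        model.subspaces_ = [np.array([0]), np.array([1])]
        for learner, cols in zip(model.learners_, model.subspaces_):
            learner.fit(X[:, cols], y)
        probe = np.array([[0.0, 0.0]])  # feature 0 says 100, feature 1 says 125
        assert model.predict(probe)[0] == 100.0

    def test_schema_mismatch_rejected(self, default_table):
        cfg = EnsembleConfig(n_learners=2, subspace_dim=10, seed=0)
        model = train_subspace_ensemble(default_table, cfg)
        with pytest.raises(ValueError):
            predict(model, np.ones((3, 7)))


class TestCrossValidation:
    def test_stratified_folds_predict_every_row_once(self, default_table):
        cfg = EnsembleConfig(n_learners=5, subspace_dim=40, seed=0)
        preds = kfold_cross_validate(default_table, cfg, k=10)
        assert len(preds.frame) == 300
        fold_sizes = preds.frame.groupby("fold").size()
        assert (fold_sizes == 30).all()
        per_fold_class = preds.frame.groupby(["fold", "true"]).size()
        assert (per_fold_class == 3).all()

    def test_noise_free_study_is_perfectly_classified(self, noise_free_plan, cell):
        recs = generate_study(
            replace(noise_free_plan, days=1, rounds_per_day=10), seed=0, cell=cell
        )
        # perturb infinitesimally so replicate rows are not exactly identical
        table = assemble_feature_table(recs)
        cfg = EnsembleConfig(n_learners=5, subspace_dim=67, seed=0)
        preds = kfold_cross_validate(table, cfg, k=5)
        assert preds.accuracy == 1.0

    def test_class_smaller_than_k_rejected(self, default_table):
        cfg = EnsembleConfig(seed=0)
        with pytest.raises(ValueError):
            kfold_cross_validate(default_table, cfg, k=40)

    def test_agrees_with_sklearn_bagging_reference(self, default_table):
        """Independent cross-check: sklearn's feature-bagging ensemble (the
        same random-subspace family) lands within a few points."""
        from sklearn.ensemble import BaggingClassifier
        from sklearn.model_selection import cross_val_predict
        from sklearn.neighbors import KNeighborsClassifier

        cfg = EnsembleConfig(seed=0)
        mine = kfold_cross_validate(default_table, cfg, k=10).accuracy
        ref = BaggingClassifier(
            estimator=KNeighborsClassifier(n_neighbors=1),
            n_estimators=30,
            max_features=67,
            bootstrap=False,
            bootstrap_features=False,
            random_state=0,
        )
        X = default_table.features.to_numpy(float)
        ref_pred = cross_val_predict(ref, X, default_table.labels, cv=10)
        ref_acc = float(np.mean(ref_pred == default_table.labels))
        assert abs(mine - ref_acc) < 0.06


class TestPreprocessing:
    def test_burst_cells_are_removed(self, default_table):
        cleaned = preprocess_feature_table(default_table)
        raw = default_table.features.to_numpy(float)
        out = cleaned.features.to_numpy(float)
        changed = np.abs(raw - out) > 1e-12
        assert 0 < changed.mean() < 0.10  # touches a few cells, not the bulk

    def test_preprocessing_improves_median_cv_accuracy(self, plan, cell):
        """Moving-median preprocessing raises the ensemble's accuracy on
        average across seeds (outlier bursts and gain-noise tails removed)."""
        raws, pres = [], []
        for seed in range(4):
            table = assemble_feature_table(generate_study(plan, seed, cell))
            cfg = EnsembleConfig(seed=seed)
            raws.append(kfold_cross_validate(table, cfg).accuracy)
            pres.append(
                kfold_cross_validate(preprocess_feature_table(table), cfg).accuracy
            )
        assert np.median(pres) > np.median(raws)


class TestMetrics:
    def test_perfect_predictions(self):
        frame = pd.DataFrame(
            {"true": [75.0, 100.0] * 5, "predicted": [75.0, 100.0] * 5,
             "fold": [0] * 10}
        )
        m = classification_metrics(PredictionSet(frame))
        assert m.accuracy == 1.0
        assert np.allclose(m.f1, 1.0)
        assert np.allclose(m.fnr, 0.0)

    def test_hand_computed_three_class_confusion(self):
        # true/pred pairs building the matrix [[8,1,0],[0,9,2],[0,0,10]]
        rows = (
            [(1, 1)] * 8 + [(1, 2)] * 1
            + [(2, 2)] * 9 + [(2, 3)] * 2
            + [(3, 3)] * 10
        )
        frame = pd.DataFrame(
            {"true": [float(t) for t, _ in rows],
             "predicted": [float(p) for _, p in rows],
             "fold": [0] * len(rows)}
        )
        m = classification_metrics(PredictionSet(frame))
        assert np.array_equal(m.confusion, [[8, 1, 0], [0, 9, 2], [0, 0, 10]])
        assert m.accuracy == pytest.approx(27 / 30)
        assert m.recall == pytest.approx([8 / 9, 9 / 11, 1.0])
        assert m.precision == pytest.approx([1.0, 9 / 10, 10 / 12])
        f1_0 = 2 * (8 / 9) / (1 + 8 / 9)
        f1_1 = 2 * (9 / 10) * (9 / 11) / (9 / 10 + 9 / 11)
        f1_2 = 2 * (10 / 12) / (1 + 10 / 12)
        assert m.macro_f1 == pytest.approx((f1_0 + f1_1 + f1_2) / 3)

    def test_label_swap_leaves_accuracy_unchanged(self):
        rng = np.random.default_rng(0)
        true = rng.choice([75.0, 100.0, 125.0], size=60)
        pred = rng.choice([75.0, 100.0, 125.0], size=60)
        base = classification_metrics(
            PredictionSet(pd.DataFrame({"true": true, "predicted": pred, "fold": 0}))
        ).accuracy
        swap = {75.0: 100.0, 100.0: 75.0, 125.0: 125.0}
        swapped = classification_metrics(
            PredictionSet(
                pd.DataFrame(
                    {"true": [swap[t] for t in true],
                     "predicted": [swap[p] for p in pred], "fold": 0}
                )
            )
        ).accuracy
        assert base == pytest.approx(swapped)

    def test_confusion_row_sums_and_trace_identity(self, default_table):
        cfg = EnsembleConfig(n_learners=5, subspace_dim=40, seed=1)
        m = classification_metrics(kfold_cross_validate(default_table, cfg))
        assert (m.confusion.sum(axis=1) == 30).all()
        assert m.accuracy == pytest.approx(
            np.trace(m.confusion) / m.confusion.sum()
        )

    def test_unseen_predicted_label_rejected(self):
        frame = pd.DataFrame(
            {"true": [75.0] * 3, "predicted": [75.0, 75.0, 999.0], "fold": 0}
        )
        with pytest.raises(ValueError):
            classification_metrics(PredictionSet(frame))
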