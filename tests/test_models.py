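"""Model zoo: cross-validation, hyperparameter search, refit, bundles."""

import numpy as np
import pytest

from encap.encoders import FeatureMatrix, FeatureSchema, _spec, make_encoder
from encap.models import (
    ModelBundle,
    ModelError,
    ModelSpec,
    available_families,
    build_estimator,
    cross_validate,
    family_available,
    fit_final,
    stratified_folds,
)
from encap.motifs import MotifSet
from encap.peptides import LabeledPeptideSet, Peptide
from encap.pipeline import PipelineConfig, train_bundle
from encap.preprocess import fit_robust_scaler
from encap.simulate import SyntheticConfig, generate
from encap.tpe import optimize_hyperparameters


def matrix_from(values, names=None):
    values = np.asarray(values, dtype=float)
    names = names or [f"f{i}" for i in range(values.shape[1])]
    schema = FeatureSchema([_spec("raw", lambda s: None, names)])
    return FeatureMatrix(schema, values, [f"r{i}" for i in range(values.shape[0])])


def separable_data(rng, n=60):
    y = np.array([0, 1] * (n // 2))
    x = rng.normal(size=(n, 5))
    x[:, 0] = y * 10 + rng.normal(0, 0.1, n)  # fully separable feature
    return matrix_from(x), y


class TestModelSpec:
    def test_unknown_family_rejected(self):
        with pytest.raises(ModelError):
            ModelSpec("SVM")

    def test_unknown_hyperparameter_rejected(self):
        with pytest.raises(ModelError, match="unknown hyperparameters"):
            ModelSpec("RF", {"bogus": 1})

    def test_catboost_family_reports_availability_not_crash(self):
        # CB is registered; whether its backend is installed is a runtime
        # property, never an import error
        assert isinstance(family_available("CB"), bool)
        assert set(available_families()) <= {"RF", "ET", "GBC", "XGB", "LGBM", "CB"}

    @pytest.mark.parametrize("fam", ["RF", "ET", "GBC", "LDA", "XGB", "LGBM"])
    def test_available_backends_build_and_fit(self, fam, rng):
        if not family_available(fam):
            pytest.skip(f"{fam} backend not installed")
        m, y = separable_data(rng)
        est = build_estimator(ModelSpec(fam), seed=0)
        est.fit(m.values, y)
        assert est.predict_proba(m.values).shape == (60, 2)


class TestCrossValidation:
    def test_fold_assignment_is_partition(self, rng):
        y = rng.integers(0, 2, 50)
        y[:10] = 1
        y[10:20] = 0
        folds = stratified_folds(y, 5, seed=0)
        assert set(folds) == set(range(5))
        sizes = np.bincount(folds)
        assert sizes.max() - sizes.min() <= 1

    def test_leave_one_out_limit(self, rng):
        m, y = separable_data(rng, n=10)
        cv = cross_validate(ModelSpec("RF", {"n_estimators": 20}), m, y, folds=5, seed=0)
        assert len(cv.fold_reports) == 5

    def test_perfectly_separable_data_reaches_mcc_one(self, rng):
        m, y = separable_data(rng, n=60)
        cv = cross_validate(ModelSpec("RF", {"n_estimators": 50}), m, y, folds=5, seed=1)
        assert cv.mcc == 1.0

    def test_identical_seed_identical_folds_and_metrics(self, rng):
        m, y = separable_data(rng, n=40)
        a = cross_validate(ModelSpec("RF", {"n_estimators": 30}), m, y, 5, seed=3)
        b = cross_validate(ModelSpec("RF", {"n_estimators": 30}), m, y, 5, seed=3)
        np.testing.assert_array_equal(a.fold_assignment, b.fold_assignment)
        np.testing.assert_array_equal(a.oof_probabilities, b.oof_probabilities)

    def test_class_smaller_than_folds_rejected(self, rng):
        m, _ = separable_data(rng, n=20)
        y = np.zeros(20, dtype=int)
        y[:3] = 1
        with pytest.raises(ModelError):
            cross_validate(ModelSpec("RF"), m, y, folds=5, seed=0)


class TestHyperparameterSearch:
    def test_single_trial_returns_defaults(self, rng):
        m, y = separable_data(rng, n=40)
        spec, trace = optimize_hyperparameters("RF", m, y, trials=1, folds=3, seed=0)
        assert spec.hyperparameters == {}
        assert len(trace) == 1

    def test_best_objective_never_below_default(self, rng):
        m, y = separable_data(rng, n=40)
        spec, trace = optimize_hyperparameters("RF", m, y, trials=6, folds=3, seed=0)
        default_obj = trace[0].objective
        best_obj = max(t.objective for t in trace)
        assert best_obj >= default_obj
        assert trace[0].hyperparameters == {}

    def test_trace_running_best_is_monotone(self, rng):
        m, y = separable_data(rng, n=40)
        _, trace = optimize_hyperparameters("LDA", m, y, trials=5, folds=3, seed=2)
        best = -np.inf
        for t in trace:
            best = max(best, t.objective)
            assert best >= t.objective

    def test_reproducible_for_fixed_seed(self, rng):
        m, y = separable_data(rng, n=40)
        s1, t1 = optimize_hyperparameters("RF", m, y, trials=5, folds=3, seed=9)
        s2, t2 = optimize_hyperparameters("RF", m, y, trials=5, folds=3, seed=9)
        assert s1.hyperparameters == s2.hyperparameters
        assert [t.hyperparameters for t in t1] == [t.hyperparameters for t in t2]

    def test_depth_recovered_on_depth_limited_problem(self, rng):
        # XOR-of-two-features needs depth >= 2; depth-1 trees fail.
        n = 200
        x = rng.integers(0, 2, (n, 2)).astype(float)
        y = (x[:, 0] != x[:, 1]).astype(int)
        x += rng.normal(0, 0.05, x.shape)
        m = matrix_from(x)
        # exhaustive grid over depth identifies the optimal plateau
        grid_scores = {}
        for depth in range(1, 17):
            cv = cross_validate(
                ModelSpec("RF", {"max_depth": depth, "n_estimators": 50}),
                m, y, folds=3, seed=0,
            )
            grid_scores[depth] = cv.mcc
        plateau_floor = min(d for d, s in grid_scores.items()
                            if s >= max(grid_scores.values()) - 0.05)
        assert plateau_floor >= 2  # depth-1 stumps cannot express XOR
        spec, trace = optimize_hyperparameters("RF", m, y, trials=15, folds=3, seed=1)
        # the search reaches the plateau: depth inside it, objective near grid-best
        assert spec.hyperparameters.get("max_depth", 16) >= plateau_floor
        assert max(t.objective for t in trace) >= max(grid_scores.values()) - 0.05


class TestFinalFitAndBundle:
    def _bundle(self, seed=0):
        train = generate(SyntheticConfig(n_pos=40, n_neg=40, seed=seed))
        regs = [
            make_encoder("AAC"),
            make_encoder("GAAC"),
            make_encoder("APAAC", lam=3),  # raises the bundle length minimum to 4
            make_encoder("OVPC_Hydrophobic"),
        ]
        cfg = PipelineConfig(
            grid=(5, 10), families=("RF",), boruta_max_iter=8, trials=2,
            report_folds=3, select_folds=3, opt_folds=3,
        )
        art = train_bundle(train, MotifSet.from_lists(["FATP"], []), "RF",
                           registry=regs, config=cfg)
        return art, train

    def test_training_accuracy_bounds_cv_accuracy(self, rng):
        art, train = self._bundle()
        records = art.bundle.predict(train)
        preds = np.array([r["label"] for r in records])
        train_acc = (preds == train.y).mean()
        assert train_acc >= art.cv_report.pooled.accuracy - 1e-9

    def test_two_fits_same_seed_identical_predictions(self, rng):
        m, y = separable_data(rng, n=40)
        probe = matrix_from(rng.normal(size=(10, 5)))
        probe.values[:, 0] = rng.normal(5, 3, 10)
        a = fit_final(ModelSpec("RF", {"n_estimators": 30}), m, y, seed=5)
        b = fit_final(ModelSpec("RF", {"n_estimators": 30}), m, y, seed=5)
        fp = m.schema.fingerprint()
        np.testing.assert_array_equal(
            a.predict_proba(probe.values, fp), b.predict_proba(probe.values, fp)
        )

    def test_schema_fingerprint_mismatch_rejected(self, rng):
        m, y = separable_data(rng, n=40)
        model = fit_final(ModelSpec("RF", {"n_estimators": 10}), m, y, seed=0)
        with pytest.raises(ModelError, match="fingerprint"):
            model.predict_proba(m.values, "deadbeef")

    def test_bundle_round_trip_identical_predictions(self, tmp_path):
        art, train = self._bundle()
        probe = generate(SyntheticConfig(n_pos=10, n_neg=10, seed=77))
        before = art.bundle.predict(probe)
        art.bundle.save(tmp_path / "bundle")
        reloaded = ModelBundle.load(tmp_path / "bundle")
        after = reloaded.predict(probe)
        assert [r["probability"] for r in before] == [r["probability"] for r in after]

    def test_purity_same_peptide_twice_bit_identical(self):
        art, _ = self._bundle()
        probe = generate(SyntheticConfig(n_pos=5, n_neg=5, seed=13))
        p1 = art.bundle.predict(probe)
        p2 = art.bundle.predict(probe)
        assert [r["probability"] for r in p1] == [r["probability"] for r in p2]

    def test_short_peptide_gets_error_entry_others_proceed(self):
        art, _ = self._bundle()
        data = LabeledPeptideSet(
            [Peptide("ok", "FATPLLDK"), Peptide("tiny", "ACD")], [1, 0]
        )
        records = art.bundle.predict(data)
        assert records[0]["error"] == "" and records[0]["probability"] is not None
        assert "minimum" in records[1]["error"]

    def test_threshold_inclusive_rule(self):
        art, _ = self._bundle()
        # synthesize a record check: label = 1 iff probability >= threshold
        probe = generate(SyntheticConfig(n_pos=20, n_neg=20, seed=5))
        for r in art.bundle.predict(probe):
            assert r["label"] == int(r["probability"] >= art.bundle.threshold)
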