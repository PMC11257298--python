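"""The seven classifier families, stratified cross-validation, final refit
and the deployable prediction bundle.

Families: random forest (RF), extra trees (ET), gradient boosting (GBC),
XGBoost (XGB), LightGBM (LGBM), CatBoost (CB) and linear discriminant
analysis (LDA).  Boosting backends are imported lazily; a family whose
backend is not installed reports itself unavailable instead of failing.
Class imbalance is deliberately left untouched (no resampling or class
weights), and the decision threshold defaults to 0.5 with probability
exactly at threshold mapping to the positive class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.model_selection import StratifiedKFold

from .encoders import (
    EncoderSpec,
    FeatureMatrix,
    FeatureSchema,
    encode_all,
)
from .metrics import MetricsReport, evaluate
from .motifs import MotifSet, encode_motifs
from .peptides import LabeledPeptideSet
from .preprocess import ScalerParams, apply_scaler, fit_robust_scaler


class ModelError(ValueError):
    pass


ENSEMBLE_FAMILIES = ["RF", "ET", "GBC", "XGB", "LGBM", "CB"]
ALL_FAMILIES = ENSEMBLE_FAMILIES + ["LDA"]

#: Hyperparameter search spaces per family.  Each entry:
#: name -> ("int"|"float"|"logfloat"|"logint"|"cat", low, high | choices)
SEARCH_SPACES: dict[str, dict[str, tuple]] = {
    "RF": {
        "n_estimators": ("logint", 50, 500),
        "max_depth": ("int", 2, 16),
        "min_samples_split": ("int", 2, 10),
        "max_features": ("cat", ["sqrt", "log2", None]),
    },
    "ET": {
        "n_estimators": ("logint", 50, 500),
        "max_depth": ("int", 2, 16),
        "min_samples_split": ("int", 2, 10),
        "max_features": ("cat", ["sqrt", "log2", None]),
    },
    "GBC": {
        "n_estimators": ("logint", 50, 500),
        "learning_rate": ("logfloat", 1e-3, 0.3),
        "max_depth": ("int", 2, 8),
        "subsample": ("float", 0.5, 1.0),
    },
    "XGB": {
        "n_estimators": ("logint", 50, 500),
        "learning_rate": ("logfloat", 1e-3, 0.3),
        "max_depth": ("int", 2, 8),
        "subsample": ("float", 0.5, 1.0),
        "colsample_bytree": ("float", 0.5, 1.0),
        "min_child_weight": ("int", 1, 10),
    },
    "LGBM": {
        "n_estimators": ("logint", 50, 500),
        "learning_rate": ("logfloat", 1e-3, 0.3),
        "num_leaves": ("logint", 7, 127),
        "min_child_samples": ("int", 2, 30),
        "subsample": ("float", 0.5, 1.0),
        "colsample_bytree": ("float", 0.5, 1.0),
    },
    "CB": {
        "iterations": ("logint", 50, 500),
        "learning_rate": ("logfloat", 1e-3, 0.3),
        "depth": ("int", 2, 8),
        "l2_leaf_reg": ("logfloat", 1.0, 10.0),
    },
    "LDA": {
        "solver": ("cat", ["svd", "lsqr"]),
    },
}


def family_available(family: str) -> bool:
    if family in ("RF", "ET", "GBC", "LDA"):
        return True
    try:
        if family == "XGB":
            import xgboost  # noqa: F401
        elif family == "LGBM":
            import lightgbm  # noqa: F401
        elif family == "CB":
            import catboost  # noqa: F401
        else:
            return False
    except ImportError:
        return False
    return True


def available_families(families=None) -> list[str]:
    families = families or ENSEMBLE_FAMILIES
    return [f for f in families if family_available(f)]


@dataclass(frozen=True)
class ModelSpec:
    """A classifier family plus a (possibly empty) hyperparameter map."""

    family: str
    hyperparameters: dict = field(default_factory=dict, hash=False)

    def __post_init__(self) -> None:
        if self.family not in ALL_FAMILIES:
            raise ModelError(f"unknown family {self.family!r}")
        allowed = set(SEARCH_SPACES[self.family])
        unknown = set(self.hyperparameters) - allowed
        if unknown:
            raise ModelError(
                f"{self.family}: unknown hyperparameters {sorted(unknown)}"
            )


def build_estimator(spec: ModelSpec, seed: int):
    """Instantiate the backend estimator, single-threaded and seeded."""
    hp = dict(spec.hyperparameters)
    fam = spec.family
    if fam == "RF":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **hp)
    if fam == "ET":
        return ExtraTreesClassifier(random_state=seed, n_jobs=1, **hp)
    if fam == "GBC":
        return GradientBoostingClassifier(random_state=seed, **hp)
    if fam == "LDA":
        if hp.get("solver") == "lsqr":
            hp["shrinkage"] = "auto"
        return LinearDiscriminantAnalysis(**hp)
    if fam == "XGB":
        from xgboost import XGBClassifier

        return XGBClassifier(
            random_state=seed, n_jobs=1, eval_metric="logloss", **hp
        )
    if fam == "LGBM":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(
            random_state=seed, n_jobs=1, verbosity=-1, deterministic=True,
            force_row_wise=True, **hp
        )
    if fam == "CB":
        from catboost import CatBoostClassifier

        return CatBoostClassifier(
            random_seed=seed, verbose=False, thread_count=1, **hp
        )
    raise ModelError(f"family {fam} unavailable")


@dataclass
class CVResult:
    spec: ModelSpec
    fold_reports: list[MetricsReport]
    pooled: MetricsReport
    fold_assignment: np.ndarray  # test-fold index per row
    oof_probabilities: np.ndarray

    @property
    def mcc(self) -> float:
        return self.pooled.mcc


def stratified_folds(labels: np.ndarray, folds: int, seed: int) -> np.ndarray:
    y = np.asarray(labels, dtype=int)
    if folds < 2:
        raise ModelError("folds must be >= 2")
    if np.bincount(y, minlength=2).min() < folds:
        raise ModelError("each class must have at least `folds` members")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    for k, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        assignment[test_idx] = k
    return assignment


def cross_validate(
    spec: ModelSpec,
    m: FeatureMatrix,
    labels,
    folds: int = 5,
    seed: int = 0,
    scale_in_fold: bool = True,
    threshold: float = 0.5,
) -> CVResult:
    """Stratified k-fold CV with leakage-safe per-fold scaling.

    With ``scale_in_fold=False`` (the flowchart's stage ordering, where the
    whole CV set is normalized before ranking) the matrix is used as given.
    The aggregate report is computed over pooled out-of-fold predictions.
    """
    y = np.asarray(labels, dtype=int)
    assignment = stratified_folds(y, folds, seed)
    oof = np.empty(len(y))
    fold_reports: list[MetricsReport] = []
    for k in range(folds):
        test_mask = assignment == k
        train_mask = ~test_mask
        x_train = FeatureMatrix(
            m.schema, m.values[train_mask], [m.row_ids[i] for i in np.flatnonzero(train_mask)]
        )
        x_test = FeatureMatrix(
            m.schema, m.values[test_mask], [m.row_ids[i] for i in np.flatnonzero(test_mask)]
        )
        if scale_in_fold:
            params = fit_robust_scaler(x_train)
            x_train = apply_scaler(params, x_train)
            x_test = apply_scaler(params, x_test)
        est = build_estimator(spec, seed)
        est.fit(x_train.values, y[train_mask])
        probs = est.predict_proba(x_test.values)[:, 1]
        oof[test_mask] = probs
        fold_reports.append(evaluate(y[test_mask], probs, threshold))
    pooled = evaluate(y, oof, threshold)
    return CVResult(spec, fold_reports, pooled, assignment, oof)


@dataclass
class TrainedModel:
    family: str
    estimator: object
    schema_fingerprint: str
    n_train: int
    seed: int

    def predict_proba(self, values: np.ndarray, fingerprint: str) -> np.ndarray:
        if fingerprint != self.schema_fingerprint:
            raise ModelError("feature schema fingerprint mismatch")
        return self.estimator.predict_proba(values)[:, 1]


def fit_final(
    spec: ModelSpec, full_cv_set: FeatureMatrix, labels, seed: int = 0
) -> TrainedModel:
    """Refit on the entire CV set with the chosen hyperparameters — the
    independent-test protocol (the refit model sees the held-out folds'
    training share too)."""
    y = np.asarray(labels, dtype=int)
    est = build_estimator(spec, seed)
    est.fit(full_cv_set.values, y)
    return TrainedModel(
        family=spec.family,
        estimator=est,
        schema_fingerprint=full_cv_set.schema.fingerprint(),
        n_train=len(y),
        seed=seed,
    )


@dataclass
class ModelBundle:
    """Self-sufficient deployable unit: raw peptides in, labels out."""

    registry: list[EncoderSpec]
    scaler: ScalerParams
    selected_features: list[str]
    motifs: MotifSet
    model: TrainedModel
    spec: ModelSpec
    threshold: float = 0.5

    def feature_space(self, m_scaled: FeatureMatrix, data: LabeledPeptideSet) -> FeatureMatrix:
        """Selected-feature block plus appended motif bits."""
        sub = m_scaled.select(self.selected_features)
        bits = np.array([encode_motifs(p, self.motifs) for p in data.peptides])
        if bits.size == 0:
            bits = bits.reshape(len(data), 0)
        values = np.hstack([sub.values, bits])
        names = self.selected_features + [f"motif_{m.pattern}_{m.origin}" for m in self.motifs]
        from .encoders import _spec as _passthrough

        return FeatureMatrix(
            FeatureSchema([_passthrough("bundle", lambda s: None, names)]),
            values,
            list(m_scaled.row_ids),
        )

    def predict(self, data: LabeledPeptideSet):
        """Per-peptide probability and label.

        Peptides violating an encoder length minimum yield an error entry;
        the rest proceed.  Returns a list of dict records.
        """
        records = []
        ok_idx = []
        min_len = FeatureSchema(self.registry).min_length
        for i, pep in enumerate(data.peptides):
            if len(pep) < min_len:
                records.append(
                    {"id": pep.id, "probability": None, "label": None,
                     "error": f"shorter than encoder minimum {min_len}"}
                )
            else:
                ok_idx.append(i)
                records.append(None)
        if ok_idx:
            sub = data.subset(ok_idx)
            m = encode_all(sub, self.registry)
            m = apply_scaler(self.scaler, m)
            fm = self.feature_space(m, sub)
            probs = self.model.predict_proba(fm.values, fm.schema.fingerprint())
            for j, i in enumerate(ok_idx):
                prob = float(probs[j])
                records[i] = {
                    "id": data.peptides[i].id,
                    "probability": prob,
                    "label": int(prob >= self.threshold),
                    "error": "",
                }
        return records

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.scaler.save(outdir / "scaler.json")
        (outdir / "features.txt").write_text("\n".join(self.selected_features) + "\n")
        self.motifs.save(outdir / "motifs.tsv")
        (outdir / "registry.json").write_text(
            json.dumps([{"name": s.name, "params": s.params} for s in self.registry])
        )
        joblib.dump(self.model.estimator, outdir / "model.joblib")
        (outdir / "meta.json").write_text(
            json.dumps(
                {
                    "family": self.spec.family,
                    "hyperparameters": self.spec.hyperparameters,
                    "threshold": self.threshold,
                    "schema_fingerprint": self.model.schema_fingerprint,
                    "n_train": self.model.n_train,
                    "seed": self.model.seed,
                }
            )
        )

    @staticmethod
    def load(outdir: str | Path) -> "ModelBundle":
        from .encoders import rebuild_registry

        outdir = Path(outdir)
        meta = json.loads((outdir / "meta.json").read_text())
        registry = rebuild_registry(
            json.loads((outdir / "registry.json").read_text())
        )
        model = TrainedModel(
            family=meta["family"],
            estimator=joblib.load(outdir / "model.joblib"),
            schema_fingerprint=meta["schema_fingerprint"],
            n_train=meta["n_train"],
            seed=meta["seed"],
        )
        return ModelBundle(
            registry=registry,
            scaler=ScalerParams.load(outdir / "scaler.json"),
            selected_features=(outdir / "features.txt").read_text().split(),
            motifs=MotifSet.load(outdir / "motifs.tsv"),
            model=model,
            spec=ModelSpec(meta["family"], meta["hyperparameters"]),
            threshold=meta["threshold"],
        )
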