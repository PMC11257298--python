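"""Two-stage training orchestration.

Stage 1 (feature engineering): encode the cross-validation set under the
registry, robust-scale, rank features against shadow copies, and pick the
best top-N prefix by grid cross-validation.  The selected features are
combined with the binary motif block.  Stage 2 (model optimization):
sequential hyperparameter search maximizing mean CV MCC, a 10-fold CV
report at the chosen configuration, and a final refit on the entire CV
set — the model used for independent testing and deployment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .boruta import RankedFeatureList, boruta_rank
from .encoders import EncoderSpec, FeatureMatrix, FeatureSchema, default_registry, encode_all
from .metrics import MetricsReport, evaluate
from .models import (
    CVResult,
    ModelBundle,
    ModelSpec,
    TrainedModel,
    cross_validate,
    fit_final,
)
from .motifs import MotifSet, encode_motifs
from .peptides import LabeledPeptideSet
from .preprocess import ScalerParams, apply_scaler, fit_robust_scaler, zero_variance_filter
from .subset_search import DEFAULT_GRID, SubsetSearchResult, search_best_subset
from .tpe import TrialRecord, optimize_hyperparameters


@dataclass
class PipelineConfig:
    """Resolved run configuration; every stochastic stage has its own seed."""

    grid: tuple = DEFAULT_GRID
    families: tuple | None = None        # None -> available ensemble families
    select_folds: int = 5
    boruta_max_iter: int = 50
    boruta_alpha: float = 0.05
    boruta_trees: int = 200
    trials: int = 100
    opt_folds: int = 5
    report_folds: int = 10
    threshold: float = 0.5
    paper_mode: bool = False             # scale once on the whole CV set inside CV
    drop_zero_variance: bool = False
    seed_rank: int = 0
    seed_select: int = 1
    seed_opt: int = 2
    seed_fit: int = 3

    def to_json(self) -> str:
        d = asdict(self)
        d["grid"] = list(self.grid)
        d["families"] = list(self.families) if self.families else None
        return json.dumps(d, indent=1)


@dataclass
class TrainingArtifacts:
    config: PipelineConfig
    scaler: ScalerParams
    ranking: RankedFeatureList
    subset: SubsetSearchResult
    spec: ModelSpec
    trial_trace: list[TrialRecord]
    cv_report: CVResult
    bundle: ModelBundle
    dropped_features: list[str] = field(default_factory=list)


def combined_matrix(
    scaled: FeatureMatrix,
    selected: list[str],
    motifs: MotifSet,
    data: LabeledPeptideSet,
) -> tuple[FeatureMatrix, np.ndarray]:
    """Selected scaled features with the motif bit block appended.

    Returns the matrix and a boolean column mask marking motif columns
    (excluded from any further scaling)."""
    sub = scaled.select(selected)
    bits = np.array([encode_motifs(p, motifs) for p in data.peptides], dtype=float)
    if bits.size == 0:
        bits = bits.reshape(len(data), 0)
    names = selected + [f"motif_{m.pattern}_{m.origin}" for m in motifs]
    from .encoders import _spec as _passthrough

    fm = FeatureMatrix(
        FeatureSchema([_passthrough("stage2", lambda s: None, names)]),
        np.hstack([sub.values, bits]),
        list(scaled.row_ids),
    )
    mask = np.zeros(len(names), dtype=bool)
    mask[len(selected):] = True
    return fm, mask


def train_bundle(
    train: LabeledPeptideSet,
    motifs: MotifSet,
    family: str,
    registry: list[EncoderSpec] | None = None,
    config: PipelineConfig | None = None,
) -> TrainingArtifacts:
    """Run both stages end to end on a training (CV) set."""
    cfg = config or PipelineConfig()
    registry = registry if registry is not None else default_registry()
    y = train.y

    raw = encode_all(train, registry)
    scaler = fit_robust_scaler(raw)
    scaled = apply_scaler(scaler, raw)

    rank_input = scaled
    dropped: list[str] = []
    if cfg.drop_zero_variance:
        rank_input, dropped = zero_variance_filter(scaled)

    ranking = boruta_rank(
        rank_input,
        y,
        max_iter=cfg.boruta_max_iter,
        alpha=cfg.boruta_alpha,
        seed=cfg.seed_rank,
        n_estimators=cfg.boruta_trees,
    )

    subset = search_best_subset(
        ranking,
        scaled if cfg.paper_mode else raw,
        y,
        grid=cfg.grid,
        families=cfg.families,
        folds=cfg.select_folds,
        seed=cfg.seed_select,
        scale_in_fold=not cfg.paper_mode,
    )

    stage2, motif_mask = combined_matrix(scaled, subset.best_subset, motifs, train)
    spec, trace = optimize_hyperparameters(
        family,
        stage2,
        y,
        trials=cfg.trials,
        folds=cfg.opt_folds,
        seed=cfg.seed_opt,
        scale_in_fold=False,  # stage-2 matrix is already on the deployment scale
    )
    cv_report = cross_validate(
        spec, stage2, y, folds=cfg.report_folds, seed=cfg.seed_opt,
        scale_in_fold=False, threshold=cfg.threshold,
    )
    model = fit_final(spec, stage2, y, seed=cfg.seed_fit)
    bundle = ModelBundle(
        registry=registry,
        scaler=scaler,
        selected_features=subset.best_subset,
        motifs=motifs,
        model=model,
        spec=spec,
        threshold=cfg.threshold,
    )
    return TrainingArtifacts(
        config=cfg,
        scaler=scaler,
        ranking=ranking,
        subset=subset,
        spec=spec,
        trial_trace=trace,
        cv_report=cv_report,
        bundle=bundle,
        dropped_features=dropped,
    )


def independent_test(
    bundle: ModelBundle, test: LabeledPeptideSet
) -> tuple[MetricsReport, np.ndarray]:
    """Evaluate a trained bundle on held-out peptides."""
    records = bundle.predict(test)
    ok = [r for r in records if r["error"] == ""]
    if len(ok) != len(records):
        bad = [r["id"] for r in records if r["error"]]
        raise ValueError(f"test peptides failed encoding: {bad[:5]}")
    probs = np.array([r["probability"] for r in records])
    report = evaluate(test.y, probs, bundle.threshold)
    return report, probs


def save_artifacts(art: TrainingArtifacts, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(art.config.to_json())
    art.ranking.save_tsv(outdir / "ranking.tsv")
    art.subset.save(outdir / "subset_search.json")
    art.subset.score_table_tsv(outdir / "subset_scores.tsv")
    (outdir / "trials.json").write_text(
        json.dumps(
            [
                {"number": t.number, "hyperparameters": t.hyperparameters,
                 "objective": t.objective, "seed": t.seed}
                for t in art.trial_trace
            ],
            indent=1,
        )
    )
    (outdir / "cv_report.json").write_text(
        json.dumps(art.cv_report.pooled.as_dict(), indent=1)
    )
    art.bundle.save(outdir / "bundle")
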