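"""Heuristic best-feature-number search.

For each candidate size N on the grid, the top-N prefix of the ranked
feature list is evaluated by stratified k-fold cross-validation under each
ensemble family at implementation-default hyperparameters; the per-N score
is the best MCC across families, and the chosen subset is the top-N prefix
maximizing that score (smallest N on ties).  The default grid is
N = 50, 70, ..., 410 with 5 folds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .boruta import RankedFeatureList
from .encoders import FeatureMatrix
from .models import ModelSpec, available_families, cross_validate


class SubsetSearchError(ValueError):
    pass


DEFAULT_GRID = tuple(range(50, 411, 20))


@dataclass
class SubsetSearchResult:
    grid: list[int]
    scores: dict[int, dict[str, float]]  # N -> family -> CV MCC
    best_mcc: dict[int, float]           # N -> max over families
    best_family: dict[int, str]
    chosen_n: int
    best_subset: list[str]               # top-N prefix of the ranking
    warnings: list[str] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "grid": self.grid,
                    "scores": {str(n): s for n, s in self.scores.items()},
                    "best_mcc": {str(n): v for n, v in self.best_mcc.items()},
                    "best_family": {str(n): f for n, f in self.best_family.items()},
                    "chosen_n": self.chosen_n,
                    "best_subset": self.best_subset,
                    "warnings": self.warnings,
                },
                indent=1,
            )
        )

    def score_table_tsv(self, path: str | Path) -> None:
        families = sorted({f for s in self.scores.values() for f in s})
        lines = ["N\t" + "\t".join(families) + "\tbest"]
        for n in self.grid:
            row = [str(n)]
            row += [f"{self.scores[n].get(f, float('nan')):.6f}" for f in families]
            row.append(f"{self.best_mcc[n]:.6f}")
            lines.append("\t".join(row))
        Path(path).write_text("\n".join(lines) + "\n")


def search_best_subset(
    ranked: RankedFeatureList,
    m: FeatureMatrix,
    labels,
    grid: Sequence[int] = DEFAULT_GRID,
    families: Sequence[str] | None = None,
    folds: int = 5,
    seed: int = 0,
    evaluator: Callable[[list[str], str], float] | None = None,
    scale_in_fold: bool = True,
) -> SubsetSearchResult:
    """Choose the best top-N feature prefix by grid CV.

    ``evaluator(feature_names, family) -> mcc`` may be injected for testing;
    by default it runs stratified CV on the column subset of ``m``.
    Grid sizes exceeding the ranked feature count are truncated with a
    warning.  Ties in the per-N best score resolve to the smallest N.
    """
    warnings: list[str] = []
    grid = sorted(set(int(n) for n in grid))
    if not grid:
        raise SubsetSearchError("empty size grid")
    n_features = len(ranked.names)
    usable = [n for n in grid if n <= n_features]
    dropped = [n for n in grid if n > n_features]
    if dropped:
        warnings.append(
            f"grid sizes {dropped} exceed the {n_features} ranked features; truncated"
        )
    if not usable:
        usable = [n_features]
        warnings.append(f"all grid sizes too large; falling back to N={n_features}")

    fams = list(families) if families is not None else available_families()
    if evaluator is None:
        missing = [f for f in fams if f not in available_families(fams)]
        if missing:
            warnings.append(f"families unavailable and skipped: {missing}")
        fams = [f for f in fams if f in available_families(fams)]
        if not fams:
            raise SubsetSearchError("no available model families")

        def evaluator(feature_names: list[str], family: str) -> float:
            sub = m.select(feature_names)
            cv = cross_validate(
                ModelSpec(family), sub, labels, folds=folds, seed=seed,
                scale_in_fold=scale_in_fold,
            )
            return cv.mcc

    scores: dict[int, dict[str, float]] = {}
    best_mcc: dict[int, float] = {}
    best_family: dict[int, str] = {}
    for n in usable:
        prefix = ranked.top(n)
        per_family = {fam: float(evaluator(prefix, fam)) for fam in fams}
        scores[n] = per_family
        top_fam = max(per_family, key=lambda f: (per_family[f], f))
        best_family[n] = top_fam
        best_mcc[n] = per_family[top_fam]

    # argmax over N; ties resolve to the smallest N (grid iterated ascending)
    chosen = usable[0]
    for n in usable[1:]:
        if best_mcc[n] > best_mcc[chosen]:
            chosen = n
    return SubsetSearchResult(
        grid=usable,
        scores=scores,
        best_mcc=best_mcc,
        best_family=best_family,
        chosen_n=chosen,
        best_subset=ranked.top(chosen),
        warnings=warnings,
    )
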