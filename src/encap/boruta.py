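"""Shadow-feature relevance ranking (the Boruta procedure).

Each iteration appends a shuffled copy of every undecided feature, fits a
random-forest importance estimator on real + shadow columns, and scores a
"hit" for every real feature whose importance exceeds the best shadow
importance.  Two-sided binomial tests (Bonferroni-corrected over the
undecided features) confirm features that hit significantly more often
than chance and reject those that hit significantly less often.  The final
ordering is by decision tier (confirmed, tentative, rejected), then mean
importance descending, with lexicographic name tie-breaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .encoders import FeatureMatrix


class RankingError(ValueError):
    pass


@dataclass
class RankedFeatureList:
    """Importance-ordered features with confirmed/tentative/rejected status."""

    names: list[str]
    importance: dict[str, float]
    status: dict[str, str]
    hits: dict[str, int]
    n_iter: int

    def top(self, n: int) -> list[str]:
        return self.names[:n]

    @property
    def confirmed(self) -> list[str]:
        return [n for n in self.names if self.status[n] == "confirmed"]

    def save_tsv(self, path: str | Path) -> None:
        lines = ["rank\tfeature\timportance\tstatus\thits"]
        for i, n in enumerate(self.names, start=1):
            lines.append(
                f"{i}\t{n}\t{self.importance[n]:.8g}\t{self.status[n]}\t{self.hits[n]}"
            )
        Path(path).write_text("\n".join(lines) + "\n")

    @staticmethod
    def load_tsv(path: str | Path) -> "RankedFeatureList":
        names, imp, status, hits = [], {}, {}, {}
        lines = Path(path).read_text().splitlines()[1:]
        n_iter = 0
        for line in lines:
            _, name, im, st, h = line.split("\t")
            names.append(name)
            imp[name] = float(im)
            status[name] = st
            hits[name] = int(h)
        return RankedFeatureList(names, imp, status, hits, n_iter)


_TIER = {"confirmed": 0, "tentative": 1, "rejected": 2}


def boruta_rank(
    m: FeatureMatrix,
    labels: np.ndarray,
    max_iter: int = 50,
    alpha: float = 0.05,
    seed: int = 0,
    n_estimators: int = 200,
) -> RankedFeatureList:
    """Rank features of ``m`` against shuffled shadow copies.

    Requires both classes present with >= 5 rows each.  Deterministic for a
    fixed seed.  Importances are accumulated across iterations and averaged
    for the final ordering.
    """
    y = np.asarray(labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise RankingError("ranking requires both classes present")
    if counts.min() < 5:
        raise RankingError("ranking requires >= 5 rows per class")
    x = m.values
    names = m.columns
    p = len(names)
    rng = np.random.default_rng(seed)

    undecided = np.ones(p, dtype=bool)
    status = np.array(["tentative"] * p, dtype=object)
    hits = np.zeros(p, dtype=int)
    tested = 0  # iterations a feature could have hit in (same for all)
    imp_sum = np.zeros(p)
    imp_cnt = np.zeros(p, dtype=int)

    for it in range(max_iter):
        if not undecided.any():
            break
        active = np.flatnonzero(undecided)
        shadows = x[:, active].copy()
        for j in range(shadows.shape[1]):
            rng.shuffle(shadows[:, j])
        xb = np.hstack([x, shadows])
        forest = RandomForestClassifier(
            n_estimators=n_estimators,
            max_depth=7,
            n_jobs=1,
            random_state=int(rng.integers(2**31 - 1)),
        )
        forest.fit(xb, y)
        imp = forest.feature_importances_
        real_imp, shadow_imp = imp[:p], imp[p:]
        imp_sum += real_imp
        imp_cnt += 1
        threshold = shadow_imp.max() if shadow_imp.size else 0.0
        hits[undecided] += (real_imp[undecided] > threshold).astype(int)
        tested += 1

        # Bonferroni-corrected two-sided binomial decisions on undecided features
        n_undecided = int(undecided.sum())
        a = alpha / max(n_undecided, 1)
        for j in np.flatnonzero(undecided):
            p_hi = stats.binom.sf(hits[j] - 1, tested, 0.5)
            p_lo = stats.binom.cdf(hits[j], tested, 0.5)
            if p_hi < a:
                status[j] = "confirmed"
                undecided[j] = False
            elif p_lo < a:
                status[j] = "rejected"
                undecided[j] = False

    mean_imp = imp_sum / np.maximum(imp_cnt, 1)
    order = sorted(
        range(p), key=lambda j: (_TIER[status[j]], -mean_imp[j], names[j])
    )
    ordered = [names[j] for j in order]
    return RankedFeatureList(
        names=ordered,
        importance={names[j]: float(mean_imp[j]) for j in range(p)},
        status={names[j]: str(status[j]) for j in range(p)},
        hits={names[j]: int(hits[j]) for j in range(p)},
        n_iter=tested,
    )
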