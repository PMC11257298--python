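"""Sequential model-based hyperparameter search (tree-structured Parzen
estimator style).

Trial 1 always evaluates the family's implementation defaults.  A fixed
number of startup trials samples uniformly from the search space; after
that, each parameter is proposed by splitting past trials into the
top-gamma "good" set and the rest, modelling both with one-dimensional
Parzen windows (Gaussian kernels for numeric parameters, weighted
categorical counts for choices), and taking the candidate maximizing the
good/bad density ratio among a fixed number of draws from the good model.
The objective is mean cross-validated MCC, maximized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .encoders import FeatureMatrix
from .models import SEARCH_SPACES, ModelError, ModelSpec, cross_validate


@dataclass
class TrialRecord:
    number: int
    hyperparameters: dict
    objective: float
    seed: int


@dataclass
class TPEConfig:
    n_startup: int = 10
    n_candidates: int = 24
    gamma: float = 0.25


def _to_unit(kind: str, value, low, high) -> float:
    if kind in ("logint", "logfloat"):
        return (math.log(value) - math.log(low)) / (math.log(high) - math.log(low))
    return (value - low) / (high - low)


def _from_unit(kind: str, u: float, low, high):
    u = min(max(u, 0.0), 1.0)
    if kind in ("logint", "logfloat"):
        v = math.exp(math.log(low) + u * (math.log(high) - math.log(low)))
    else:
        v = low + u * (high - low)
    if kind in ("int", "logint"):
        v = int(round(v))
        v = min(max(v, int(low)), int(high))
    return v


def _sample_uniform(space: dict, rng: np.random.Generator) -> dict:
    out = {}
    for name, spec in space.items():
        kind = spec[0]
        if kind == "cat":
            choices = spec[1]
            out[name] = choices[rng.integers(len(choices))]
        else:
            out[name] = _from_unit(kind, rng.random(), spec[1], spec[2])
    return out


def _parzen_propose(
    name: str,
    spec: tuple,
    good: list[dict],
    bad: list[dict],
    rng: np.random.Generator,
    n_candidates: int,
):
    kind = spec[0]
    if kind == "cat":
        choices = spec[1]
        prior = 1.0
        g_counts = np.array(
            [prior + sum(t[name] == c for t in good) for c in choices], dtype=float
        )
        b_counts = np.array(
            [prior + sum(t[name] == c for t in bad) for c in choices], dtype=float
        )
        g_p = g_counts / g_counts.sum()
        b_p = b_counts / b_counts.sum()
        idx = rng.choice(len(choices), size=n_candidates, p=g_p)
        best = max(set(idx.tolist()), key=lambda i: g_p[i] / b_p[i])
        return choices[best]

    low, high = spec[1], spec[2]
    g_u = np.array([_to_unit(kind, t[name], low, high) for t in good])
    b_u = np.array([_to_unit(kind, t[name], low, high) for t in bad])

    def density(points: np.ndarray, obs: np.ndarray) -> np.ndarray:
        # Parzen mixture: observations plus a uniform prior component
        bw = max(1.0 / max(len(obs), 1) ** 0.5 * 0.5, 0.1)
        comp = np.exp(-0.5 * ((points[:, None] - obs[None, :]) / bw) ** 2) / (
            bw * math.sqrt(2 * math.pi)
        )
        return (comp.sum(axis=1) + 1.0) / (len(obs) + 1.0)

    centers = g_u[rng.integers(len(g_u), size=n_candidates)]
    bw = max(1.0 / max(len(g_u), 1) ** 0.5 * 0.5, 0.1)
    cands = centers + rng.normal(0.0, bw, size=n_candidates)
    cands = np.clip(cands, 0.0, 1.0)
    ratio = density(cands, g_u) / density(cands, b_u)
    return _from_unit(kind, float(cands[int(np.argmax(ratio))]), low, high)


def optimize_hyperparameters(
    family: str,
    m: FeatureMatrix,
    labels,
    trials: int = 100,
    folds: int = 5,
    seed: int = 0,
    config: TPEConfig | None = None,
    scale_in_fold: bool = True,
) -> tuple[ModelSpec, list[TrialRecord]]:
    """Maximize mean CV MCC over the family's declared search space.

    Returns the argmax trial's spec (trial 1 is always the defaults, so the
    returned objective can never fall below the default configuration's)
    and the full trial trace.  Reproducible for a fixed seed.
    """
    if trials < 1:
        raise ModelError("trials must be >= 1")
    space = SEARCH_SPACES.get(family)
    if not space:
        raise ModelError(f"no search space declared for family {family!r}")
    cfg = config or TPEConfig()
    rng = np.random.default_rng(seed)

    records: list[TrialRecord] = []

    def run_trial(number: int, hp: dict) -> TrialRecord:
        spec = ModelSpec(family, hp)
        cv = cross_validate(
            spec, m, labels, folds=folds, seed=seed, scale_in_fold=scale_in_fold
        )
        rec = TrialRecord(number, dict(hp), cv.mcc, seed)
        records.append(rec)
        return rec

    run_trial(1, {})  # family defaults first, always
    for t in range(2, trials + 1):
        scored = [r for r in records if r.hyperparameters]
        if t <= cfg.n_startup or len(scored) < 4:
            hp = _sample_uniform(space, rng)
        else:
            ordered = sorted(scored, key=lambda r: -r.objective)
            n_good = max(1, int(math.ceil(cfg.gamma * len(ordered))))
            good = [r.hyperparameters for r in ordered[:n_good]]
            bad = [r.hyperparameters for r in ordered[n_good:]] or good
            hp = {
                name: _parzen_propose(name, spec, good, bad, rng, cfg.n_candidates)
                for name, spec in space.items()
            }
        run_trial(t, hp)

    best = max(records, key=lambda r: r.objective)
    return ModelSpec(family, best.hyperparameters), records
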