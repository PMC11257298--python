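"""Sequence-order encoders: amphiphilic pseudo amino acid composition
(APAAC) and quasi-sequence order (QSO).
"""

from __future__ import annotations

import numpy as np

from ..tables import AMINO_ACIDS, APAAC_HYDROPHILICITY, APAAC_HYDROPHOBICITY
from ..tables import grantham_distance_matrix
from ..tables.scales_synthetic import sequence_order_distance_matrix

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def _standardized(scale: dict[str, float]) -> np.ndarray:
    arr = np.array([scale[a] for a in AMINO_ACIDS])
    return (arr - arr.mean()) / arr.std()


_H1 = _standardized(APAAC_HYDROPHOBICITY)
_H2 = _standardized(APAAC_HYDROPHILICITY)

# Distance matrices for the two QSO coupling blocks, computed once.
_D_SW = sequence_order_distance_matrix()
_D_GRANTHAM = grantham_distance_matrix()


def apaac(seq: str, lam: int = 3, weight: float = 0.05) -> np.ndarray:
    """Composition (20) plus 2*lam amphiphilic correlation terms.

    Tier j couples hydrophobicity (odd slots) and hydrophilicity (even
    slots) of residues j apart; with lam=0 the output is plain normalized
    composition.
    """
    L = len(seq)
    if L <= lam:
        raise ValueError(f"APAAC requires length > lambda ({lam}), got {L}")
    idx = np.array([_AA_INDEX[c] for c in seq])
    counts = np.bincount(idx, minlength=20).astype(float)
    taus: list[float] = []
    for j in range(1, lam + 1):
        h1 = float(np.mean(_H1[idx[:-j]] * _H1[idx[j:]]))
        h2 = float(np.mean(_H2[idx[:-j]] * _H2[idx[j:]]))
        taus.extend([h1, h2])
    tau = np.array(taus)
    denom = counts.sum() + weight * tau.sum()
    return np.concatenate([counts / denom, weight * tau / denom])


def qso(seq: str, nlag: int = 3, weight: float = 0.1) -> np.ndarray:
    """Two blocks of 20+nlag values, one per distance matrix.

    Block d: counts f_r and coupling terms tau_d = sum_i dist(s_i, s_{i+d})^2,
    jointly normalized by sum(f) + w * sum(tau).
    """
    L = len(seq)
    if L <= nlag:
        raise ValueError(f"QSO requires length > nlag ({nlag}), got {L}")
    idx = np.array([_AA_INDEX[c] for c in seq])
    counts = np.bincount(idx, minlength=20).astype(float)
    blocks: list[np.ndarray] = []
    for dist in (_D_SW, _D_GRANTHAM):
        tau = np.array(
            [float(np.sum(dist[idx[:-d], idx[d:]] ** 2)) for d in range(1, nlag + 1)]
        )
        denom = counts.sum() + weight * tau.sum()
        blocks.append(np.concatenate([counts / denom, weight * tau / denom]))
    return np.concatenate(blocks)


def apaac_names(lam: int = 3) -> list[str]:
    names = [f"APAAC_{a}" for a in AMINO_ACIDS]
    for j in range(1, lam + 1):
        names += [f"APAAC_tau{j}_hydrophobicity", f"APAAC_tau{j}_hydrophilicity"]
    return names


def qso_names(nlag: int = 3) -> list[str]:
    names: list[str] = []
    for tag in ("SW", "G"):
        names += [f"QSO_{tag}_{a}" for a in AMINO_ACIDS]
        names += [f"QSO_{tag}_tau{d}" for d in range(1, nlag + 1)]
    return names
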