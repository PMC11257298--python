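"""Compositional encoders: AAC, DPC, GAAC, GDPC, CKSAAP, CKSAAGP, CTriad, DDE.

Frequencies are raw counts divided by the number of windows (L, L-1 or
L-k-1); no pseudocounts.  DDE standardizes dipeptide frequencies against
expectations derived from the 61 sense codons of the standard genetic code.
"""

from __future__ import annotations

import itertools

import numpy as np

from ..tables import AMINO_ACIDS, CODON_COUNTS, CTRIAD_GROUPS, GAAC_GROUPS

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_GROUP_NAMES = list(GAAC_GROUPS)
_GROUP_OF = {a: g for g, members in GAAC_GROUPS.items() for a in members}
_GROUP_INDEX = {g: i for i, g in enumerate(_GROUP_NAMES)}
_TRIAD_OF = {a: i for i, grp in enumerate(CTRIAD_GROUPS) for a in grp}

DIPEPTIDES = [a + b for a in AMINO_ACIDS for b in AMINO_ACIDS]
GROUP_PAIRS = [f"{g1}.{g2}" for g1 in _GROUP_NAMES for g2 in _GROUP_NAMES]


def aac(seq: str) -> np.ndarray:
    v = np.zeros(20)
    for ch in seq:
        v[_AA_INDEX[ch]] += 1
    return v / len(seq)


def dpc(seq: str) -> np.ndarray:
    v = np.zeros(400)
    for i in range(len(seq) - 1):
        v[_AA_INDEX[seq[i]] * 20 + _AA_INDEX[seq[i + 1]]] += 1
    return v / (len(seq) - 1)


def gaac(seq: str) -> np.ndarray:
    v = np.zeros(5)
    for ch in seq:
        v[_GROUP_INDEX[_GROUP_OF[ch]]] += 1
    return v / len(seq)


def gdpc(seq: str) -> np.ndarray:
    v = np.zeros(25)
    for i in range(len(seq) - 1):
        g1 = _GROUP_INDEX[_GROUP_OF[seq[i]]]
        g2 = _GROUP_INDEX[_GROUP_OF[seq[i + 1]]]
        v[g1 * 5 + g2] += 1
    return v / (len(seq) - 1)


def cksaap(seq: str, gap: int) -> np.ndarray:
    """Frequencies of residue pairs separated by exactly ``gap`` positions."""
    n_windows = len(seq) - gap - 1
    v = np.zeros(400)
    for i in range(n_windows):
        v[_AA_INDEX[seq[i]] * 20 + _AA_INDEX[seq[i + gap + 1]]] += 1
    return v / n_windows


def cksaagp(seq: str, gap: int) -> np.ndarray:
    n_windows = len(seq) - gap - 1
    v = np.zeros(25)
    for i in range(n_windows):
        g1 = _GROUP_INDEX[_GROUP_OF[seq[i]]]
        g2 = _GROUP_INDEX[_GROUP_OF[seq[i + gap + 1]]]
        v[g1 * 5 + g2] += 1
    return v / n_windows


def ctriad(seq: str) -> np.ndarray:
    v = np.zeros(343)
    for i in range(len(seq) - 2):
        a, b, c = _TRIAD_OF[seq[i]], _TRIAD_OF[seq[i + 1]], _TRIAD_OF[seq[i + 2]]
        v[a * 49 + b * 7 + c] += 1
    return v / (len(seq) - 2)


def dde(seq: str) -> np.ndarray:
    """Dipeptide deviation from expected mean.

    For dipeptide ij: Dc = observed frequency over L-1 windows,
    Tm = (C_i/61)(C_j/61) with C the sense-codon counts,
    Tv = Tm(1-Tm)/(L-1), DDE = (Dc - Tm)/sqrt(Tv).
    """
    n = len(seq) - 1
    dc = dpc(seq)
    tm = np.array(
        [(CODON_COUNTS[d[0]] / 61.0) * (CODON_COUNTS[d[1]] / 61.0) for d in DIPEPTIDES]
    )
    tv = tm * (1.0 - tm) / n
    return (dc - tm) / np.sqrt(tv)


def triad_names() -> list[str]:
    return [
        f"CTriad_g{a + 1}g{b + 1}g{c + 1}"
        for a, b, c in itertools.product(range(7), repeat=3)
    ]
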