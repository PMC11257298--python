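"""Repeat and entropy descriptors: DDR, RRI, SER, SEP."""

from __future__ import annotations

import numpy as np

from ..tables import AMINO_ACIDS, SEP_PARTITIONS


def ddr(seq: str) -> np.ndarray:
    """Distance distribution of repeats: per residue type, the mean gap
    between consecutive occurrences normalized by peptide length (0 when
    the residue occurs fewer than twice)."""
    L = len(seq)
    out = np.zeros(20)
    for ai, a in enumerate(AMINO_ACIDS):
        pos = [i for i, c in enumerate(seq) if c == a]
        if len(pos) >= 2:
            gaps = np.diff(pos)
            out[ai] = float(gaps.mean()) / L
    return out


def rri(seq: str) -> np.ndarray:
    """Residue repeats index: longest homopolymeric run over length."""
    best = run = 1
    for i in range(1, len(seq)):
        run = run + 1 if seq[i] == seq[i - 1] else 1
        best = max(best, run)
    return np.array([best / len(seq)])


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def ser(seq: str) -> np.ndarray:
    """Shannon entropy (bits) of the residue frequency distribution."""
    counts = np.array([seq.count(a) for a in AMINO_ACIDS], dtype=float)
    return np.array([_entropy(counts)])


def sep(seq: str) -> np.ndarray:
    """Shannon entropy of the class-frequency distribution under each of
    the 14 physicochemical partitions."""
    out = np.zeros(len(SEP_PARTITIONS))
    for pi, groups in enumerate(SEP_PARTITIONS.values()):
        counts = np.array(
            [sum(c in grp for c in seq) for grp in groups], dtype=float
        )
        out[pi] = _entropy(counts)
    return out


DDR_NAMES = [f"DDR_{a}" for a in AMINO_ACIDS]
RRI_NAMES = ["RRI"]
SER_NAMES = ["SER"]
SEP_NAMES = [f"SEP_{p}" for p in SEP_PARTITIONS]
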