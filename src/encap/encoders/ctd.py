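"""Composition / Transition / Distribution descriptors over the 13
three-class physicochemical partitions (39 + 39 + 195 values).
"""

from __future__ import annotations

import numpy as np

from ..tables import CTD_PROPERTIES

_PROPS = list(CTD_PROPERTIES)
_CLASS_OF = {
    prop: {a: gi for gi, grp in enumerate(groups) for a in grp}
    for prop, groups in CTD_PROPERTIES.items()
}
_DIST_POINTS = (0.0, 0.25, 0.5, 0.75, 1.0)
_POINT_TAGS = ("first", "p25", "p50", "p75", "p100")


def ctdc(seq: str) -> np.ndarray:
    """Per-property class frequencies; each property block sums to 1."""
    out = np.zeros(39)
    for pi, prop in enumerate(_PROPS):
        cls = _CLASS_OF[prop]
        for ch in seq:
            out[pi * 3 + cls[ch]] += 1
    return out / len(seq)


def ctdt(seq: str) -> np.ndarray:
    """Class-transition frequencies between adjacent residues.

    For each property, the three values count adjacent pairs whose classes
    are {1,2}, {1,3} and {2,3} (either direction), divided by L-1 pairs.
    Homopolymers give all zeros.
    """
    n = len(seq) - 1
    out = np.zeros(39)
    pair_slot = {(0, 1): 0, (0, 2): 1, (1, 2): 2}
    for pi, prop in enumerate(_PROPS):
        cls = _CLASS_OF[prop]
        for i in range(n):
            a, b = cls[seq[i]], cls[seq[i + 1]]
            if a != b:
                out[pi * 3 + pair_slot[(min(a, b), max(a, b))]] += 1
    return out / n


def ctdd(seq: str) -> np.ndarray:
    """Distribution: percent positions (1-based, of L) of the first, 25%,
    50%, 75% and last occurrence of each class; 0 for absent classes.
    """
    L = len(seq)
    out = np.zeros(195)
    for pi, prop in enumerate(_PROPS):
        cls = _CLASS_OF[prop]
        positions: list[list[int]] = [[], [], []]
        for i, ch in enumerate(seq):
            positions[cls[ch]].append(i + 1)
        for gi in range(3):
            pos = positions[gi]
            base = pi * 15 + gi * 5
            if not pos:
                continue
            n = len(pos)
            for qi, q in enumerate(_DIST_POINTS):
                k = max(1, int(np.ceil(q * n)))
                out[base + qi] = 100.0 * pos[k - 1] / L
    return out


def ctdc_names() -> list[str]:
    return [f"CTDC_{p}_g{g + 1}" for p in _PROPS for g in range(3)]


def ctdt_names() -> list[str]:
    return [f"CTDT_{p}_{t}" for p in _PROPS for t in ("g1g2", "g1g3", "g2g3")]


def ctdd_names() -> list[str]:
    return [
        f"CTDD_{p}_g{g + 1}_{tag}"
        for p in _PROPS
        for g in range(3)
        for tag in _POINT_TAGS
    ]
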