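"""Synthetic stand-in residue scales.

The multidimensional descriptor scales MSW, Ez, Cougar, the two extra
dimensions of the five-dimensional z-scale, and the sequence-order
distance matrix paired with the Grantham matrix are not reproducible here
from primary sources.  Each table in this module is therefore a
*constructed, synthetic stand-in*: a documented combination of published
per-residue properties (hydropathy, hydrophilicity, mass, volume, charge,
polarity), standardized to zero mean and unit variance across the 20
residues.  They preserve the dimensionality, scaling behaviour and rough
physicochemical meaning of the originals, but not their exact values;
every downstream computation treats them as opaque pinned tables.
"""

from __future__ import annotations

import numpy as np

from .groupings import AMINO_ACIDS
from .scales_builtin import (
    APAAC_HYDROPHILICITY,
    GRANTHAM_PROPERTIES,
    HELLBERG_Z3,
    KYTE_DOOLITTLE,
    RESIDUE_MASS,
)

_CHARGE = {a: 0.0 for a in AMINO_ACIDS}
_CHARGE.update({"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.1})

_PI_APPROX = {
    "A": 6.0, "C": 5.1, "D": 2.8, "E": 3.2, "F": 5.5, "G": 6.0, "H": 7.6,
    "I": 6.0, "K": 9.7, "L": 6.0, "M": 5.7, "N": 5.4, "P": 6.3, "Q": 5.7,
    "R": 10.8, "S": 5.7, "T": 5.6, "V": 6.0, "W": 5.9, "Y": 5.7,
}


def _standardize(values: dict[str, float]) -> dict[str, float]:
    arr = np.array([values[a] for a in AMINO_ACIDS], dtype=float)
    sd = arr.std()
    arr = (arr - arr.mean()) / (sd if sd > 0 else 1.0)
    return dict(zip(AMINO_ACIDS, arr))


def _stack(*columns: dict[str, float]) -> dict[str, tuple[float, ...]]:
    cols = [_standardize(c) for c in columns]
    return {a: tuple(c[a] for c in cols) for a in AMINO_ACIDS}


_POLARITY = {a: GRANTHAM_PROPERTIES[a][1] for a in AMINO_ACIDS}
_VOLUME = {a: GRANTHAM_PROPERTIES[a][2] for a in AMINO_ACIDS}

#: Synthetic stand-in for the 3-D molecular-surface (MSW) scale:
#: [hydropathy, mass, approximate residue pI].
MSW_SYNTHETIC = _stack(KYTE_DOOLITTLE, RESIDUE_MASS, _PI_APPROX)

#: Synthetic stand-in for the 3-D lipid-bilayer insertion-energy (Ez)
#: scale: [hydrophilicity, charge, polarity].
EZ_SYNTHETIC = _stack(APAAC_HYDROPHILICITY, _CHARGE, _POLARITY)

#: Synthetic stand-in for the 3-D "cougar" composite descriptor scale:
#: [z1, side-chain volume, charge].
COUGAR_SYNTHETIC = _stack({a: HELLBERG_Z3[a][0] for a in AMINO_ACIDS}, _VOLUME, _CHARGE)

#: Five-dimensional z-scale: published z1-z3 plus two synthetic stand-in
#: dimensions [mass, polarity] replacing the unavailable z4/z5 columns.
Z5_SYNTHETIC = {
    a: HELLBERG_Z3[a]
    + (
        _stack(RESIDUE_MASS)[a][0],
        _stack(_POLARITY)[a][0],
    )
    for a in AMINO_ACIDS
}

#: Six-dimensional one-hot-like class encoding: Acidic, Basic, Hydrophobic,
#: Polar, aRomatic, Kink-inducing membership per residue.
ABHPRK = {
    a: (
        float(a in "DE"),
        float(a in "KRH"),
        float(a in "VILMFWC"),
        float(a in "STNQY"),
        float(a in "FWY"),
        float(a in "GP"),
    )
    for a in AMINO_ACIDS
}

#: Registry of the multidimensional residue scales used by the
#: scale-descriptor encoders, keyed by descriptor type name.
SCALE_TABLES: dict[str, dict[str, tuple[float, ...]]] = {
    "MSW": MSW_SYNTHETIC,
    "Z3": HELLBERG_Z3,
    "Z5": Z5_SYNTHETIC,
    "Ez": EZ_SYNTHETIC,
    "Cougar": COUGAR_SYNTHETIC,
    "ABHPRK": ABHPRK,
}


def sequence_order_distance_matrix() -> np.ndarray:
    """Synthetic stand-in for the Schneider-Wrede physicochemical distance
    matrix used by the quasi-sequence-order encoder.

    Euclidean distance over standardized [hydropathy, hydrophilicity, mass],
    mirroring the hydrophobicity/steric basis of the original matrix.
    """
    cols = _stack(KYTE_DOOLITTLE, APAAC_HYDROPHILICITY, RESIDUE_MASS)
    arr = np.array([cols[a] for a in AMINO_ACIDS])
    diff = arr[:, None, :] - arr[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))
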