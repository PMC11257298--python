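"""Published per-residue numeric scales, pinned for bit-exact reproducibility.

Sources are cited per table. Values are transcribed from the primary
literature; nothing here is fitted to data at run time.
"""

from __future__ import annotations

import numpy as np

from .groupings import AMINO_ACIDS

#: Normalized hydrophobicity used by the amphiphilic pseudo-composition
#: encoder (Tanford-type consensus scale of the classical PseAAC papers).
APAAC_HYDROPHOBICITY = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19, "G": 0.48,
    "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06, "M": 0.64, "N": -0.78,
    "P": 0.12, "Q": -0.85, "R": -2.53, "S": -0.18, "T": -0.05, "V": 1.08,
    "W": 0.81, "Y": 0.26,
}

#: Hopp & Woods (1981) hydrophilicity.
APAAC_HYDROPHILICITY = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5, "G": 0.0,
    "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8, "M": -1.3, "N": 0.2,
    "P": 0.0, "Q": 0.2, "R": 3.0, "S": 0.3, "T": -0.4, "V": -1.5,
    "W": -3.4, "Y": -2.3,
}

#: Kyte & Doolittle (1982) hydropathy.
KYTE_DOOLITTLE = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8, "G": -0.4,
    "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8, "M": 1.9, "N": -3.5,
    "P": -1.6, "Q": -3.5, "R": -4.5, "S": -0.8, "T": -0.7, "V": 4.2,
    "W": -0.9, "Y": -1.3,
}

#: Hellberg et al. (1987) three principal-property z-scales (z1, z2, z3).
HELLBERG_Z3 = {
    "A": (0.07, -1.73, 0.09), "C": (0.71, -0.97, 4.13),
    "D": (3.64, 1.13, 2.36), "E": (3.08, 0.39, -0.07),
    "F": (-4.92, 1.30, 0.45), "G": (2.23, -5.36, 0.30),
    "H": (2.41, 1.74, 1.11), "I": (-4.44, -1.68, -1.03),
    "K": (2.84, 1.41, -3.14), "L": (-4.19, -1.03, -0.98),
    "M": (-2.49, -0.27, -0.41), "N": (3.22, 1.45, 0.84),
    "P": (-1.22, 0.88, 2.23), "Q": (2.18, 0.53, -1.14),
    "R": (2.88, 2.52, -3.44), "S": (1.96, -1.63, 0.57),
    "T": (0.92, -2.09, -1.40), "V": (-2.69, -2.53, -1.29),
    "W": (-4.75, 3.65, 0.85), "Y": (-1.39, 2.32, 0.01),
}

#: Radzicka & Wolfenden water->cyclohexane transfer free energies
#: (kcal/mol), the per-residue basis of the Boman binding-potential index.
BOMAN_SCALE = {
    "A": 1.81, "C": 1.28, "D": -8.72, "E": -6.81, "F": 2.98, "G": 0.94,
    "H": -4.66, "I": 4.92, "K": -5.55, "L": 4.92, "M": 2.35, "N": -6.64,
    "P": 0.0, "Q": -5.54, "R": -14.92, "S": -3.40, "T": -2.57, "V": 4.04,
    "W": 2.33, "Y": -0.14,
}

#: Average residue masses (Da), used for the molecular-weight descriptor
#: cross-checks and the constructed scales.
RESIDUE_MASS = {
    "A": 71.08, "C": 103.14, "D": 115.09, "E": 129.12, "F": 147.18,
    "G": 57.05, "H": 137.14, "I": 113.16, "K": 128.17, "L": 113.16,
    "M": 131.19, "N": 114.10, "P": 97.12, "Q": 128.13, "R": 156.19,
    "S": 87.08, "T": 101.10, "V": 99.13, "W": 186.21, "Y": 163.18,
}

#: Grantham (1974) per-residue properties: composition c, polarity p,
#: side-chain volume v.  Distances are recomputed from the closed form
#: below instead of shipping the 20x20 matrix.
GRANTHAM_PROPERTIES = {
    "A": (0.00, 8.1, 31.0), "C": (2.75, 5.5, 55.0), "D": (1.38, 13.0, 54.0),
    "E": (0.92, 12.3, 83.0), "F": (0.00, 5.2, 132.0), "G": (0.74, 9.0, 3.0),
    "H": (0.58, 10.4, 96.0), "I": (0.00, 5.2, 111.0), "K": (0.33, 11.3, 119.0),
    "L": (0.00, 4.9, 111.0), "M": (0.00, 5.7, 105.0), "N": (1.33, 11.6, 56.0),
    "P": (0.39, 8.0, 32.5), "Q": (0.89, 10.5, 85.0), "R": (0.65, 10.5, 124.0),
    "S": (1.42, 9.2, 32.0), "T": (0.71, 8.6, 61.0), "V": (0.00, 5.9, 84.0),
    "W": (0.13, 5.4, 170.0), "Y": (0.20, 6.2, 136.0),
}

_GRANTHAM_ALPHA = 1.833
_GRANTHAM_BETA = 0.1018
_GRANTHAM_GAMMA = 0.000399


def grantham_distance_matrix() -> np.ndarray:
    """20x20 Grantham chemical distance matrix in alphabet order.

    D(i,j) = rho * sqrt(alpha*(c_i-c_j)^2 + beta*(p_i-p_j)^2 + gamma*(v_i-v_j)^2),
    with rho fixed so that the mean off-diagonal distance equals 100, the
    normalization used in the original publication.
    """
    props = np.array([GRANTHAM_PROPERTIES[a] for a in AMINO_ACIDS])
    dc = props[:, None, 0] - props[None, :, 0]
    dp = props[:, None, 1] - props[None, :, 1]
    dv = props[:, None, 2] - props[None, :, 2]
    raw = np.sqrt(_GRANTHAM_ALPHA * dc**2 + _GRANTHAM_BETA * dp**2 + _GRANTHAM_GAMMA * dv**2)
    off = raw[~np.eye(20, dtype=bool)]
    return raw * (100.0 / off.mean())
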