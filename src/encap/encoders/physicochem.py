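"""Global physicochemical descriptors, multidimensional residue-scale
summaries and overlapping property-class compositions.

Scalar descriptors that have canonical implementations (molecular weight,
isoelectric point, instability index, aromaticity) are delegated to
Biopython's ProtParam; the remainder (charge, Boman index, aliphatic
index, hydrophobic ratio) are computed from the pinned tables.
"""

from __future__ import annotations

import numpy as np
from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from ..tables import AMINO_ACIDS, BOMAN_SCALE, OVPC_CLASSES
from ..tables.scales_synthetic import SCALE_TABLES

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

# Side-chain and terminal pKa values (EMBOSS-like set) for the
# Henderson-Hasselbalch net-charge sum.
_PKA_POS = {"K": 10.5, "R": 12.5, "H": 6.0}
_PKA_NEG = {"D": 3.65, "E": 4.25, "C": 8.3, "Y": 10.07}
_PKA_NTERM = 9.0
_PKA_CTERM = 2.34

GLOBAL_NAMES = [
    "length",
    "molecular_weight",
    "charge",
    "charge_density",
    "isoelectric_point",
    "instability_index",
    "aromaticity",
    "aliphatic_index",
    "boman_index",
    "hydrophobic_ratio",
]

_HYDROPHOBIC = set("VILMFWC")


def net_charge(seq: str, ph: float = 7.0) -> float:
    """Henderson-Hasselbalch net charge at the given pH."""
    pos = 1.0 / (1.0 + 10 ** (ph - _PKA_NTERM))
    neg = 1.0 / (1.0 + 10 ** (_PKA_CTERM - ph))
    for ch in seq:
        if ch in _PKA_POS:
            pos += 1.0 / (1.0 + 10 ** (ph - _PKA_POS[ch]))
        elif ch in _PKA_NEG:
            neg += 1.0 / (1.0 + 10 ** (_PKA_NEG[ch] - ph))
    return pos - neg


def aliphatic_index(seq: str) -> float:
    """Ikai aliphatic index from mole percents: X_A + 2.9 X_V + 3.9 (X_I + X_L)."""
    L = len(seq)
    x = {a: 100.0 * seq.count(a) / L for a in "AVIL"}
    return x["A"] + 2.9 * x["V"] + 3.9 * (x["I"] + x["L"])


def boman_index(seq: str) -> float:
    """Mean transfer free energy with sign flipped: higher values indicate
    stronger protein-binding / hydrophilic character."""
    return -sum(BOMAN_SCALE[c] for c in seq) / len(seq)


def isoelectric_point(seq: str, tol: float = 1e-5) -> float:
    """Root of the Bjellqvist net-charge function, found by bisection over
    the full 0-14 pH range (short acidic peptides can sit below pH 4)."""
    ip = IsoelectricPoint(seq)
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if ip.charge_at_pH(mid) > 0.0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def global_properties(seq: str) -> np.ndarray:
    if len(seq) < 2:
        raise ValueError("global descriptors require length >= 2 (instability index)")
    pa = ProteinAnalysis(seq)
    mw = pa.molecular_weight()
    charge = net_charge(seq)
    return np.array(
        [
            float(len(seq)),
            mw,
            charge,
            charge / mw,
            isoelectric_point(seq),
            pa.instability_index(),
            pa.aromaticity(),
            aliphatic_index(seq),
            boman_index(seq),
            sum(c in _HYDROPHOBIC for c in seq) / len(seq),
        ]
    )


# --- multidimensional residue-scale summaries -------------------------------

#: Ten order-independent-safe summary statistics per scale dimension.
_STATS10 = ("mean", "std", "min", "max", "median", "q25", "q75", "first", "last", "range")
#: Five additional short-window statistics used by the 15-per-dimension mode.
_STATS15 = _STATS10 + ("nterm3", "cterm3", "maxwin3", "minwin3", "msd")


def _summaries(profile: np.ndarray, tags: tuple[str, ...]) -> list[float]:
    out: list[float] = []
    win3 = (
        np.convolve(profile, np.ones(3) / 3.0, mode="valid")
        if len(profile) >= 3
        else profile
    )
    for tag in tags:
        if tag == "mean":
            out.append(float(profile.mean()))
        elif tag == "std":
            out.append(float(profile.std()))
        elif tag == "min":
            out.append(float(profile.min()))
        elif tag == "max":
            out.append(float(profile.max()))
        elif tag == "median":
            out.append(float(np.median(profile)))
        elif tag == "q25":
            out.append(float(np.quantile(profile, 0.25)))
        elif tag == "q75":
            out.append(float(np.quantile(profile, 0.75)))
        elif tag == "first":
            out.append(float(profile[0]))
        elif tag == "last":
            out.append(float(profile[-1]))
        elif tag == "range":
            out.append(float(profile.max() - profile.min()))
        elif tag == "nterm3":
            out.append(float(profile[:3].mean()))
        elif tag == "cterm3":
            out.append(float(profile[-3:].mean()))
        elif tag == "maxwin3":
            out.append(float(win3.max()))
        elif tag == "minwin3":
            out.append(float(win3.min()))
        elif tag == "msd":
            out.append(float(np.abs(np.diff(profile)).mean()))
    return out


def scale_descriptor(seq: str, scale_name: str, stats: int = 10) -> np.ndarray:
    """Summaries of the per-residue profile of each scale dimension.

    ``stats`` selects 10 or 15 summary statistics per dimension; the
    15-statistic mode adds terminal and sliding-window summaries and
    requires length >= 3.
    """
    table = SCALE_TABLES[scale_name]
    tags = _STATS15 if stats == 15 else _STATS10
    if stats == 15 and len(seq) < 3:
        raise ValueError(f"{scale_name}: 15-statistic mode requires length >= 3")
    dims = len(next(iter(table.values())))
    arr = np.array([table[c] for c in seq])  # L x dims
    out: list[float] = []
    for d in range(dims):
        out.extend(_summaries(arr[:, d], tags))
    return np.array(out)


def scale_descriptor_names(scale_name: str, stats: int = 10) -> list[str]:
    table = SCALE_TABLES[scale_name]
    dims = len(next(iter(table.values())))
    tags = _STATS15 if stats == 15 else _STATS10
    return [f"{scale_name}_d{d + 1}_{tag}" for d in range(dims) for tag in tags]


def abhprk(seq: str) -> np.ndarray:
    """Mean membership of the six ABHPRK classes (acidic, basic,
    hydrophobic, polar, aromatic, kink-inducing)."""
    table = SCALE_TABLES["ABHPRK"]
    arr = np.array([table[c] for c in seq])
    return arr.mean(axis=0)


ABHPRK_NAMES = [
    f"ABHPRK_{t}" for t in ("acidic", "basic", "hydrophobic", "polar", "aromatic", "kink")
]


def ovpc(seq: str) -> np.ndarray:
    """Overlapping property composition: the fraction of residues in each
    of the 14 (mutually overlapping) property classes."""
    return np.array(
        [sum(c in members for c in seq) / len(seq) for members in OVPC_CLASSES.values()]
    )


OVPC_NAMES = [f"OVPC_{cls}" for cls in OVPC_CLASSES]
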