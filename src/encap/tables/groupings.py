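"""Residue alphabets and categorical groupings.

All groupings here are fixed at import time; encoders never mutate them.
Every grouping covers the 20 standard residues exactly once per partition
(overlapping classes, e.g. :data:`OVPC_CLASSES`, are explicitly not partitions).
"""

from __future__ import annotations

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Number of sense codons per residue in the standard genetic code (total 61).
#: Used by the DDE encoder for its expected dipeptide means.
CODON_COUNTS = {
    "A": 4, "C": 2, "D": 2, "E": 2, "F": 2, "G": 4, "H": 2, "I": 3, "K": 2,
    "L": 6, "M": 1, "N": 2, "P": 4, "Q": 2, "R": 6, "S": 6, "T": 4, "V": 4,
    "W": 1, "Y": 2,
}

#: Five-group alphabet for GAAC / GDPC / CKSAAGP:
#: aliphatic, aromatic, positively charged, negatively charged, uncharged.
GAAC_GROUPS = {
    "aliphatic": "GAVLMI",
    "aromatic": "FYW",
    "positive": "KRH",
    "negative": "DE",
    "uncharged": "STCPNQ",
}

#: Conjoint-triad classes (7 groups by dipole and side-chain volume).
CTRIAD_GROUPS = ["AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C"]

#: The 13 three-class physicochemical partitions behind the CTD descriptors:
#: seven hydrophobicity scales plus van der Waals volume, polarity,
#: polarizability, charge, secondary structure and solvent accessibility.
#: Each value is a (group1, group2, group3) partition of the alphabet.
CTD_PROPERTIES = {
    "hydrophobicity_PRAM900101": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "hydrophobicity_ARGP820101": ("QSTNGDE", "RAHCKMV", "LYPFIW"),
    "hydrophobicity_ZIMJ680101": ("QNGSWTDERA", "HMCKV", "LPFYI"),
    "hydrophobicity_PONP930101": ("KPDESNQT", "GRHA", "YMFWLCVI"),
    "hydrophobicity_CASG920101": ("KDEQPSRNTG", "AHYMLV", "FIWC"),
    "hydrophobicity_ENGD860101": ("RDKENQHYP", "SGTAW", "CVLIMF"),
    "hydrophobicity_FASG890101": ("KERSQD", "NTPG", "AYHWVMFLIC"),
    "normwaalsvolume": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondarystruct": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solventaccess": ("ALFCGIVW", "RKQEND", "MSPTHY"),
}

#: Partitions over which the property-entropy (SEP) descriptor is computed:
#: the 13 CTD partitions plus a binary aromatic / non-aromatic split.
SEP_PARTITIONS = dict(CTD_PROPERTIES)
SEP_PARTITIONS["aromatic_binary"] = ("FWYH", "ACDEGIKLMNPQRSTV")

#: Overlapping property classes for the OVPC (overlapping property
#: composition) block: one class-fraction feature per entry. Classes
#: deliberately overlap (e.g. E is both charged and hydrophilic).
OVPC_CLASSES = {
    "Aliphatic": "AVLI",
    "Aromatic": "FWY",
    "Polar": "STNQCYH",
    "Nonpolar": "AVLIMFWGP",
    "Charged": "EDRKH",
    "Positive": "RKH",
    "Negative": "DE",
    "Tiny": "AGSC",
    "Small": "AGSCTDNPV",
    "Bulky": "FWYRKILM",
    "Hydrophobic": "VILMFWC",
    "Hydrophilic": "RNDEQHKST",
    "Sulfur": "CM",
    "KinkInducer": "GP",
}

#: Residue classes used in the property-stratified evaluation.  These
#: intentionally overlap: E, D, R, K, H are both hydrophilic and charged,
#: while A, G, P, Y belong to none of the three classes.
PROPERTY_CLASSES = {
    "hydrophobic": set("VILMFWC"),
    "hydrophilic": set("RNDEQHKST"),
    "charged": set("EDRKH"),
}
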