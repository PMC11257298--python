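"""Binary motif presence/absence features.

Motifs are plain consensus strings (3-20 residues) discovered externally
on the positive and negative classes separately; this module only consumes
them.  Matching is exact contiguous substring: bit i is 1 iff motif i
occurs anywhere in the peptide.  Duplicate strings across the positive and
negative lists are kept as distinct bits in class order, preserving the
combined block sizes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np

from .peptides import Peptide
from .tables import AMINO_ACIDS

_VALID = set(AMINO_ACIDS)


class MotifError(ValueError):
    pass


@dataclass(frozen=True)
class Motif:
    pattern: str
    origin: str  # "pos" (TTCA) or "neg" (non-TTCA)

    def __post_init__(self) -> None:
        if not 3 <= len(self.pattern) <= 20:
            raise MotifError(f"motif {self.pattern!r}: length must be 3-20")
        bad = set(self.pattern) - _VALID
        if bad:
            raise MotifError(f"motif {self.pattern!r}: illegal characters {sorted(bad)}")
        if self.origin not in ("pos", "neg"):
            raise MotifError(f"motif origin must be 'pos' or 'neg', got {self.origin!r}")


@dataclass
class MotifSet:
    """Ordered motif list: positives first, then negatives, input order
    preserved within class."""

    motifs: list[Motif]

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self) -> Iterator[Motif]:
        return iter(self.motifs)

    @staticmethod
    def from_lists(positive: list[str], negative: list[str]) -> "MotifSet":
        return MotifSet(
            [Motif(p.upper(), "pos") for p in positive]
            + [Motif(n.upper(), "neg") for n in negative]
        )

    def save(self, path: str | Path) -> None:
        lines = [f"{m.pattern}\t{m.origin}" for m in self.motifs]
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))

    @staticmethod
    def load(path: str | Path) -> "MotifSet":
        return load_motifs(path)


def load_motifs(path: str | Path) -> MotifSet:
    """Read a motif list: either ``<motif><TAB><pos|neg>`` lines or STREME
    text output (consensus strings on ``MOTIF`` lines, all one class)."""
    path = Path(path)
    text = path.read_text()
    pos: list[str] = []
    neg: list[str] = []
    streme_motifs = re.findall(r"^MOTIF\s+(?:\d+-)?([A-Z]+)", text, flags=re.M)
    if streme_motifs and "\t" not in text:
        pos = streme_motifs
    else:
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise MotifError(f"{path}:{lineno}: expected '<motif>\\t<pos|neg>'")
            pattern, tag = parts[0].strip().upper(), parts[1].strip().lower()
            if tag in ("pos", "ttca", "1"):
                pos.append(pattern)
            elif tag in ("neg", "non-ttca", "0"):
                neg.append(pattern)
            else:
                raise MotifError(f"{path}:{lineno}: unknown class tag {tag!r}")
    return MotifSet.from_lists(pos, neg)


def encode_motifs(p: Peptide | str, motifs: MotifSet) -> np.ndarray:
    """Bit vector of length ``len(motifs)``: 1 iff the motif occurs as a
    contiguous exact substring."""
    seq = p.sequence if isinstance(p, Peptide) else p
    return np.array([1.0 if m.pattern in seq else 0.0 for m in motifs])


# Motif consensus lists reported for the two benchmark antigen corpora
# (published results used as inputs): 9 + 2 strings for the first corpus,
# 3 + 5 for the second.
DS1_MOTIFS = MotifSet.from_lists(
    ["FATP", "AEEA", "ALQP", "AVI", "LMK", "SLADTN", "VFGI", "RLAE", "LLD"],
    ["IPRHL", "ALAG"],
)
DS2_MOTIFS = MotifSet.from_lists(
    ["LMK", "ADV", "AGIGIL"],
    ["AQID", "EFP", "AVADE", "VDEV", "ITD"],
)
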