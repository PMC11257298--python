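"""Reading, validating, writing and splitting labeled peptide sets.

Peptides are short (typically 8-14 residue) sequences over the 20 standard
amino acids, labeled 1 for tumor T cell antigens (TTCAs) and 0 for
non-TTCAs.  Records containing non-standard residues are rejected and
reported rather than aborting the run, mirroring how curated antigen sets
are filtered in practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

from .tables import AMINO_ACIDS

_VALID = set(AMINO_ACIDS)
MIN_LENGTH = 3


class PeptideError(ValueError):
    """Raised for invalid peptide records or malformed input files."""


@dataclass(frozen=True)
class Peptide:
    """A validated amino-acid sequence with an identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < MIN_LENGTH:
            raise PeptideError(f"{self.id}: sequence shorter than {MIN_LENGTH} residues")
        bad = set(seq) - _VALID
        if bad:
            raise PeptideError(f"{self.id}: non-standard amino acid {''.join(sorted(bad))}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class RejectedRecord:
    id: str
    sequence: str
    reason: str


@dataclass
class LabeledPeptideSet:
    """Parallel lists of peptides and binary labels (1=TTCA, 0=non-TTCA)."""

    peptides: list[Peptide] = field(default_factory=list)
    labels: list[int] = field(default_factory=list)
    rejected: list[RejectedRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.peptides) != len(self.labels):
            raise PeptideError("peptides and labels differ in length")
        ids = [p.id for p in self.peptides]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise PeptideError(f"duplicate peptide ids: {', '.join(dupes)}")
        for lab in self.labels:
            if lab not in (0, 1):
                raise PeptideError(f"label must be 0 or 1, got {lab!r}")

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self) -> Iterator[tuple[Peptide, int]]:
        return iter(zip(self.peptides, self.labels))

    @property
    def sequences(self) -> list[str]:
        return [p.sequence for p in self.peptides]

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.peptides]

    @property
    def y(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=int)

    def subset(self, indices: Iterable[int]) -> "LabeledPeptideSet":
        idx = list(indices)
        return LabeledPeptideSet(
            peptides=[self.peptides[i] for i in idx],
            labels=[self.labels[i] for i in idx],
        )

    def class_counts(self) -> tuple[int, int]:
        y = self.y
        return int((y == 1).sum()), int((y == 0).sum())


def _build(records: Iterable[tuple[str, str, int]]) -> LabeledPeptideSet:
    peptides: list[Peptide] = []
    labels: list[int] = []
    rejected: list[RejectedRecord] = []
    seen: set[str] = set()
    for pid, seq, label in records:
        if pid in seen:
            raise PeptideError(f"duplicate peptide ids: {pid}")
        seen.add(pid)
        try:
            peptides.append(Peptide(pid, seq))
            labels.append(int(label))
        except PeptideError as exc:
            rejected.append(RejectedRecord(pid, seq, str(exc).split(": ", 1)[-1]))
    out = LabeledPeptideSet(peptides, labels)
    out.rejected = rejected
    return out


def _parse_label(token: str, where: str) -> int:
    token = token.strip()
    if token in {"1", "TTCA", "pos", "positive"}:
        return 1
    if token in {"0", "non-TTCA", "neg", "negative"}:
        return 0
    raise PeptideError(f"{where}: cannot parse label {token!r}")


def read_peptides(path: str | Path, format: str = "fasta") -> LabeledPeptideSet:
    """Read a labeled peptide set from FASTA (``>id|label``) or TSV
    (``sequence<TAB>label``).

    Records with non-standard residues are collected in ``.rejected`` with a
    reason, not raised.  Duplicate ids and unparseable files raise
    :class:`PeptideError`.
    """
    path = Path(path)
    if not path.exists():
        raise PeptideError(f"no such file: {path}")
    records: list[tuple[str, str, int]] = []
    if format == "fasta":
        try:
            for rec in SeqIO.parse(str(path), "fasta"):
                header = rec.id
                if "|" not in header:
                    raise PeptideError(f"{header}: FASTA header lacks '|label' suffix")
                pid, _, lab = header.rpartition("|")
                records.append((pid, str(rec.seq), _parse_label(lab, pid)))
        except PeptideError:
            raise
        except Exception as exc:  # malformed FASTA
            raise PeptideError(f"unparseable FASTA {path}: {exc}") from exc
    elif format == "tsv":
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) == 2:
                seq, lab = parts
                pid = f"pep{lineno}"
            elif len(parts) == 3:
                pid, seq, lab = parts
            else:
                raise PeptideError(f"{path}:{lineno}: expected 2 or 3 tab-separated fields")
            records.append((pid, seq.strip(), _parse_label(lab, f"{path}:{lineno}")))
    else:
        raise PeptideError(f"unknown format {format!r} (expected 'fasta' or 'tsv')")
    return _build(records)


def write_peptides(data: LabeledPeptideSet, path: str | Path, format: str = "fasta") -> None:
    """Write a labeled set in a form :func:`read_peptides` round-trips."""
    path = Path(path)
    lines: list[str] = []
    if format == "fasta":
        for pep, lab in data:
            lines.append(f">{pep.id}|{lab}")
            lines.append(pep.sequence)
    elif format == "tsv":
        for pep, lab in data:
            lines.append(f"{pep.id}\t{pep.sequence}\t{lab}")
    else:
        raise PeptideError(f"unknown format {format!r}")
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def write_rejected_manifest(data: LabeledPeptideSet, path: str | Path) -> None:
    lines = ["id\tsequence\treason"]
    lines += [f"{r.id}\t{r.sequence}\t{r.reason}" for r in data.rejected]
    Path(path).write_text("\n".join(lines) + "\n")


def stratified_split(
    data: LabeledPeptideSet, test_fraction: float, seed: int
) -> tuple[LabeledPeptideSet, LabeledPeptideSet]:
    """Per-class random split into (train, test).

    The test partition receives ``round(class_count * test_fraction)`` members
    of each class; the two partitions are disjoint and exhaustive, and the
    assignment is reproducible for a fixed seed.
    """
    if not 0.0 < test_fraction < 1.0:
        raise PeptideError("test_fraction must be in (0, 1)")
    y = data.y
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for cls in (0, 1):
        members = np.flatnonzero(y == cls)
        if len(members) < 2:
            raise PeptideError(f"class {cls} has fewer than 2 members; cannot split")
        n_test = int(round(len(members) * test_fraction))
        n_test = min(max(n_test, 0), len(members))
        chosen = rng.permutation(members)[:n_test]
        test_idx.extend(int(i) for i in chosen)
    test_set = set(test_idx)
    train_idx = [i for i in range(len(data)) if i not in test_set]
    test_idx = sorted(test_idx)
    return data.subset(train_idx), data.subset(test_idx)
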