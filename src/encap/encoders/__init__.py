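"""Encoder registry: named feature families, schemas and matrix encoding.

The default registry comprises 57 feature types totalling 4349 numeric
values per peptide: compositional families (AAC, DPC, DDE, CTriad, GAAC,
GDPC, gap-resolved CKSAAP/CKSAAGP), CTD descriptors, sequence-order
families (APAAC, QSO), repeat/entropy descriptors (DDR, RRI, SER, SEP),
ten scalar global properties, multidimensional residue-scale summaries
(MSW, Z3, Z5, Ez, Cougar, ABHPRK) and 14 overlapping property-class
fractions (OVPC).  Every family declares its output size up front; no
encoder has data-dependent dimensionality.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from ..peptides import LabeledPeptideSet, Peptide
from ..tables import AMINO_ACIDS
from . import compositional as comp
from . import ctd as ctdmod
from . import physicochem as phys
from . import repeats as rep
from .order import apaac, apaac_names, qso, qso_names


class EncoderError(ValueError):
    """Raised for length violations or registry misconfiguration."""


@dataclass(frozen=True)
class EncoderSpec:
    """A named feature family with fixed parameters and declared size."""

    name: str
    params: dict = field(default_factory=dict, hash=False)
    size: int = 0
    min_length: int = 1
    _encode: Callable[[str], np.ndarray] = field(default=None, repr=False, hash=False)
    _names: tuple[str, ...] = field(default=(), repr=False, hash=False)

    def encode(self, p: Peptide | str) -> np.ndarray:
        seq = p.sequence if isinstance(p, Peptide) else p
        if len(seq) < self.min_length:
            raise EncoderError(
                f"encoder {self.name} requires length >= {self.min_length}, "
                f"got {len(seq)}"
            )
        v = self._encode(seq)
        if v.shape != (self.size,):
            raise EncoderError(
                f"encoder {self.name} emitted {v.shape[0]} values, declared {self.size}"
            )
        return v

    @property
    def feature_names(self) -> list[str]:
        return list(self._names)


def _spec(name, fn, names, min_length=1, params=None) -> EncoderSpec:
    names = list(names)
    return EncoderSpec(
        name=name,
        params=params or {},
        size=len(names),
        min_length=min_length,
        _encode=fn,
        _names=tuple(names),
    )


def make_encoder(name: str, **params) -> EncoderSpec:
    """Instantiate a single encoder family by name.

    Parameterized families: ``CKSAAP``/``CKSAAGP`` (``gap``), ``APAAC``
    (``lam``, ``weight``), ``QSO`` (``nlag``, ``weight``), scale
    descriptors (``stats`` = 10 or 15).
    """
    aa = AMINO_ACIDS
    if name == "AAC":
        return _spec("AAC", comp.aac, [f"AAC_{a}" for a in aa])
    if name == "DPC":
        return _spec("DPC", comp.dpc, [f"DPC_{d}" for d in comp.DIPEPTIDES], 2)
    if name == "DDE":
        return _spec("DDE", comp.dde, [f"DDE_{d}" for d in comp.DIPEPTIDES], 2)
    if name == "GAAC":
        return _spec("GAAC", comp.gaac, [f"GAAC_{g}" for g in comp._GROUP_NAMES])
    if name == "GDPC":
        return _spec("GDPC", comp.gdpc, [f"GDPC_{g}" for g in comp.GROUP_PAIRS], 2)
    if name == "CTriad":
        return _spec("CTriad", comp.ctriad, comp.triad_names(), 3)
    if name == "CKSAAP":
        gap = int(params.get("gap", 0))
        return _spec(
            f"CKSAAP_gap{gap}",
            lambda s, g=gap: comp.cksaap(s, g),
            [f"CKSAAP_gap{gap}_{d}" for d in comp.DIPEPTIDES],
            gap + 2,
            {"gap": gap},
        )
    if name == "CKSAAGP":
        gap = int(params.get("gap", 0))
        return _spec(
            f"CKSAAGP_gap{gap}",
            lambda s, g=gap: comp.cksaagp(s, g),
            [f"CKSAAGP_gap{gap}_{d}" for d in comp.GROUP_PAIRS],
            gap + 2,
            {"gap": gap},
        )
    if name == "CTDC":
        return _spec("CTDC", ctdmod.ctdc, ctdmod.ctdc_names())
    if name == "CTDT":
        return _spec("CTDT", ctdmod.ctdt, ctdmod.ctdt_names(), 2)
    if name == "CTDD":
        return _spec("CTDD", ctdmod.ctdd, ctdmod.ctdd_names())
    if name == "APAAC":
        lam = int(params.get("lam", 3))
        w = float(params.get("weight", 0.05))
        return _spec(
            "APAAC",
            lambda s: apaac(s, lam, w),
            apaac_names(lam),
            lam + 1,
            {"lam": lam, "weight": w},
        )
    if name == "QSO":
        nlag = int(params.get("nlag", 3))
        w = float(params.get("weight", 0.1))
        return _spec(
            "QSO",
            lambda s: qso(s, nlag, w),
            qso_names(nlag),
            nlag + 1,
            {"nlag": nlag, "weight": w},
        )
    if name == "DDR":
        return _spec("DDR", rep.ddr, rep.DDR_NAMES)
    if name == "RRI":
        return _spec("RRI", rep.rri, rep.RRI_NAMES)
    if name == "SER":
        return _spec("SER", rep.ser, rep.SER_NAMES)
    if name == "SEP":
        return _spec("SEP", rep.sep, rep.SEP_NAMES)
    if name == "Globals":
        return _spec(
            "Globals",
            phys.global_properties,
            [f"global_{n}" for n in phys.GLOBAL_NAMES],
            2,
        )
    if name in ("MSW", "Z3", "Z5", "Ez", "Cougar"):
        stats = int(params.get("stats", 15 if name == "Z5" else 10))
        return _spec(
            name,
            lambda s, n=name, k=stats: phys.scale_descriptor(s, n, k),
            phys.scale_descriptor_names(name, stats),
            3 if stats == 15 else 1,
            {"stats": stats},
        )
    if name == "ABHPRK":
        return _spec("ABHPRK", phys.abhprk, phys.ABHPRK_NAMES)
    if name == "OVPC":
        return _spec("OVPC", phys.ovpc, phys.OVPC_NAMES)
    if name.startswith("global_"):
        prop = name.split("_", 1)[1]
        if prop not in phys.GLOBAL_NAMES:
            raise EncoderError(f"unknown global descriptor {prop!r}")
        i = phys.GLOBAL_NAMES.index(prop)
        return _spec(name, lambda s, i=i: _cached_globals(s)[i : i + 1], [name], 2)
    if name.startswith("OVPC_"):
        cls = name.split("_", 1)[1]
        from ..tables import OVPC_CLASSES

        if cls not in OVPC_CLASSES:
            raise EncoderError(f"unknown OVPC class {cls!r}")
        members = OVPC_CLASSES[cls]
        return _spec(
            name,
            lambda s, m=members: np.array([sum(c in m for c in s) / len(s)]),
            [name],
        )
    raise EncoderError(f"unknown encoder family {name!r}")


def rebuild_registry(config: list[dict]) -> list[EncoderSpec]:
    """Rebuild a registry from ``[{"name": ..., "params": {...}}, ...]``
    (the serialized form used by saved model bundles)."""
    specs: list[EncoderSpec] = []
    for entry in config:
        name, params = entry["name"], dict(entry.get("params") or {})
        for base in ("CKSAAP", "CKSAAGP"):
            if name.startswith(base + "_gap"):
                name = base
        specs.append(make_encoder(name, **params))
    return specs


from functools import lru_cache


@lru_cache(maxsize=4096)
def _cached_globals(seq: str) -> np.ndarray:
    return phys.global_properties(seq)


def default_registry() -> list[EncoderSpec]:
    """The full 57-type registry (4349 features per peptide).

    CKSAAP and CKSAAGP are gap-resolved (gaps 0-5), each gap its own type;
    each OVPC class is its own single-value type.  Minimum peptide length
    under the full registry is 7 (CKSAAP at gap 5).
    """
    from ..tables import OVPC_CLASSES

    specs: list[EncoderSpec] = [
        make_encoder("AAC"),
        make_encoder("DPC"),
        make_encoder("DDE"),
        make_encoder("CTriad"),
        make_encoder("GAAC"),
        make_encoder("GDPC"),
    ]
    specs += [make_encoder("CKSAAP", gap=g) for g in range(6)]
    specs += [make_encoder("CKSAAGP", gap=g) for g in range(6)]
    specs += [make_encoder(n) for n in ("CTDC", "CTDT", "CTDD")]
    specs += [make_encoder("APAAC", lam=3), make_encoder("QSO", nlag=3)]
    specs += [make_encoder(n) for n in ("DDR", "RRI", "SER", "SEP")]
    # ten scalar globals, each registered as its own single-value type
    for i, n in enumerate(phys.GLOBAL_NAMES):
        specs.append(
            _spec(
                f"global_{n}",
                lambda s, i=i: _cached_globals(s)[i : i + 1],
                [f"global_{n}"],
                2,
            )
        )
    specs += [
        make_encoder("MSW"),
        make_encoder("Z3"),
        make_encoder("Z5"),
        make_encoder("Ez"),
        make_encoder("Cougar"),
        make_encoder("ABHPRK"),
    ]
    specs += [make_encoder(f"OVPC_{cls}") for cls in OVPC_CLASSES]
    return specs


@dataclass
class FeatureSchema:
    """Ordered registry of (feature name, source encoder) pairs."""

    specs: list[EncoderSpec]

    def __post_init__(self) -> None:
        names = self.names
        if len(set(names)) != len(names):
            raise EncoderError("duplicate feature names across registry")

    @property
    def names(self) -> list[str]:
        return [n for spec in self.specs for n in spec.feature_names]

    def __len__(self) -> int:
        return sum(spec.size for spec in self.specs)

    @property
    def min_length(self) -> int:
        return max(spec.min_length for spec in self.specs)

    def fingerprint(self) -> str:
        import hashlib

        h = hashlib.sha256("\n".join(self.names).encode())
        return h.hexdigest()[:16]

    def to_json(self) -> str:
        return json.dumps(
            [
                {"name": s.name, "params": s.params, "size": s.size}
                for s in self.specs
            ],
            indent=1,
        )


@dataclass
class FeatureMatrix:
    """Peptides x features numeric grid with row ids and a schema."""

    schema: FeatureSchema
    values: np.ndarray
    row_ids: list[str]

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.row_ids), len(self.schema)):
            raise EncoderError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.row_ids)} rows x {len(self.schema)} features"
            )
        if not np.all(np.isfinite(self.values)):
            raise EncoderError("non-finite values in feature matrix")

    @property
    def columns(self) -> list[str]:
        return self.schema.names

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.columns)

    def select(self, feature_names: list[str]) -> "FeatureMatrix":
        """Column-subset matrix; the reduced schema is a single pass-through
        block preserving the requested order."""
        col_index = {n: i for i, n in enumerate(self.columns)}
        missing = [n for n in feature_names if n not in col_index]
        if missing:
            raise EncoderError(f"unknown features requested: {missing[:5]}")
        idx = [col_index[n] for n in feature_names]
        sub = _spec("subset", lambda s: None, feature_names)
        return FeatureMatrix(FeatureSchema([sub]), self.values[:, idx], list(self.row_ids))

    def save_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="id", float_format="%.10g")

    @staticmethod
    def load_tsv(path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col="id")
        sub = _spec("loaded", lambda s: None, list(df.columns))
        return FeatureMatrix(
            FeatureSchema([sub]), df.to_numpy(float), [str(i) for i in df.index]
        )


def encode_peptide(p: Peptide | str, registry: list[EncoderSpec]) -> np.ndarray:
    return np.concatenate([spec.encode(p) for spec in registry])


def encode_all(data: LabeledPeptideSet, registry: list[EncoderSpec]) -> FeatureMatrix:
    """Encode every peptide under every registered family.

    Any encoder failure aborts with the peptide id and encoder name; rows
    keep input order and columns follow registry order.
    """
    schema = FeatureSchema(registry)
    rows = np.empty((len(data), len(schema)))
    for ri, pep in enumerate(data.peptides):
        off = 0
        for spec in registry:
            try:
                rows[ri, off : off + spec.size] = spec.encode(pep)
            except Exception as exc:
                raise EncoderError(f"peptide {pep.id!r}, encoder {spec.name}: {exc}") from exc
            off += spec.size
    return FeatureMatrix(schema, rows, data.ids)


__all__ = [
    "EncoderError",
    "EncoderSpec",
    "FeatureSchema",
    "FeatureMatrix",
    "make_encoder",
    "default_registry",
    "encode_all",
    "encode_peptide",
]
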