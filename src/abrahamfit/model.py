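"""The Abraham solvation parameter model.

The model expresses a log10 partition coefficient of a solute between two
phases as a linear free-energy relationship over solute descriptors::

    log Ps = c + e*E + s*S + a*A + b*B + v*V      (water -> solvent)
    log Ks = c + e*E + s*S + a*A + b*B + l*L      (gas -> solvent)

E is the excess molar refractivity ((cm^3/mol)/10), S the
dipolarity/polarizability, A and B the hydrogen-bond acidity and basicity,
V the McGowan characteristic volume ((cm^3/mol)/100) and L the log10
gas-hexadecane partition coefficient at 298 K.  The lowercase coefficients
characterise the solvent system (the "process").  Two bridging identities
connect partitions to saturation solubilities and gas-phase partitions:
``Ps = Cs/Cw`` and ``Ps = Ks/Kw``.  All logarithms are base 10.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .exceptions import IncompleteDescriptorsError, MalformedCoefficientsError

__all__ = [
    "DESCRIPTOR_NAMES",
    "PROCESS_KINDS",
    "SoluteDescriptors",
    "ProcessCoefficients",
    "SolventInfo",
    "CoefficientTable",
    "predict_log_partition",
    "log_p_from_solubility",
    "log_k_from_log_p",
]

#: Descriptor fields in canonical order (solute-level unknowns included).
DESCRIPTOR_NAMES = ("E", "S", "A", "B", "V", "L", "log_kw", "log_cw")

PROCESS_KINDS = (
    "water_to_solvent",
    "gas_to_solvent",
    "gas_to_water_V",
    "gas_to_water_L",
    "auxiliary",
)

# Which descriptor multiplies which coefficient, per process kind.
_V_KINDS = frozenset({"water_to_solvent", "gas_to_water_V"})
_L_KINDS = frozenset({"gas_to_solvent", "gas_to_water_L"})


@dataclass(frozen=True)
class SoluteDescriptors:
    """The solute descriptor vector plus solute-level unknowns.

    Unset fields are ``None`` ("absent"); set fields are "fixed" if listed
    in :attr:`fixed`, otherwise "free".  A field can therefore never be
    simultaneously fixed and free, and a fixed field must carry a value.
    """

    E: float | None = None
    S: float | None = None
    A: float | None = None
    B: float | None = None
    V: float | None = None
    L: float | None = None
    log_kw: float | None = None
    log_cw: float | None = None
    fixed: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        unknown = set(self.fixed) - set(DESCRIPTOR_NAMES)
        if unknown:
            raise ValueError(f"unknown descriptor names in 'fixed': {sorted(unknown)}")
        for name in self.fixed:
            if getattr(self, name) is None:
                raise ValueError(f"descriptor {name} flagged fixed but has no value")
        if self.V is not None and self.V <= 0:
            raise ValueError(f"McGowan volume must be positive, got V={self.V}")

    def status(self, name: str) -> str:
        value = getattr(self, name)
        if value is None:
            return "absent"
        return "fixed" if name in self.fixed else "free"

    def require(self, *names: str) -> None:
        missing = [n for n in names if getattr(self, n) is None]
        if missing:
            raise IncompleteDescriptorsError(
                f"incomplete descriptors: missing {', '.join(missing)}"
            )

    def replace(self, **changes) -> "SoluteDescriptors":
        return replace(self, **changes)

    # -- flat JSON I/O: one key per descriptor plus a "fixed" list ---------
    def to_dict(self) -> dict:
        out = {n: getattr(self, n) for n in DESCRIPTOR_NAMES if getattr(self, n) is not None}
        out["fixed"] = sorted(self.fixed)
        return out

    @classmethod
    def from_dict(cls, data: Mapping) -> "SoluteDescriptors":
        values = {k: float(v) for k, v in data.items() if k in DESCRIPTOR_NAMES}
        return cls(**values, fixed=frozenset(data.get("fixed", ())))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SoluteDescriptors":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class ProcessCoefficients:
    """One solvent system's equation coefficients.

    ``v`` is active for the V-form processes (water_to_solvent,
    gas_to_water_V), ``l`` for the L-form ones (gas_to_solvent,
    gas_to_water_L); an ``auxiliary`` record may use any subset.  ``None``
    marks an inactive term.
    """

    system_id: str
    process_kind: str
    c: float = 0.0
    e: float = 0.0
    s: float = 0.0
    a: float = 0.0
    b: float = 0.0
    v: float | None = None
    l: float | None = None

    def __post_init__(self) -> None:
        if self.process_kind not in PROCESS_KINDS:
            raise MalformedCoefficientsError(
                f"{self.system_id}: unknown process_kind {self.process_kind!r}"
            )
        if self.process_kind == "auxiliary":
            return
        if self.v is not None and self.l is not None:
            raise MalformedCoefficientsError(
                f"malformed coefficients for {self.system_id}: both v and l active"
            )
        if self.process_kind in _V_KINDS and self.v is None:
            raise MalformedCoefficientsError(
                f"{self.system_id} ({self.process_kind}): v coefficient required"
            )
        if self.process_kind in _L_KINDS and self.l is None:
            raise MalformedCoefficientsError(
                f"{self.system_id} ({self.process_kind}): l coefficient required"
            )

    def active_terms(self) -> dict[str, float]:
        """Map descriptor name -> coefficient for every active term.

        The intercept is not included.  A water->solvent record never
        references L, and a gas->solvent record never references V.
        """
        terms = {"E": self.e, "S": self.s, "A": self.a, "B": self.b}
        if self.process_kind == "auxiliary":
            if self.v is not None:
                terms["V"] = self.v
            if self.l is not None:
                terms["L"] = self.l
        elif self.process_kind in _V_KINDS:
            terms["V"] = self.v
        else:
            terms["L"] = self.l
        return terms


@dataclass(frozen=True)
class SolventInfo:
    """Solvent metadata used for classification and unit conversion."""

    name: str
    beta: float | None = None
    density: float | None = None  # g/cm^3 at 298 K
    molar_mass: float | None = None  # g/mol
    has_coefficients: bool = False

    def __post_init__(self) -> None:
        if self.beta is not None and not (0.0 <= self.beta <= 1.2):
            raise ValueError(f"{self.name}: Kamlet-Taft beta {self.beta} outside [0, 1.2]")
        if self.density is not None and self.density <= 0:
            raise ValueError(f"{self.name}: density must be positive")


class CoefficientTable:
    """Collection of :class:`ProcessCoefficients`, unique per (system, kind)."""

    def __init__(self, records: Iterable[ProcessCoefficients]):
        self._by_key: dict[tuple[str, str], ProcessCoefficients] = {}
        for rec in records:
            key = (rec.system_id, rec.process_kind)
            if key in self._by_key:
                raise MalformedCoefficientsError(
                    f"duplicate coefficient record for {rec.system_id!r} / {rec.process_kind}"
                )
            self._by_key[key] = rec

    def __len__(self) -> int:
        return len(self._by_key)

    def __iter__(self) -> Iterator[ProcessCoefficients]:
        return iter(self._by_key.values())

    def get(self, system_id: str, process_kind: str) -> ProcessCoefficients:
        try:
            return self._by_key[(system_id, process_kind)]
        except KeyError:
            raise KeyError(f"no {process_kind} coefficients for {system_id!r}") from None

    def has(self, system_id: str, process_kind: str) -> bool:
        return (system_id, process_kind) in self._by_key

    def has_solvent_pair(self, system_id: str) -> bool:
        """Both equation forms available (needed to fit a solvent)."""
        return self.has(system_id, "water_to_solvent") and self.has(system_id, "gas_to_solvent")

    def systems(self, process_kind: str) -> list[str]:
        return [s for (s, k) in self._by_key if k == process_kind]

    def closures(self) -> list[ProcessCoefficients]:
        """The gas->water records constraining log Kw."""
        return [r for r in self if r.process_kind in ("gas_to_water_V", "gas_to_water_L")]

    # -- CSV I/O: header system_id,process_kind,c,e,s,a,b,v,l --------------
    @classmethod
    def from_csv(cls, path: str | Path) -> "CoefficientTable":
        df = pd.read_csv(path, comment="#")
        records = []
        for row in df.itertuples(index=False):
            records.append(
                ProcessCoefficients(
                    system_id=row.system_id,
                    process_kind=row.process_kind,
                    c=float(row.c),
                    e=float(row.e),
                    s=float(row.s),
                    a=float(row.a),
                    b=float(row.b),
                    v=None if pd.isna(row.v) else float(row.v),
                    l=None if pd.isna(row.l) else float(row.l),
                )
            )
        return cls(records)

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {f.name: getattr(rec, f.name) for f in fields(ProcessCoefficients)}
            for rec in self
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def predict_log_partition(desc: SoluteDescriptors, coeffs: ProcessCoefficients) -> float:
    """Evaluate the LFER for one solvent system.

    Returns ``c + e*E + s*S + a*A + b*B + v*V`` for V-form processes or
    ``c + e*E + s*S + a*A + b*B + l*L`` for L-form ones.  Only the
    descriptors actually referenced by the record's active terms are read,
    so e.g. L may be absent when evaluating a water->solvent record.
    """
    terms = coeffs.active_terms()
    desc.require(*terms)
    return coeffs.c + sum(coef * getattr(desc, name) for name, coef in terms.items())


def log_p_from_solubility(log_cs: float, log_cw: float) -> float:
    """log10 water->solvent partition from saturation solubilities, Ps = Cs/Cw."""
    if not (math.isfinite(log_cs) and math.isfinite(log_cw)):
        raise ValueError("log solubilities must be finite")
    return log_cs - log_cw


def log_k_from_log_p(log_ps: float, log_kw: float) -> float:
    """log10 gas->solvent partition from Ps = Ks/Kw."""
    if not (math.isfinite(log_ps) and math.isfinite(log_kw)):
        raise ValueError("log partitions must be finite")
    return log_ps + log_kw
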