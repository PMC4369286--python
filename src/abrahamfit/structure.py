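"""Structure-derived descriptors: McGowan volume and fragment-based E.

V follows the McGowan atomic-contribution scheme: sum tabulated atomic
volumes and subtract 6.56 cm^3/mol per bond, with bonds counted as
``atoms - 1 + rings``; the result is reported in (cm^3/mol)/100.  Ring
count is explicit user input (no perception from connectivity); for a
hydrogen-bonded carboxylic acid dimer treated as one unit, the ring closed
by the two hydrogen bonds counts as one ring and its hydrogen bonds as two
bonds.

E (excess molar refractivity) is estimated by fragment arithmetic: carry a
known analog's E across a structural substitution whose E increment is
known from a reference pair, and relate monomer to hydrogen-bonded dimer by
an empirical affine law calibrated on liquid aromatic carboxylic acids.
That dimer relation is specific to carboxylic acids; applying it to other
solute classes is not supported.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import pandas as pd

from .exceptions import EmptyMoleculeError, UnknownElementError

__all__ = [
    "BOND_DEDUCTION",
    "MolecularComposition",
    "parse_formula",
    "atomic_volumes",
    "mcgowan_volume",
    "e_by_fragment_offset",
    "e_dimer_from_monomer",
]

#: McGowan per-bond volume deduction, cm^3/mol.
BOND_DEDUCTION = 6.56

#: Affine monomer -> dimer relation for E, calibrated on aromatic acids.
E_DIMER_INTERCEPT = -0.418
E_DIMER_SLOPE = 1.839

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@lru_cache(maxsize=1)
def atomic_volumes() -> dict[str, float]:
    """McGowan atomic volumes (cm^3/mol) from the bundled fixture."""
    path = resources.files("abrahamfit.data") / "mcgowan_volumes.csv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p, comment="#")
    return dict(zip(df["element"], df["volume_cm3_per_mol"]))


@dataclass(frozen=True)
class MolecularComposition:
    """Element counts plus an explicit ring count."""

    element_counts: dict[str, int] = field(default_factory=dict)
    ring_count: int = 0

    def __post_init__(self) -> None:
        for el, n in self.element_counts.items():
            if n < 0 or n != int(n):
                raise ValueError(f"element count for {el} must be a non-negative integer")
        if self.ring_count < 0:
            raise ValueError("ring_count must be non-negative")
        if self.atom_count > 0 and self.bond_count < 0:
            raise ValueError("inconsistent composition: negative bond count")

    @property
    def atom_count(self) -> int:
        return sum(self.element_counts.values())

    @property
    def bond_count(self) -> int:
        return self.atom_count - 1 + self.ring_count


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-notation molecular formula like ``C9H8O2``."""
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        pos = match.end()
        element, digits = match.groups()
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
    if pos != len(formula) or not counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def mcgowan_volume(
    composition: MolecularComposition | str | dict[str, int],
    rings: int | None = None,
) -> float:
    """McGowan characteristic volume V in (cm^3/mol)/100.

    ``composition`` may be a :class:`MolecularComposition`, a formula
    string, or an element-count map; in the latter two cases ``rings``
    supplies the ring count (default 0).
    """
    if isinstance(composition, str):
        composition = MolecularComposition(parse_formula(composition), rings or 0)
    elif isinstance(composition, dict):
        composition = MolecularComposition(dict(composition), rings or 0)
    elif rings is not None and rings != composition.ring_count:
        raise ValueError("rings argument conflicts with composition.ring_count")

    if composition.atom_count == 0:
        raise EmptyMoleculeError("empty molecule: no atoms to sum")
    table = atomic_volumes()
    total = 0.0
    for element, count in composition.element_counts.items():
        if element not in table:
            raise UnknownElementError(f"no atomic volume for element {element!r}")
        total += count * table[element]
    return (total - BOND_DEDUCTION * composition.bond_count) / 100.0


def e_by_fragment_offset(
    target_analog_e: float, reference_pair: tuple[float, float]
) -> float:
    """Carry a known structural E increment onto an analog.

    ``reference_pair = (E_with, E_without)`` is a pair of compounds
    differing by exactly the substitution separating the target from its
    analog; the same difference is added to the analog's E.  Returned at
    full precision; report rounded to hundredths.
    """
    e_with, e_without = reference_pair
    for x in (target_analog_e, e_with, e_without):
        if not math.isfinite(x):
            raise ValueError("E values must be finite")
    return target_analog_e + (e_with - e_without)


def e_dimer_from_monomer(e_monomer: float) -> float:
    """E of the hydrogen-bonded carboxylic acid dimer from the monomer's E."""
    if not math.isfinite(e_monomer):
        raise ValueError("E must be finite")
    return E_DIMER_INTERCEPT + E_DIMER_SLOPE * e_monomer
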