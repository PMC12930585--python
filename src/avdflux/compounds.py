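"""Compound registry and unit conversions.

Every quantitative step in the pipeline — molar yields, selectivity,
isotope mass shifts, MID correction formulas — needs elemental formulas
and molar masses for the tracked metabolites of the 5-aminovaleramide
(5-AVD) production network.  This module holds a small registry of those
compounds (5-AVD, 5-aminovalerate, glutarate, lysine, sugars, central
intermediates) and the mass/molar interconversions used throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "CompoundSpec",
    "ATOMIC_WEIGHTS",
    "parse_formula",
    "get_compound",
    "register_compound",
    "convert_concentration",
    "intracellular_concentration",
    "CYTOPLASM_VOLUME_FACTOR",
]

#: Standard atomic weights (IUPAC 2021 abridged), g/mol.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "Si": 28.085,
}

#: Cytoplasm volume per cell dry weight for C. glutamicum, uL/mg_CDW.
CYTOPLASM_VOLUME_FACTOR = 1.95

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental formula string like ``C5H12N2O`` into counts."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise ValueError(f"malformed formula {formula!r}")
        pos = m.end()
        el, n = m.group(1), m.group(2)
        if el not in ATOMIC_WEIGHTS:
            raise KeyError(f"unknown element {el!r} in formula {formula!r}")
        counts[el] = counts.get(el, 0) + (int(n) if n else 1)
    if pos != len(formula) or not counts:
        raise ValueError(f"malformed formula {formula!r}")
    return counts


@dataclass(frozen=True)
class CompoundSpec:
    """A tracked metabolite: name, elemental formula and derived quantities."""

    name: str
    formula: dict[str, int]
    aliases: tuple[str, ...] = field(default_factory=tuple)

    @classmethod
    def from_string(cls, name: str, formula: str, aliases: tuple[str, ...] = ()) -> "CompoundSpec":
        return cls(name=name, formula=parse_formula(formula), aliases=aliases)

    @property
    def molar_mass(self) -> float:
        """Molar mass in g/mol from standard atomic weights."""
        return sum(ATOMIC_WEIGHTS[el] * n for el, n in self.formula.items())

    @property
    def n_carbon(self) -> int:
        return self.formula.get("C", 0)

    @property
    def n_nitrogen(self) -> int:
        return self.formula.get("N", 0)


def _build_registry() -> dict[str, CompoundSpec]:
    specs = [
        CompoundSpec.from_string("5-AVD", "C5H12N2O", ("5-aminovaleramide", "5-aminopentanamide", "AVD")),
        CompoundSpec.from_string("5-AVA", "C5H11NO2", ("5-aminovalerate", "AVA")),
        CompoundSpec.from_string("GTA", "C5H8O4", ("glutarate",)),
        CompoundSpec.from_string("lysine", "C6H14N2O2", ("LYS", "l-lysine")),
        CompoundSpec.from_string("DAP", "C7H14N2O4", ("diaminopimelate",)),
        CompoundSpec.from_string("diaminopentane", "C5H14N2", ("cadaverine",)),
        CompoundSpec.from_string("glucose", "C6H12O6", ("GLC",)),
        CompoundSpec.from_string("fructose", "C6H12O6", ("FRU",)),
        CompoundSpec.from_string("sucrose", "C12H22O11", ("SUC",)),
        CompoundSpec.from_string("glutamate", "C5H9NO4", ("GLU", "l-glutamate")),
        CompoundSpec.from_string("alanine", "C3H7NO2", ("ALA",)),
        CompoundSpec.from_string("serine", "C3H7NO3", ("SER",)),
        CompoundSpec.from_string("aspartate", "C4H7NO4", ("ASP",)),
        CompoundSpec.from_string("trehalose", "C12H22O11", ("TRE",)),
    ]
    reg: dict[str, CompoundSpec] = {}
    for spec in specs:
        reg[spec.name.lower()] = spec
        for alias in spec.aliases:
            reg[alias.lower()] = spec
    return reg


_REGISTRY = _build_registry()


def get_compound(name: str) -> CompoundSpec:
    """Look up a compound by name or alias (case-insensitive)."""
    try:
        return _REGISTRY[name.lower()]
    except KeyError:
        raise KeyError(f"unknown compound {name!r}") from None


def register_compound(spec: CompoundSpec) -> None:
    """Add a compound (and its aliases) to the registry."""
    _REGISTRY[spec.name.lower()] = spec
    for alias in spec.aliases:
        _REGISTRY[alias.lower()] = spec


def convert_concentration(compound: CompoundSpec | str, value: float, direction: str) -> float:
    """Convert between mass and molar concentration.

    Parameters
    ----------
    compound : CompoundSpec or registered name
    value : concentration, mM (``to_mass``) or g/L (``to_molar``)
    direction : ``"to_mass"`` (mM -> g/L) or ``"to_molar"`` (g/L -> mM)

    1 mM of a compound with molar mass M corresponds to M mg/L, i.e.
    M/1000 g/L (for 5-AVD: 1 mM = 116 mg/L).
    """
    if isinstance(compound, str):
        compound = get_compound(compound)
    if value < 0:
        raise ValueError(f"concentration must be >= 0, got {value}")
    if direction == "to_mass":
        return value * compound.molar_mass / 1000.0
    if direction == "to_molar":
        return value * 1000.0 / compound.molar_mass
    raise ValueError(f"direction must be 'to_mass' or 'to_molar', got {direction!r}")


def intracellular_concentration(amount_umol_per_g: float, volume_factor: float = CYTOPLASM_VOLUME_FACTOR) -> float:
    """Convert an intracellular pool (umol/g_CDW) to cytoplasmic mM.

    Uses the cytoplasm volume factor (uL/mg_CDW); the units cancel to
    mmol/L directly: umol/g divided by uL/mg is mM.
    """
    if volume_factor <= 0:
        raise ValueError(f"volume factor must be > 0, got {volume_factor}")
    if amount_umol_per_g < 0:
        raise ValueError(f"pool amount must be >= 0, got {amount_umol_per_g}")
    return amount_umol_per_g / volume_factor
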