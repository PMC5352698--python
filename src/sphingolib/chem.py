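"""Elemental formula arithmetic, monoisotopic masses, and adduct/ion m/z.

All m/z values in the package are computed here from a single frozen table of
monoisotopic masses.  Ion m/z follows the convention

    mz = (mass(M) + dH * mass(H) - z * mass(e-)) / |z|

where ``M`` is the neutralised (hydrogen-supplemented) fragment or molecule,
``dH`` the signed count of rearranged hydrogens and ``z`` the signed charge.
The electron-mass correction is applied by default; it can be switched off
per call for instruments/conventions that ignore it (the difference is
0.00055 Da per charge, below QTOF accuracy).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterator, Mapping

__all__ = [
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "ChemFormula",
    "Adduct",
    "IonMass",
    "ADDUCTS",
    "get_adduct",
    "load_adducts_yaml",
    "formula_mass",
    "ion_mz",
    "adduct_mz",
]

# IUPAC 2013 monoisotopic atomic masses (Da), >= 6 decimals.
MONOISOTOPIC_MASS: Mapping[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "S": 31.97207069,
    "Na": 22.98976928,
    "K": 38.96370649,
    "Cl": 34.96885268,
}

ELECTRON_MASS = 0.00054857990946
PROTON_MASS = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for unknown elements or negative element counts."""


@dataclass(frozen=True)
class ChemFormula:
    """An elemental composition (element symbol -> non-negative count).

    Supports element-wise addition and subtraction; subtraction raises
    :class:`FormulaError` if any count would become negative.  Instances are
    immutable and hashable.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: Dict[str, int] = {}
        for element, n in self.counts.items():
            if element not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol: {element!r}")
            n = int(n)
            if n < 0:
                raise FormulaError(f"negative count for {element}: {n}")
            if n > 0:
                clean[element] = n
        object.__setattr__(self, "counts", clean)

    @classmethod
    def parse(cls, text: str) -> "ChemFormula":
        """Parse a plain formula string such as ``'C16H32O3'``."""
        text = text.strip()
        counts: Dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(text):
            if match.start() != pos:
                raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
            symbol, digits = match.groups()
            if symbol not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol: {symbol!r} in {text!r}")
            counts[symbol] = counts.get(symbol, 0) + (int(digits) if digits else 1)
            pos = match.end()
        if pos != len(text):
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        return cls(counts)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other: "ChemFormula") -> "ChemFormula":
        counts = dict(self.counts)
        for element, n in other.counts.items():
            counts[element] = counts.get(element, 0) + n
        return ChemFormula(counts)

    def __sub__(self, other: "ChemFormula") -> "ChemFormula":
        counts = dict(self.counts)
        for element, n in other.counts.items():
            remaining = counts.get(element, 0) - n
            if remaining < 0:
                raise FormulaError(
                    f"subtraction would leave {remaining} {element} in "
                    f"{self} - {other}"
                )
            counts[element] = remaining
        return ChemFormula(counts)

    def __mul__(self, k: int) -> "ChemFormula":
        if k < 0:
            raise FormulaError("cannot multiply a formula by a negative integer")
        return ChemFormula({e: n * k for e, n in self.counts.items()})

    __rmul__ = __mul__

    def contains(self, other: "ChemFormula") -> bool:
        """True if ``other`` is an element-wise sub-formula of ``self``."""
        return all(self.counts.get(e, 0) >= n for e, n in other.counts.items())

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self.counts)

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __hash__(self) -> int:
        return hash(tuple(sorted(self.counts.items())))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ChemFormula):
            return NotImplemented
        return dict(self.counts) == dict(other.counts)

    @property
    def mass(self) -> float:
        """Monoisotopic mass in Da."""
        return sum(MONOISOTOPIC_MASS[e] * n for e, n in self.counts.items())

    def hill(self) -> str:
        """Hill-order formula string (C, H, then alphabetical)."""
        order = []
        if "C" in self.counts:
            order.append("C")
            if "H" in self.counts:
                order.append("H")
            order.extend(sorted(e for e in self.counts if e not in ("C", "H")))
        else:
            order = sorted(self.counts)
        return "".join(f"{e}{self.counts[e] if self.counts[e] != 1 else ''}" for e in order)

    def __str__(self) -> str:
        return self.hill() or "(empty)"

    def __repr__(self) -> str:
        return f"ChemFormula({self.hill()!r})"


def formula_mass(f: ChemFormula) -> float:
    """Monoisotopic mass of a formula in Da (0.0 for the empty formula)."""
    return f.mass


@dataclass(frozen=True)
class IonMass:
    """A computed ion m/z together with its provenance."""

    mz: float
    charge: int
    source_formula: ChemFormula
    hydrogen_delta: int

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"non-positive m/z: {self.mz}")


@dataclass(frozen=True)
class Adduct:
    """An ESI adduct: a signed formula delta applied to the neutral molecule.

    ``formula_delta`` maps element symbol to a signed count, e.g. ``{'H': -1}``
    for ``[M-H]-``.  All shipped adducts are singly charged.
    """

    name: str
    formula_delta: Mapping[str, int]
    charge: int
    polarity: str  # "positive" | "negative"

    def __post_init__(self) -> None:
        if abs(self.charge) != 1:
            raise ValueError(f"adduct {self.name}: only |charge| = 1 is supported")
        expected = "positive" if self.charge > 0 else "negative"
        if self.polarity != expected:
            raise ValueError(
                f"adduct {self.name}: polarity {self.polarity!r} inconsistent "
                f"with charge {self.charge:+d}"
            )

    @property
    def mass_delta(self) -> float:
        return sum(MONOISOTOPIC_MASS[e] * n for e, n in self.formula_delta.items())


ADDUCTS: Dict[str, Adduct] = {
    a.name: a
    for a in [
        Adduct("[M+H]+", {"H": 1}, +1, "positive"),
        Adduct("[M+NH4]+", {"N": 1, "H": 4}, +1, "positive"),
        Adduct("[M+Na]+", {"Na": 1}, +1, "positive"),
        Adduct("[M-H]-", {"H": -1}, -1, "negative"),
        Adduct("[M+HCOO]-", {"C": 1, "H": 1, "O": 2}, -1, "negative"),
        Adduct("[M+CH3COO]-", {"C": 2, "H": 3, "O": 2}, -1, "negative"),
    ]
}

# tolerated spelling variants (minus sign, spacing)
_ADDUCT_ALIASES = {
    "[M−H]-": "[M-H]-",
    "[M-H]−": "[M-H]-",
    "[M+CH3COO]−": "[M+CH3COO]-",
    "[M+HCOO]−": "[M+HCOO]-",
    "[M+FA-H]-": "[M+HCOO]-",
    "[M+Hac-H]-": "[M+CH3COO]-",
}


def get_adduct(name: str) -> Adduct:
    key = name.strip()
    key = _ADDUCT_ALIASES.get(key, key)
    if key not in ADDUCTS:
        supported = ", ".join(sorted(ADDUCTS))
        raise KeyError(f"unsupported adduct {name!r}; supported: {supported}")
    return ADDUCTS[key]


def load_adducts_yaml(path) -> Dict[str, Adduct]:
    """Load additional adduct definitions from a YAML file.

    Schema: a mapping of adduct name to ``{delta: {element: signed count},
    charge: int}``.  Returns a fresh registry (built-ins plus file entries);
    the module-level registry is never mutated.
    """
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    registry = dict(ADDUCTS)
    for name, entry in raw.items():
        charge = int(entry["charge"])
        registry[name] = Adduct(
            name=name,
            formula_delta=dict(entry["delta"]),
            charge=charge,
            polarity="positive" if charge > 0 else "negative",
        )
    return registry


def ion_mz(
    f: ChemFormula,
    hydrogen_delta: int,
    charge: int,
    *,
    electron_correction: bool = True,
) -> IonMass:
    """m/z of ``[M + dH * H]`` at the given signed charge.

    ``mz = (mass(f) + dH*m_H - z*m_e) / |z|``.  ``charge = 0`` is an error.
    """
    if charge == 0:
        raise ValueError("charge must be non-zero")
    hydrogens = f["H"] + hydrogen_delta
    if hydrogens < 0:
        raise FormulaError(
            f"{f} cannot lose {-hydrogen_delta} hydrogens (has {f['H']})"
        )
    mass = f.mass + hydrogen_delta * MONOISOTOPIC_MASS["H"]
    if electron_correction:
        mass -= charge * ELECTRON_MASS
    return IonMass(
        mz=mass / abs(charge),
        charge=charge,
        source_formula=f,
        hydrogen_delta=hydrogen_delta,
    )


def adduct_mz(
    neutral: ChemFormula,
    adduct: Adduct | str,
    *,
    electron_correction: bool = True,
) -> IonMass:
    """Precursor m/z of a neutral molecule under an ESI adduct."""
    if not neutral:
        raise ValueError("neutral formula must be non-empty")
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    mass = neutral.mass + adduct.mass_delta
    if electron_correction:
        mass -= adduct.charge * ELECTRON_MASS
    h_delta = adduct.formula_delta.get("H", 0)
    return IonMass(
        mz=mass / abs(adduct.charge),
        charge=adduct.charge,
        source_formula=neutral,
        hydrogen_delta=h_delta,
    )
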