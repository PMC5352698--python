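"""Sphingolipid classes, shorthand nomenclature and combinatorial enumeration.

A sphingolipid species is modelled from three building blocks: a sphingoid
base (dihydroxy ``d`` or trihydroxy ``t``), one N-acyl fatty acid (non-,
alpha-, beta-, or esterified omega-hydroxylated), and a head group (hydrogen
for ceramide, one hexose for HexCer, phosphocholine for SM).  Shorthand
follows the common convention ``Cer[AS] d18:1/16:0``; esterified
omega-hydroxy (EO) species carry a third chain, ``Cer[EOS] d18:1/30:0/18:2``
(base / omega-hydroxy fatty acid / esterified fatty acid).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import pandas as pd
import yaml

from .chem import ChemFormula

__all__ = [
    "SphingoidBase",
    "AcylChain",
    "LipidSpecies",
    "ClassDefinition",
    "CLASS_TABLE",
    "ClassRanges",
    "EnumerationConfig",
    "parse_name",
    "format_name",
    "species_formula",
    "enumerate_class",
    "build_manifest",
    "reference_manifest",
    "default_ranges",
]

H2O = ChemFormula({"H": 2, "O": 1})
HEXOSE_RESIDUE = ChemFormula({"C": 6, "H": 10, "O": 5})  # hexose - H2O
PHOSPHOCHOLINE_RESIDUE = ChemFormula({"C": 5, "H": 12, "N": 1, "O": 3, "P": 1})


class NameParseError(ValueError):
    """Raised when a shorthand lipid name cannot be parsed."""


@dataclass(frozen=True)
class SphingoidBase:
    """A sphingoid long-chain base.

    kind ``DS`` (dihydrosphingosine, saturated), ``S`` (sphingosine) and
    ``P`` (phytosphingosine, trihydroxy) map onto the ``d``/``t`` hydroxyl
    prefixes of the shorthand.
    """

    kind: str  # DS | S | P
    carbons: int
    double_bonds: int

    def __post_init__(self) -> None:
        if self.kind not in ("DS", "S", "P"):
            raise ValueError(f"unknown sphingoid kind: {self.kind!r}")
        if self.carbons < 2:
            raise ValueError(f"sphingoid base needs >= 2 carbons, got {self.carbons}")
        if self.double_bonds < 0:
            raise ValueError("negative double-bond count")
        if self.kind == "DS" and self.double_bonds != 0:
            raise ValueError("dihydrosphingosine (DS) base must be saturated")

    @property
    def hydroxyls(self) -> int:
        return 3 if self.kind == "P" else 2

    @property
    def formula(self) -> ChemFormula:
        # d-base CnH(2n+3-2d)NO2 (sphinganine C18H39NO2, sphingosine C18H37NO2);
        # t-base adds one oxygen (phytosphingosine C18H39NO3).
        return ChemFormula(
            {
                "C": self.carbons,
                "H": 2 * self.carbons + 3 - 2 * self.double_bonds,
                "N": 1,
                "O": self.hydroxyls,
            }
        )

    def shorthand(self) -> str:
        prefix = "t" if self.kind == "P" else "d"
        return f"{prefix}{self.carbons}:{self.double_bonds}"


@dataclass(frozen=True)
class AcylChain:
    """An N-acyl fatty acid: carbons, double bonds and hydroxylation type.

    ``hydroxy_type`` is N (none), A (alpha), B (beta) or EO (esterified
    omega-hydroxy); EO chains carry the esterified fatty acid as
    ``ester_chain``.
    """

    carbons: int
    double_bonds: int
    hydroxy_type: str  # N | A | B | EO
    ester_chain: Optional["AcylChain"] = None

    def __post_init__(self) -> None:
        if self.hydroxy_type not in ("N", "A", "B", "EO"):
            raise ValueError(f"unknown hydroxy type: {self.hydroxy_type!r}")
        if self.carbons < 2:
            raise ValueError(f"acyl chain needs >= 2 carbons, got {self.carbons}")
        if self.double_bonds < 0:
            raise ValueError("negative double-bond count")
        if (self.ester_chain is not None) != (self.hydroxy_type == "EO"):
            raise ValueError("ester_chain present iff hydroxy_type == 'EO'")
        if self.ester_chain is not None and self.ester_chain.hydroxy_type != "N":
            raise ValueError("esterified chain must be a plain (N) fatty acid")

    @property
    def formula(self) -> ChemFormula:
        """Formula of the free fatty acid (before amide condensation)."""
        oxygens = {"N": 2, "A": 3, "B": 3, "EO": 3}[self.hydroxy_type]
        acid = ChemFormula(
            {
                "C": self.carbons,
                "H": 2 * self.carbons - 2 * self.double_bonds,
                "O": oxygens,
            }
        )
        if self.ester_chain is not None:
            acid = acid + self.ester_chain.formula - H2O
        return acid

    def shorthand(self) -> str:
        text = f"{self.carbons}:{self.double_bonds}"
        if self.ester_chain is not None:
            text += f"/{self.ester_chain.shorthand()}"
        return text


@dataclass(frozen=True)
class ClassDefinition:
    code: str
    head: str  # Cer | HexCer | SM
    fa_type: str  # N | A | B | EO
    base_kind: str  # DS | S | P


def _class_table() -> Dict[str, ClassDefinition]:
    table: Dict[str, ClassDefinition] = {}
    for head in ("Cer", "HexCer"):
        for fa_type, base_kind in [
            ("N", "S"), ("N", "DS"), ("N", "P"),
            ("A", "S"), ("A", "DS"), ("A", "P"),
            ("B", "S"), ("B", "DS"),
            ("EO", "S"), ("EO", "DS"),
        ]:
            code = f"{head}[{fa_type}{base_kind}]"
            table[code] = ClassDefinition(code, head, fa_type, base_kind)
    table["SM"] = ClassDefinition("SM", "SM", "N", "S")
    return table


#: The 21 supported sphingolipid classes.
CLASS_TABLE: Mapping[str, ClassDefinition] = _class_table()


@dataclass(frozen=True)
class LipidSpecies:
    """One sphingolipid species: class code + sphingoid base + acyl chain."""

    class_code: str
    base: SphingoidBase
    chain: AcylChain

    def __post_init__(self) -> None:
        definition = CLASS_TABLE.get(self.class_code)
        if definition is None:
            raise NameParseError(f"unknown lipid class: {self.class_code!r}")
        if definition.base_kind != self.base.kind:
            raise ValueError(
                f"{self.class_code} requires a {definition.base_kind} base, "
                f"got {self.base.kind}"
            )
        if definition.fa_type != self.chain.hydroxy_type:
            raise ValueError(
                f"{self.class_code} requires fatty-acid type {definition.fa_type}, "
                f"got {self.chain.hydroxy_type}"
            )

    @property
    def head(self) -> str:
        return CLASS_TABLE[self.class_code].head

    @property
    def name(self) -> str:
        return format_name(self)

    @property
    def formula(self) -> ChemFormula:
        return species_formula(self)


_NAME_RE = re.compile(
    r"""^\s*
    (?P<cls>SM|Cer|HexCer)              # head / class stem
    (?:\s*\[\s*(?P<type>[A-Z]+)\s*\])?  # [NS], [AS], ... (absent for SM)
    \s*\(?\s*
    (?P<prefix>[dt])(?P<bc>\d+):(?P<bd>\d+)
    \s*/\s*(?P<fc>\d+):(?P<fd>\d+)
    (?:\s*/\s*(?P<ec>\d+):(?P<ed>\d+))? # ester chain for EO classes
    \s*\)?\s*$""",
    re.VERBOSE,
)


def parse_name(text: str) -> LipidSpecies:
    """Parse shorthand such as ``'Cer[AS] d18:1/16:0'`` into a species.

    Accepts optional parentheses and flexible spacing:
    ``Cer [AS] (d18:1/16:0)`` parses identically.
    """
    match = _NAME_RE.match(text)
    if match is None:
        raise NameParseError(f"cannot parse lipid name {text!r}")
    stem = match.group("cls")
    fa_base = match.group("type")
    if stem == "SM":
        if fa_base is not None:
            raise NameParseError(f"SM takes no [..] class qualifier in {text!r}")
        class_code = "SM"
    else:
        if fa_base is None:
            raise NameParseError(f"missing [..] class qualifier in {text!r}")
        class_code = f"{stem}[{fa_base}]"
    definition = CLASS_TABLE.get(class_code)
    if definition is None:
        raise NameParseError(
            f"unknown lipid class {class_code!r} at position {match.start('cls')}"
        )
    prefix = match.group("prefix")
    expected_prefix = "t" if definition.base_kind == "P" else "d"
    if prefix != expected_prefix:
        raise NameParseError(
            f"{class_code} expects a {expected_prefix!r} base, got {prefix!r} in {text!r}"
        )
    base = SphingoidBase(
        kind=definition.base_kind,
        carbons=int(match.group("bc")),
        double_bonds=int(match.group("bd")),
    )
    ester = None
    if match.group("ec") is not None:
        if definition.fa_type != "EO":
            raise NameParseError(f"{class_code} takes no ester chain in {text!r}")
        ester = AcylChain(int(match.group("ec")), int(match.group("ed")), "N")
    elif definition.fa_type == "EO":
        raise NameParseError(f"{class_code} requires an ester chain in {text!r}")
    chain = AcylChain(
        carbons=int(match.group("fc")),
        double_bonds=int(match.group("fd")),
        hydroxy_type=definition.fa_type,
        ester_chain=ester,
    )
    return LipidSpecies(class_code=class_code, base=base, chain=chain)


def format_name(species: LipidSpecies) -> str:
    """Canonical shorthand, the inverse of :func:`parse_name`."""
    return f"{species.class_code} {species.base.shorthand()}/{species.chain.shorthand()}"


def species_formula(species: LipidSpecies) -> ChemFormula:
    """Molecular formula via block condensation.

    base + fatty acid - H2O (amide bond); HexCer adds a hexose residue,
    SM a phosphocholine residue (each a further condensation).
    """
    formula = species.base.formula + species.chain.formula - H2O
    if species.head == "HexCer":
        formula = formula + HEXOSE_RESIDUE
    elif species.head == "SM":
        formula = formula + PHOSPHOCHOLINE_RESIDUE
    return formula


# ---------------------------------------------------------------------------
# enumeration configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassRanges:
    """Building-block ranges for one class (inclusive min/max pairs)."""

    fa_carbons: Tuple[int, int]
    fa_double_bonds: Tuple[int, int]
    base_carbons: Tuple[int, int]
    base_double_bonds: Tuple[int, int]
    ester_carbons: Optional[Tuple[int, int]] = None
    ester_double_bonds: Optional[Tuple[int, int]] = None
    parity: str = "all"  # "all" | "even" (fatty-acid carbon parity filter)
    adducts: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for label in ("fa_carbons", "fa_double_bonds", "base_carbons",
                      "base_double_bonds", "ester_carbons", "ester_double_bonds"):
            pair = getattr(self, label)
            if pair is None:
                continue
            lo, hi = pair
            if lo > hi:
                raise ValueError(f"{label}: min {lo} > max {hi}")
        if self.parity not in ("all", "even"):
            raise ValueError(f"parity must be 'all' or 'even', got {self.parity!r}")


@dataclass(frozen=True)
class EnumerationConfig:
    """Per-class enumeration ranges, loadable from YAML."""

    classes: Mapping[str, ClassRanges]

    @classmethod
    def from_dict(cls, raw: Mapping) -> "EnumerationConfig":
        classes: Dict[str, ClassRanges] = {}
        for code, entry in (raw.get("classes") or {}).items():
            if code not in CLASS_TABLE:
                raise ValueError(f"unknown lipid class in config: {code!r}")

            def pair(key, default=None):
                value = entry.get(key, default)
                if value is None:
                    return None
                lo, hi = value
                return (int(lo), int(hi))

            classes[code] = ClassRanges(
                fa_carbons=pair("fa_carbons"),
                fa_double_bonds=pair("fa_double_bonds"),
                base_carbons=pair("base_carbons"),
                base_double_bonds=pair("base_double_bonds"),
                ester_carbons=pair("ester_carbons"),
                ester_double_bonds=pair("ester_double_bonds"),
                parity=entry.get("parity", "all"),
                adducts=tuple(entry.get("adducts", ())),
            )
        return cls(classes=classes)

    @classmethod
    def from_yaml(cls, path) -> "EnumerationConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def default_ranges() -> EnumerationConfig:
    """The shipped default enumeration ranges (fatty acid 12-36 carbons with
    0-3 double bonds, sphingoid 14-30 carbons with 0-7 double bonds)."""
    ref = resources.files("sphingolib.data").joinpath("default_ranges.yaml")
    with resources.as_file(ref) as path:
        return EnumerationConfig.from_yaml(path)


def enumerate_class(class_code: str, config: EnumerationConfig) -> List[LipidSpecies]:
    """Enumerate one representative species per composition in a class.

    The Cartesian product of the configured ranges, in deterministic
    lexicographic order (fatty-acid carbons, fatty-acid double bonds,
    base carbons, base double bonds, then ester chain for EO classes).
    Dihydrosphingosine (DS) classes silently restrict base double bonds to 0.
    """
    if class_code not in CLASS_TABLE:
        raise KeyError(f"unknown lipid class: {class_code!r}")
    if class_code not in config.classes:
        raise KeyError(f"class {class_code!r} not present in configuration")
    definition = CLASS_TABLE[class_code]
    ranges = config.classes[class_code]

    def span(pair):
        return range(pair[0], pair[1] + 1)

    fa_carbons = [c for c in span(ranges.fa_carbons)
                  if ranges.parity == "all" or c % 2 == 0]
    base_dbs = list(span(ranges.base_double_bonds))
    if definition.base_kind == "DS":
        base_dbs = [db for db in base_dbs if db == 0]

    if definition.fa_type == "EO":
        if ranges.ester_carbons is None or ranges.ester_double_bonds is None:
            raise ValueError(f"{class_code}: EO class requires ester chain ranges")
        ester_axis = [
            AcylChain(ec, ed, "N")
            for ec in span(ranges.ester_carbons)
            for ed in span(ranges.ester_double_bonds)
        ]
    else:
        ester_axis = [None]

    species: List[LipidSpecies] = []
    for fc, fd, bc, bd, ester in itertools.product(
        fa_carbons,
        span(ranges.fa_double_bonds),
        span(ranges.base_carbons),
        base_dbs,
        ester_axis,
    ):
        species.append(
            LipidSpecies(
                class_code=class_code,
                base=SphingoidBase(definition.base_kind, bc, bd),
                chain=AcylChain(fc, fd, definition.fa_type, ester),
            )
        )
    return species


def build_manifest(records: Iterable) -> pd.DataFrame:
    """Per-class structure and spectrum counts of a built library.

    ``records`` is any iterable of objects exposing ``class_code`` and
    ``name`` (one entry per species x adduct).  Returns a DataFrame with
    columns class / structures / spectra, plus a trailing ``total`` row.
    """
    structures: Dict[str, set] = {}
    spectra: Dict[str, int] = {}
    for record in records:
        code = record.class_code
        structures.setdefault(code, set()).add(record.name)
        spectra[code] = spectra.get(code, 0) + 1
    rows = [
        {"class": code, "structures": len(structures[code]), "spectra": spectra[code]}
        for code in sorted(structures)
    ]
    frame = pd.DataFrame(rows, columns=["class", "structures", "spectra"])
    total = pd.DataFrame(
        [{"class": "total",
          "structures": int(frame["structures"].sum()) if len(frame) else 0,
          "spectra": int(frame["spectra"].sum()) if len(frame) else 0}]
    )
    return pd.concat([frame, total], ignore_index=True)


def reference_manifest() -> pd.DataFrame:
    """The published library manifest: per-class structure counts and adduct
    multiplicities for the 21 classes, with spectra = structures x adducts.

    The structure counts are manifest data (they reflect class-specific
    curation filters that are not derivable from the stated ranges alone).
    """
    ref = resources.files("sphingolib.data").joinpath("reference_manifest.tsv")
    with resources.as_file(ref) as path:
        frame = pd.read_csv(path, sep="\t")
    frame["spectra"] = frame["structures"] * frame["adducts"]
    return frame
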