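"""Hydrogen-rearrangement rule engine and in silico spectrum generation.

Low-energy CID fragments are modelled as neutralised (valence-satisfied)
substructures ``M'`` plus or minus rearranged hydrogens: ``[M' +- aH]+`` or
``[M' +- bH]-``.  The nine allowed hydrogen deltas are fixed by the HR rule
table below; per-class diagnostic-ion templates (shipped as YAML data) map
a species' building blocks to the neutral substructure of each product ion.
The engine itself only does formula arithmetic -- the chemistry lives in the
template files, which keeps classes auditable and extensible.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import yaml

from .chem import Adduct, ChemFormula, IonMass, adduct_mz, get_adduct, ion_mz
from .nomenclature import (
    H2O,
    EnumerationConfig,
    LipidSpecies,
    enumerate_class,
    format_name,
    species_formula,
)

__all__ = [
    "HRRule",
    "HR_RULES",
    "TemplateEntry",
    "FragmentTemplate",
    "TemplateRegistry",
    "Peak",
    "PeakAnnotation",
    "SpectrumRecord",
    "apply_hr_rule",
    "generate_spectrum",
    "build_library",
    "annotate_peaks",
]

#: Relative intensity assigned to declared dehydration satellite ions.
DEHYDRATION_INTENSITY = 150

#: Product ions closer than this (Th) are merged, keeping the larger intensity.
MERGE_TOLERANCE = 0.001


@dataclass(frozen=True)
class HRRule:
    """One hydrogen-rearrangement rule: a fixed hydrogen delta per cleavage."""

    id: str
    precursor_form: str  # "neutral" | "ionized"
    hydrogen_delta: int
    polarity: str  # "positive" | "negative"


HR_RULES: Mapping[str, HRRule] = {
    r.id: r
    for r in [
        HRRule("P1", "neutral", -1, "positive"),
        HRRule("P2", "neutral", +1, "positive"),
        HRRule("P3", "ionized", 0, "positive"),
        HRRule("P4", "ionized", -2, "positive"),
        HRRule("N1", "neutral", -1, "negative"),
        HRRule("N2", "neutral", -3, "negative"),
        HRRule("N3", "neutral", -2, "negative"),
        HRRule("N4", "ionized", 0, "negative"),
        HRRule("N5", "ionized", -2, "negative"),
    ]
}


def apply_hr_rule(
    fragment_neutral: ChemFormula, rule: HRRule | str | Sequence
) -> IonMass:
    """Ion m/z of a neutral fragment under one HR rule (or a combination).

    A sequence of rules models consecutive cleavages; their hydrogen deltas
    add (e.g. N2 + N5 gives a total delta of -5).  All rules in a
    combination must share one polarity.
    """
    if isinstance(rule, (HRRule, str)):
        rules: List[HRRule] = [HR_RULES[rule] if isinstance(rule, str) else rule]
    else:
        rules = [HR_RULES[r] if isinstance(r, str) else r for r in rule]
    polarities = {r.polarity for r in rules}
    if len(polarities) != 1:
        raise ValueError(f"mixed-polarity rule combination: {[r.id for r in rules]}")
    charge = 1 if polarities.pop() == "positive" else -1
    delta = sum(r.hydrogen_delta for r in rules)
    return ion_mz(fragment_neutral, delta, charge)


@dataclass(frozen=True)
class TemplateEntry:
    """One diagnostic ion: a formula expression, HR rule(s), and intensity."""

    label: str
    formula_expr: str
    rules: Tuple[str, ...]
    intensity: int
    origin: str  # fatty-acid | sphingoid | head | precursor | rearrangement
    dehydration: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.intensity <= 999:
            raise ValueError(f"intensity must be in [0, 999]: {self.intensity}")
        for rule_id in self.rules:
            if rule_id not in HR_RULES:
                raise ValueError(f"unknown HR rule: {rule_id!r}")


@dataclass(frozen=True)
class FragmentTemplate:
    class_code: str
    polarity: str
    adducts: Tuple[str, ...]
    entries: Tuple[TemplateEntry, ...]

    def __post_init__(self) -> None:
        if not any(e.intensity == 999 for e in self.entries):
            raise ValueError(
                f"template {self.class_code}/{self.polarity}: no base peak (999)"
            )


# ---------------------------------------------------------------------------
# formula expressions
# ---------------------------------------------------------------------------

_EXPR_TOKEN = re.compile(r"\s*([+-])\s*")


def _species_blocks(species: LipidSpecies) -> Dict[str, ChemFormula]:
    """Named building-block formulas available to template expressions."""
    fa_acid = species.chain.formula
    blocks = {
        "species": species_formula(species),
        "base": species.base.formula,
        "fa_acid": fa_acid,
        "fa_amide": fa_acid - ChemFormula({"O": 1}) + ChemFormula({"N": 1, "H": 1}),
    }
    if species.chain.ester_chain is not None:
        blocks["est_acid"] = species.chain.ester_chain.formula
    return blocks


def eval_formula_expr(expr: str, blocks: Mapping[str, ChemFormula]) -> ChemFormula:
    """Evaluate expressions like ``'fa_amide + C2H2 - H2O'``.

    Terms are block names or literal formulas, combined left to right.
    """
    parts = _EXPR_TOKEN.split(expr.strip())
    if not parts or not parts[0]:
        raise ValueError(f"empty formula expression: {expr!r}")
    terms = [("+", parts[0])]
    for sign, token in zip(parts[1::2], parts[2::2]):
        terms.append((sign, token))
    result = ChemFormula({})
    for sign, token in terms:
        token = token.strip()
        formula = blocks.get(token)
        if formula is None:
            formula = ChemFormula.parse(token)
        result = result + formula if sign == "+" else result - formula
    return result


# ---------------------------------------------------------------------------
# template registry
# ---------------------------------------------------------------------------


class TemplateRegistry:
    """Per-class fragment templates keyed by (class code, polarity)."""

    def __init__(self) -> None:
        self._templates: Dict[Tuple[str, str], FragmentTemplate] = {}

    @classmethod
    def default(cls) -> "TemplateRegistry":
        registry = cls()
        data = resources.files("sphingolib.data")
        for name in ("templates_negative.yaml", "templates_positive.yaml"):
            with resources.as_file(data.joinpath(name)) as path:
                registry.load_yaml(path)
        return registry

    def load_yaml(self, path) -> None:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        polarity = raw["polarity"]
        shared: Mapping[str, List[dict]] = raw.get("shared") or {}
        for class_code, cfg in (raw.get("classes") or {}).items():
            entries: List[dict] = []
            if "extends" in cfg:
                entries.extend(shared[cfg["extends"]])
            for extra in cfg.get("plus", ()):
                entries.extend(shared[extra])
            entries.extend(cfg.get("entries", ()))
            template = FragmentTemplate(
                class_code=class_code,
                polarity=polarity,
                adducts=tuple(get_adduct(a).name for a in cfg["adducts"]),
                entries=tuple(
                    TemplateEntry(
                        label=e["label"],
                        formula_expr=e["formula"],
                        rules=tuple(e["rules"]),
                        intensity=int(e["intensity"]),
                        origin=e["origin"],
                        dehydration=bool(e.get("dehydration", False)),
                    )
                    for e in entries
                ),
            )
            self._templates[(class_code, polarity)] = template

    def get(self, class_code: str, polarity: str) -> FragmentTemplate:
        try:
            return self._templates[(class_code, polarity)]
        except KeyError:
            raise KeyError(
                f"no {polarity}-mode fragment template registered for "
                f"class {class_code!r}"
            ) from None

    def __contains__(self, key: Tuple[str, str]) -> bool:
        return key in self._templates


_default_registry: Optional[TemplateRegistry] = None


def default_registry() -> TemplateRegistry:
    global _default_registry
    if _default_registry is None:
        _default_registry = TemplateRegistry.default()
    return _default_registry


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PeakAnnotation:
    """Provenance of a product ion: label, HR rule(s), neutral formula, dH."""

    label: str
    rules: Tuple[str, ...]
    formula: ChemFormula
    hydrogen_delta: int

    def to_string(self) -> str:
        return (
            f"{self.label}|{'+'.join(self.rules)}|{self.formula.hill()}"
            f"|{self.hydrogen_delta:+d}"
        )

    @classmethod
    def from_string(cls, text: str) -> "PeakAnnotation":
        label, rules, formula, delta = text.rsplit("|", 3)
        return cls(
            label=label,
            rules=tuple(rules.split("+")) if rules else (),
            formula=ChemFormula.parse(formula),
            hydrogen_delta=int(delta),
        )


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: int
    annotation: Optional[PeakAnnotation] = None


@dataclass
class SpectrumRecord:
    """An annotated in silico MS/MS spectrum for one species x adduct."""

    name: str
    class_code: str
    adduct: str
    polarity: str
    precursor_mz: float
    peaks: List[Peak]
    formula: Optional[ChemFormula] = None
    smiles: Optional[str] = None
    rt: Optional[float] = None
    comment: Dict[str, str] = field(default_factory=dict)
    species: Optional[LipidSpecies] = None

    @property
    def record_id(self) -> str:
        return f"{self.name}; {self.adduct}"

    def base_peak_intensity(self) -> int:
        return max((p.intensity for p in self.peaks), default=0)


def generate_spectrum(
    species: LipidSpecies,
    adduct: Adduct | str,
    registry: Optional[TemplateRegistry] = None,
) -> SpectrumRecord:
    """Generate the annotated in silico spectrum of one species under one adduct.

    The precursor m/z is that of the adduct ion; product ions are computed
    from the neutral molecule through the class template.  Declared
    dehydration satellites are expanded, and product ions closer than
    0.001 Th are merged keeping the larger intensity.
    """
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    registry = registry or default_registry()
    template = registry.get(species.class_code, adduct.polarity)
    if adduct.name not in template.adducts:
        raise KeyError(
            f"adduct {adduct.name} not in template scope for "
            f"{species.class_code} ({', '.join(template.adducts)})"
        )
    blocks = _species_blocks(species)
    neutral = blocks["species"]
    precursor = adduct_mz(neutral, adduct)

    raw: List[Peak] = []
    for entry in template.entries:
        fragment = eval_formula_expr(entry.formula_expr, blocks)
        variants = [(fragment, entry.intensity, entry.label)]
        if entry.dehydration:
            variants.append(
                (fragment - H2O, DEHYDRATION_INTENSITY, entry.label + " - H2O")
            )
        for formula, intensity, label in variants:
            ion = apply_hr_rule(formula, entry.rules)
            raw.append(
                Peak(
                    mz=ion.mz,
                    intensity=intensity,
                    annotation=PeakAnnotation(
                        label=label,
                        rules=entry.rules,
                        formula=formula,
                        hydrogen_delta=ion.hydrogen_delta,
                    ),
                )
            )

    raw.sort(key=lambda p: p.mz)
    merged: List[Peak] = []
    for peak in raw:
        if merged and peak.mz - merged[-1].mz < MERGE_TOLERANCE:
            if peak.intensity > merged[-1].intensity:
                merged[-1] = replace(peak, mz=merged[-1].mz)
        else:
            merged.append(peak)

    for peak in merged:
        if peak.mz > precursor.mz + 0.5:
            raise ValueError(
                f"product ion {peak.annotation.label!r} at {peak.mz:.4f} exceeds "
                f"precursor {precursor.mz:.4f} for {format_name(species)}"
            )

    return SpectrumRecord(
        name=format_name(species),
        class_code=species.class_code,
        adduct=adduct.name,
        polarity=adduct.polarity,
        precursor_mz=precursor.mz,
        peaks=merged,
        formula=neutral,
        comment={},
        species=species,
    )


def build_library(
    config: EnumerationConfig,
    registry: Optional[TemplateRegistry] = None,
    classes: Optional[Sequence[str]] = None,
) -> List[SpectrumRecord]:
    """Enumerate every configured species x adduct into spectrum records."""
    registry = registry or default_registry()
    records: List[SpectrumRecord] = []
    for class_code in classes if classes is not None else config.classes:
        ranges = config.classes.get(class_code)
        if ranges is None:
            raise KeyError(f"class {class_code!r} not present in configuration")
        for species in enumerate_class(class_code, config):
            for adduct_name in ranges.adducts:
                try:
                    records.append(generate_spectrum(species, adduct_name, registry))
                except Exception as err:
                    raise RuntimeError(
                        f"failed to generate spectrum for "
                        f"{format_name(species)} {adduct_name}: {err}"
                    ) from err
    return records


def annotate_peaks(
    observed: Sequence[Tuple[float, float]],
    species: LipidSpecies | SpectrumRecord,
    adduct: Optional[Adduct | str] = None,
    tolerance_mda: float = 10.0,
    registry: Optional[TemplateRegistry] = None,
) -> List[Tuple[float, float, Optional[PeakAnnotation], Optional[float]]]:
    """Match observed peaks to template ions within a tolerance (mDa).

    The reference is either a species (whose spectrum under ``adduct`` is
    generated) or an existing :class:`SpectrumRecord`.  Each observed peak
    is assigned the nearest template ion within ``tolerance_mda`` (ties
    resolved toward lower template m/z) or left unassigned.  Template depth
    is the shipped two-cleavage maximum.  Returns (mz, intensity,
    annotation-or-None, error-mDa-or-None) tuples.
    """
    if tolerance_mda <= 0:
        raise ValueError("tolerance must be positive")
    if isinstance(species, SpectrumRecord):
        reference = species
    else:
        if adduct is None:
            raise ValueError("adduct is required when annotating against a species")
        reference = generate_spectrum(species, adduct, registry)
    tolerance = tolerance_mda / 1000.0
    results = []
    for mz, intensity in observed:
        best = None
        for peak in reference.peaks:
            delta = abs(peak.mz - mz)
            if delta > tolerance:
                continue
            if best is None or (delta, peak.mz) < (best[0], best[1].mz):
                best = (delta, peak)
        if best is None:
            results.append((mz, intensity, None, None))
        else:
            results.append(
                (mz, intensity, best[1].annotation, (mz - best[1].mz) * 1000.0)
            )
    return results
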