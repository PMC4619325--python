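"""Elemental formulas, monoisotopic masses, adduct m/z and carbon isotopolog ratios.

All masses are in daltons (Da). The mass scale is anchored at ¹²C = 12 exactly;
the remaining entries are the masses of the most abundant isotope of each
element. Charged species use the proton mass (i.e. the electron mass is
accounted for), so ``[M+H]+`` of a neutral monoisotopic mass M is
``M + 1.00727646``, not ``M + 1.0078250``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Mapping

__all__ = [
    "Formula",
    "FormulaError",
    "IonSpecies",
    "BUILTIN_IONS",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "theoretical_ria",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "C13_C12_DELTA",
]

#: Mass of the most abundant isotope per element, Da.
MONOISOTOPIC_MASSES: Dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "F": 18.9984031627,
    "Na": 22.9897692820,
    "Mg": 23.9850417,
    "Si": 27.9769265347,
    "P": 30.9737615120,
    "S": 31.9720706912,
    "Cl": 34.9688527100,
    "K": 38.9637064864,
    "Ca": 39.9625909,
    "Fe": 55.9349363,
    "Se": 79.9165218,
    "Br": 78.9183376,
    "I": 126.9044719,
}

PROTON_MASS = 1.00727646
ELECTRON_MASS = 0.000548579909

#: ¹³C − ¹²C mass difference, Da; spacing of the first carbon isotopolog.
C13_C12_DELTA = 1.00336

#: IUPAC representative isotopic abundances of carbon.
C12_ABUNDANCE = 0.9893
C13_ABUNDANCE = 0.0107


class FormulaError(ValueError):
    """Raised for unparsable or chemically invalid formula strings."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class Formula:
    """An elemental composition as a mapping element symbol -> count."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.counts or all(n == 0 for n in self.counts.values()):
            raise FormulaError("formula must contain at least one atom")
        for sym, n in self.counts.items():
            if sym not in MONOISOTOPIC_MASSES:
                raise FormulaError(f"unknown element symbol {sym!r}")
            if n < 0:
                raise FormulaError(f"negative count for element {sym!r}")

    def __getitem__(self, symbol: str) -> int:
        return self.counts.get(symbol, 0)

    def hill(self) -> str:
        """Canonical Hill-order string: C, H first (if carbon present), rest alphabetical."""
        items = {s: n for s, n in self.counts.items() if n > 0}
        if "C" in items:
            order = ["C"] + (["H"] if "H" in items else [])
            order += sorted(s for s in items if s not in ("C", "H"))
        else:
            order = sorted(items)
        return "".join(f"{s}{items[s] if items[s] != 1 else ''}" for s in order)

    def __add__(self, other: "Formula") -> "Formula":
        merged = dict(self.counts)
        for s, n in other.counts.items():
            merged[s] = merged.get(s, 0) + n
        return Formula(merged)


def parse_formula(text: str) -> Formula:
    """Parse a Hill-notation formula string such as ``"C12H18O3"``.

    Element symbols are an upper-case letter optionally followed by one
    lower-case letter; a missing count means 1. Raises :class:`FormulaError`
    on empty input, unknown elements or any stray characters.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: Dict[str, int] = {}
    pos = 0
    for m in _TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(f"unparsable formula segment {text[pos:m.start()]!r} in {text!r}")
        sym, digits = m.group(1), m.group(2)
        if sym not in MONOISOTOPIC_MASSES:
            raise FormulaError(f"unknown element symbol {sym!r} in {text!r}")
        counts[sym] = counts.get(sym, 0) + (int(digits) if digits else 1)
        pos = m.end()
    if pos != len(text):
        raise FormulaError(f"unparsable formula segment {text[pos:]!r} in {text!r}")
    return Formula(counts)


def monoisotopic_mass(formula: Formula | str) -> float:
    """Neutral monoisotopic mass in Da (sum of most-abundant-isotope masses)."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    return sum(MONOISOTOPIC_MASSES[s] * n for s, n in formula.counts.items())


@dataclass(frozen=True)
class IonSpecies:
    """A detected ion form relative to the neutral molecule.

    ``mass_delta`` is added to the neutral monoisotopic mass before dividing
    by ``|charge|``; it already includes electron gain/loss.
    """

    label: str
    mass_delta: float
    charge: int

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("ion species must carry a non-zero charge")


BUILTIN_IONS: Dict[str, IonSpecies] = {
    ion.label: ion
    for ion in (
        IonSpecies("[M+H]+", PROTON_MASS, +1),
        IonSpecies("[M+Na]+", MONOISOTOPIC_MASSES["Na"] - ELECTRON_MASS, +1),
        IonSpecies("[M+NH4]+", MONOISOTOPIC_MASSES["N"] + 4 * MONOISOTOPIC_MASSES["H"] - ELECTRON_MASS, +1),
        IonSpecies("[M+K]+", MONOISOTOPIC_MASSES["K"] - ELECTRON_MASS, +1),
        IonSpecies("[M-H]-", -PROTON_MASS, -1),
        IonSpecies("[M+Cl]-", MONOISOTOPIC_MASSES["Cl"] + ELECTRON_MASS, -1),
    )
}


def get_ion(label: str, extra: Mapping[str, IonSpecies] | None = None) -> IonSpecies:
    """Look up an ion species by label among built-ins plus user-defined ones."""
    if extra and label in extra:
        return extra[label]
    try:
        return BUILTIN_IONS[label]
    except KeyError:
        known = sorted(BUILTIN_IONS)
        raise KeyError(f"unknown ion species {label!r}; built-ins: {known}") from None


def adduct_mz(neutral_mass: float, ion: IonSpecies) -> float:
    """m/z of an ion species: ``(neutral_mass + mass_delta) / |charge|``."""
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    mz = (neutral_mass + ion.mass_delta) / abs(ion.charge)
    if not mz > 0:
        raise ValueError(f"non-positive m/z for {ion.label} of mass {neutral_mass}")
    return mz


def theoretical_ria(formula: Formula | str) -> float:
    """Carbon-only relative isotopolog abundance, intensity(M+1)/intensity(M).

    For a molecule with n carbons the ratio of the first isotopic peak to the
    monoisotopic peak is ``n × a(¹³C)/a(¹²C)`` (the leading terms of the
    binomial isotope distribution). Contributions of N, O, S and other
    heteroatoms to M+1 are deliberately ignored, so the value is biased low
    for heteroatom-rich compositions.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    n_c = formula["C"]
    if n_c < 1:
        raise ValueError("RIA requires at least one carbon atom")
    return n_c * (C13_ABUNDANCE / C12_ABUNDANCE)
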