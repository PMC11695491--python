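"""Elemental-formula arithmetic for exact-mass screening.

Monoisotopic masses, adduct m/z values and ppm errors underpin suspect
matching and feature annotation throughout the pipeline.  Only singly
charged positive-mode chemistry is covered: the screening workflow this
package implements acquires [M+H]+ ions, and isotope fine structure is
out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, NamedTuple

__all__ = [
    "MONOISOTOPIC_MASSES",
    "PROTON_MASS",
    "ADDUCT_OFFSETS",
    "ChemicalFormula",
    "MassValue",
    "FormulaError",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "round_half_up",
]

# Most-abundant-isotope masses in Da (IUPAC/CODATA, >=6 decimals).
MONOISOTOPIC_MASSES: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "Cl": 34.96885268,
    "Br": 78.9183371,
    "F": 18.99840322,
    "P": 30.97376163,
    "Na": 22.9897692809,
    "K": 38.96370668,
}

#: Mass of a proton in Da (electron mass accounted for).
PROTON_MASS = 1.007276

#: m/z offset added to the neutral monoisotopic mass per adduct.
ADDUCT_OFFSETS: dict[str, float] = {
    "[M+H]+": PROTON_MASS,
}


class FormulaError(ValueError):
    """Raised for malformed or unsupported elemental formulas."""


class MassValue(NamedTuple):
    """A monoisotopic mass in Da, tagged as neutral or ionic."""

    value: float
    kind: str = "neutral"  # "neutral" | "ion"

    def __float__(self) -> float:
        return self.value


def _as_float(m: "MassValue | float") -> float:
    return float(m)


_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ChemicalFormula:
    """An elemental composition, e.g. ``{C: 12, H: 10, O: 2}``.

    Counts are strictly positive; element symbols must be in
    :data:`MONOISOTOPIC_MASSES`.
    """

    element_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.element_counts:
            raise FormulaError("empty formula")
        for elem, count in self.element_counts.items():
            if elem not in MONOISOTOPIC_MASSES:
                raise FormulaError(f"unknown element symbol: {elem!r}")
            if not isinstance(count, int) or count < 1:
                raise FormulaError(f"count for {elem} must be a positive integer, got {count!r}")
        # canonical storage order (Hill): C, H, then alphabetical
        object.__setattr__(self, "element_counts", dict(sorted(self.element_counts.items(), key=_hill_key)))

    def __add__(self, other: "ChemicalFormula") -> "ChemicalFormula":
        counts = dict(self.element_counts)
        for elem, n in other.element_counts.items():
            counts[elem] = counts.get(elem, 0) + n
        return ChemicalFormula(counts)

    def hill(self) -> str:
        """Hill-notation string: C first, H second, remainder alphabetical."""
        parts = []
        for elem, count in self.element_counts.items():
            parts.append(elem if count == 1 else f"{elem}{count}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def _hill_key(item: tuple[str, int]) -> tuple[int, str]:
    elem = item[0]
    if elem == "C":
        return (0, "")
    if elem == "H":
        return (1, "")
    return (2, elem)


def parse_formula(text: str) -> ChemicalFormula:
    """Parse a Hill-notation formula string such as ``"C12H10O2"``.

    Whitespace between element tokens is tolerated (formulas pasted from
    tables often carry it).  Repeated element tokens are summed.
    """
    compact = re.sub(r"\s+", "", text)
    if not compact:
        raise FormulaError("empty formula string")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(compact):
        m = _TOKEN_RE.match(compact, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        elem, digits = m.group(1), m.group(2)
        if elem not in MONOISOTOPIC_MASSES:
            raise FormulaError(f"unknown element symbol {elem!r} in {text!r}")
        count = int(digits) if digits else 1
        if count < 1:
            raise FormulaError(f"zero count for element {elem!r} in {text!r}")
        counts[elem] = counts.get(elem, 0) + count
        pos = m.end()
    return ChemicalFormula(counts)


def monoisotopic_mass(f: ChemicalFormula) -> MassValue:
    """Neutral monoisotopic mass: sum of count x most-abundant-isotope mass."""
    total = sum(count * MONOISOTOPIC_MASSES[elem] for elem, count in f.element_counts.items())
    return MassValue(total, "neutral")


def adduct_mz(neutral: "MassValue | float", adduct: str = "[M+H]+") -> MassValue:
    """m/z of the given adduct of a neutral mass.

    Only singly charged adducts are supported; for [M+H]+ the offset is
    the proton mass (1.007276 Da).
    """
    try:
        offset = ADDUCT_OFFSETS[adduct]
    except KeyError:
        raise FormulaError(f"unsupported adduct label: {adduct!r}") from None
    value = _as_float(neutral)
    if value <= 0:
        raise ValueError("neutral mass must be positive")
    return MassValue(value + offset, "ion")


def ppm_error(measured: "MassValue | float", theoretical: "MassValue | float") -> float:
    """Signed relative mass error in parts per million (measured - theoretical)."""
    theo = _as_float(theoretical)
    if theo <= 0:
        raise ValueError("theoretical mass must be positive")
    return (_as_float(measured) - theo) / theo * 1e6


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at the given decimal place.

    Used for reported percentages and decile sizes; Python's built-in
    banker's rounding would round 0.5-ties down half the time.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
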