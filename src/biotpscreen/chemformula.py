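"""Elemental-formula parsing and exact monoisotopic mass arithmetic.

All mass prediction and ppm matching in the package runs on plain elemental
formulas: a formula is a mapping of element symbol to a signed integer count,
and its monoisotopic mass is the sum of most-abundant-isotope masses.  Average
masses are never used — LC-HRMS feature masses are monoisotopic by convention.

Isotope masses come from the NIST table bundled with :mod:`pyteomics`
(``pyteomics.mass.nist_mass``); the proton mass constant is the CODATA value
1.00727646677 Da from the same source.  ``C`` maps to exactly 12.0 by the
definition of the unified atomic mass scale.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Iterator, Mapping

from pyteomics import mass as _ptmass

__all__ = [
    "FormulaError",
    "MolecularFormula",
    "ISOTOPE_MASSES",
    "PROTON_MASS",
    "parse_formula",
    "monoisotopic_mass",
    "mz_from_neutral",
    "neutral_from_mz",
    "ppm_error",
]


class FormulaError(ValueError):
    """Malformed formula text, unknown element, or a non-finalized formula
    used where a physical (all counts >= 0) formula is required."""


_ELEMENT_RE = re.compile(r"^[A-Z][a-z]?$")


def _build_isotope_table() -> Mapping[str, float]:
    table = {}
    for symbol, isotopes in _ptmass.nist_mass.items():
        if _ELEMENT_RE.match(symbol):
            # key 0 holds the most abundant isotope's mass
            table[symbol] = isotopes[0][0]
    return MappingProxyType(table)


#: element symbol -> monoisotopic (most abundant isotope) mass, Da; immutable.
ISOTOPE_MASSES: Mapping[str, float] = _build_isotope_table()

#: CODATA proton mass, Da (pyteomics.mass nist_mass["H+"]).
PROTON_MASS: float = 1.00727646677

_ADDUCTS = {
    "[M+H]+": +PROTON_MASS,
    "[M-H]-": -PROTON_MASS,
}
# tolerate the typographic minus sign in adduct labels
_ADDUCT_ALIASES = {"[M−H]−": "[M-H]-", "[M−H]-": "[M-H]-"}

_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """An element -> signed count map.

    Negative counts are permitted transiently (they arise inside
    transformation-rule deltas) but a *finalized* formula — anything
    user-visible or passed to :func:`monoisotopic_mass` — must have all
    counts >= 0 and at least one count > 0.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for el, n in self.counts.items():
            if not _ELEMENT_RE.match(el) or el not in ISOTOPE_MASSES:
                raise FormulaError(f"unknown element symbol: {el!r}")
            if int(n) != n:
                raise FormulaError(f"non-integer count for {el}: {n!r}")
            if n != 0:
                clean[el] = int(n)
        object.__setattr__(self, "counts", MappingProxyType(clean))

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return MolecularFormula(merged)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        return self + other.negate()

    def negate(self) -> "MolecularFormula":
        return MolecularFormula({el: -n for el, n in self.counts.items()})

    # -- predicates -------------------------------------------------------
    @property
    def is_finalized(self) -> bool:
        return bool(self.counts) and all(n > 0 for n in self.counts.values())

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.counts.items())

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    # -- formatting -------------------------------------------------------
    def hill(self) -> str:
        """Canonical Hill-order string: C, H, then alphabetical (no C: all
        alphabetical, H included)."""
        items = dict(self.counts)
        parts = []
        if "C" in items:
            order = ["C"] + (["H"] if "H" in items else [])
            order += sorted(el for el in items if el not in ("C", "H"))
        else:
            order = sorted(items)
        for el in order:
            n = items[el]
            if n < 0:
                raise FormulaError(
                    f"cannot format non-finalized formula (negative {el} count)"
                )
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __str__(self) -> str:
        return self.hill()

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-notation formula string, e.g. ``"C16H21NO2"``.

    Only element symbols and positive integer counts are accepted — no
    charges, isotope labels, or parentheses.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m or not m.group(1):
            raise FormulaError(f"cannot parse formula {text!r} at {text[pos:]!r}")
        el, digits = m.group(1), m.group(2)
        if el not in ISOTOPE_MASSES:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return MolecularFormula(counts)


def monoisotopic_mass(formula: MolecularFormula) -> float:
    """Exact monoisotopic mass in Da of a finalized formula."""
    if not formula.is_finalized:
        raise FormulaError(
            f"formula {dict(formula.counts)!r} is not finalized "
            "(empty or negative counts)"
        )
    return sum(n * ISOTOPE_MASSES[el] for el, n in formula)


def _normalize_adduct(adduct: str) -> str:
    adduct = _ADDUCT_ALIASES.get(adduct, adduct)
    if adduct not in _ADDUCTS:
        raise ValueError(
            f"unsupported adduct {adduct!r}; supported: {sorted(_ADDUCTS)}"
        )
    return adduct


def mz_from_neutral(neutral_mass: float, adduct: str) -> float:
    """m/z of a singly charged ion from a neutral monoisotopic mass."""
    if neutral_mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {neutral_mass}")
    return neutral_mass + _ADDUCTS[_normalize_adduct(adduct)]


def neutral_from_mz(mz: float, adduct: str) -> float:
    """Inverse of :func:`mz_from_neutral` (exact round-trip)."""
    neutral = mz - _ADDUCTS[_normalize_adduct(adduct)]
    if neutral <= 0:
        raise ValueError(f"m/z {mz} with adduct {adduct} gives nonpositive mass")
    return neutral


def ppm_error(measured: float, theoretical: float) -> float:
    """Signed parts-per-million deviation of a measured from a theoretical mass."""
    if theoretical <= 0:
        raise ValueError("theoretical mass must be positive")
    return 1e6 * (measured - theoretical) / theoretical
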