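"""Elemental-formula arithmetic for negative-mode bile-acid HRMS.

Everything downstream (library matching, conjugate discovery, diagnostic
fragment ions, synthetic data) derives its masses from this module so that
theoretical m/z values are computed in exactly one place.

Conventions
-----------
* Monoisotopic masses only (most abundant isotope per element); isotope
  patterns are out of scope.
* The observed ion is always the deprotonated molecule [M-H]- at charge 1:
  ``m/z = M - m_proton`` where the proton mass already accounts for the
  electron kept by the anion.
* ppm error is signed: ``(observed - theoretical) / theoretical * 1e6``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "DEUTERIUM_MASS_SHIFT",
    "ElementalFormula",
    "BiotransformDelta",
    "DELTAS",
    "parse_formula",
    "monoisotopic_mass",
    "mz_mh_minus",
    "ppm_error",
    "apply_delta",
]

#: Monoisotopic atomic masses (Da) of the most abundant isotope, CODATA/IUPAC,
#: >= 8 decimals. C, H, N, O, S cover the bile-acid / phase-II-conjugate space.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,  # exact by definition
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "S": 31.97207117,
}

#: Mass of the proton (Da). [M-H]- = M - PROTON_MASS: removing H+ leaves the
#: electron with the anion, so this single constant handles the electron too.
PROTON_MASS = 1.00727646

#: Electron rest mass (Da); needed only for radical anions (e.g. SO3-.).
ELECTRON_MASS = 0.00054858

#: Mass difference D - H (Da), for deuterated internal standards.
DEUTERIUM_MASS_SHIFT = 1.00627675

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Malformed formula string or unknown element symbol."""


@dataclass(frozen=True)
class ElementalFormula:
    """An element -> count mapping with non-negative counts.

    Equality is count-wise; zero counts are dropped so ``C24H40O4`` and
    ``C24H40N0O4`` compare equal.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for el, n in self.counts.items():
            if el not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol: {el!r}")
            n = int(n)
            if n < 0:
                raise FormulaError(f"negative count for {el}: {n}")
            if n:
                clean[el] = n
        object.__setattr__(self, "counts", clean)

    # mapping-style access -------------------------------------------------
    def __getitem__(self, el: str) -> int:
        return self.counts.get(el, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self.counts)

    def __len__(self) -> int:
        return len(self.counts)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, ElementalFormula):
            return dict(self.counts) == dict(other.counts)
        return NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self.counts.items()))

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical.
        order = ["C", "H"] + sorted(k for k in self.counts if k not in ("C", "H"))
        parts = []
        for el in order:
            n = self[el]
            if n == 1:
                parts.append(el)
            elif n > 1:
                parts.append(f"{el}{n}")
        return "".join(parts)

    @property
    def mass(self) -> float:
        """Neutral monoisotopic mass in Da."""
        return monoisotopic_mass(self)


@dataclass(frozen=True)
class BiotransformDelta:
    """A fixed biotransformation as a signed element-count delta."""

    name: str
    label: str  # suffix used in target names, e.g. "+SO3"
    delta: Mapping[str, int]

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self.delta)


#: The biotransformation vocabulary: phase-II conjugations plus the oxidative
#: reactions seen in liver-fraction incubations.
DELTAS: dict[str, BiotransformDelta] = {
    d.name: d
    for d in (
        BiotransformDelta("sulfation", "+SO3", {"S": 1, "O": 3}),
        BiotransformDelta("glucuronidation", "+Gluc", {"C": 6, "H": 8, "O": 6}),
        BiotransformDelta("hydroxylation", "+O", {"O": 1}),
        BiotransformDelta("dihydroxylation", "+2O", {"O": 2}),
        BiotransformDelta("oxidation-to-keto", "+O-2H", {"O": 1, "H": -2}),
        BiotransformDelta("dehydrogenation", "-2H", {"H": -2}),
        BiotransformDelta("dehydroxylation", "-O", {"O": -1}),
        BiotransformDelta("glycine-amidation", "+Gly", {"C": 2, "H": 3, "N": 1, "O": 1}),
        BiotransformDelta("taurine-amidation", "+Tau", {"C": 2, "H": 5, "N": 1, "O": 2, "S": 1}),
    )
}


def parse_formula(text: str) -> ElementalFormula:
    """Parse a molecular formula string like ``"C24H40O7S"``.

    Repeated element symbols are summed.  Raises :class:`FormulaError` on an
    unknown element or a malformed string.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError(f"not a formula string: {text!r}")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        if not m.group(0):
            break
        el = m.group(1)
        if el not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        n = int(m.group(2)) if m.group(2) else 1
        counts[el] = counts.get(el, 0) + n
        pos = m.end()
    if pos != len(text):
        raise FormulaError(f"malformed formula {text!r} at position {pos}")
    return ElementalFormula(counts)


def monoisotopic_mass(f: ElementalFormula | Mapping[str, int]) -> float:
    """Monoisotopic mass (Da) of a formula or signed element-count mapping.

    Signed mappings are allowed so biotransformation deltas (e.g. ``-2H``)
    have a well-defined, possibly negative, mass.
    """
    counts = f.counts if isinstance(f, ElementalFormula) else f
    total = 0.0
    for el, n in counts.items():
        try:
            total += MONOISOTOPIC_MASS[el] * n
        except KeyError:
            raise FormulaError(f"unknown element symbol: {el!r}") from None
    return total


def mz_mh_minus(f: ElementalFormula | str, label_mass_shift: float = 0.0) -> float:
    """Theoretical m/z of the [M-H]- ion of a neutral formula.

    ``label_mass_shift`` adds a fixed isotope-label offset (deuterated
    internal standards: ``n_D * DEUTERIUM_MASS_SHIFT``).
    """
    if isinstance(f, str):
        f = parse_formula(f)
    if f["H"] < 1:
        raise FormulaError(f"cannot deprotonate {f}: no hydrogen")
    return monoisotopic_mass(f) + label_mass_shift - PROTON_MASS


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be positive, got {theoretical}")
    return (observed - theoretical) / theoretical * 1e6


def apply_delta(f: ElementalFormula, d: BiotransformDelta) -> ElementalFormula:
    """Apply a biotransformation delta count-wise.

    Raises :class:`FormulaError` if any resulting count would be negative
    (e.g. dehydroxylation of a formula without oxygen).
    """
    counts = dict(f.counts)
    for el, n in d.delta.items():
        counts[el] = counts.get(el, 0) + n
        if counts[el] < 0:
            raise FormulaError(
                f"{d.name} of {f} would give negative {el} count"
            )
    return ElementalFormula(counts)
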