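"""The bile-acid standards library and deuterated internal standards.

The packaged library mirrors a commercial 46-standard bile-acid mix plus 14
deuterated internal standards.  Formulas were compiled from standard
references using steroid-core arithmetic (unconjugated non-keto species:
mono-OH C24H40O3, di-OH C24H40O4, tri-OH C24H40O5; keto groups replace an
-OH by =O, i.e. +O-2H on the reduced parent; nor- species lack one CH2;
glycine amidation adds C2H3NO and taurine amidation C2H5NO2S).  Reference
retention times are data, not computation: the packaged values come from the
default synthetic scenario and follow the tri < di < mono elution order of a
reversed-phase C18 gradient.

Self-consistency is enforced at load: every glycine/taurine conjugate whose
parent is present in the library must equal parent + amidation delta, and
hydroxyl classes of unconjugated non-keto species must match the core
formulas above.  A library failing these checks refuses to load.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .chem import (
    DELTAS,
    DEUTERIUM_MASS_SHIFT,
    ElementalFormula,
    apply_delta,
    mz_mh_minus,
    parse_formula,
)

__all__ = ["LibraryEntry", "BileAcidLibrary", "load_default_library", "LibraryError"]

CONJUGATION_CLASSES = ("unconjugated", "glycine", "taurine")
HYDROXYL_CLASSES = ("mono", "di", "tri", "other")

_HYDROXYL_CORE = {
    "mono": parse_formula("C24H40O3"),
    "di": parse_formula("C24H40O4"),
    "tri": parse_formula("C24H40O5"),
}

_AMIDATION = {"glycine": DELTAS["glycine-amidation"], "taurine": DELTAS["taurine-amidation"]}


class LibraryError(ValueError):
    """Library file violates the self-consistency invariants."""


@dataclass(frozen=True)
class LibraryEntry:
    """One named bile acid (analyte) or deuterated internal standard."""

    name: str
    formula: ElementalFormula
    conjugation_class: str
    hydroxyl_class: str
    parent: str | None = None
    reference_rt: float | None = None
    is_internal_standard: bool = False
    deuterium_count: int = 0

    @property
    def label_mass_shift(self) -> float:
        """Isotope-label offset in Da (0 for analytes)."""
        return self.deuterium_count * DEUTERIUM_MASS_SHIFT

    @property
    def mz(self) -> float:
        """Theoretical [M-H]- m/z, including any deuterium label."""
        return mz_mh_minus(self.formula, self.label_mass_shift)


class BileAcidLibrary:
    """A validated collection of analyte and internal-standard entries."""

    def __init__(self, entries: list[LibraryEntry], *, validate: bool = True):
        self.entries = list(entries)
        self._by_name = {e.name: e for e in self.entries}
        if len(self._by_name) != len(self.entries):
            raise LibraryError("duplicate compound names in library")
        if validate:
            self.validate()

    # -- access ------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, name: str) -> LibraryEntry:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def analytes(self) -> list[LibraryEntry]:
        return [e for e in self.entries if not e.is_internal_standard]

    @property
    def internal_standards(self) -> list[LibraryEntry]:
        return [e for e in self.entries if e.is_internal_standard]

    def analytes_with_formula(self, formula: ElementalFormula) -> list[LibraryEntry]:
        return [e for e in self.analytes if e.formula == formula]

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        """Abort load on amidation or hydroxyl-class inconsistencies."""
        for e in self.entries:
            if e.conjugation_class not in CONJUGATION_CLASSES:
                raise LibraryError(f"{e.name}: bad conjugation class {e.conjugation_class!r}")
            if e.hydroxyl_class not in HYDROXYL_CLASSES:
                raise LibraryError(f"{e.name}: bad hydroxyl class {e.hydroxyl_class!r}")
            if e.is_internal_standard:
                # parent here names the unlabeled analog; same neutral formula
                if e.parent and e.parent in self._by_name:
                    if e.formula != self._by_name[e.parent].formula:
                        raise LibraryError(
                            f"{e.name}: labeled formula {e.formula} != analog "
                            f"{e.parent} ({self._by_name[e.parent].formula})"
                        )
            elif e.conjugation_class in _AMIDATION and e.parent and e.parent in self._by_name:
                parent = self._by_name[e.parent]
                expected = apply_delta(parent.formula, _AMIDATION[e.conjugation_class])
                if e.formula != expected:
                    raise LibraryError(
                        f"{e.name}: formula {e.formula} != parent {e.parent} "
                        f"+ {e.conjugation_class} amidation ({expected})"
                    )
            if (
                e.conjugation_class == "unconjugated"
                and e.hydroxyl_class in _HYDROXYL_CORE
                and not e.is_internal_standard
            ):
                if e.formula != _HYDROXYL_CORE[e.hydroxyl_class]:
                    raise LibraryError(
                        f"{e.name}: {e.hydroxyl_class}-OH class expects "
                        f"{_HYDROXYL_CORE[e.hydroxyl_class]}, got {e.formula}"
                    )
            if e.is_internal_standard and e.deuterium_count <= 0:
                raise LibraryError(f"{e.name}: internal standard without deuterium label")

    # -- I/O ---------------------------------------------------------------
    REQUIRED_COLUMNS = (
        "name",
        "formula",
        "conjugation_class",
        "hydroxyl_class",
        "reference_rt_min",
        "is_internal_standard",
        "deuterium_count",
    )

    @classmethod
    def from_csv(cls, path: str | Path, *, validate: bool = True) -> "BileAcidLibrary":
        df = pd.read_csv(path, dtype={"parent": "string"})
        missing = set(cls.REQUIRED_COLUMNS) - set(df.columns)
        if missing:
            raise LibraryError(f"library file missing columns: {sorted(missing)}")
        entries = []
        for row in df.itertuples(index=False):
            rt = getattr(row, "reference_rt_min")
            parent = getattr(row, "parent", None)
            entries.append(
                LibraryEntry(
                    name=str(row.name),
                    formula=parse_formula(str(row.formula)),
                    conjugation_class=str(row.conjugation_class),
                    hydroxyl_class=str(row.hydroxyl_class),
                    parent=None if pd.isna(parent) or parent == "" else str(parent),
                    reference_rt=None if pd.isna(rt) else float(rt),
                    is_internal_standard=bool(int(row.is_internal_standard)),
                    deuterium_count=int(row.deuterium_count),
                )
            )
        return cls(entries, validate=validate)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [e.name for e in self.entries],
                "formula": [str(e.formula) for e in self.entries],
                "conjugation_class": [e.conjugation_class for e in self.entries],
                "hydroxyl_class": [e.hydroxyl_class for e in self.entries],
                "parent": [e.parent for e in self.entries],
                "reference_rt_min": [e.reference_rt for e in self.entries],
                "is_internal_standard": [int(e.is_internal_standard) for e in self.entries],
                "deuterium_count": [e.deuterium_count for e in self.entries],
                "mz_mh_minus": [e.mz for e in self.entries],
            }
        )


def load_default_library() -> BileAcidLibrary:
    """Load the packaged 46-analyte / 14-internal-standard library."""
    ref = importlib.resources.files("bileprof.data") / "bile_acid_library.csv"
    with importlib.resources.as_file(ref) as path:
        lib = BileAcidLibrary.from_csv(path)
    n_analytes, n_is = len(lib.analytes), len(lib.internal_standards)
    if (n_analytes, n_is) != (46, 14):
        raise LibraryError(
            f"packaged library must hold 46 analytes + 14 internal standards, "
            f"found {n_analytes} + {n_is}"
        )
    return lib
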