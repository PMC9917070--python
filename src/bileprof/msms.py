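"""Conjugate-class assignment from negative-mode MS/MS spectra.

Bile-acid steroid cores fragment poorly, but the conjugate moieties give
bright low-mass diagnostic ions:

* glycine conjugates: deprotonated glycine, m/z 74.02;
* taurine conjugates: deprotonated taurine m/z 124.01 plus companion ions
  C2H3SO3- (106.98), HSO3- (80.97) and the SO3 radical anion (79.96);
* sulfate conjugates: hydrogensulfate HSO4-, m/z 96.96.

All diagnostic masses are computed from elemental formulas via
:mod:`bileprof.chem`, never hard-coded, so they stay consistent with the
target-list arithmetic.  A classification that contradicts the exact-mass
assignment can force a re-annotation to an isomeric formula — e.g. a
"GLCA + SO3" feature whose spectrum shows the taurine ion is reinterpreted
as a taurine conjugate of a keto-DCA-type core, which shares the elemental
formula C26H43NO7S.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from pyteomics import mgf as _mgf

from .chem import DELTAS, ELECTRON_MASS, apply_delta, monoisotopic_mass, mz_mh_minus, parse_formula
from .annotate import Annotation
from .library import BileAcidLibrary

__all__ = [
    "Spectrum",
    "DiagnosticRule",
    "DIAGNOSTIC_RULES",
    "GLYCINE_ION",
    "TAURINE_ION",
    "HYDROGENSULFATE_ION",
    "classify_spectrum",
    "reconcile_annotation",
    "read_mgf",
    "write_mgf",
    "classification_report",
]

# Diagnostic product ions, from formulas of the corresponding neutrals.
GLYCINE_ION = mz_mh_minus("C2H5NO2")          # 74.0248
TAURINE_ION = mz_mh_minus("C2H7NO3S")         # 124.0074
VINYLSULFONATE_ION = mz_mh_minus("C2H4O3S")   # 106.9808, C2H3SO3-
BISULFITE_ION = mz_mh_minus("H2SO3")          # 80.9652, HSO3-
SULFITE_RADICAL_ION = monoisotopic_mass(parse_formula("O3S")) + ELECTRON_MASS  # 79.9573, SO3-.
HYDROGENSULFATE_ION = mz_mh_minus("H2SO4")    # 96.9601, HSO4-


@dataclass(frozen=True)
class Spectrum:
    """A centroided MS/MS spectrum with relative intensities (0-100)."""

    key: str
    precursor_mz: float
    peaks: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        peaks = tuple(sorted((float(m), float(i)) for m, i in self.peaks))
        for _, inten in peaks:
            if not 0.0 <= inten <= 100.0:
                raise ValueError("relative intensities must lie in [0, 100]")
        object.__setattr__(self, "peaks", peaks)


@dataclass(frozen=True)
class DiagnosticRule:
    """Call ``class_name`` when >= ``min_ions`` of ``ions`` are present."""

    class_name: str
    ions: tuple[float, ...]
    min_ions: int = 1
    min_rel_intensity: float = 1.0


#: Rule table in precedence order: taurine > sulfate > glycine.  Taurine can
#: fire either on deprotonated taurine alone or on two of its sulfur-bearing
#: companions (a single low-mass S ion is ambiguous with sulfate chemistry).
DIAGNOSTIC_RULES: tuple[DiagnosticRule, ...] = (
    DiagnosticRule("taurine", (TAURINE_ION,), min_ions=1),
    DiagnosticRule(
        "taurine",
        (VINYLSULFONATE_ION, BISULFITE_ION, SULFITE_RADICAL_ION),
        min_ions=2,
    ),
    DiagnosticRule("sulfate", (HYDROGENSULFATE_ION,), min_ions=1),
    DiagnosticRule("glycine", (GLYCINE_ION,), min_ions=1),
)

#: Which biotransformation delta realises each MS/MS class.
_CLASS_DELTA = {
    "glycine": DELTAS["glycine-amidation"],
    "taurine": DELTAS["taurine-amidation"],
    "sulfate": DELTAS["sulfation"],
}


def _ion_present(s: Spectrum, ion: float, tol: float, min_rel: float) -> bool:
    return any(abs(mz - ion) <= tol and inten >= min_rel for mz, inten in s.peaks)


def classify_spectrum(
    s: Spectrum,
    tol: float = 0.01,
    min_rel_intensity: float = 1.0,
) -> str:
    """Classify a spectrum as ``glycine``, ``taurine``, ``sulfate`` or ``none``.

    ``tol`` is an absolute Da window (~100 ppm at m/z 100, matching TOF
    MS/MS low-mass accuracy); peaks below ``min_rel_intensity`` percent are
    ignored.  The result is independent of peak order.
    """
    for rule in DIAGNOSTIC_RULES:
        hits = sum(_ion_present(s, ion, tol, min_rel_intensity) for ion in rule.ions)
        if hits >= rule.min_ions:
            return rule.class_name
    return "none"


def _implied_class(a: Annotation, library: BileAcidLibrary) -> str:
    """The conjugate class implied by the exact-mass assignment."""
    if a.delta_name == "sulfation":
        return "sulfate"
    if a.delta_name == "glucuronidation":
        return "glucuronide"
    name = (a.target_name or "").removesuffix(" isomer")
    if name in library:
        cc = library[name].conjugation_class
        if cc in ("glycine", "taurine"):
            return cc
    return "none"


def reconcile_annotation(
    a: Annotation,
    cls: str,
    library: BileAcidLibrary,
) -> Annotation:
    """Reconcile an exact-mass annotation with its MS/MS classification.

    If the MS/MS class contradicts the mass-based assignment and some
    library analyte + class delta reproduces the annotated formula, the
    annotation is rewritten to that isomeric interpretation and flagged
    ``msms_reassigned``; if no isomeric reinterpretation exists it is kept
    and flagged ``msms_conflict``.  Agreement (or no MS/MS call) leaves the
    annotation unchanged apart from recording the class.
    """
    a = replace(a, flags=list(a.flags), msms_class=cls)
    if cls == "none" or a.target_formula is None:
        return a
    if _implied_class(a, library) == cls:
        return a
    delta = _CLASS_DELTA[cls]
    candidates = []
    for e in library.analytes:
        try:
            if apply_delta(e.formula, delta) == a.target_formula:
                candidates.append(e.name)
        except Exception:
            continue
    if candidates:
        parent = sorted(candidates)[0]
        a.target_name = f"{parent}{delta.label} isomer"
        a.delta_name = delta.name
        a.flags.append("msms_reassigned")
    else:
        a.flags.append("msms_conflict")
    return a


# ---------------------------------------------------------------------------
# MGF I/O (via pyteomics)


def read_mgf(path: str | Path) -> dict[str, Spectrum]:
    """Read an MGF file into spectra keyed by their TITLE."""
    spectra: dict[str, Spectrum] = {}
    with _mgf.MGF(str(path)) as reader:
        for entry in reader:
            title = str(entry["params"].get("title", ""))
            pep = entry["params"].get("pepmass", (0.0,))
            inten = entry["intensity array"]
            top = float(inten.max()) if len(inten) else 1.0
            peaks = tuple(
                (float(m), float(i) / top * 100.0)
                for m, i in zip(entry["m/z array"], inten)
            )
            spectra[title] = Spectrum(key=title, precursor_mz=float(pep[0]), peaks=peaks)
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    entries = [
        {
            "m/z array": [m for m, _ in s.peaks],
            "intensity array": [i for _, i in s.peaks],
            "params": {"title": s.key, "pepmass": s.precursor_mz, "charge": "1-"},
        }
        for s in spectra
    ]
    _mgf.write(entries, str(path), file_mode="w")


def classification_report(
    spectra: Sequence[Spectrum],
    tol: float = 0.01,
    min_rel_intensity: float = 1.0,
):
    """Tabulate per-spectrum classifications with the matched ions."""
    import pandas as pd

    all_ions = {
        "taurine_124": TAURINE_ION,
        "C2H3SO3_107": VINYLSULFONATE_ION,
        "HSO3_81": BISULFITE_ION,
        "SO3_80": SULFITE_RADICAL_ION,
        "HSO4_97": HYDROGENSULFATE_ION,
        "glycine_74": GLYCINE_ION,
    }
    rows = []
    for s in spectra:
        row = {"spectrum_key": s.key, "precursor_mz": s.precursor_mz}
        row["msms_class"] = classify_spectrum(s, tol, min_rel_intensity)
        for label, ion in all_ions.items():
            row[label] = _ion_present(s, ion, tol, min_rel_intensity)
        rows.append(row)
    return pd.DataFrame(rows)
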