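"""Metabolite calling from liver-fraction incubations and plasma cross-matching.

Each bile-acid parent is incubated with S9/microsomal fractions under a
full cofactor set (NADPH-regenerating system + PAPS); control incubations
omit one cofactor each.  A feature in the full run is called a metabolite
when it matches parent + biotransformation within the ppm tolerance and its
area exceeds ``fold_threshold`` times the best matching peak in the
*least-supporting* control — each control still carries the other cofactor,
so an oxidative metabolite remains visible in the no-PAPS control and a
sulfate in the no-NADP+ control; the informative comparison is against the
control lacking the cofactor that produced it.  Which control lacks the
peak also assigns the cofactor dependence (NADPH vs PAPS).

Called metabolites are then matched back to plasma isomer/conjugate
annotations by identical formula and retention-time agreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotate import Feature
from .chem import BiotransformDelta, DELTAS, ElementalFormula, apply_delta, mz_mh_minus, ppm_error
from .library import LibraryEntry

__all__ = [
    "OXIDATIVE_DELTAS",
    "SULFATION_DELTAS",
    "IncubationRun",
    "MetaboliteCall",
    "call_metabolites",
    "cross_match",
    "calls_to_frame",
]

#: Biotransformation vocabulary of oxidative (NADPH-driven) incubations.
OXIDATIVE_DELTAS: tuple[BiotransformDelta, ...] = (
    DELTAS["hydroxylation"],
    DELTAS["dihydroxylation"],
    DELTAS["oxidation-to-keto"],
    DELTAS["dehydrogenation"],
    DELTAS["dehydroxylation"],
)
#: ... and of the sulfation (PAPS-driven) pathway.
SULFATION_DELTAS: tuple[BiotransformDelta, ...] = (DELTAS["sulfation"],)

_NADPH_DELTAS = {d.name for d in OXIDATIVE_DELTAS}

CONDITIONS = ("full", "no_NADP", "no_PAPS")


@dataclass(frozen=True)
class IncubationRun:
    """One incubation of a parent bile acid under one cofactor condition."""

    parent: LibraryEntry
    condition: str
    features: tuple[Feature, ...]

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown incubation condition {self.condition!r}")
        object.__setattr__(self, "features", tuple(self.features))


@dataclass(frozen=True)
class MetaboliteCall:
    parent_name: str
    delta_name: str
    formula: ElementalFormula
    mz: float
    rt: float
    area: float
    ppm: float
    cofactor_dependence: str  # "NADPH" or "PAPS"
    fold_over_control: float


def _control_area(
    controls: Sequence[IncubationRun],
    condition: str,
    mz: float,
    rt: float,
    ppm_tol: float,
    rt_window: float,
) -> float | None:
    """Largest matching control peak area, or None if that control is absent."""
    runs = [c for c in controls if c.condition == condition]
    if not runs:
        return None
    best = 0.0
    for run in runs:
        for f in run.features:
            if abs(ppm_error(f.mz, mz)) <= ppm_tol and abs(f.rt - rt) <= rt_window:
                best = max(best, f.area)
    return best


def call_metabolites(
    full: IncubationRun,
    controls: Sequence[IncubationRun],
    deltas: Sequence[BiotransformDelta] = OXIDATIVE_DELTAS + SULFATION_DELTAS,
    ppm_tol: float = 10.0,
    fold_threshold: float = 5.0,
    rt_window: float = 0.2,
) -> list[MetaboliteCall]:
    """Call cofactor-dependent metabolites of ``full.parent``.

    A feature is called for the delta whose theoretical m/z it matches when
    its area is at least ``fold_threshold`` times the matching peak in the
    weakest control.  Raises if no control run is supplied.
    """
    if not controls:
        raise ValueError("at least one control incubation is required")
    parent = full.parent
    targets: list[tuple[BiotransformDelta, ElementalFormula, float]] = []
    for d in deltas:
        try:
            f = apply_delta(parent.formula, d)
        except Exception:
            continue
        if f == parent.formula:
            continue
        targets.append((d, f, mz_mh_minus(f)))

    calls: list[MetaboliteCall] = []
    for feat in sorted(full.features, key=lambda f: (f.mz, f.rt)):
        for d, formula, mz in targets:
            ppm = ppm_error(feat.mz, mz)
            if abs(ppm) > ppm_tol:
                continue
            areas = {
                cond: _control_area(controls, cond, mz, feat.rt, ppm_tol, rt_window)
                for cond in ("no_NADP", "no_PAPS")
            }
            present = [a for a in areas.values() if a is not None]
            floor = min(present)
            if floor > 0 and feat.area < fold_threshold * floor:
                continue  # comparable signal in every control: background
            absent_nadp = areas["no_NADP"] is not None and feat.area >= fold_threshold * max(
                areas["no_NADP"], 1e-12
            )
            absent_paps = areas["no_PAPS"] is not None and feat.area >= fold_threshold * max(
                areas["no_PAPS"], 1e-12
            )
            if absent_nadp and not absent_paps:
                dependence = "NADPH"
            elif absent_paps and not absent_nadp:
                dependence = "PAPS"
            else:  # missing from both (or only one control supplied): use chemistry
                dependence = "NADPH" if d.name in _NADPH_DELTAS else "PAPS"
            fold = feat.area / floor if floor > 0 else float("inf")
            calls.append(
                MetaboliteCall(
                    parent_name=parent.name,
                    delta_name=d.name,
                    formula=formula,
                    mz=feat.mz,
                    rt=feat.rt,
                    area=feat.area,
                    ppm=ppm,
                    cofactor_dependence=dependence,
                    fold_over_control=fold,
                )
            )
            break  # one call per feature (first matching delta)
    return calls


def cross_match(
    plasma_targets: Sequence,
    calls: Sequence[MetaboliteCall],
    rt_tol: float = 0.30,
) -> list[tuple]:
    """Match plasma isomer/conjugate targets to in-vitro metabolite calls.

    ``plasma_targets`` is any sequence of objects exposing ``formula`` (str
    or ElementalFormula) and ``rt``.  Pairs require identical formula and
    |dRT| <= ``rt_tol``; matching is one-to-one, greedily by nearest RT.
    """
    candidates = []
    for pt in plasma_targets:
        pt_formula = str(getattr(pt, "formula"))
        pt_rt = float(getattr(pt, "rt"))
        for call in calls:
            if str(call.formula) != pt_formula:
                continue
            drt = abs(pt_rt - call.rt)
            if drt <= rt_tol:
                candidates.append((drt, pt, call))
    candidates.sort(key=lambda c: (c[0], str(getattr(c[1], "formula")), c[2].rt))
    matched: list[tuple] = []
    used_targets: set[int] = set()
    used_calls: set[int] = set()
    for drt, pt, call in candidates:
        if id(pt) in used_targets or id(call) in used_calls:
            continue
        used_targets.add(id(pt))
        used_calls.add(id(call))
        matched.append((pt, call, drt))
    return matched


def calls_to_frame(calls: Iterable[MetaboliteCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parent": c.parent_name,
                "delta": c.delta_name,
                "formula": str(c.formula),
                "mz": c.mz,
                "rt_min": c.rt,
                "area": c.area,
                "ppm": c.ppm,
                "cofactor_dependence": c.cofactor_dependence,
                "fold_over_control": c.fold_over_control,
            }
            for c in calls
        ]
    )
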