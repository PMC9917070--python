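"""Tiered assignment of LC-MS features to the bile-acid library.

Three evidence tiers, mirroring semi-targeted HRMS practice:

``identified``
    accurate mass within ``ppm_tol`` of a library analyte *and* retention
    time within ``rt_tol`` of its reference RT;
``isomer``
    accurate mass matches a library formula but the RT does not — the
    feature is some isomer of that formula, named after the library
    exemplar;
``conjugate_tentative``
    accurate mass matches a library formula plus a phase-II mass shift
    (sulfation +SO3, glucuronidation +C6H8O6 by default); no RT evidence.

Features matching nothing within tolerance stay ``unassigned``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chem import BiotransformDelta, DELTAS, ElementalFormula, apply_delta, mz_mh_minus, ppm_error
from .library import BileAcidLibrary

__all__ = [
    "Feature",
    "Target",
    "Annotation",
    "DEFAULT_CONJUGATION_DELTAS",
    "build_target_list",
    "annotate_features",
    "group_isomers",
    "read_feature_csv",
    "annotations_to_frame",
]

#: Conjugation deltas searched by default: the two phase-II conjugations the
#: accurate-mass filter targets.  Glucuronidation stays in the default set
#: even though such conjugates rarely reach significance in plasma.
DEFAULT_CONJUGATION_DELTAS: tuple[BiotransformDelta, ...] = (
    DELTAS["sulfation"],
    DELTAS["glucuronidation"],
)

TIERS = ("identified", "isomer", "conjugate_tentative", "unassigned")


@dataclass(frozen=True)
class Feature:
    """One detected LC-MS peak in one sample."""

    sample_id: str
    mz: float
    rt: float
    area: float
    feature_id: str = ""
    msms_key: str | None = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"feature m/z must be positive, got {self.mz}")
        if self.rt < 0 or self.area < 0:
            raise ValueError("feature RT and area must be non-negative")


@dataclass(frozen=True)
class Target:
    """One entry of the accurate-mass target list.

    ``kind`` is ``"analyte"`` (46 library compounds, each with a reference
    RT) or ``"conjugate"`` (analyte formula + delta; duplicate conjugate
    formulas are collapsed, ``members`` lists the indistinguishable
    parents).
    """

    name: str
    formula: ElementalFormula
    mz: float
    kind: str
    delta_name: str | None = None
    reference_rt: float | None = None
    conjugation_class: str = "unconjugated"
    members: tuple[str, ...] = ()


@dataclass
class Annotation:
    """A feature's tiered library assignment."""

    feature: Feature
    tier: str = "unassigned"
    target_name: str | None = None
    target_formula: ElementalFormula | None = None
    delta_name: str | None = None
    ppm: float | None = None
    delta_rt: float | None = None
    msms_class: str | None = None
    flags: list[str] = field(default_factory=list)


def build_target_list(
    library: BileAcidLibrary,
    deltas: Sequence[BiotransformDelta] = DEFAULT_CONJUGATION_DELTAS,
) -> list[Target]:
    """Expand the analyte library into an accurate-mass target list.

    One target per analyte plus one per analyte x conjugation delta;
    conjugate targets sharing a formula are collapsed into a single target
    (they are indistinguishable by exact mass) named after the
    lexicographically first parent.
    """
    targets: list[Target] = [
        Target(
            name=e.name,
            formula=e.formula,
            mz=mz_mh_minus(e.formula),
            kind="analyte",
            reference_rt=e.reference_rt,
            conjugation_class=e.conjugation_class,
        )
        for e in library.analytes
    ]
    conj: dict[tuple[str, str], list[str]] = {}
    for e in library.analytes:
        for d in deltas:
            try:
                f = apply_delta(e.formula, d)
            except Exception:
                continue  # delta not applicable to this formula
            conj.setdefault((str(f), d.name), []).append(e.name)
    for (fstr, dname), parents in sorted(conj.items()):
        parents = sorted(parents)
        d = DELTAS[dname]
        f = apply_delta(library[parents[0]].formula, d)
        targets.append(
            Target(
                name=f"{parents[0]}{d.label}",
                formula=f,
                mz=mz_mh_minus(f),
                kind="conjugate",
                delta_name=dname,
                members=tuple(parents),
                conjugation_class=library[parents[0]].conjugation_class,
            )
        )
    return targets


def annotate_features(
    features: Iterable[Feature],
    targets: Sequence[Target],
    ppm_tol: float = 10.0,
    rt_tol: float = 0.30,
) -> list[Annotation]:
    """Assign each feature its best target, or leave it unassigned.

    The best target minimises (|ppm|, |dRT|, name); ties on |ppm| occur
    exactly for same-formula analytes, where the nearest reference RT picks
    the exemplar.  Conjugate targets carry no RT and sort after analytes at
    equal |ppm|.  Internally features are sorted by (m/z, RT, sample,
    feature id) so the output is deterministic for any input order.
    """
    if ppm_tol <= 0 or rt_tol <= 0:
        raise ValueError("ppm_tol and rt_tol must be positive")
    feats = sorted(features, key=lambda f: (f.mz, f.rt, f.sample_id, f.feature_id))
    if not targets:
        return [Annotation(feature=f) for f in feats]
    tmz = np.array([t.mz for t in targets])
    out: list[Annotation] = []
    for f in feats:
        ppm = (f.mz - tmz) / tmz * 1e6
        cand = np.flatnonzero(np.abs(ppm) <= ppm_tol)
        if cand.size == 0:
            out.append(Annotation(feature=f))
            continue

        def sort_key(i: int):
            t = targets[i]
            drt = abs(f.rt - t.reference_rt) if t.reference_rt is not None else np.inf
            return (abs(ppm[i]), drt, t.name)

        best = targets[min(cand, key=sort_key)]
        a = Annotation(
            feature=f,
            target_name=best.name,
            target_formula=best.formula,
            delta_name=best.delta_name,
            ppm=ppm_error(f.mz, best.mz),
        )
        if best.kind == "conjugate":
            a.tier = "conjugate_tentative"
        elif best.reference_rt is not None and abs(f.rt - best.reference_rt) <= rt_tol:
            a.tier = "identified"
            a.delta_rt = f.rt - best.reference_rt
        else:
            a.tier = "isomer"
            a.target_name = f"{best.name} isomer"
        out.append(a)
    return out


def group_isomers(annotations: Iterable[Annotation]) -> dict[str, list[Annotation]]:
    """Group isomer-tier annotations by formula, ordered by RT.

    Within a group the order is RT ascending, then feature id (stable
    tie-break for co-eluting members).  Keys are formula strings; each
    group's members share the library exemplar label.
    """
    groups: dict[str, list[Annotation]] = {}
    for a in annotations:
        if a.tier != "isomer":
            continue
        groups.setdefault(str(a.target_formula), []).append(a)
    for members in groups.values():
        members.sort(key=lambda a: (a.feature.rt, a.feature.feature_id, a.feature.sample_id))
    return dict(sorted(groups.items()))


# ---------------------------------------------------------------------------
# I/O

FEATURE_COLUMNS = ("sample_id", "mz", "rt_min", "area")


def read_feature_csv(path: str | Path) -> list[Feature]:
    """Read a feature table (sample_id, mz, rt_min, area[, feature_id, msms_key])."""
    df = pd.read_csv(path)
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: feature table missing columns {sorted(missing)}")
    feats = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            feats.append(
                Feature(
                    sample_id=str(row.sample_id),
                    mz=float(row.mz),
                    rt=float(row.rt_min),
                    area=float(row.area),
                    feature_id=str(getattr(row, "feature_id", "") or f"F{i:05d}"),
                    msms_key=(None if pd.isna(getattr(row, "msms_key", None)) else str(row.msms_key))
                    if "msms_key" in df.columns
                    else None,
                )
            )
        except (TypeError, ValueError) as err:
            raise ValueError(f"{path}: row {i + 2}: {err}") from err
    return feats


def annotations_to_frame(annotations: Iterable[Annotation]) -> pd.DataFrame:
    rows = []
    for a in annotations:
        rows.append(
            {
                "feature_id": a.feature.feature_id,
                "sample_id": a.feature.sample_id,
                "mz": a.feature.mz,
                "rt_min": a.feature.rt,
                "area": a.feature.area,
                "tier": a.tier,
                "target_name": a.target_name,
                "target_formula": None if a.target_formula is None else str(a.target_formula),
                "delta_name": a.delta_name,
                "ppm": a.ppm,
                "delta_rt_min": a.delta_rt,
                "msms_class": a.msms_class,
                "flags": ";".join(a.flags),
            }
        )
    return pd.DataFrame(rows)
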