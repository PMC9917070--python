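"""Internal-standard normalization and dose-group differential screening.

Peak areas are normalised to a deuterated internal standard (IS) chosen per
target (same conjugation class, nearest retention time), and the resulting
area ratios are compared between the lowest and highest dose groups with a
two-sample Student t-test.  A target is flagged significant when p < 0.05
and the fold change of group-mean ratios exceeds 2, the conventional
threshold pair for this kind of screen.  No multiple-testing correction is
applied by default; Benjamini-Hochberg is available by flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .annotate import Annotation, Feature
from .library import BileAcidLibrary, LibraryEntry

__all__ = [
    "StudyDesign",
    "DifferentialResult",
    "ScreenTarget",
    "assign_internal_standard",
    "match_internal_standards",
    "normalize",
    "is_significant",
    "differential_test",
    "cluster_annotations",
    "screen_study",
    "summarize_profile",
]

P_THRESHOLD = 0.05
FC_THRESHOLD = 2.0
#: Maximum RT gap (min) between consecutive same-formula features that still
#: belong to one chromatographic peak group across samples.
CLUSTER_GAP = 0.25


@dataclass(frozen=True)
class StudyDesign:
    """Dose groups -> sample ids."""

    groups: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        groups = {str(g): tuple(s) for g, s in self.groups.items()}
        object.__setattr__(self, "groups", groups)
        seen: set[str] = set()
        for g, samples in groups.items():
            if len(samples) < 2:
                raise ValueError(f"group {g!r} needs >= 2 samples for testing")
            dup = seen & set(samples)
            if dup:
                raise ValueError(f"samples in multiple groups: {sorted(dup)}")
            seen |= set(samples)

    @property
    def samples(self) -> list[str]:
        return [s for g in self.groups.values() for s in g]

    @classmethod
    def from_csv(cls, path: str | Path) -> "StudyDesign":
        df = pd.read_csv(path, dtype=str)
        if not {"sample_id", "group"} <= set(df.columns):
            raise ValueError(f"{path}: design file needs columns sample_id, group")
        groups: dict[str, list[str]] = {}
        for row in df.itertuples(index=False):
            groups.setdefault(str(row.group), []).append(str(row.sample_id))
        return cls({g: tuple(s) for g, s in groups.items()})


@dataclass
class DifferentialResult:
    target_name: str
    group_lo: str
    group_hi: str
    ratios_lo: tuple[float, ...]
    ratios_hi: tuple[float, ...]
    t_stat: float
    p_value: float
    fold_change: float
    significant: bool
    tier: str = ""
    formula: str = ""
    delta_name: str | None = None
    rt: float | None = None
    internal_standard: str | None = None
    flags: list[str] = field(default_factory=list)
    p_adjusted: float | None = None


@dataclass
class ScreenTarget:
    """One screenable quantity: a peak group pooled across samples."""

    label: str
    tier: str
    formula: str
    rt: float
    areas: dict[str, float]  # sample_id -> area (max if several peaks)
    delta_name: str | None = None
    exemplar: str | None = None


# ---------------------------------------------------------------------------
# internal-standard assignment and normalization


def assign_internal_standard(
    analyte_name: str | None,
    conjugation_class: str,
    analyte_rt: float | None,
    is_library: Sequence[LibraryEntry],
) -> LibraryEntry:
    """Pick the IS for a target: labelled analog > same class by RT > RT.

    Deterministic rule: an IS whose parent is the analyte itself wins
    outright; otherwise the IS of the same conjugation class with the
    nearest reference RT; failing that, the globally RT-nearest IS.
    """
    is_entries = [e for e in is_library if e.is_internal_standard]
    if not is_entries:
        raise ValueError("internal-standard library is empty")
    if analyte_name:
        for e in is_entries:
            if e.parent == analyte_name:
                return e

    def rt_dist(e: LibraryEntry) -> tuple[float, str]:
        if analyte_rt is None or e.reference_rt is None:
            return (math.inf, e.name)
        return (abs(e.reference_rt - analyte_rt), e.name)

    same_class = [e for e in is_entries if e.conjugation_class == conjugation_class]
    pool = same_class if same_class else is_entries
    return min(pool, key=rt_dist)


def match_internal_standards(
    features: Iterable[Feature],
    library: BileAcidLibrary,
    ppm_tol: float = 10.0,
    rt_tol: float = 0.30,
) -> tuple[pd.DataFrame, set[str]]:
    """Locate the IS peaks in every sample.

    Returns (table indexed by IS name with one column per sample holding the
    peak area, set of feature ids consumed as IS peaks).  Missing IS peaks
    are NaN.
    """
    feats = list(features)
    table: dict[str, dict[str, float]] = {}
    used: set[str] = set()
    for e in library.internal_standards:
        row: dict[str, float] = {}
        for f in feats:
            if abs((f.mz - e.mz) / e.mz * 1e6) <= ppm_tol and (
                e.reference_rt is None or abs(f.rt - e.reference_rt) <= rt_tol
            ):
                if f.area > row.get(f.sample_id, -1.0):
                    row[f.sample_id] = f.area
                used.add(f.feature_id)
        table[e.name] = row
    df = pd.DataFrame(table).T
    df.index.name = "internal_standard"
    return df, used


def normalize(
    analyte_areas: Mapping[str, float],
    is_areas: Mapping[str, float],
) -> tuple[dict[str, float], list[str]]:
    """Per-sample area ratios analyte/IS.

    Samples where the IS peak is missing or non-positive get no ratio and
    are returned in the flagged list.
    """
    ratios: dict[str, float] = {}
    flagged: list[str] = []
    for sample, area in analyte_areas.items():
        is_area = is_areas.get(sample)
        if is_area is None or not np.isfinite(is_area) or is_area <= 0:
            flagged.append(sample)
            continue
        ratios[sample] = area / is_area
    return ratios, flagged


# ---------------------------------------------------------------------------
# differential testing


def is_significant(
    p_value: float,
    fold_change: float,
    p_threshold: float = P_THRESHOLD,
    fc_threshold: float = FC_THRESHOLD,
    direction_agnostic: bool = False,
) -> bool:
    """The screening rule: p below threshold AND fold change beyond it."""
    return bool(
        p_value < p_threshold
        and np.isfinite(fold_change)
        and (
            fold_change > fc_threshold
            or (direction_agnostic and fold_change < 1.0 / fc_threshold)
        )
    )


def differential_test(
    ratios_lo: Sequence[float],
    ratios_hi: Sequence[float],
    group_lo: str = "lo",
    group_hi: str = "hi",
    target_name: str = "",
    equal_var: bool = True,
    p_threshold: float = P_THRESHOLD,
    fc_threshold: float = FC_THRESHOLD,
    direction_agnostic: bool = False,
) -> DifferentialResult:
    """Two-sample t-test plus fold change of group-mean area ratios.

    Student's equal-variance test by default (``equal_var=False`` gives
    Welch).  Fold change is mean(hi)/mean(lo) on the raw ratio scale.
    Degenerate cases: both groups constant and equal -> p = 1; mean(lo) = 0
    -> fold change undefined and flagged.
    """
    lo = np.asarray(ratios_lo, dtype=float)
    hi = np.asarray(ratios_hi, dtype=float)
    lo = lo[np.isfinite(lo)]
    hi = hi[np.isfinite(hi)]
    if lo.size < 2 or hi.size < 2:
        raise ValueError("need >= 2 finite ratios per group")
    flags: list[str] = []
    if lo.std(ddof=1) == 0.0 and hi.std(ddof=1) == 0.0:
        t_stat, p = (0.0, 1.0) if lo.mean() == hi.mean() else (math.inf, 0.0)
        flags.append("zero_variance")
    else:
        t_stat, p = _sps.ttest_ind(hi, lo, equal_var=equal_var)
        t_stat, p = float(t_stat), float(p)
    if lo.mean() == 0.0:
        fc = math.nan
        flags.append("fc_undefined")
    else:
        fc = float(hi.mean() / lo.mean())
    significant = is_significant(p, fc, p_threshold, fc_threshold, direction_agnostic)
    return DifferentialResult(
        target_name=target_name,
        group_lo=group_lo,
        group_hi=group_hi,
        ratios_lo=tuple(lo),
        ratios_hi=tuple(hi),
        t_stat=t_stat,
        p_value=p,
        fold_change=fc,
        significant=significant,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# pooling annotated features into screenable targets


def _split_by_rt_gap(annotations: list[Annotation], gap: float) -> list[list[Annotation]]:
    annotations = sorted(annotations, key=lambda a: (a.feature.rt, a.feature.feature_id))
    clusters: list[list[Annotation]] = []
    for a in annotations:
        if clusters and a.feature.rt - clusters[-1][-1].feature.rt <= gap:
            clusters[-1].append(a)
        else:
            clusters.append([a])
    return clusters


def cluster_annotations(
    annotations: Iterable[Annotation],
    gap: float = CLUSTER_GAP,
) -> list[ScreenTarget]:
    """Pool annotations into per-target peak groups across samples.

    Identified-tier features group by library name directly; isomer and
    conjugate tiers group by formula and are split into RT clusters
    wherever consecutive (sorted) RTs are more than ``gap`` minutes apart.
    Within a cluster each sample contributes its largest-area feature.
    """
    by_key: dict[tuple[str, str, str], list[Annotation]] = {}
    for a in annotations:
        if a.tier in ("unassigned",) or a.target_name is None:
            continue
        key = (a.tier, str(a.target_formula), a.target_name)
        by_key.setdefault(key, []).append(a)

    targets: list[ScreenTarget] = []
    for (tier, formula, name), members in sorted(by_key.items()):
        clusters = [members] if tier == "identified" else _split_by_rt_gap(members, gap)
        for cluster in clusters:
            rts = [a.feature.rt for a in cluster]
            rt = float(np.median(rts))
            areas: dict[str, float] = {}
            for a in cluster:
                s = a.feature.sample_id
                areas[s] = max(areas.get(s, 0.0), a.feature.area)
            label = name if tier == "identified" else f"{name} @ {rt:.1f} min"
            exemplar = name.removesuffix(" isomer")
            targets.append(
                ScreenTarget(
                    label=label,
                    tier=tier,
                    formula=formula,
                    rt=rt,
                    areas=areas,
                    delta_name=cluster[0].delta_name,
                    exemplar=exemplar,
                )
            )
    targets.sort(key=lambda t: (t.tier, t.formula, t.rt, t.label))
    return targets


def _target_conjugation_class(target: ScreenTarget, library: BileAcidLibrary) -> str:
    name = target.exemplar or ""
    if name in library:
        return library[name].conjugation_class
    # conjugate names look like "CDCA+SO3": classify by the parent part
    base = name.split("+")[0]
    if base in library:
        return library[base].conjugation_class
    return "unconjugated"


def screen_study(
    annotations: Iterable[Annotation],
    is_areas: pd.DataFrame,
    design: StudyDesign,
    library: BileAcidLibrary,
    contrast: tuple[str, str] | None = None,
    gap: float = CLUSTER_GAP,
    p_threshold: float = P_THRESHOLD,
    fc_threshold: float = FC_THRESHOLD,
    equal_var: bool = True,
    direction_agnostic: bool = False,
    bh_correct: bool = False,
) -> list[DifferentialResult]:
    """Run the full lo-vs-hi differential screen over annotated features.

    ``contrast`` defaults to (lowest, highest) dose by numeric group label.
    Targets with fewer than two normalised ratios on either side are
    dropped with a flag rather than tested.
    """
    if contrast is None:
        labels = sorted(design.groups, key=lambda g: float(g))
        contrast = (labels[0], labels[-1])
    lo_label, hi_label = contrast
    results: list[DifferentialResult] = []
    for target in cluster_annotations(annotations, gap=gap):
        is_entry = assign_internal_standard(
            target.exemplar if target.exemplar in library else None,
            _target_conjugation_class(target, library),
            target.rt,
            library.internal_standards,
        )
        is_row = is_areas.loc[is_entry.name].to_dict() if is_entry.name in is_areas.index else {}
        ratios, _flagged = normalize(target.areas, is_row)
        lo = [ratios[s] for s in design.groups[lo_label] if s in ratios]
        hi = [ratios[s] for s in design.groups[hi_label] if s in ratios]
        if len(lo) < 2 or len(hi) < 2:
            continue
        res = differential_test(
            lo,
            hi,
            group_lo=lo_label,
            group_hi=hi_label,
            target_name=target.label,
            equal_var=equal_var,
            p_threshold=p_threshold,
            fc_threshold=fc_threshold,
            direction_agnostic=direction_agnostic,
        )
        res.tier = target.tier
        res.formula = target.formula
        res.delta_name = target.delta_name
        res.rt = target.rt
        res.internal_standard = is_entry.name
        results.append(res)
    if bh_correct and results:
        from statsmodels.stats.multitest import multipletests

        _, p_adj, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
        for r, q in zip(results, p_adj):
            r.p_adjusted = float(q)
    return results


def summarize_profile(
    results: Iterable[DifferentialResult],
    tiers: Sequence[str] = ("identified", "isomer", "conjugate_tentative"),
) -> dict[str, int]:
    """Count significant targets per annotation tier (and conjugate delta)."""
    counts = {tier: 0 for tier in tiers}
    counts["sulfate_conjugates"] = 0
    counts["glucuronide_conjugates"] = 0
    for r in results:
        if not r.significant:
            continue
        if r.tier in counts:
            counts[r.tier] += 1
        if r.tier == "conjugate_tentative":
            if r.delta_name == "sulfation":
                counts["sulfate_conjugates"] += 1
            elif r.delta_name == "glucuronidation":
                counts["glucuronide_conjugates"] += 1
    return counts


def results_to_frame(results: Iterable[DifferentialResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "target_name": r.target_name,
                "tier": r.tier,
                "formula": r.formula,
                "delta_name": r.delta_name,
                "rt_min": r.rt,
                "internal_standard": r.internal_standard,
                "group_lo": r.group_lo,
                "group_hi": r.group_hi,
                "n_lo": len(r.ratios_lo),
                "n_hi": len(r.ratios_hi),
                "t_stat": r.t_stat,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
                "fold_change": r.fold_change,
                "significant": r.significant,
                "flags": ";".join(r.flags),
            }
        )
    return pd.DataFrame(rows)
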