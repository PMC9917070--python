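"""End-to-end orchestration of the semi-targeted profiling workflow.

Stage order mirrors the bench workflow: locate internal-standard peaks,
assign every remaining feature to the library (identified / isomer /
conjugate tiers), verify conjugate classes against MS/MS diagnostic ions,
run the internal-standard-normalised dose screen, call in-vitro metabolites
and cross-match them to the significant plasma targets.  Every run can
emit a manifest (config snapshot, seed, input paths, output checksums) so
reruns are reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .annotate import (
    Annotation,
    Feature,
    annotate_features,
    annotations_to_frame,
    build_target_list,
)
from .invitro import IncubationRun, call_metabolites, calls_to_frame, cross_match
from .library import BileAcidLibrary, load_default_library
from .msms import Spectrum, classify_spectrum, reconcile_annotation
from .stats import (
    DifferentialResult,
    StudyDesign,
    match_internal_standards,
    results_to_frame,
    screen_study,
    summarize_profile,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """One source of truth for every tolerance and threshold in the run."""

    ppm_tol: float = 10.0
    rt_tol: float = 0.30
    cluster_gap: float = 0.25
    p_threshold: float = 0.05
    fc_threshold: float = 2.0
    msms_tol: float = 0.01
    msms_min_rel_intensity: float = 1.0
    invitro_fold_threshold: float = 5.0
    invitro_rt_window: float = 0.2
    contrast: tuple[str, str] | None = None
    equal_var: bool = True
    direction_agnostic: bool = False
    bh_correct: bool = False


@dataclass
class PipelineResult:
    annotations: list[Annotation]
    results: list[DifferentialResult]
    summary: dict
    is_areas: pd.DataFrame
    msms_report: pd.DataFrame | None = None
    calls: list = field(default_factory=list)
    matches: list = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    @property
    def annotation_frame(self) -> pd.DataFrame:
        return annotations_to_frame(self.annotations)

    @property
    def results_frame(self) -> pd.DataFrame:
        return results_to_frame(self.results)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass(frozen=True)
class _PlasmaTarget:
    """Significant plasma target exposed to the in-vitro cross-match."""

    label: str
    tier: str
    formula: str
    rt: float


def run_pipeline(
    features: Sequence[Feature],
    design: StudyDesign,
    library: BileAcidLibrary | None = None,
    spectra: Mapping[str, Spectrum] | None = None,
    invitro_runs: Sequence[IncubationRun] | None = None,
    config: PipelineConfig = PipelineConfig(),
    outdir: str | Path | None = None,
    seed: int | None = None,
    input_paths: Mapping[str, str] | None = None,
) -> PipelineResult:
    """Run annotation, MS/MS reconciliation, screening and cross-matching."""
    library = library or load_default_library()
    targets = build_target_list(library)

    # 1. consume internal-standard peaks
    is_areas, used = match_internal_standards(
        features, library, ppm_tol=config.ppm_tol, rt_tol=config.rt_tol
    )
    analyte_features = [f for f in features if f.feature_id not in used]

    # 2. tiered annotation
    annotations = annotate_features(
        analyte_features, targets, ppm_tol=config.ppm_tol, rt_tol=config.rt_tol
    )

    # 3. MS/MS diagnostic-ion reconciliation
    msms_report = None
    if spectra:
        reconciled = []
        report_rows = []
        for a in annotations:
            key = a.feature.msms_key
            if key and key in spectra:
                cls = classify_spectrum(
                    spectra[key], tol=config.msms_tol,
                    min_rel_intensity=config.msms_min_rel_intensity,
                )
                before = a.target_name
                if a.tier in ("conjugate_tentative", "isomer"):
                    a = reconcile_annotation(a, cls, library)
                else:
                    a.msms_class = cls
                report_rows.append(
                    {
                        "spectrum_key": key,
                        "feature_id": a.feature.feature_id,
                        "tier": a.tier,
                        "assigned": before,
                        "msms_class": cls,
                        "final": a.target_name,
                        "flags": ";".join(a.flags),
                    }
                )
            reconciled.append(a)
        annotations = reconciled
        msms_report = pd.DataFrame(report_rows)

    # 4. differential screen
    results = screen_study(
        annotations,
        is_areas,
        design,
        library,
        contrast=config.contrast,
        gap=config.cluster_gap,
        p_threshold=config.p_threshold,
        fc_threshold=config.fc_threshold,
        equal_var=config.equal_var,
        direction_agnostic=config.direction_agnostic,
        bh_correct=config.bh_correct,
    )

    # 5. in-vitro metabolite calls and RT cross-match
    calls, matches = [], []
    if invitro_runs:
        by_parent: dict[str, dict[str, list[IncubationRun]]] = {}
        for run in invitro_runs:
            by_parent.setdefault(run.parent.name, {}).setdefault(run.condition, []).append(run)
        for parent_name in sorted(by_parent):
            runs = by_parent[parent_name]
            full_runs = runs.get("full", [])
            controls = [r for c in ("no_NADP", "no_PAPS") for r in runs.get(c, [])]
            for full in full_runs:
                calls.extend(
                    call_metabolites(
                        full,
                        controls,
                        ppm_tol=config.ppm_tol,
                        fold_threshold=config.invitro_fold_threshold,
                        rt_window=config.invitro_rt_window,
                    )
                )
        plasma_side = [
            _PlasmaTarget(label=r.target_name, tier=r.tier, formula=r.formula, rt=r.rt)
            for r in results
            if r.significant and r.tier in ("isomer", "conjugate_tentative") and r.rt is not None
        ]
        matches = cross_match(plasma_side, calls, rt_tol=config.rt_tol)

    # 6. summary counts
    counts = summarize_profile(results)
    identified_names = sorted(
        {a.target_name for a in annotations if a.tier == "identified" and a.target_name}
    )
    summary = {
        "n_features": len(list(features)),
        "n_identified_standards": len(identified_names),
        "n_unassigned_features": sum(a.tier == "unassigned" for a in annotations),
        "significant_identified": counts["identified"],
        "significant_isomers": counts["isomer"],
        "significant_conjugates": counts["conjugate_tentative"],
        "significant_sulfate_conjugates": counts["sulfate_conjugates"],
        "significant_glucuronide_conjugates": counts["glucuronide_conjugates"],
        "invitro_calls": len(calls),
        "invitro_crossmatches": len(matches),
    }

    result = PipelineResult(
        annotations=annotations,
        results=results,
        summary=summary,
        is_areas=is_areas,
        msms_report=msms_report,
        calls=calls,
        matches=matches,
    )
    if outdir is not None:
        result.manifest = _write_outputs(
            result, Path(outdir), config, seed=seed, input_paths=input_paths
        )
    return result


def _write_outputs(
    result: PipelineResult,
    outdir: Path,
    config: PipelineConfig,
    seed: int | None,
    input_paths: Mapping[str, str] | None,
) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    result.annotation_frame.to_csv(outdir / "annotations.csv", index=False)
    written["annotations"] = outdir / "annotations.csv"
    result.results_frame.to_csv(outdir / "differential.csv", index=False)
    written["differential"] = outdir / "differential.csv"
    result.is_areas.to_csv(outdir / "internal_standards.csv")
    written["internal_standards"] = outdir / "internal_standards.csv"
    if result.msms_report is not None:
        result.msms_report.to_csv(outdir / "msms_reconciliation.csv", index=False)
        written["msms_reconciliation"] = outdir / "msms_reconciliation.csv"
    if result.calls:
        calls_to_frame(result.calls).to_csv(outdir / "invitro_calls.csv", index=False)
        written["invitro_calls"] = outdir / "invitro_calls.csv"
        pd.DataFrame(
            [
                {
                    "plasma_target": pt.label,
                    "plasma_tier": pt.tier,
                    "formula": pt.formula,
                    "plasma_rt": pt.rt,
                    "invitro_parent": call.parent_name,
                    "invitro_delta": call.delta_name,
                    "invitro_rt": call.rt,
                    "delta_rt": drt,
                }
                for pt, call, drt in result.matches
            ]
        ).to_csv(outdir / "invitro_crossmatch.csv", index=False)
        written["invitro_crossmatch"] = outdir / "invitro_crossmatch.csv"
    pd.DataFrame([result.summary]).to_csv(outdir / "summary.csv", index=False)
    written["summary"] = outdir / "summary.csv"

    report_lines = ["semi-targeted bile-acid profiling report", "=" * 42]
    for key, value in result.summary.items():
        report_lines.append(f"{key:36s} {value}")
    (outdir / "report.txt").write_text("\n".join(report_lines) + "\n")
    written["report"] = outdir / "report.txt"

    manifest = {
        "package_version": __version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "config": dataclasses.asdict(config),
        "input_paths": dict(input_paths or {}),
        "outputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in written.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
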