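"""Truth-annotated synthetic LC-HRMS bile-acid studies.

Generates the study structure the analysis modules assume: a 4-dose x
3-replicate plasma profiling experiment over the packaged 46-standard /
14-internal-standard library, with planted isomers, sulfate and glucuronide
conjugates, decoy features, diagnostic MS/MS spectra, and in-vitro
liver-fraction incubation runs — all with a per-feature ground-truth table.

Noise model: peak areas are multiplicative-lognormal around
baseline x dose-multiplier (areas are positive and CV-scaled); m/z errors
are ppm-scale truncated Gaussians; retention times jitter by a truncated
Gaussian around the planted value.  Dose effects follow a log-linear dose
response anchored so the highest/lowest dose ratio equals the planted fold
change.  Identical config + seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .annotate import Feature
from .chem import DELTAS, ElementalFormula, apply_delta, mz_mh_minus, parse_formula
from .invitro import IncubationRun
from .library import BileAcidLibrary, load_default_library
from .msms import (
    BISULFITE_ION,
    GLYCINE_ION,
    HYDROGENSULFATE_ION,
    SULFITE_RADICAL_ION,
    TAURINE_ION,
    VINYLSULFONATE_ION,
    Spectrum,
)
from .stats import StudyDesign

__all__ = ["ScenarioConfig", "PlasmaStudy", "make_plasma_study", "make_invitro_suite"]


@dataclass
class ScenarioConfig:
    """All knobs of the synthetic study; defaults ship in a scenario file."""

    groups: tuple[str, ...] = ("75", "150", "300", "600")
    replicates: int = 3
    analytical_cv: float = 0.10
    baseline_log_cv: float = 0.5
    mass_ppm_sigma: float = 3.0
    mass_ppm_max: float = 5.0
    rt_jitter_sigma: float = 0.05
    rt_jitter_max: float = 0.10
    lod: float = 500.0
    decoy_count: int = 15
    decoy_mz_range: tuple[float, float] = (350.0, 550.0)
    decoy_exclusion_ppm: float = 25.0
    is_nominal_area: float = 50_000.0
    standard_baseline_area: float = 100_000.0
    isomer_baseline_area: float = 20_000.0
    conjugate_baseline_area: float = 30_000.0
    decoy_area: float = 8_000.0
    invitro_leakage: float = 0.0
    invitro_parent_area: float = 500_000.0
    invitro_metabolite_area: float = 50_000.0
    cross_pathway_in_controls: bool = True
    absent_standards: tuple[str, ...] = ()
    effects: Mapping[str, float] = field(default_factory=dict)
    isomers: tuple[Mapping, ...] = ()
    conjugates: tuple[Mapping, ...] = ()
    invitro_plan: Mapping[str, Sequence[Mapping]] = field(default_factory=dict)
    sample_drift: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.analytical_cv < 0 or self.replicates < 2:
            raise ValueError("need non-negative CV and >= 2 replicates")
        for name, fc in self.effects.items():
            if fc <= 0:
                raise ValueError(f"non-positive fold change for {name}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "ScenarioConfig":
        kwargs = dict(raw)
        for key in ("groups", "absent_standards"):
            if key in kwargs:
                kwargs[key] = tuple(str(x) for x in kwargs[key])
        for key in ("isomers", "conjugates"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        if "decoy_mz_range" in kwargs:
            kwargs["decoy_mz_range"] = tuple(kwargs["decoy_mz_range"])
        if "effects" in kwargs:
            kwargs["effects"] = {str(k): float(v) for k, v in kwargs["effects"].items()}
        return cls(**kwargs)

    @classmethod
    def default(cls) -> "ScenarioConfig":
        ref = importlib.resources.files("bileprof.data") / "scenario_default.yaml"
        with importlib.resources.as_file(ref) as path:
            return cls.from_yaml(path)

    @property
    def samples(self) -> list[tuple[str, str]]:
        """(group, sample_id) pairs, e.g. ("75", "S75r1")."""
        return [
            (g, f"S{g}r{i}") for g in self.groups for i in range(1, self.replicates + 1)
        ]

    def design(self) -> StudyDesign:
        groups: dict[str, list[str]] = {g: [] for g in self.groups}
        for g, s in self.samples:
            groups[g].append(s)
        return StudyDesign({g: tuple(s) for g, s in groups.items()})

    def dose_multiplier(self, fc: float, group: str) -> float:
        """Log-linear dose response: 1 at the lowest dose, fc at the highest."""
        doses = np.array([float(g) for g in self.groups])
        lo, hi = doses.min(), doses.max()
        if fc == 1.0 or hi == lo:
            return 1.0
        frac = (np.log(float(group)) - np.log(lo)) / (np.log(hi) - np.log(lo))
        return float(fc**frac)


@dataclass
class PlasmaStudy:
    """A generated plasma study: features, spectra, design, ground truth."""

    features: pd.DataFrame  # sample_id, feature_id, mz, rt_min, area, msms_key
    truth: pd.DataFrame
    design: StudyDesign
    spectra: list[Spectrum]
    config: ScenarioConfig

    def feature_objects(self) -> list[Feature]:
        return [
            Feature(
                sample_id=row.sample_id,
                mz=row.mz,
                rt=row.rt_min,
                area=row.area,
                feature_id=row.feature_id,
                msms_key=row.msms_key if isinstance(row.msms_key, str) else None,
            )
            for row in self.features.itertuples(index=False)
        ]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        from .msms import write_mgf

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "features": outdir / "features.csv",
            "truth": outdir / "truth.csv",
            "design": outdir / "design.csv",
            "spectra": outdir / "spectra.mgf",
        }
        self.features.to_csv(paths["features"], index=False)
        self.truth.to_csv(paths["truth"], index=False)
        pd.DataFrame(
            [(s, g) for g, ss in self.design.groups.items() for s in ss],
            columns=["sample_id", "group"],
        ).to_csv(paths["design"], index=False)
        if self.spectra:
            write_mgf(self.spectra, paths["spectra"])
        else:
            paths.pop("spectra")
        return paths


def _truncated_normal(
    rng: np.random.Generator, sigma: float, bound: float, size: int
) -> np.ndarray:
    """Gaussian draws redrawn (not clipped) until within +/- bound."""
    if sigma <= 0:
        return np.zeros(size)
    out = rng.normal(0.0, sigma, size)
    bad = np.abs(out) > bound
    while bad.any():
        out[bad] = rng.normal(0.0, sigma, int(bad.sum()))
        bad = np.abs(out) > bound
    return out


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-1 multiplicative lognormal noise with the given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(-0.5 * sigma**2, sigma, size)


@dataclass(frozen=True)
class _Planted:
    compound: str
    kind: str  # standard / internal_standard / isomer / conjugate / decoy
    tier_expected: str
    formula: str
    mz: float
    rt: float
    baseline: float
    fc: float
    msms_class: str | None
    delta_name: str | None = None


def _spectrum_peaks(rng: np.random.Generator, cls: str, precursor: float) -> tuple:
    """Diagnostic + sub-1% background peaks for a conjugate class."""
    peaks: list[tuple[float, float]] = []
    jit = lambda: rng.normal(0.0, 0.002)
    if cls == "glycine":
        peaks.append((GLYCINE_ION + jit(), rng.uniform(40, 90)))
    elif cls == "taurine":
        peaks.append((TAURINE_ION + jit(), rng.uniform(60, 95)))
        peaks.append((VINYLSULFONATE_ION + jit(), rng.uniform(10, 40)))
        peaks.append((BISULFITE_ION + jit(), rng.uniform(10, 40)))
        peaks.append((SULFITE_RADICAL_ION + jit(), rng.uniform(5, 30)))
    elif cls == "sulfate":
        peaks.append((HYDROGENSULFATE_ION + jit(), rng.uniform(40, 85)))
    # weak steroid-backbone fragments, all below the 1% call threshold
    for _ in range(3):
        peaks.append((rng.uniform(150.0, max(200.0, precursor - 20.0)), rng.uniform(0.1, 0.9)))
    peaks.append((precursor, 100.0))
    return tuple(peaks)


def _plan_compounds(cfg: ScenarioConfig, library: BileAcidLibrary, rng) -> list[_Planted]:
    planted: list[_Planted] = []
    absent = set(cfg.absent_standards)
    for e in library.analytes:
        if e.name in absent:
            continue
        baseline = cfg.standard_baseline_area * _lognormal_noise(rng, cfg.baseline_log_cv, 1)[0]
        cls = e.conjugation_class if e.conjugation_class in ("glycine", "taurine") else None
        planted.append(
            _Planted(
                compound=e.name,
                kind="standard",
                tier_expected="identified",
                formula=str(e.formula),
                mz=e.mz,
                rt=float(e.reference_rt),
                baseline=baseline,
                fc=float(cfg.effects.get(e.name, 1.0)),
                msms_class=cls,
            )
        )
    for e in library.internal_standards:
        planted.append(
            _Planted(
                compound=e.name,
                kind="internal_standard",
                tier_expected="internal_standard",
                formula=str(e.formula),
                mz=e.mz,
                rt=float(e.reference_rt),
                baseline=cfg.is_nominal_area,
                fc=1.0,
                msms_class=None,
            )
        )
    for i, row in enumerate(cfg.isomers):
        f = parse_formula(str(row["formula"]))
        baseline = cfg.isomer_baseline_area * _lognormal_noise(rng, cfg.baseline_log_cv, 1)[0]
        planted.append(
            _Planted(
                compound=f"isomer_{i:02d}_{row['formula']}",
                kind="isomer",
                tier_expected="isomer",
                formula=str(f),
                mz=mz_mh_minus(f),
                rt=float(row["rt"]),
                baseline=baseline,
                fc=float(row["fc"]),
                msms_class=row.get("msms_class"),
            )
        )
    for i, row in enumerate(cfg.conjugates):
        parent = library[str(row["parent"])]
        delta = DELTAS[str(row["delta"])]
        f = apply_delta(parent.formula, delta)
        baseline = cfg.conjugate_baseline_area * _lognormal_noise(rng, cfg.baseline_log_cv, 1)[0]
        default_cls = "sulfate" if delta.name == "sulfation" else None
        planted.append(
            _Planted(
                compound=f"{row['parent']}{delta.label}@{row['rt']}",
                kind="conjugate",
                tier_expected="conjugate_tentative",
                formula=str(f),
                mz=mz_mh_minus(f),
                rt=float(row["rt"]),
                baseline=baseline,
                fc=float(row["fc"]),
                msms_class=row.get("msms_class", default_cls),
                delta_name=delta.name,
            )
        )
    # decoys: unannotatable masses away from every target (analyte, conjugate
    # of any vocabulary delta, and internal standard)
    protected = [e.mz for e in library.entries]
    for e in library.analytes:
        for d in DELTAS.values():
            try:
                protected.append(mz_mh_minus(apply_delta(e.formula, d)))
            except Exception:
                continue
    for p in planted:
        protected.append(p.mz)
    protected_arr = np.array(sorted(protected))
    lo_mz, hi_mz = cfg.decoy_mz_range
    n_drawn = 0
    while n_drawn < cfg.decoy_count:
        mz = float(rng.uniform(lo_mz, hi_mz))
        if np.min(np.abs(mz - protected_arr)) / mz * 1e6 <= cfg.decoy_exclusion_ppm:
            continue
        planted.append(
            _Planted(
                compound=f"decoy_{n_drawn:02d}",
                kind="decoy",
                tier_expected="unassigned",
                formula="",
                mz=mz,
                rt=float(rng.uniform(4.0, 44.0)),
                baseline=cfg.decoy_area,
                fc=1.0,
                msms_class=None,
            )
        )
        n_drawn += 1
    return planted


def make_plasma_study(
    cfg: ScenarioConfig | None = None,
    seed: int = 0,
    library: BileAcidLibrary | None = None,
    with_msms: bool = True,
) -> PlasmaStudy:
    """Generate a complete plasma dose-response study with ground truth."""
    cfg = cfg or ScenarioConfig.default()
    library = library or load_default_library()
    rng = np.random.default_rng(seed)
    planted = _plan_compounds(cfg, library, rng)
    samples = cfg.samples
    n = len(samples)
    drift = cfg.sample_drift or {}

    rows = []
    truth_rows = []
    spectra: list[Spectrum] = []
    for p in planted:
        area_noise = _lognormal_noise(rng, cfg.analytical_cv, n)
        ppm_err = _truncated_normal(rng, cfg.mass_ppm_sigma, cfg.mass_ppm_max, n)
        rt_jit = _truncated_normal(rng, cfg.rt_jitter_sigma, cfg.rt_jitter_max, n)
        for j, (group, sample_id) in enumerate(samples):
            mult = cfg.dose_multiplier(p.fc, group)
            area = p.baseline * mult * area_noise[j] * float(drift.get(sample_id, 1.0))
            if area < cfg.lod:
                continue
            fid = f"{sample_id}_{p.compound}"
            mz = p.mz * (1.0 + ppm_err[j] * 1e-6)
            rt = p.rt + rt_jit[j]
            msms_key = None
            if with_msms and p.msms_class is not None:
                msms_key = fid
                spectra.append(
                    Spectrum(
                        key=fid,
                        precursor_mz=mz,
                        peaks=_spectrum_peaks(rng, p.msms_class, mz),
                    )
                )
            rows.append((sample_id, fid, mz, rt, area, msms_key))
            truth_rows.append(
                (
                    fid,
                    sample_id,
                    p.compound,
                    p.kind,
                    p.tier_expected,
                    p.formula,
                    p.delta_name,
                    p.fc,
                    p.baseline,
                    p.mz,
                    p.rt,
                    ppm_err[j],
                    p.msms_class,
                )
            )

    features = pd.DataFrame(
        rows, columns=["sample_id", "feature_id", "mz", "rt_min", "area", "msms_key"]
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "feature_id",
            "sample_id",
            "compound",
            "kind",
            "tier_expected",
            "formula",
            "delta_name",
            "planted_fc",
            "baseline_area",
            "theoretical_mz",
            "nominal_rt",
            "ppm_error_true",
            "msms_class_true",
        ],
    )
    return PlasmaStudy(
        features=features, truth=truth, design=cfg.design(), spectra=spectra, config=cfg
    )


def make_invitro_suite(
    cfg: ScenarioConfig | None = None,
    seed: int = 0,
    library: BileAcidLibrary | None = None,
) -> tuple[list[IncubationRun], pd.DataFrame]:
    """Generate full / no-NADP+ / no-PAPS incubation runs per planned parent.

    Metabolites appear in the full run per the scenario plan; each control
    lacks the metabolites of its missing cofactor (down to
    ``invitro_leakage`` x the full area) but, reflecting the incubation
    chemistry, keeps the other pathway's metabolites unless
    ``cross_pathway_in_controls`` is off.
    """
    cfg = cfg or ScenarioConfig.default()
    library = library or load_default_library()
    rng = np.random.default_rng(seed)
    runs: list[IncubationRun] = []
    truth_rows = []
    for parent_name in cfg.invitro_plan:
        if parent_name not in library:
            raise KeyError(f"unknown incubation parent {parent_name!r}")
        parent = library[parent_name]
        mets = []  # (delta, formula, mz, rt, area, pathway)
        for step in cfg.invitro_plan[parent_name]:
            delta = DELTAS[str(step["delta"])]
            formula = apply_delta(parent.formula, delta)
            pathway = "PAPS" if delta.name == "sulfation" else "NADPH"
            for rt in step["rts"]:
                area = cfg.invitro_metabolite_area * _lognormal_noise(
                    rng, cfg.analytical_cv, 1
                )[0]
                mets.append((delta, formula, mz_mh_minus(formula), float(rt), area, pathway))
                truth_rows.append(
                    (parent_name, delta.name, str(formula), float(rt), pathway)
                )
        for condition in ("full", "no_NADP", "no_PAPS"):
            feats = []
            parent_area = cfg.invitro_parent_area * _lognormal_noise(rng, cfg.analytical_cv, 1)[0]
            ppm = _truncated_normal(rng, cfg.mass_ppm_sigma, cfg.mass_ppm_max, 1 + len(mets))
            jit = _truncated_normal(rng, cfg.rt_jitter_sigma, cfg.rt_jitter_max, 1 + len(mets))
            feats.append(
                Feature(
                    sample_id=f"{parent_name}_{condition}",
                    mz=parent.mz * (1 + ppm[0] * 1e-6),
                    rt=float(parent.reference_rt) + jit[0],
                    area=parent_area,
                    feature_id=f"{parent_name}_{condition}_parent",
                )
            )
            blocked = {"no_NADP": "NADPH", "no_PAPS": "PAPS"}.get(condition)
            for k, (delta, formula, mz, rt, area, pathway) in enumerate(mets):
                if condition != "full":
                    if pathway == blocked:
                        area = area * cfg.invitro_leakage
                    elif not cfg.cross_pathway_in_controls:
                        area = 0.0
                if area <= 0:
                    continue
                feats.append(
                    Feature(
                        sample_id=f"{parent_name}_{condition}",
                        mz=mz * (1 + ppm[1 + k] * 1e-6),
                        rt=rt + jit[1 + k],
                        area=area,
                        feature_id=f"{parent_name}_{condition}_{delta.label}_{rt}",
                    )
                )
            runs.append(IncubationRun(parent=parent, condition=condition, features=tuple(feats)))
    truth = pd.DataFrame(
        truth_rows, columns=["parent", "delta", "formula", "rt_min", "cofactor"]
    )
    return runs, truth
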