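"""Extracted-ion chromatograms and peak detection/integration.

Replaces the vendor peak-integration step with a small, transparent
algorithm: robust baseline (median) and noise (1.4826 x MAD) estimates, a
5-point moving average used only to locate apexes, peak boundaries at the
nearest valley or at 1% of apex height (whichever comes first), and
trapezoidal integration on the *raw* trace so smoothing cannot bias areas.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks as _find_peaks

__all__ = ["Trace", "DetectedPeak", "extract_xic", "detect_peaks", "read_trace_table"]


@dataclass(frozen=True)
class Trace:
    """An extracted-ion chromatogram on the acquisition RT grid."""

    rt: np.ndarray  # minutes, strictly increasing
    intensity: np.ndarray  # counts, >= 0
    target_mz: float
    ppm_window: float

    def __post_init__(self) -> None:
        rt = np.asarray(self.rt, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if rt.shape != inten.shape or rt.ndim != 1:
            raise ValueError("rt and intensity must be equal-length 1-D arrays")
        if rt.size and np.any(np.diff(rt) <= 0):
            raise ValueError("rt grid must be strictly increasing")
        if np.any(inten < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "rt", rt)
        object.__setattr__(self, "intensity", inten)


@dataclass(frozen=True)
class DetectedPeak:
    apex_rt: float
    left_rt: float
    right_rt: float
    area: float
    apex_intensity: float
    snr: float

    def __post_init__(self) -> None:
        if not (self.left_rt < self.apex_rt < self.right_rt):
            raise ValueError("peak boundaries must bracket the apex")
        if self.area < 0:
            raise ValueError("peak area must be non-negative")


def read_trace_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format raw trace: TSV with columns rt_min, mz, intensity."""
    df = pd.read_csv(path, sep="\t")
    missing = {"rt_min", "mz", "intensity"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: trace table missing columns {sorted(missing)}")
    return df


def _decode_binary(elem, ns: str) -> np.ndarray:
    """Decode one mzML <binaryDataArray> (64/32-bit float, zlib or none)."""
    import base64
    import zlib

    accessions = {c.get("accession") for c in elem.findall(f"{ns}cvParam")}
    text = elem.findtext(f"{ns}binary") or ""
    raw = base64.b64decode(text)
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml(path: str | Path) -> pd.DataFrame:
    """Flatten a centroided mzML file into the long trace format.

    Minimal reader for standard mzML (MS1 scans, base64 float arrays,
    optional zlib compression); scan times are normalised to minutes.
    """
    import xml.etree.ElementTree as ET

    ns = "{http://psi.hupo.org/ms/mzml}"
    tree = ET.parse(str(path))
    rows = {"rt_min": [], "mz": [], "intensity": []}
    for spectrum in tree.iter(f"{ns}spectrum"):
        params = {c.get("accession"): c for c in spectrum.findall(f"{ns}cvParam")}
        level = params.get("MS:1000511")
        if level is not None and level.get("value") not in ("", "1"):
            continue
        rt_min = np.nan
        for scan in spectrum.iter(f"{ns}scan"):
            for c in scan.findall(f"{ns}cvParam"):
                if c.get("accession") == "MS:1000016":  # scan start time
                    value = float(c.get("value"))
                    unit = (c.get("unitName") or "minute").lower()
                    rt_min = value / 60.0 if unit.startswith("second") else value
        mzs = intens = None
        for arr in spectrum.iter(f"{ns}binaryDataArray"):
            accessions = {c.get("accession") for c in arr.findall(f"{ns}cvParam")}
            if "MS:1000514" in accessions:  # m/z array
                mzs = _decode_binary(arr, ns)
            elif "MS:1000515" in accessions:  # intensity array
                intens = _decode_binary(arr, ns)
        if mzs is None or intens is None or not np.isfinite(rt_min):
            continue
        rows["rt_min"].extend([rt_min] * len(mzs))
        rows["mz"].extend(map(float, mzs))
        rows["intensity"].extend(map(float, intens))
    return pd.DataFrame(rows)


def extract_xic(
    run: pd.DataFrame | str | Path,
    target_mz: float,
    ppm_window: float,
) -> Trace:
    """Sum per-scan intensity within +/- ``ppm_window`` of ``target_mz``.

    ``run`` is a long-format table (rt_min, mz, intensity), a path to such
    a TSV, or a path to a centroided mzML file.  The output trace keeps the
    full acquisition RT grid, with zeros where nothing matches.
    """
    if ppm_window <= 0:
        raise ValueError("ppm_window must be positive")
    if isinstance(run, (str, Path)):
        run = _read_mzml(run) if str(run).lower().endswith(".mzml") else read_trace_table(run)
    if run.empty:
        raise ValueError("empty run: no scans to extract from")
    grid = np.unique(run["rt_min"].to_numpy(dtype=float))
    half = target_mz * ppm_window * 1e-6
    sel = run[(run["mz"] >= target_mz - half) & (run["mz"] <= target_mz + half)]
    summed = sel.groupby("rt_min")["intensity"].sum()
    intensity = np.zeros_like(grid)
    if len(summed):
        idx = np.searchsorted(grid, summed.index.to_numpy(dtype=float))
        intensity[idx] = summed.to_numpy(dtype=float)
    return Trace(rt=grid, intensity=intensity, target_mz=target_mz, ppm_window=ppm_window)


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or y.size < window:
        return y.astype(float)
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(y, pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")[: y.size]


def detect_peaks(
    t: Trace,
    min_snr: float = 3.0,
    min_points: int = 5,
    smooth_window: int = 5,
) -> list[DetectedPeak]:
    """Detect and integrate peaks in a trace; RT-sorted, possibly empty.

    Apexes are local maxima of the smoothed trace above
    baseline + ``min_snr`` x noise; boundaries extend to the nearest valley
    on each side or to where the raw trace falls below 1% of apex height;
    candidates narrower than ``min_points`` grid points are rejected.
    """
    y = t.intensity
    if y.size < min_points or not np.any(y > 0):
        return []
    baseline = float(np.median(y))
    noise = 1.4826 * float(np.median(np.abs(y - baseline)))
    smooth = _moving_average(y, smooth_window)
    threshold = baseline + min_snr * noise
    apexes, _ = _find_peaks(smooth, height=max(threshold, np.max(y) * 1e-6))
    peaks: list[DetectedPeak] = []
    for apex in apexes:
        apex_height = y[max(0, apex - 1) : apex + 2].max()
        floor = max(0.01 * apex_height, baseline)
        left = apex
        while left > 0 and y[left - 1] > floor and smooth[left - 1] <= smooth[left]:
            left -= 1
        right = apex
        while right < y.size - 1 and y[right + 1] > floor and smooth[right + 1] <= smooth[right]:
            right += 1
        if right - left + 1 < min_points:
            continue
        if not (t.rt[left] < t.rt[apex] < t.rt[right]):
            continue
        area = float(np.trapezoid(y[left : right + 1], t.rt[left : right + 1]))
        snr = float((apex_height - baseline) / noise) if noise > 0 else float("inf")
        peaks.append(
            DetectedPeak(
                apex_rt=float(t.rt[apex]),
                left_rt=float(t.rt[left]),
                right_rt=float(t.rt[right]),
                area=area,
                apex_intensity=float(apex_height),
                snr=snr,
            )
        )
    peaks.sort(key=lambda p: p.apex_rt)
    return peaks
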