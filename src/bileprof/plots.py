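"""Plotting helpers: extracted-ion chromatograms and screen volcano plots."""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .signal import DetectedPeak, Trace
from .stats import DifferentialResult


def plot_xic(trace: Trace, peaks: Sequence[DetectedPeak] = (), ax=None):
    """Plot one XIC with detected peak apexes and integration bounds."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    ax.plot(trace.rt, trace.intensity, lw=0.8, color="tab:blue")
    for p in peaks:
        ax.axvspan(p.left_rt, p.right_rt, alpha=0.15, color="tab:orange")
        ax.plot([p.apex_rt], [p.apex_intensity], "v", color="tab:red", ms=5)
    ax.set_xlabel("retention time (min)")
    ax.set_ylabel("intensity")
    ax.set_title(f"XIC m/z {trace.target_mz:.4f} +/- {trace.ppm_window:g} ppm")
    return ax


def plot_volcano(
    results: Iterable[DifferentialResult],
    p_threshold: float = 0.05,
    fc_threshold: float = 2.0,
    ax=None,
):
    """log2 fold change vs -log10 p, significant targets highlighted."""
    import matplotlib.pyplot as plt

    results = [r for r in results if np.isfinite(r.fold_change) and r.fold_change > 0]
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    x = np.log2([r.fold_change for r in results])
    y = -np.log10(np.clip([r.p_value for r in results], 1e-300, None))
    sig = np.array([r.significant for r in results], dtype=bool)
    ax.scatter(x[~sig], y[~sig], s=12, color="0.6", label="not significant")
    ax.scatter(x[sig], y[sig], s=14, color="tab:red", label="significant")
    ax.axhline(-np.log10(p_threshold), ls="--", lw=0.7, color="0.3")
    for sign in (1, -1):
        ax.axvline(sign * np.log2(fc_threshold), ls="--", lw=0.7, color="0.3")
    ax.set_xlabel("log2 fold change (high/low dose)")
    ax.set_ylabel("-log10 p")
    ax.legend(frameon=False, fontsize=8)
    return ax
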