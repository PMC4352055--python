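"""Forward BOLD prediction from module demand functions.

A module's activity is described as a 0–1 demand function of time.  The
predicted BOLD signal is the convolution of this demand function with a
hemodynamic response function (HRF) — equivalently, one HRF per activity
period, summed — sampled at scan times.  The HRF is the conventional
difference of two gamma densities (peak and undershoot), which rises slowly
and peaks about 5 s after the neural event.

Predictions are in arbitrary amplitude units; a scalar gain per module is
fitted downstream when comparing against percent-signal-change data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .task_models import DemandTrace, TrialSpec

__all__ = [
    "HRFSpec",
    "ScanGrid",
    "PredictedCurve",
    "hrf_kernel",
    "demand_to_boxcar",
    "convolve_predict",
    "condition_average",
    "predict_module",
]


@dataclass(frozen=True)
class HRFSpec:
    """Double-gamma HRF: ``g(t; peak) − ratio · g(t; undershoot)``.

    Defaults are the conventional parameterization (shapes 6 and 16, unit
    rates, undershoot ratio 1/6, 32 s support), giving a peak near 5 s.
    ``dt`` is the sampling resolution in seconds.
    """

    peak_shape: float = 6.0
    undershoot_shape: float = 16.0
    peak_rate: float = 1.0
    undershoot_rate: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    support: float = 32.0
    dt: float = 0.1

    def __post_init__(self) -> None:
        for name in ("peak_shape", "undershoot_shape", "peak_rate",
                     "undershoot_rate", "support", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.undershoot_ratio < 0:
            raise ValueError("undershoot_ratio must be non-negative")
        if self.dt > self.support:
            raise ValueError("dt must not exceed support")


@dataclass(frozen=True)
class ScanGrid:
    """Scan sampling: repetition time ``tr`` (s), scan count, run onset."""

    tr: float
    n_scans: int
    run_onset: float = 0.0

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.n_scans < 1:
            raise ValueError("n_scans must be at least 1")

    @property
    def times(self) -> np.ndarray:
        return self.run_onset + self.tr * np.arange(self.n_scans)

    @property
    def duration(self) -> float:
        return self.run_onset + self.tr * self.n_scans


@dataclass
class PredictedCurve:
    """Condition-averaged, trial-locked prediction (or data) curve."""

    module: str
    condition: str
    values: np.ndarray
    baseline_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("curve values must be finite")


def hrf_kernel(spec: HRFSpec | None = None) -> np.ndarray:
    """Sampled (unnormalized) double-gamma kernel on ``[0, support]`` at ``dt``."""
    spec = spec or HRFSpec()
    t = np.arange(int(round(spec.support / spec.dt)) + 1) * spec.dt
    peak = stats.gamma.pdf(t, spec.peak_shape, scale=1.0 / spec.peak_rate)
    under = stats.gamma.pdf(t, spec.undershoot_shape, scale=1.0 / spec.undershoot_rate)
    return peak - spec.undershoot_ratio * under


def demand_to_boxcar(
    trace: DemandTrace,
    module: str,
    dt: float,
    total_len: float,
) -> np.ndarray:
    """Sample the module's 0–1 demand function on a ``dt`` grid.

    Sample ``k`` is 1 iff ``k·dt`` falls inside any half-open activity
    interval ``[onset, offset)``.
    """
    if dt <= 0 or total_len <= 0:
        raise ValueError("dt and total_len must be positive")
    n = int(np.ceil(total_len / dt))
    box = np.zeros(n)
    for onset, offset in trace.module_intervals(module):
        if offset > total_len + 1e-9:
            raise ValueError(
                f"interval ({onset:.3f}, {offset:.3f}) of module {module!r} "
                f"extends beyond total_len={total_len:.3f}"
            )
        lo = int(np.ceil(onset / dt - 1e-9))
        hi = int(np.ceil(offset / dt - 1e-9))
        box[lo:min(hi, n)] = 1.0
    return box


def convolve_predict(
    boxcar: np.ndarray,
    kernel: np.ndarray,
    scans: ScanGrid,
    dt: float,
) -> np.ndarray:
    """Convolve a sampled demand function with the HRF and sample at scans.

    The discrete convolution is scaled by ``dt`` so that it approximates the
    continuous integral; scan values are taken at the nearest ``dt`` sample
    (zero beyond the convolved support).
    """
    full = np.convolve(boxcar, kernel) * dt
    idx = np.rint(scans.times / dt).astype(int)
    out = np.zeros(scans.n_scans)
    ok = (idx >= 0) & (idx < full.size)
    out[ok] = full[idx[ok]]
    return out


def predict_module(
    trace: DemandTrace,
    module: str,
    hrf: HRFSpec,
    scans: ScanGrid,
) -> np.ndarray:
    """Per-scan BOLD prediction for one module of a run trace."""
    total = max(scans.duration, trace.end_time)
    box = demand_to_boxcar(trace, module, hrf.dt, total)
    return convolve_predict(box, hrf_kernel(hrf), scans, hrf.dt)


def condition_average(
    values: np.ndarray,
    trials: list[TrialSpec],
    scans: ScanGrid,
    window: int,
    *,
    module: str = "",
    baseline: str = "onset",
) -> dict[str, PredictedCurve]:
    """Average trial-locked windows of a per-scan signal by condition.

    For each trial the ``window``-scan segment starting at the scan nearest
    the trial onset is taken and the baseline value (the onset scan's, under
    the default rule) subtracted.  Segments are averaged within condition.
    Trials whose window exceeds the run are dropped with a warning, and
    conditions left with no trials are omitted with a warning.
    """
    if baseline != "onset":
        raise ValueError(f"unknown baseline rule {baseline!r}")
    values = np.asarray(values, dtype=float)
    segments: dict[str, list[np.ndarray]] = {}
    for trial in trials:
        start = int(np.rint((trial.onset - scans.run_onset) / scans.tr))
        if start < 0 or start + window > values.size:
            warnings.warn(
                f"trial at {trial.onset:.1f}s: window of {window} scans does not "
                "fit in the run; trial dropped",
                stacklevel=2,
            )
            continue
        seg = values[start:start + window] - values[start]
        segments.setdefault(trial.condition, []).append(seg)
    conditions = {t.condition for t in trials}
    for cond in conditions - set(segments):
        warnings.warn(f"condition {cond!r} has no usable trials; omitted",
                      stacklevel=2)
    return {
        cond: PredictedCurve(module=module, condition=cond,
                             values=np.mean(segs, axis=0))
        for cond, segs in sorted(segments.items())
    }
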