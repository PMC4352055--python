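"""Model evaluation: ROI time courses, event-locked averages, fit statistics.

Model predictions and observed ROI BOLD curves are compared per module with
three statistics: Tucker's congruence coefficient (TCC, the proportionality
of two vectors — Σxy/√(Σx²Σy²), in [−1, 1], sensitive to slope and sign),
the squared Pearson correlation R² (slope- and sign-insensitive), and the
root-mean-square deviation in percent-signal-change units.  TCC values
between .85 and .94 are conventionally read as fair similarity and values
over .95 as near-identity.

Behavioral filtering implements the dataset rules: subjects are dropped when
their accuracy does not exceed the cutoff, and, among correct trials, trials
with an RT more than ``rt_sd_cutoff`` standard deviations above the mean of
their subject × condition cell are removed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .bold import PredictedCurve, ScanGrid
from .roi import ROIMask
from .task_models import TrialSpec

__all__ = [
    "FitReport",
    "BehavioralFilterConfig",
    "tcc",
    "r_squared",
    "rmsd",
    "fit_gain",
    "extract_roi_timecourse",
    "event_locked_average",
    "fit_report",
    "filter_behavior",
]


def _vec(x) -> np.ndarray:
    v = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(v)):
        raise ValueError("input vector must be finite")
    return v


def tcc(x, y) -> float:
    """Tucker's congruence coefficient: Σxy / √(Σx² Σy²).

    1 means identical (proportional with positive slope), −1 a complete
    opposite.  Unlike R² it is sensitive to the sign and slope of the
    relationship and handles flat curves.
    """
    x, y = _vec(x), _vec(y)
    if x.size != y.size or x.size < 2:
        raise ValueError("tcc needs two equal-length vectors of length >= 2")
    nx, ny = np.dot(x, x), np.dot(y, y)
    if nx == 0 or ny == 0:
        raise ValueError("tcc is undefined for a zero vector")
    return float(np.dot(x, y) / np.sqrt(nx * ny))


def r_squared(x, y) -> float:
    """Squared Pearson correlation (insensitive to slope sign and scale)."""
    x, y = _vec(x), _vec(y)
    if x.size != y.size or x.size < 3:
        raise ValueError("r_squared needs equal-length vectors of length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("r_squared is undefined for a zero-variance vector")
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def rmsd(x, y) -> float:
    """Root-mean-square deviation, in the units of the inputs."""
    x, y = _vec(x), _vec(y)
    if x.size != y.size or x.size < 1:
        raise ValueError("rmsd needs two equal-length nonempty vectors")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def fit_gain(model, data) -> float:
    """Least-squares scalar gain g minimizing ||data − g·model||²."""
    m, d = _vec(model), _vec(data)
    denom = np.dot(m, m)
    if denom == 0:
        raise ValueError("cannot fit a gain to an all-zero model curve")
    return float(np.dot(m, d) / denom)


def extract_roi_timecourse(data: np.ndarray, roi: ROIMask) -> np.ndarray:
    """Unweighted spatial mean over ROI voxels, per scan."""
    data = np.asarray(data, dtype=float)
    if data.shape[:3] != tuple(roi.grid.dims):
        raise ValueError("data spatial shape does not match the ROI grid")
    if roi.size == 0:
        raise ValueError("ROI is empty")
    return data[roi.mask].mean(axis=0)


def event_locked_average(
    timecourse: np.ndarray,
    trials: list[TrialSpec],
    scans: ScanGrid,
    window: int,
    *,
    module: str = "",
    baseline: str = "onset",
) -> dict[str, PredictedCurve]:
    """Per-condition percent-signal-change curves, trial-locked.

    Each trial's ``window``-scan segment (from the scan nearest its onset)
    is converted to percent change relative to the baseline scan of that
    trial, then averaged within condition.  Trials extending past the run
    end are dropped with a warning.
    """
    if baseline != "onset":
        raise ValueError(f"unknown baseline rule {baseline!r}")
    tc = np.asarray(timecourse, dtype=float)
    segments: dict[str, list[np.ndarray]] = {}
    for trial in trials:
        start = int(np.rint((trial.onset - scans.run_onset) / scans.tr))
        if start < 0 or start + window > tc.size:
            warnings.warn(
                f"trial at {trial.onset:.1f}s extends past the run; dropped",
                stacklevel=2,
            )
            continue
        base = tc[start]
        if base == 0:
            raise ValueError("baseline scan value is zero; percent change undefined")
        seg = 100.0 * (tc[start:start + window] - base) / base
        segments.setdefault(trial.condition, []).append(seg)
    for cond in {t.condition for t in trials} - set(segments):
        warnings.warn(f"condition {cond!r} has no usable trials; omitted",
                      stacklevel=2)
    return {
        cond: PredictedCurve(module=module, condition=cond,
                             values=np.mean(segs, axis=0))
        for cond, segs in sorted(segments.items())
    }


@dataclass
class FitReport:
    """Per module × mapping fit statistics (the summary-table machinery)."""

    module: str
    mapping: str
    tcc_aggregate: float
    tcc_individual_mean: float
    tcc_individual_sd: float
    tcc_individual_min: float
    tcc_individual_max: float
    r_squared: float
    rmsd: float
    gain: float
    n_subjects: int

    def __post_init__(self) -> None:
        for name in ("tcc_aggregate", "tcc_individual_mean",
                     "tcc_individual_min", "tcc_individual_max"):
            v = getattr(self, name)
            if not -1.0 - 1e-9 <= v <= 1.0 + 1e-9:
                raise ValueError(f"{name}={v} outside [-1, 1]")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-9:
            raise ValueError("r_squared outside [0, 1]")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def to_row(self) -> dict:
        return asdict(self)


def _concat_conditions(curves: dict[str, PredictedCurve],
                       conditions: list[str]) -> np.ndarray:
    return np.concatenate([np.asarray(curves[c].values, float) for c in conditions])


def fit_report(
    model_curves: dict[str, PredictedCurve],
    data_curves_aggregate: dict[str, PredictedCurve],
    data_curves_per_subject: dict[str, dict[str, PredictedCurve]],
    *,
    module: str = "",
    mapping: str = "data_driven",
) -> FitReport:
    """Fit statistics of model curves against aggregate and per-subject data.

    Aggregate statistics are computed on the concatenation of all condition
    curves (one number per module × mapping); the model is scaled by a
    least-squares gain before RMSD.  The individual TCC is computed per
    subject on that subject's concatenated curves; subjects missing a
    condition are dropped with a warning.
    """
    conditions = sorted(set(model_curves) & set(data_curves_aggregate))
    if not conditions:
        raise ValueError("model and data curves share no conditions")
    if set(model_curves) != set(data_curves_aggregate):
        warnings.warn("model and aggregate data condition sets differ; using "
                      f"their intersection {conditions}", stacklevel=2)
    m = _concat_conditions(model_curves, conditions)
    d = _concat_conditions(data_curves_aggregate, conditions)
    gain = fit_gain(m, d)
    agg_tcc = tcc(m, d)
    agg_r2 = r_squared(m, d)
    agg_rmsd = rmsd(gain * m, d)

    individual = []
    for subject, curves in sorted(data_curves_per_subject.items()):
        if not set(conditions) <= set(curves):
            warnings.warn(f"subject {subject!r} is missing conditions; dropped",
                          stacklevel=2)
            continue
        individual.append(tcc(m, _concat_conditions(curves, conditions)))
    if not individual:
        raise ValueError("no subject has the full condition set")
    ind = np.asarray(individual)
    return FitReport(
        module=module,
        mapping=mapping,
        tcc_aggregate=agg_tcc,
        tcc_individual_mean=float(ind.mean()),
        tcc_individual_sd=float(ind.std(ddof=1)) if ind.size > 1 else 0.0,
        tcc_individual_min=float(ind.min()),
        tcc_individual_max=float(ind.max()),
        r_squared=agg_r2,
        rmsd=agg_rmsd,
        gain=gain,
        n_subjects=int(ind.size),
    )


@dataclass(frozen=True)
class BehavioralFilterConfig:
    """Subject accuracy cutoff and per-cell RT trimming rule."""

    accuracy_cutoff: float = 0.85
    rt_sd_cutoff: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.accuracy_cutoff < 1.0:
            raise ValueError("accuracy_cutoff must be in (0, 1)")
        if self.rt_sd_cutoff <= 0:
            raise ValueError("rt_sd_cutoff must be positive")


def filter_behavior(
    trials: pd.DataFrame,
    config: BehavioralFilterConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Apply the behavioral exclusion rules; returns (retained, log).

    ``trials`` needs columns ``subject``, ``condition``, ``rt``, ``correct``.
    Subjects whose accuracy does not exceed ``accuracy_cutoff`` are dropped
    entirely.  Then, among correct trials only, trials with
    ``rt > mean + rt_sd_cutoff · sd`` of their subject × condition cell are
    removed (sample sd; cells with fewer than 2 correct trials are left
    unfiltered and noted in the log).  Incorrect trials of retained subjects
    are dropped (analysis uses correct trials only).
    """
    config = config or BehavioralFilterConfig()
    required = {"subject", "condition", "rt", "correct"}
    if not required <= set(trials.columns):
        raise ValueError(f"trials frame must have columns {sorted(required)}")
    log: dict = {"excluded_subjects": [], "rt_outliers": 0,
                 "unfilterable_cells": [], "incorrect_dropped": 0}

    acc = trials.groupby("subject")["correct"].mean()
    bad = acc[acc <= config.accuracy_cutoff]
    log["excluded_subjects"] = [
        {"subject": s, "accuracy": float(a)} for s, a in bad.items()
    ]
    kept = trials[~trials["subject"].isin(bad.index)]
    correct = kept[kept["correct"].astype(bool)].copy()
    log["incorrect_dropped"] = int(len(kept) - len(correct))

    keep_idx = []
    for (subj, cond), cell in correct.groupby(["subject", "condition"]):
        if len(cell) < 2:
            log["unfilterable_cells"].append({"subject": subj, "condition": cond})
            keep_idx.extend(cell.index)
            continue
        cut = cell["rt"].mean() + config.rt_sd_cutoff * cell["rt"].std(ddof=1)
        ok = cell[cell["rt"] <= cut]
        log["rt_outliers"] += int(len(cell) - len(ok))
        keep_idx.extend(ok.index)
    return correct.loc[sorted(keep_idx)], log
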