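"""Readers and writers for the tool's on-disk formats.

Volumes, masks and label images are NIfTI-1 (via nibabel); traces, events,
curves and fit tables are tab-separated text; ROI sidecars, fit reports and
provenance records are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .bold import PredictedCurve
from .glm import StatMap, VolumeGrid
from .roi import ROIMask, center_of_mass
from .task_models import DemandTrace, TrialSpec

__all__ = [
    "write_trace", "read_trace",
    "write_events", "read_events",
    "write_curves", "read_curves",
    "save_volume", "load_volume",
    "save_statmap", "load_statmap",
    "save_roi", "load_roi",
    "write_provenance",
]

_TRACE_COLS = ["module", "trial", "onset", "offset"]
_EVENT_COLS = ["onset", "duration", "condition", "rt", "correct"]


def _parse_error(path, exc) -> ValueError:
    return ValueError(f"malformed file {path}: {exc}")


# ---------------------------------------------------------------------------
# TSV formats
# ---------------------------------------------------------------------------

def write_trace(trace: DemandTrace, path, *, trial_ids: dict | None = None) -> None:
    """Write a run trace as TSV with columns module/trial/onset/offset.

    ``trial_ids`` optionally maps ``(module, onset)`` to a trial index;
    otherwise the trial column is 0.
    """
    rows = []
    for module, ivs in sorted(trace.intervals.items()):
        for onset, offset in ivs:
            trial = 0 if trial_ids is None else trial_ids.get((module, onset), 0)
            rows.append((module, trial, onset, offset))
    df = pd.DataFrame(rows, columns=_TRACE_COLS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_trace(path, run_id: str | None = None) -> DemandTrace:
    """Read a trace TSV (all trials merged into one run-level trace)."""
    try:
        df = pd.read_csv(path, sep="\t")
        missing = set(_TRACE_COLS) - set(df.columns)
        if missing:
            raise ValueError(f"missing columns {sorted(missing)}")
        intervals: dict[str, list[tuple[float, float]]] = {}
        for _, row in df.iterrows():
            intervals.setdefault(str(row["module"]), []).append(
                (float(row["onset"]), float(row["offset"]))
            )
    except (OSError, ValueError, KeyError) as exc:
        raise _parse_error(path, exc) from exc
    return DemandTrace(run_id=run_id or Path(path).stem, intervals=intervals)


def write_events(trials: list[TrialSpec], path, *,
                 rts: np.ndarray | None = None,
                 correct: np.ndarray | None = None) -> None:
    """Write a trial event table (BIDS-events-like TSV dialect)."""
    n = len(trials)
    rts = np.full(n, np.nan) if rts is None else np.asarray(rts, float)
    correct = np.ones(n, dtype=int) if correct is None else np.asarray(correct, int)
    df = pd.DataFrame({
        "onset": [t.onset for t in trials],
        "duration": [t.duration for t in trials],
        "condition": [t.condition for t in trials],
        "rt": rts,
        "correct": correct,
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_events(path) -> list[TrialSpec]:
    try:
        df = pd.read_csv(path, sep="\t")
        missing = {"onset", "duration", "condition"} - set(df.columns)
        if missing:
            raise ValueError(f"missing columns {sorted(missing)}")
        return [
            TrialSpec(condition=str(r["condition"]), onset=float(r["onset"]),
                      duration=float(r["duration"]))
            for _, r in df.iterrows()
        ]
    except (OSError, ValueError, KeyError) as exc:
        raise _parse_error(path, exc) from exc


def read_events_frame(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t")
    except OSError as exc:
        raise _parse_error(path, exc) from exc


def write_curves(curves: dict[str, PredictedCurve] | list[PredictedCurve],
                 path) -> None:
    """Write prediction/data curves as TSV module/condition/scan/value."""
    if isinstance(curves, dict):
        curves = list(curves.values())
    rows = [
        (c.module, c.condition, k, v)
        for c in curves
        for k, v in enumerate(np.asarray(c.values, float))
    ]
    df = pd.DataFrame(rows, columns=["module", "condition", "scan", "value"])
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_curves(path) -> list[PredictedCurve]:
    try:
        df = pd.read_csv(path, sep="\t")
        out = []
        for (module, cond), g in df.groupby(["module", "condition"], sort=True):
            g = g.sort_values("scan")
            out.append(PredictedCurve(module=str(module), condition=str(cond),
                                      values=g["value"].to_numpy()))
        return out
    except (OSError, ValueError, KeyError) as exc:
        raise _parse_error(path, exc) from exc


# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------

def save_volume(array: np.ndarray, grid: VolumeGrid, path,
                dtype=np.float32) -> None:
    img = nib.Nifti1Image(np.asarray(array).astype(dtype), np.asarray(grid.affine))
    nib.save(img, str(path))


def load_volume(path) -> tuple[np.ndarray, VolumeGrid]:
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata())
    except Exception as exc:  # nibabel raises several exception types
        raise _parse_error(path, exc) from exc
    grid = VolumeGrid(dims=tuple(data.shape[:3]), affine=np.asarray(img.affine))
    return data, grid


def save_statmap(statmap: StatMap, path_t, path_p=None) -> None:
    save_volume(statmap.t_values, statmap.grid, path_t, dtype=np.float32)
    if path_p is not None:
        save_volume(statmap.p_values, statmap.grid, path_p, dtype=np.float64)


def load_statmap(path_t, path_p, df: int) -> StatMap:
    t, grid = load_volume(path_t)
    p, pgrid = load_volume(path_p)
    grid.require_match(pgrid, "p-value volume")
    return StatMap(grid=grid, t_values=t, p_values=p, df=df)


def save_roi(roi: ROIMask, path) -> None:
    """Write an ROI as uint8 NIfTI plus a JSON sidecar with metadata."""
    path = Path(path)
    save_volume(roi.mask.astype(np.uint8), roi.grid, path, dtype=np.uint8)
    com = center_of_mass(roi) if roi.size else [None, None, None]
    sidecar = {
        "module": roi.module,
        "hemisphere": roi.hemisphere,
        "seed_voxel": list(roi.seed) if roi.seed is not None else None,
        "size_voxels": roi.size,
        "center_of_mass_mm": [float(v) for v in com] if roi.size else None,
    }
    json_path = Path(str(path).removesuffix(".nii.gz").removesuffix(".nii") + ".json")
    json_path.write_text(json.dumps(sidecar, indent=2) + "\n")


def load_roi(path) -> ROIMask:
    data, grid = load_volume(path)
    json_path = Path(str(path).removesuffix(".nii.gz").removesuffix(".nii") + ".json")
    meta = {}
    if json_path.exists():
        meta = json.loads(json_path.read_text())
    seed = meta.get("seed_voxel")
    return ROIMask(
        grid=grid,
        mask=data > 0.5,
        seed=tuple(seed) if seed else None,
        module=meta.get("module", ""),
        hemisphere=meta.get("hemisphere", "left"),
    )


def write_provenance(path, *, command: str, inputs: dict, parameters: dict,
                     seed: int | None) -> None:
    from . import __version__

    record = {
        "command": command,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "parameters": parameters,
        "seed": seed,
        "tool_version": __version__,
    }
    Path(path).write_text(json.dumps(record, indent=2, default=str) + "\n")
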