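"""Synthetic group fMRI data with known ground truth.

The generator stands in for real scanner data so every pipeline stage can
be exercised against a known answer: spherical "true" module regions are
placed at the published left-hemisphere module centers (MNI mm), each
in-region voxel's time series is baseline plus the convolved demand of its
module (scaled by a per-module amplitude and a per-subject multiplier) plus
drift and noise (white or AR(1)), and out-of-region voxels carry noise only.

The default grid is 40×48×40 at 4 mm isotropic with an MNI-like affine —
small enough for desk-scale tests while still containing all published
module centers.  Default signal conditions: amplitude/sigma = 1 and a
between-subject amplitude sd of 0.2 across a default group of 18 subjects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy import ndimage, signal, stats

from .bold import HRFSpec, ScanGrid, predict_module
from .glm import StatMap, VolumeGrid, connectivity_structure
from .roi import ROIMask
from .task_models import (
    AlgebraParams,
    MultitaskParams,
    DemandTrace,
    TrialSpec,
    generate_algebra_session,
    generate_multitask_session,
)

__all__ = [
    "DATA_DRIVEN_CENTERS",
    "ORIGINAL_CENTERS",
    "NoiseModel",
    "GroundTruth",
    "SubjectRun",
    "default_grid",
    "make_truth",
    "simulate_subject_run",
    "simulate_group",
    "iter_group",
    "make_toy_statmap",
]

#: Published left-hemisphere module centers (MNI mm) of the data-driven
#: mapping; the left-manual entry is the mirrored right-manual center.
#: Used only as generator defaults, never by any algorithm.
DATA_DRIVEN_CENTERS: dict[str, tuple[float, float, float]] = {
    "problem_state": (-38.0, -50.0, 48.0),   # intraparietal sulcus
    "declarative": (-46.0, 16.0, 26.0),      # inferior frontal sulcus
    "manual_right": (-33.0, -18.0, 57.0),    # precentral gyrus (left hemi)
    "manual_left": (33.0, -18.0, 57.0),      # mirrored homologue
    "aural": (-58.0, -21.0, 4.0),            # superior temporal gyrus
    "visual": (-30.0, -84.0, 15.0),          # middle occipital gyrus
}

#: The older literature-based mapping's centers, for reference/config.
ORIGINAL_CENTERS: dict[str, tuple[float, float, float]] = {
    "problem_state": (-24.0, -67.0, 44.0),
    "declarative": (-43.0, 24.0, 25.0),
    "manual_right": (-42.0, -23.0, 54.0),
    "manual_left": (42.0, -23.0, 54.0),
    "aural": (-48.0, -21.0, 7.0),
    "visual": (-43.0, -60.0, -16.0),
}


def default_grid() -> VolumeGrid:
    """40×48×40 grid at 4 mm isotropic, MNI-like affine (x negative = left)."""
    affine = np.array(
        [
            [4.0, 0.0, 0.0, -78.0],
            [0.0, 4.0, 0.0, -94.0],
            [0.0, 0.0, 4.0, -72.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )
    return VolumeGrid(dims=(40, 48, 40), affine=affine)


@dataclass(frozen=True)
class NoiseModel:
    """Scan noise: white or AR(1) with stationary sd ``sigma``, plus an
    optional linear drift of peak-to-peak amplitude ``drift_amp``."""

    sigma: float = 1.0
    ar_rho: float = 0.0
    drift_amp: float = 0.0
    kind: str = "white"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if not -1.0 < self.ar_rho < 1.0:
            raise ValueError("|ar_rho| must be < 1")
        if self.kind not in ("white", "ar1"):
            raise ValueError("kind must be 'white' or 'ar1'")

    def sample(self, shape: tuple[int, ...], rng: np.random.Generator) -> np.ndarray:
        """Noise array with time as the last axis (float32 for volume sizes)."""
        if self.sigma == 0:
            return np.zeros(shape, dtype=np.float32)
        white = self.sigma * rng.standard_normal(size=shape, dtype=np.float32)
        if self.kind == "white" or self.ar_rho == 0:
            return white
        white *= np.float32(np.sqrt(1.0 - self.ar_rho**2))
        return signal.lfilter([1.0], [1.0, -self.ar_rho], white, axis=-1)


@dataclass
class GroundTruth:
    """True module regions and signal amplitudes of a synthetic study."""

    regions: dict[str, ROIMask]
    amplitudes: dict[str, float]
    subject_amp_sd: float = 0.2
    baseline: float = 100.0

    def __post_init__(self) -> None:
        for module, amp in self.amplitudes.items():
            if amp < 0:
                raise ValueError(f"amplitude for {module!r} must be >= 0")
        if self.subject_amp_sd < 0:
            raise ValueError("subject_amp_sd must be >= 0")

    @property
    def grid(self) -> VolumeGrid:
        return next(iter(self.regions.values())).grid


def make_truth(
    grid: VolumeGrid | None = None,
    centers: dict[str, tuple[float, float, float]] | None = None,
    radius_mm: float = 12.0,
    *,
    amplitude: float = 1.0,
    subject_amp_sd: float = 0.2,
    baseline: float = 100.0,
) -> GroundTruth:
    """Spherical true regions of ``radius_mm`` around each module center.

    Raises when two spheres overlap (naming the pair) or when a center lies
    outside the grid.
    """
    grid = grid or default_grid()
    centers = centers or DATA_DRIVEN_CENTERS
    nx, ny, nz = grid.dims
    ijk = np.argwhere(np.ones(grid.dims, dtype=bool))
    world = grid.voxel_to_world(ijk)
    regions: dict[str, ROIMask] = {}
    for module, center in centers.items():
        c = np.asarray(center, float)
        cv = grid.world_to_voxel(c)[0]
        if np.any(cv < -0.5) or np.any(cv > np.asarray(grid.dims) - 0.5):
            raise ValueError(f"center of {module!r} at {center} lies outside the grid")
        dist = np.linalg.norm(world - c, axis=1)
        mask = np.zeros(grid.dims, dtype=bool)
        inside = ijk[dist <= radius_mm]
        if inside.size == 0:  # radius below voxel size: keep the center voxel
            inside = np.rint(cv).astype(int)[None, :]
        mask[tuple(inside.T)] = True
        regions[module] = ROIMask(grid=grid, mask=mask, module=module,
                                  hemisphere="left" if c[0] <= 0 else "right")
    mods = list(regions)
    for i, a in enumerate(mods):
        for b in mods[i + 1:]:
            if np.any(regions[a].mask & regions[b].mask):
                raise ValueError(
                    f"true regions for {a!r} and {b!r} overlap at radius "
                    f"{radius_mm} mm"
                )
    return GroundTruth(regions=regions,
                       amplitudes={m: amplitude for m in regions},
                       subject_amp_sd=subject_amp_sd, baseline=baseline)


@dataclass
class SubjectRun:
    """One simulated subject: 4D data, run trace, trials, multipliers."""

    subject: str
    data: np.ndarray
    trace: DemandTrace
    trials: list[TrialSpec]
    amp_multiplier: dict[str, float]


def simulate_subject_run(
    trace: DemandTrace,
    truth: GroundTruth,
    hrf: HRFSpec,
    scans: ScanGrid,
    noise: NoiseModel,
    rng: np.random.Generator,
    *,
    amp_multiplier: dict[str, float] | None = None,
) -> np.ndarray:
    """Forward-generate one subject's 4D run from a demand trace.

    In-region voxel series are ``baseline + amplitude · multiplier ·
    (convolved demand of the region's module, normalized to unit temporal
    sd) + drift + noise``; out-of-region voxels get baseline + drift +
    noise only.  The normalization makes ``amplitude`` the signal standard
    deviation in scanner units, so ``amplitude / noise.sigma`` is the
    temporal signal-to-noise ratio regardless of how sparse the module's
    demand is; it also matches the unit-sd regressor convention of
    :func:`cogmap.glm.build_design_matrix`, so recovered betas estimate
    ``amplitude · multiplier`` directly.
    """
    grid = truth.grid
    data = truth.baseline + noise.sample((*grid.dims, scans.n_scans), rng).astype(float)
    if noise.drift_amp:
        drift = noise.drift_amp * np.linspace(-0.5, 0.5, scans.n_scans)
        data += drift
    for module, region in truth.regions.items():
        if not trace.module_intervals(module):
            continue
        pred = predict_module(trace, module, hrf, scans)
        sd = pred.std()
        if sd == 0:
            continue
        mult = 1.0 if amp_multiplier is None else amp_multiplier.get(module, 1.0)
        data[region.mask] += truth.amplitudes[module] * mult * (pred / sd)
    return data


def _session_for(task: str, seed: int, n_per_condition: int | None,
                 trial_slot: float | None):
    if task == "algebra":
        kw = {}
        if n_per_condition is not None:
            kw["n_per_condition"] = n_per_condition
        if trial_slot is not None:
            kw["trial_slot"] = trial_slot
        params = AlgebraParams(rng_seed=seed)
        trace, trials, _ = generate_algebra_session(
            params, np.random.default_rng(seed), **kw)
        return trace, trials
    if task == "multitask":
        kw = {}
        if n_per_condition is not None:
            kw["n_per_condition"] = n_per_condition
        if trial_slot is not None:
            kw["trial_slot"] = trial_slot
        params = MultitaskParams(rng_seed=seed)
        return generate_multitask_session(params, np.random.default_rng(seed), **kw)
    raise ValueError(f"unknown task {task!r}; expected 'algebra' or 'multitask'")


def iter_group(
    n_subjects: int = 18,
    task: str = "multitask",
    *,
    truth: GroundTruth | None = None,
    hrf: HRFSpec | None = None,
    scans: ScanGrid | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
    n_per_condition: int | None = None,
    trial_slot: float | None = None,
) -> Iterator[SubjectRun]:
    """Lazily simulate a group: fresh traces, subject-specific amplitude
    multipliers (mean 1, sd ``truth.subject_amp_sd``), independent noise,
    identical grid.  Deterministic given ``seed``.

    When ``scans`` is omitted it is sized to cover the session at TR 2 s.
    """
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    truth = truth or make_truth()
    hrf = hrf or HRFSpec()
    noise = noise if noise is not None else NoiseModel()
    master = np.random.SeedSequence(seed)
    subject_seeds = master.spawn(n_subjects)
    for s, sseq in enumerate(subject_seeds):
        rng = np.random.default_rng(sseq)
        trace_seed = int(rng.integers(2**31 - 1))
        trace, trials = _session_for(task, trace_seed, n_per_condition, trial_slot)
        run_scans = scans or ScanGrid(
            tr=2.0, n_scans=int(np.ceil(trace.end_time / 2.0)) + 8)
        mult = {
            m: max(0.0, 1.0 + truth.subject_amp_sd * rng.standard_normal())
            for m in truth.regions
        }
        data = simulate_subject_run(trace, truth, hrf, run_scans, noise, rng,
                                    amp_multiplier=mult)
        yield SubjectRun(subject=f"sub-{s + 1:02d}", data=data, trace=trace,
                         trials=trials, amp_multiplier=mult)


def simulate_group(*args, **kwargs) -> list[SubjectRun]:
    """Eager version of :func:`iter_group` (mind the memory for big grids)."""
    return list(iter_group(*args, **kwargs))


def make_toy_statmap(
    grid: VolumeGrid,
    blobs: list[tuple[tuple[float, float, float], int, float]],
    *,
    df: int = 17,
    rng: np.random.Generator | None = None,
    connectivity: int = 26,
) -> StatMap:
    """Toy stat map: null background plus blobs of exact voxel counts.

    Each blob is ``(center_mm, size_voxels, peak_t)``: the ``size`` voxels
    nearest the center (a connected, roughly spherical set) get t values
    decaying linearly from ``peak_t`` at the center to ``peak_t / 2`` at the
    rim.  The background is standard-normal null noise.  Raises when blobs
    collide or touch (which would merge components).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    t_map = rng.standard_normal(grid.dims)
    occupied = np.zeros(grid.dims, dtype=bool)
    structure = connectivity_structure(connectivity)
    ijk = np.argwhere(np.ones(grid.dims, dtype=bool))
    world = grid.voxel_to_world(ijk)
    for b, (center, size, peak_t) in enumerate(blobs):
        if size < 1:
            raise ValueError("blob size must be >= 1")
        dist = np.linalg.norm(world - np.asarray(center, float), axis=1)
        order = np.argsort(dist, kind="stable")[:size]
        vox = ijk[order]
        mask = np.zeros(grid.dims, dtype=bool)
        mask[tuple(vox.T)] = True
        grown = ndimage.binary_dilation(mask, structure=structure)
        if np.any(grown & occupied):
            raise ValueError(f"blob {b} collides with an earlier blob")
        occupied |= mask
        d = dist[order]
        dmax = d.max() if d.max() > 0 else 1.0
        t_map[tuple(vox.T)] = peak_t * (1.0 - 0.5 * d / dmax)
    p = np.clip(2.0 * stats.t.sf(np.abs(t_map), df), np.finfo(float).tiny, 1.0)
    return StatMap(grid=grid, t_values=t_map, p_values=p, df=df)
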