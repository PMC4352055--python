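"""Model-based fMRI regression and group statistical maps.

Convolved module demand functions are regressed voxelwise against 4D data
(ordinary least squares per subject), subject-level coefficients are
combined with a one-sample t test per voxel, and the group map is
thresholded voxelwise with a cluster-extent filter.  An exclusive-variance
(dissociation) contrast compares the unique variance of two regressors via
squared semipartial correlations, for module pairs with overlapping
activation patterns (problem state vs. declarative memory).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .bold import HRFSpec, ScanGrid, hrf_kernel, demand_to_boxcar, convolve_predict
from .task_models import MODULES, DemandTrace

__all__ = [
    "VolumeGrid",
    "DesignMatrix",
    "StatMap",
    "FirstLevelResult",
    "CollinearityError",
    "build_design_matrix",
    "first_level_fit",
    "group_map",
    "threshold_clusters",
    "exclusive_contrast",
    "connectivity_structure",
]

_P_FLOOR = np.finfo(float).tiny
_T_CAP = 1e12


class CollinearityError(ValueError):
    """Raised when design columns are (near-)collinear."""


@dataclass(frozen=True)
class VolumeGrid:
    """Voxel grid with a world (mm, MNI orientation) affine.

    The first voxel axis is left–right with negative world x on the left.
    """

    dims: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")
        if any(d <= 0 for d in self.dims):
            raise ValueError("dims must be positive")
        aff.setflags(write=False)
        object.__setattr__(self, "affine", aff)

    @property
    def voxel_size(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(ijk)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(xyz)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def matches(self, other: "VolumeGrid", atol: float = 1e-4) -> bool:
        return self.dims == other.dims and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def require_match(self, other: "VolumeGrid", what: str = "volume") -> None:
        if not self.matches(other):
            raise ValueError(f"{what}: grid mismatch (dims/affine differ)")


@dataclass
class DesignMatrix:
    """Scans × columns design with labeled columns (intercept last)."""

    values: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("design must be 2D")
        if self.values.shape[1] != len(self.names):
            raise ValueError("column count does not match names")
        if self.values.shape[0] <= self.values.shape[1]:
            raise ValueError("need more scans than design columns")

    @property
    def n_scans(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def drop(self, name: str) -> "DesignMatrix":
        j = self.names.index(name)
        return DesignMatrix(np.delete(self.values, j, axis=1),
                            [n for n in self.names if n != name])


@dataclass
class StatMap:
    """Voxelwise t and two-sided p on a grid."""

    grid: VolumeGrid
    t_values: np.ndarray
    p_values: np.ndarray
    df: int

    def __post_init__(self) -> None:
        self.t_values = np.asarray(self.t_values, dtype=float)
        self.p_values = np.asarray(self.p_values, dtype=float)
        if self.t_values.shape != tuple(self.grid.dims):
            raise ValueError("t_values shape does not match grid dims")
        if self.p_values.shape != self.t_values.shape:
            raise ValueError("p_values shape does not match t_values")
        if np.any(self.p_values <= 0) or np.any(self.p_values > 1):
            raise ValueError("p values must lie in (0, 1]")


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3D binary structure for 6-, 18-, or 26-neighborhood adjacency."""
    try:
        rank = {6: 1, 18: 2, 26: 3}[connectivity]
    except KeyError:
        raise ValueError("connectivity must be one of 6, 18, 26") from None
    return ndimage.generate_binary_structure(3, rank)


def build_design_matrix(
    trace: DemandTrace,
    hrf: HRFSpec,
    scans: ScanGrid,
    drift_order: int = 1,
) -> DesignMatrix:
    """One mean-centered convolved regressor per active module, plus
    polynomial drift terms up to ``drift_order`` and an intercept (last).

    Modules with empty demand are excluded with a warning (an all-zero
    regressor is degenerate).  A rank-deficient result raises
    :class:`CollinearityError` naming the most collinear column pair.
    """
    kernel = hrf_kernel(hrf)
    total = max(scans.duration, trace.end_time)
    cols, names = [], []
    for module in MODULES:
        if not trace.module_intervals(module):
            if module in trace.intervals:
                warnings.warn(f"module {module!r} has empty demand; column excluded",
                              stacklevel=2)
            continue
        box = demand_to_boxcar(trace, module, hrf.dt, total)
        x = convolve_predict(box, kernel, scans, hrf.dt)
        x = x - x.mean()
        sd = x.std()
        if sd == 0:
            warnings.warn(f"module {module!r} regressor is constant; column "
                          "excluded", stacklevel=2)
            continue
        cols.append(x / sd)  # unit-sd regressors: betas are in signal-sd units
        names.append(module)
    if not cols:
        raise ValueError("trace contains no active modules")
    u = np.linspace(-1.0, 1.0, scans.n_scans)
    for k in range(1, drift_order + 1):
        d = u**k
        cols.append(d - d.mean())
        names.append(f"drift_{k}")
    cols.append(np.ones(scans.n_scans))
    names.append("intercept")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify the offending pair for the error message
        C = np.corrcoef(X[:, :-1].T)
        np.fill_diagonal(C, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(C)), C.shape)
        raise CollinearityError(
            f"design matrix is rank deficient; columns {names[i]!r} and "
            f"{names[j]!r} are collinear (|r|={abs(C[i, j]):.4f})"
        )
    return DesignMatrix(X, names)


@dataclass
class FirstLevelResult:
    """Per-voxel OLS estimates for one subject."""

    grid: VolumeGrid
    names: list[str]
    betas: np.ndarray      # (p, nx, ny, nz)
    t_values: np.ndarray   # (p, nx, ny, nz)
    sigma2: np.ndarray     # residual variance, (nx, ny, nz)
    mask: np.ndarray       # bool, (nx, ny, nz)
    df: int

    def beta_map(self, name: str) -> np.ndarray:
        return self.betas[self.names.index(name)]

    def t_map(self, name: str) -> np.ndarray:
        return self.t_values[self.names.index(name)]


def first_level_fit(
    data: np.ndarray,
    design: DesignMatrix,
    grid: VolumeGrid,
    mask: np.ndarray | None = None,
) -> FirstLevelResult:
    """Voxelwise ordinary least squares of a 4D run against the design.

    ``data`` has shape ``(nx, ny, nz, n_scans)``.  Voxels with zero temporal
    variance are excluded from the mask; masked-out voxels carry zero betas
    and t values.  ``t = beta / SE(beta)`` with ``df = scans − columns``.
    """
    data = np.asarray(data, dtype=float)
    if data.shape[:3] != tuple(grid.dims):
        raise ValueError("data spatial shape does not match grid dims")
    X = design.values
    n, p = X.shape
    if data.shape[3] != n:
        raise ValueError(
            f"data has {data.shape[3]} scans but design has {n} rows"
        )
    variance = data.var(axis=3)
    auto_mask = variance > 0
    mask = auto_mask if mask is None else (np.asarray(mask, bool) & auto_mask)
    Y = data[mask].T                               # (n, V)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)                     # (p, V)
    resid = Y - X @ beta
    df = n - p
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, 0.0)
    out_beta = np.zeros((p, *grid.dims))
    out_t = np.zeros((p, *grid.dims))
    out_s2 = np.zeros(grid.dims)
    out_beta[:, mask] = beta
    out_t[:, mask] = np.clip(tvals, -_T_CAP, _T_CAP)
    out_s2[mask] = sigma2
    return FirstLevelResult(grid=grid, names=list(design.names), betas=out_beta,
                            t_values=out_t, sigma2=out_s2, mask=mask, df=df)


def _one_sample_t(stack: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """One-sample t across axis 0 with capped t and floored p."""
    n = stack.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    df = n - 1
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where(sd == 0, np.where(mean == 0, 0.0, np.sign(mean) * _T_CAP), t)
    t = np.clip(t, -_T_CAP, _T_CAP)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, _P_FLOOR, 1.0)
    return t, p, df


def group_map(subject_betas: list[np.ndarray], grid: VolumeGrid) -> StatMap:
    """Group one-sample t map over per-subject voxelwise beta maps."""
    if len(subject_betas) < 3:
        raise ValueError("need at least 3 subjects")
    for b in subject_betas:
        if np.asarray(b).shape != tuple(grid.dims):
            raise ValueError("subject beta map grid mismatch")
    stack = np.stack([np.asarray(b, dtype=float) for b in subject_betas])
    t, p, df = _one_sample_t(stack)
    return StatMap(grid=grid, t_values=t, p_values=p, df=df)


def threshold_clusters(
    statmap: StatMap,
    p_thresh: float = 1e-7,
    min_extent: int = 250,
    connectivity: int = 26,
) -> np.ndarray:
    """Voxelwise threshold + cluster-extent filter.

    Voxels with ``p < p_thresh`` form connected components under the chosen
    connectivity; components smaller than ``min_extent`` voxels are removed
    and the survivors relabeled 1, 2, … by descending peak |t|.  Returns an
    int32 label volume (0 = background); an empty result is allowed.
    """
    structure = connectivity_structure(connectivity)
    supra = statmap.p_values < p_thresh
    labels, n = ndimage.label(supra, structure=structure)
    out = np.zeros(statmap.t_values.shape, dtype=np.int32)
    if n == 0:
        return out
    sizes = np.bincount(labels.ravel())
    keep = [lab for lab in range(1, n + 1) if sizes[lab] >= min_extent]
    abs_t = np.abs(statmap.t_values)
    peaks = ndimage.maximum(abs_t, labels=labels, index=keep) if keep else []
    order = [lab for _, lab in sorted(zip(peaks, keep), key=lambda x: -x[0])]
    for new, lab in enumerate(order, start=1):
        out[labels == lab] = new
    return out


def _sp_r2(Y: np.ndarray, design: DesignMatrix, reg: str) -> np.ndarray:
    """Squared semipartial correlation of ``reg`` (given all other columns),
    per voxel: R²(full) − R²(without reg)."""
    X_full = design.values
    X_red = design.drop(reg).values
    sst = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)

    def sse(X: np.ndarray) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        r = Y - X @ beta
        return (r**2).sum(axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        out = (sse(X_red) - sse(X_full)) / sst
    return np.where(sst > 0, out, 0.0)


def exclusive_contrast(
    subject_data: list[tuple[np.ndarray, DesignMatrix]],
    grid: VolumeGrid,
    reg_a: str,
    reg_b: str,
    *,
    collinearity_limit: float = 0.99,
) -> StatMap:
    """Dissociation map: where does ``reg_a`` explain more unique variance
    than ``reg_b``?

    Per subject and voxel the difference of squared semipartial correlations
    (a given all others − b given all others) is computed; the group map is
    a one-sample t over the per-subject differences (positive tail =
    a-exclusive).  Raises :class:`CollinearityError` when the two regressors
    correlate above ``collinearity_limit`` in any subject's design.
    """
    diffs = []
    for data, design in subject_data:
        xa, xb = design.column(reg_a), design.column(reg_b)
        r = np.corrcoef(xa, xb)[0, 1]
        if abs(r) > collinearity_limit:
            raise CollinearityError(
                f"regressors {reg_a!r} and {reg_b!r} are collinear (|r|={abs(r):.3f})"
            )
        data = np.asarray(data, dtype=float)
        if data.shape[:3] != tuple(grid.dims):
            raise ValueError("subject data grid mismatch")
        mask = data.var(axis=3) > 0
        Y = data[mask].T
        d = np.zeros(grid.dims)
        d[mask] = _sp_r2(Y, design, reg_a) - _sp_r2(Y, design, reg_b)
        diffs.append(d)
    t, p, df = _one_sample_t(np.stack(diffs))
    return StatMap(grid=grid, t_values=t, p_values=p, df=df)
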