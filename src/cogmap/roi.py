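"""Seeded region growing and ROI geometry.

Fixed-size regions of interest are grown greedily from a thresholded group
statistical map: starting at the most significant suprathreshold voxel, the
most significant voxel bordering the current region is added iteratively
until the target size (100 voxels by default) is reached or the component
is exhausted.  The growth domain can be restricted to an anatomical label
set beforehand (as done for the manual module, limited to the precentral
gyrus), and left-hemisphere regions can be mirrored through the x = 0 mm
midsagittal plane to create right-hemisphere homologues.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass

import numpy as np

from .glm import StatMap, VolumeGrid, connectivity_structure

__all__ = ["ROIMask", "grow_region", "restrict_domain", "mirror_roi",
           "center_of_mass"]


@dataclass
class ROIMask:
    """Binary region on a grid with provenance metadata."""

    grid: VolumeGrid
    mask: np.ndarray
    seed: tuple[int, int, int] | None = None
    module: str = ""
    hemisphere: str = "left"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != tuple(self.grid.dims):
            raise ValueError("mask shape does not match grid dims")
        if self.seed is not None:
            self.seed = tuple(int(v) for v in self.seed)
            if not self.mask[self.seed]:
                raise ValueError("seed voxel is not inside the mask")

    @property
    def size(self) -> int:
        return int(self.mask.sum())

    @property
    def voxels(self) -> np.ndarray:
        return np.argwhere(self.mask)

    @property
    def center_of_mass(self) -> np.ndarray:
        return center_of_mass(self)

    def dice(self, other: "ROIMask | np.ndarray") -> float:
        other_mask = other.mask if isinstance(other, ROIMask) else np.asarray(other, bool)
        inter = np.logical_and(self.mask, other_mask).sum()
        denom = self.mask.sum() + other_mask.sum()
        return 2.0 * inter / denom if denom else 0.0


def _neighbor_offsets(connectivity: int) -> np.ndarray:
    s = connectivity_structure(connectivity)
    offs = np.argwhere(s) - 1
    return offs[np.any(offs != 0, axis=1)]


def grow_region(
    statmap: StatMap,
    supra_mask: np.ndarray,
    seed: tuple[int, int, int] | str = "auto",
    target_size: int = 100,
    connectivity: int = 26,
    *,
    signed: bool = False,
    module: str = "",
    hemisphere: str = "left",
) -> ROIMask:
    """Grow a fixed-size region greedily from a seed in a stat map.

    Significance is |t| by default (``signed=True`` uses raw t).  At each
    step the most significant suprathreshold voxel adjacent to the current
    region is added (ties broken by lowest linear voxel index, so growth is
    deterministic).  Growth stops at ``target_size`` voxels or when the
    suprathreshold component is exhausted, in which case the smaller region
    is returned with a warning.
    """
    supra = np.asarray(supra_mask, dtype=bool)
    if supra.shape != tuple(statmap.grid.dims):
        raise ValueError("supra_mask shape does not match grid dims")
    if not supra.any():
        raise ValueError("supra_mask is empty")
    if target_size < 1:
        raise ValueError("target_size must be at least 1")
    score = statmap.t_values if signed else np.abs(statmap.t_values)
    if seed == "auto":
        masked = np.where(supra, score, -np.inf)
        seed = tuple(int(v) for v in np.unravel_index(np.argmax(masked), supra.shape))
    else:
        seed = tuple(int(v) for v in seed)
        if not supra[seed]:
            raise ValueError(f"seed {seed} is not suprathreshold")

    dims = supra.shape
    offsets = _neighbor_offsets(connectivity)
    region = np.zeros(dims, dtype=bool)
    in_heap = np.zeros(dims, dtype=bool)
    heap: list[tuple[float, int]] = []

    def push(vox: tuple[int, int, int]) -> None:
        lin = int(np.ravel_multi_index(vox, dims))
        heapq.heappush(heap, (-float(score[vox]), lin))
        in_heap[vox] = True

    push(seed)
    while heap and region.sum() < target_size:
        _, lin = heapq.heappop(heap)
        vox = tuple(int(v) for v in np.unravel_index(lin, dims))
        if region[vox]:
            continue
        region[vox] = True
        for off in offsets:
            nb = (vox[0] + off[0], vox[1] + off[1], vox[2] + off[2])
            if any(c < 0 or c >= d for c, d in zip(nb, dims)):
                continue
            if supra[nb] and not region[nb] and not in_heap[nb]:
                push(nb)

    n = int(region.sum())
    if n < target_size:
        warnings.warn(
            f"region growth exhausted the suprathreshold component at {n} voxels "
            f"(target {target_size})",
            stacklevel=2,
        )
    return ROIMask(grid=statmap.grid, mask=region, seed=seed, module=module,
                   hemisphere=hemisphere)


def restrict_domain(
    supra_mask: np.ndarray,
    label_image: np.ndarray,
    keep_labels: list[int] | set[int],
    grid: VolumeGrid,
    label_grid: VolumeGrid | None = None,
) -> np.ndarray:
    """Intersect a suprathreshold mask with an anatomical label set.

    Applied to the growth domain *before* region growing (e.g. restricting
    the manual module to the precentral gyrus).  Raises when the label image
    lives on a different grid or when the intersection is empty.
    """
    if label_grid is not None:
        grid.require_match(label_grid, "anatomical label image")
    supra = np.asarray(supra_mask, dtype=bool)
    labels = np.asarray(label_image)
    if labels.shape != supra.shape:
        raise ValueError("label image shape does not match mask")
    keep = np.isin(labels, list(keep_labels))
    out = supra & keep
    if not out.any():
        raise ValueError(
            f"restriction to labels {sorted(set(keep_labels))} leaves no "
            "suprathreshold voxels"
        )
    return out


def mirror_roi(roi: ROIMask) -> ROIMask:
    """Mirror a region through the midsagittal plane (world x = 0 mm).

    Each member voxel's world coordinate has its x negated and is mapped to
    the nearest voxel; reflections landing outside the grid are dropped with
    a warning reporting the count.  The hemisphere label flips.
    """
    vox = roi.voxels
    if vox.size == 0:
        raise ValueError("cannot mirror an empty ROI")
    world = roi.grid.voxel_to_world(vox)
    world[:, 0] *= -1.0
    back = np.rint(roi.grid.world_to_voxel(world)).astype(int)
    dims = np.asarray(roi.grid.dims)
    inside = np.all((back >= 0) & (back < dims), axis=1)
    dropped = int((~inside).sum())
    if dropped:
        warnings.warn(
            f"{dropped} mirrored voxel(s) fell outside the grid and were dropped",
            stacklevel=2,
        )
    back = back[inside]
    mask = np.zeros(roi.grid.dims, dtype=bool)
    mask[tuple(back.T)] = True
    new_seed = None
    if roi.seed is not None:
        sw = roi.grid.voxel_to_world(np.asarray(roi.seed, float))
        sw[:, 0] *= -1.0
        sv = np.rint(roi.grid.world_to_voxel(sw)).astype(int)[0]
        if np.all((sv >= 0) & (sv < dims)) and mask[tuple(sv)]:
            new_seed = tuple(int(v) for v in sv)
    return ROIMask(
        grid=roi.grid,
        mask=mask,
        seed=new_seed,
        module=roi.module,
        hemisphere={"left": "right", "right": "left"}.get(roi.hemisphere, roi.hemisphere),
    )


def center_of_mass(roi: ROIMask) -> np.ndarray:
    """Unweighted mean of member-voxel world (mm) coordinates."""
    vox = roi.voxels
    if vox.size == 0:
        raise ValueError("center of mass of an empty ROI is undefined")
    return roi.grid.voxel_to_world(vox).mean(axis=0)
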