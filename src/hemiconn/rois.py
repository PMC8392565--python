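"""Sphere ROI construction, hemisphere masking and midline mirroring.

The social-brain ROI collection mixes midline regions (medial prefrontal
cortex, precuneus, anterior mid-cingulate) with bilateral pairs (TPJ,
insula, MFG, S2).  To probe a single hemisphere the collection is recast
into three variants:

* ``bilateral`` — the original masks;
* ``left`` — midline masks intersected with the left hemisphere, left
  lateral masks kept, right lateral masks dropped;
* ``right`` — lateral right masks kept, and each midline mask rebuilt as
  its right-hemisphere voxels unioned with the mirror image of its
  left-hemisphere voxels (midline regions are often left-dominant, so a
  plain right intersection would under-represent them).

Hemisphere membership is decided by the world x coordinate of the voxel
center; voxels exactly on the x = 0 plane belong to neither hemisphere.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import ImageGrid

log = logging.getLogger(__name__)

NETWORKS = ("ToM", "PAIN")
LATERALITIES = ("midline", "left", "right")
VARIANTS = ("bilateral", "left", "right")


@dataclass(frozen=True)
class ROIDefinition:
    """A sphere ROI: name, network, laterality, world-mm center, radius."""

    name: str
    network: str
    laterality: str
    center: tuple[float, float, float]
    radius: float = 9.0

    def __post_init__(self) -> None:
        if self.network not in NETWORKS:
            raise ValueError(f"unknown network {self.network!r}; expected one of {NETWORKS}")
        if self.laterality not in LATERALITIES:
            raise ValueError(
                f"unknown laterality {self.laterality!r}; expected one of {LATERALITIES}"
            )
        if self.radius <= 0:
            raise ValueError(f"radius must be positive, got {self.radius}")


@dataclass
class ROIMask:
    """Binary mask on an :class:`ImageGrid` with network membership."""

    data: np.ndarray
    grid: ImageGrid
    name: str
    network: str = "ToM"
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.shape != self.grid.dims:
            raise ValueError(
                f"mask shape {self.data.shape} does not match grid dims {self.grid.dims}"
            )
        if not self.degenerate and self.n_voxels == 0:
            self.degenerate = True

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class ROISet:
    """Ordered collection of ROI masks sharing one grid."""

    variant: str
    masks: dict[str, ROIMask] = field(default_factory=dict)
    dropped: dict[str, str] = field(default_factory=dict)  # name -> reason

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        grids = {id(m.grid): m.grid for m in self.masks.values()}
        if len({(g.dims, g.voxel_size, g.origin) for g in grids.values()}) > 1:
            raise ValueError("all masks in an ROISet must share one grid")

    @property
    def grid(self) -> ImageGrid:
        return next(iter(self.masks.values())).grid

    @property
    def names(self) -> list[str]:
        return list(self.masks)

    @property
    def membership(self) -> dict[str, str]:
        return {name: m.network for name, m in self.masks.items()}

    def manifest(self) -> dict:
        return {
            "variant": self.variant,
            "rois": [
                {
                    "name": m.name,
                    "network": m.network,
                    "n_voxels": m.n_voxels,
                    "degenerate": m.degenerate,
                }
                for m in self.masks.values()
            ],
            "dropped": dict(self.dropped),
        }

    def write_manifest(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=2)


# ---------------------------------------------------------------------------
# construction

def build_sphere_roi(defn: ROIDefinition, grid: ImageGrid, network: str | None = None) -> ROIMask:
    """Closed-ball sphere mask: voxel centers within ``radius`` mm of the center."""
    x, y, z = grid.coordinate_volumes()
    cx, cy, cz = defn.center
    d2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
    data = d2 <= defn.radius**2
    if not data.any():
        raise ValueError(f"sphere ROI {defn.name!r} lies entirely outside the grid")
    return ROIMask(data, grid, defn.name, network or defn.network)


def hemisphere_mask(grid: ImageGrid, side: str) -> ROIMask:
    """Binary hemisphere mask by sign of the voxel-center world x.

    Voxels whose centers lie exactly at x = 0 belong to neither side.
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    x = grid.axis_coords(0)
    sel = x < 0 if side == "left" else x > 0
    data = np.zeros(grid.dims, dtype=bool)
    data[sel, :, :] = True
    return ROIMask(data, grid, f"{side}_hemisphere", degenerate=not data.any())


def restrict_to_hemisphere(roi: ROIMask, side: str) -> ROIMask:
    """Intersect an ROI with one hemisphere; may come back empty (degenerate)."""
    hemi = hemisphere_mask(roi.grid, side)
    data = roi.data & hemi.data
    return ROIMask(data, roi.grid, roi.name, roi.network, degenerate=not data.any())


def mirror_across_midline(roi: ROIMask) -> ROIMask:
    """Reflect a mask across the midsagittal plane (world x -> -x).

    Requires an x-symmetric grid so every mirror target lands on a voxel
    center.  The operation is a bijection on voxels: it conserves the voxel
    count and applying it twice is the identity.
    """
    if not roi.grid.is_x_symmetric:
        raise ValueError(
            "mirror_across_midline requires a grid symmetric about x=0; "
            "mirror targets would fall between voxel centers"
        )
    return replace(roi, data=np.flip(roi.data, axis=0))


def make_lateralized_set(bilateral: ROISet, variant: str) -> ROISet:
    """Derive a lateralized ROI set from the bilateral one.

    left:  midline ROIs ∩ left hemisphere; left lateral ROIs kept; right dropped.
    right: midline ROIs -> (∩ right) ∪ mirror(∩ left); right laterals kept;
           left dropped.  Mirrored voxels coinciding with existing right-
           hemisphere voxels are unioned (masks are binary).
    Empty results are dropped from the set with a recorded reason.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    if variant == "bilateral":
        return bilateral

    lateralities = _lateralities_from_names(bilateral)
    masks: dict[str, ROIMask] = {}
    dropped: dict[str, str] = {}
    for name, roi in bilateral.masks.items():
        side = lateralities[name]
        if side == variant:
            masks[name] = roi
        elif side != "midline":
            continue  # lateral ROI of the other hemisphere: dropped by design
        else:
            if variant == "left":
                new = restrict_to_hemisphere(roi, "left")
            else:
                right_part = restrict_to_hemisphere(roi, "right")
                mirrored_left = mirror_across_midline(restrict_to_hemisphere(roi, "left"))
                new = replace(roi, data=right_part.data | mirrored_left.data)
                new.degenerate = not new.data.any()
            if new.degenerate:
                reason = f"midline ROI {name!r} empty after {variant} lateralization"
                warnings.warn(reason, stacklevel=2)
                log.warning(reason)
                dropped[name] = reason
            else:
                masks[name] = new
    return ROISet(variant=variant, masks=masks, dropped=dropped)


def _lateralities_from_names(roiset: ROISet) -> dict[str, str]:
    """Infer per-ROI laterality from mask geometry.

    An ROI entirely in one hemisphere is lateral to that side; anything
    straddling (or touching) the midline is treated as midline.
    """
    out = {}
    for name, roi in roiset.masks.items():
        left = restrict_to_hemisphere(roi, "left").n_voxels
        right = restrict_to_hemisphere(roi, "right").n_voxels
        if left and not right:
            out[name] = "left"
        elif right and not left:
            out[name] = "right"
        else:
            out[name] = "midline"
    return out


def build_roi_set(
    definitions: list[ROIDefinition] | pd.DataFrame,
    grid: ImageGrid,
    variant: str = "bilateral",
) -> ROISet:
    """Build sphere masks for every definition, then lateralize if asked."""
    if isinstance(definitions, pd.DataFrame):
        definitions = definitions_from_table(definitions)
    masks = {d.name: build_sphere_roi(d, grid) for d in definitions}
    bilateral = ROISet(variant="bilateral", masks=masks)
    return make_lateralized_set(bilateral, variant)


# ---------------------------------------------------------------------------
# soft masking and resampling

def soft_hemisphere_mask(
    anatomy: np.ndarray, grid: ImageGrid, side: str, sigma_mm: float = 0.5
) -> np.ndarray:
    """Hemisphere weights in [0, 1]: a binarized hemisphere mask of the
    anatomy smoothed with an isotropic Gaussian (default sigma 0.5 mm).

    The smooth edge avoids a hard intensity cliff at the midline when the
    weights multiply an anatomical image.
    """
    if sigma_mm < 0:
        raise ValueError(f"sigma_mm must be nonnegative, got {sigma_mm}")
    anatomy = np.asarray(anatomy)
    if anatomy.shape != grid.dims:
        raise ValueError("anatomy shape does not match grid")
    hard = (anatomy > 0) & hemisphere_mask(grid, side).data
    if sigma_mm == 0:
        return hard.astype(float)
    weights = ndimage.gaussian_filter(hard.astype(float), sigma=sigma_mm / grid.voxel_size)
    return np.clip(weights, 0.0, 1.0)


def apply_soft_mask(volume: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Voxelwise multiplication of an image by a weight volume."""
    volume = np.asarray(volume, dtype=float)
    if volume.shape[:3] != weights.shape:
        raise ValueError("volume and weights shapes do not match")
    if volume.ndim == 4:
        return volume * weights[..., None]
    return volume * weights


def resample_binarize(
    prob: np.ndarray,
    source_grid: ImageGrid,
    target_grid: ImageGrid,
    threshold: float = 0.5,
    name: str = "resampled",
    network: str = "ToM",
) -> ROIMask:
    """Trilinearly resample a probabilistic mask onto a grid, then keep
    voxels whose interpolated value is >= threshold (ties included)."""
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    prob = np.asarray(prob, dtype=float)
    if prob.shape != source_grid.dims:
        raise ValueError("probabilistic mask shape does not match its grid")
    tx, ty, tz = target_grid.coordinate_volumes()
    world = np.stack([tx, ty, tz], axis=0).reshape(3, -1).T
    vox = source_grid.world_to_voxel(world).T
    values = ndimage.map_coordinates(prob, vox, order=1, mode="constant", cval=0.0)
    data = (values >= threshold).reshape(target_grid.dims)
    mask = ROIMask(data, target_grid, name, network, degenerate=not data.any())
    if mask.degenerate:
        log.warning("resample_binarize produced an empty mask for %r", name)
    return mask


# ---------------------------------------------------------------------------
# definition tables and NIfTI I/O

ROI_TABLE_COLUMNS = ["name", "network", "laterality", "x", "y", "z", "radius_mm"]


def definitions_to_table(definitions: list[ROIDefinition]) -> pd.DataFrame:
    rows = [
        (d.name, d.network, d.laterality, *d.center, d.radius) for d in definitions
    ]
    return pd.DataFrame(rows, columns=ROI_TABLE_COLUMNS)


def definitions_from_table(table: pd.DataFrame) -> list[ROIDefinition]:
    missing = set(ROI_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"ROI table is missing columns: {sorted(missing)}")
    return [
        ROIDefinition(
            name=str(r["name"]),
            network=str(r["network"]),
            laterality=str(r["laterality"]),
            center=(float(r["x"]), float(r["y"]), float(r["z"])),
            radius=float(r["radius_mm"]),
        )
        for _, r in table.iterrows()
    ]


def read_roi_definitions(path) -> list[ROIDefinition]:
    return definitions_from_table(pd.read_csv(path, sep="\t"))


def write_roi_definitions(definitions: list[ROIDefinition], path) -> None:
    definitions_to_table(definitions).to_csv(path, sep="\t", index=False)


def save_volume(data: np.ndarray, grid: ImageGrid, path) -> None:
    """Write a volume (3-D or 4-D) as NIfTI with the grid's RAS+ affine."""
    arr = np.asarray(data)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    nib.save(nib.Nifti1Image(arr, grid.affine), str(path))


def load_volume(path) -> tuple[np.ndarray, ImageGrid]:
    """Load a NIfTI volume, reorienting to RAS+ and recovering the grid.

    Only axis-aligned isotropic grids are supported; anything else has gone
    through a registration step this package deliberately does not perform.
    """
    img = nib.as_closest_canonical(nib.load(str(path)))
    aff = img.affine
    lin = aff[:3, :3]
    vs = float(lin[0, 0])
    if not np.allclose(lin, np.eye(3) * vs, atol=1e-4):
        raise ValueError(f"{path}: only axis-aligned isotropic RAS+ grids are supported")
    data = np.asarray(img.dataobj)
    grid = ImageGrid(data.shape[:3], vs, tuple(aff[:3, 3]))
    return data, grid
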