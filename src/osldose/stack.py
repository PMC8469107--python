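"""Water-equivalent depth bookkeeping and 3D grid assembly for foil stacks.

The measurement phantom is a polystyrene hemispherical cap followed by a
tight stack of thin luminescent foils.  Each foil integrates dose over
its own thickness, so its signal is assigned to the water-equivalent
depth of the foil mid-plane; per-material water-equivalent-thickness
(WET) factors convert physical thickness to water depth.  Corrected 2D
foil images are registered laterally (foil placement under the camera
jitters between readouts) and stacked into a 3D relative dose grid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .correction import FoilImage, FoilROI, RegistrationError

__all__ = [
    "StackGeometry",
    "DoseGrid3D",
    "foil_center_depth",
    "foil_depths",
    "register_slices",
    "assemble_grid",
    "normalize",
]

NORMALIZATION_MODES = ("none", "global_max", "per_slice_max")


@dataclass(frozen=True)
class StackGeometry:
    """Foil-stack phantom geometry and water-equivalence factors.

    Defaults describe a 10 mm polystyrene cap followed by forty
    0.543 mm foils, both with WET factor 1.05, i.e. a total
    water-equivalent range of (10 + 40 x 0.543) x 1.05 = 33.31 mm.
    """

    n_foils: int = 40
    foil_thickness_mm: float = 0.543
    cap_thickness_mm: float = 10.0
    wet_factor_foil: float = 1.05
    wet_factor_cap: float = 1.05

    def __post_init__(self) -> None:
        if self.n_foils < 1:
            raise ValueError("n_foils must be >= 1")
        for name in ("foil_thickness_mm", "cap_thickness_mm", "wet_factor_foil", "wet_factor_cap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def total_water_range_mm(self) -> float:
        """Water-equivalent depth of the back edge of the last foil."""
        return (
            self.cap_thickness_mm * self.wet_factor_cap
            + self.n_foils * self.foil_thickness_mm * self.wet_factor_foil
        )


def foil_center_depth(geom: StackGeometry, i: int) -> float:
    """Water-equivalent depth of the mid-plane of foil ``i`` (1-based)."""
    if not 1 <= i <= geom.n_foils:
        raise IndexError(f"foil index {i} out of range 1..{geom.n_foils}")
    return (
        geom.cap_thickness_mm * geom.wet_factor_cap
        + (i - 0.5) * geom.foil_thickness_mm * geom.wet_factor_foil
    )


def foil_depths(geom: StackGeometry) -> np.ndarray:
    """Water-equivalent mid-plane depths of all foils, ascending."""
    return np.array([foil_center_depth(geom, i) for i in range(1, geom.n_foils + 1)])


@dataclass
class DoseGrid3D:
    """Relative dose on a regular (x, y, water-depth) grid.

    ``values`` is indexed ``[z, y, x]``; lateral axes are millimetres in
    the beam's-eye plane, ``z_axis`` is water-equivalent depth in mm.
    ``valid`` marks voxels backed by measured (unmasked) pixels.
    """

    values: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray
    normalization_mode: str = "none"
    valid: np.ndarray | None = None
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.x_axis = np.asarray(self.x_axis, dtype=float)
        self.y_axis = np.asarray(self.y_axis, dtype=float)
        self.z_axis = np.asarray(self.z_axis, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be 3D [z, y, x]")
        nz, ny, nx = self.values.shape
        if (len(self.z_axis), len(self.y_axis), len(self.x_axis)) != (nz, ny, nx):
            raise ValueError("axis lengths must match values shape")
        for name, ax in (("x_axis", self.x_axis), ("y_axis", self.y_axis), ("z_axis", self.z_axis)):
            if ax.size > 1 and not np.all(np.diff(ax) > 0):
                raise ValueError(f"{name} must be strictly increasing")
        if self.normalization_mode not in NORMALIZATION_MODES:
            raise ValueError(f"unknown normalization mode {self.normalization_mode!r}")
        if self.valid is None:
            self.valid = np.ones(self.values.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.values.shape:
                raise ValueError("valid mask shape must match values")


def register_slices(
    slices: list[FoilImage], margin_px: int = 2
) -> list[FoilImage]:
    """Align foil images on a common lateral grid via their ROI centers.

    Each slice is translated so that its detected foil center lands on
    the stack-mean center, with bilinear resampling; the output grid is
    a square sized from the median foil radius.  Masks are propagated
    conservatively: a resampled pixel is valid only when every
    contributing source pixel is valid.  Slices whose radius deviates
    more than 10% from the median are rejected.
    """
    if not slices:
        raise ValueError("no slices to register")
    for s in slices:
        if s.roi is None:
            raise RegistrationError(f"slice (foil {s.foil_index}) has no detected ROI")
    radii = np.array([s.roi.radius for s in slices])
    med_r = float(np.median(radii))
    bad = [s.foil_index for s, r in zip(slices, radii) if abs(r - med_r) > 0.10 * med_r]
    if bad:
        raise RegistrationError(
            f"foil(s) {bad} have ROI radius deviating >10% from the median "
            f"({med_r:.1f} px); rejected"
        )
    centers = np.array([s.full_frame_center for s in slices])
    cbar = centers.mean(axis=0)
    half = int(round(med_r)) + margin_px
    size = 2 * half + 1
    top = np.round(cbar).astype(int) - half  # full-frame coords of output pixel (0, 0)
    out_center = (cbar[0] - top[0], cbar[1] - top[1])

    rows, cols = np.mgrid[0:size, 0:size].astype(float)
    registered: list[FoilImage] = []
    for s, center in zip(slices, centers):
        shift = center - cbar  # sample source at out + shift
        offset = top + shift - np.asarray(s.origin, dtype=float)
        if np.allclose(offset, np.round(offset), atol=1e-9):
            # integer translation: exact extraction, no interpolation
            oi = np.round(offset).astype(int)
            pix = np.zeros((size, size))
            msk = np.zeros((size, size), dtype=bool)
            src_r0, src_c0 = max(0, oi[0]), max(0, oi[1])
            src_r1 = min(s.pixels.shape[0], oi[0] + size)
            src_c1 = min(s.pixels.shape[1], oi[1] + size)
            if src_r1 > src_r0 and src_c1 > src_c0:
                dst_r0, dst_c0 = src_r0 - oi[0], src_c0 - oi[1]
                pix[dst_r0 : dst_r0 + (src_r1 - src_r0), dst_c0 : dst_c0 + (src_c1 - src_c0)] = (
                    s.pixels[src_r0:src_r1, src_c0:src_c1]
                )
                msk[dst_r0 : dst_r0 + (src_r1 - src_r0), dst_c0 : dst_c0 + (src_c1 - src_c0)] = (
                    s.mask[src_r0:src_r1, src_c0:src_c1]
                )
        else:
            coords = np.array([rows + offset[0], cols + offset[1]])
            filled = np.where(s.mask, s.pixels, 0.0)
            pix = ndimage.map_coordinates(filled, coords, order=1, cval=0.0)
            mask_f = ndimage.map_coordinates(
                s.mask.astype(float), coords, order=1, cval=0.0
            )
            msk = mask_f >= 1.0 - 1e-9
            pix[~msk] = 0.0
        registered.append(
            replace(
                s,
                pixels=pix,
                mask=msk,
                roi=FoilROI(center=out_center, radius=s.roi.radius),
                origin=(0, 0),
                steps=s.steps + ("register_slices",),
            )
        )
    return registered


def assemble_grid(
    slices: list[FoilImage], geom: StackGeometry, pixel_pitch_mm: float
) -> DoseGrid3D:
    """Stack registered slices into a 3D grid at their foil depths.

    Lateral axes are millimetres relative to the common registered foil
    center; no depth interpolation is performed, the grid simply holds
    one measured plane per foil.
    """
    if not slices:
        raise ValueError("no slices to assemble")
    shape = slices[0].pixels.shape
    for s in slices:
        if s.pixels.shape != shape:
            raise ValueError("all slices must share one lateral grid; register first")
    idx = [s.foil_index for s in slices]
    if len(set(idx)) != len(idx):
        raise ValueError(f"duplicate foil indices (depth collision): {sorted(idx)}")
    order = np.argsort(idx)
    slices = [slices[i] for i in order]
    z = np.array([foil_center_depth(geom, s.foil_index) for s in slices])
    values = np.stack([s.pixels for s in slices])
    valid = np.stack([s.mask for s in slices])
    center = slices[0].roi.center if slices[0].roi is not None else (
        (shape[0] - 1) / 2.0,
        (shape[1] - 1) / 2.0,
    )
    y_axis = (np.arange(shape[0]) - center[0]) * pixel_pitch_mm
    x_axis = (np.arange(shape[1]) - center[1]) * pixel_pitch_mm
    return DoseGrid3D(
        values=values,
        x_axis=x_axis,
        y_axis=y_axis,
        z_axis=z,
        normalization_mode="none",
        valid=valid,
        provenance=("assemble_grid",),
    )


def normalize(grid: DoseGrid3D, mode: str) -> DoseGrid3D:
    """Return a copy normalised to the 3D maximum or per-depth maxima.

    ``global_max`` mirrors normalising to the maximum of the whole 3D
    signal; ``per_slice_max`` normalises each depth's cross-section to
    its own maximum (the convention used for field-shape comparisons).
    """
    if mode not in NORMALIZATION_MODES:
        raise ValueError(f"unknown normalization mode {mode!r}")
    values = grid.values.copy()
    if mode == "none":
        return replace(grid, values=values, normalization_mode="none")
    if not grid.valid.any():
        raise ValueError("grid has no valid voxels")
    if mode == "global_max":
        m = float(values[grid.valid].max())
        if m <= 0:
            raise ValueError("grid maximum is not positive; cannot normalize")
        values /= m
    else:  # per_slice_max
        for k in range(values.shape[0]):
            sl_valid = grid.valid[k]
            if not sl_valid.any():
                raise ValueError(f"slice at z={grid.z_axis[k]:.3f} mm has no valid voxels")
            m = float(values[k][sl_valid].max())
            if m <= 0:
                raise ValueError(
                    f"slice at z={grid.z_axis[k]:.3f} mm has non-positive maximum"
                )
            values[k] /= m
    return replace(
        grid,
        values=values,
        normalization_mode=mode,
        provenance=grid.provenance + (f"normalize:{mode}",),
    )
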