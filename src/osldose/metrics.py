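"""Depth/lateral profile extraction, SOBP metrics and grid comparison.

Clinical metrics of a spread-out Bragg peak (SOBP) are read off the
central depth-dose profile: the plateau level, the distal depths R90
and R10 where dose falls to 90% / 10% of the plateau, the distal
fall-off R10 - R90, and the modulation, taken here as the distance from
the proximal to the distal 90% crossing (the prevailing ocular-beam
convention).  Because foil stacks sample depth coarsely (one point per
foil), the distal edge is refined by fitting a Gaussian-CDF (erf) edge
to the distal segment.  Lateral field shape is compared through line
profiles and marching-squares isodose contours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from scipy.interpolate import RegularGridInterpolator
from skimage import measure

from .stack import DoseGrid3D

__all__ = [
    "MetricsError",
    "NoCrossingError",
    "DepthDoseCurve",
    "SOBPMetrics",
    "IsodoseSet",
    "LateralProfile",
    "ComparisonReport",
    "central_depth_profile",
    "lateral_profile",
    "sobp_metrics",
    "extract_isodose",
    "compare_grids",
]

_Z90 = float(stats.norm.ppf(0.9))  # 1.2816: 90% quantile of the standard normal


class MetricsError(ValueError):
    """Invalid input to a metric extraction."""


class NoCrossingError(MetricsError):
    """A required dose level is never crossed by the profile."""


@dataclass
class DepthDoseCurve:
    """Relative dose versus water-equivalent depth."""

    depths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.depths.shape != self.values.shape or self.depths.ndim != 1:
            raise MetricsError("depths and values must be matching 1D arrays")
        if not np.all(np.isfinite(self.depths)) or not np.all(np.isfinite(self.values)):
            raise MetricsError("curve must be finite")
        if self.depths.size > 1 and not np.all(np.diff(self.depths) > 0):
            raise MetricsError("depths must be strictly increasing")
        if np.any(self.values < 0):
            raise MetricsError("relative dose must be non-negative")


@dataclass(frozen=True)
class SOBPMetrics:
    """Clinical summary of a spread-out Bragg peak."""

    r90: float
    r10: float
    distal_falloff: float
    modulation: float
    plateau_level: float

    def __post_init__(self) -> None:
        if not self.r10 > self.r90:
            raise MetricsError("R10 must lie deeper than R90")
        if self.modulation <= 0:
            raise MetricsError("modulation must be positive")


@dataclass
class IsodoseSet:
    """Isodose contours per relative level, polylines in mm (x, y)."""

    levels: tuple[float, ...]
    contours: dict[float, list[np.ndarray]]


@dataclass
class LateralProfile:
    """A lateral line profile at fixed depth."""

    coords_mm: np.ndarray
    values: np.ndarray
    valid: np.ndarray
    depth_mm: float
    axis: str


def _field_centroid(values: np.ndarray, valid: np.ndarray, y_axis, x_axis) -> tuple[float, float]:
    w = np.where(valid, np.clip(values, 0.0, None), 0.0)
    if w.ndim == 3:
        w = w.sum(axis=0)
    total = w.sum()
    if total <= 0:
        raise MetricsError("cannot locate field centroid: no positive signal")
    cy = float((w.sum(axis=1) * y_axis).sum() / total)
    cx = float((w.sum(axis=0) * x_axis).sum() / total)
    return cy, cx


def central_depth_profile(grid: DoseGrid3D, window_mm: float = 2.0) -> DepthDoseCurve:
    """Mean dose in a lateral window around the field centroid, per depth.

    Averaging over a small square window (default 2 mm side) suppresses
    the pixel noise a single-column profile would carry.
    """
    if window_mm <= 0:
        raise MetricsError("window_mm must be positive")
    cy, cx = _field_centroid(grid.values, grid.valid, grid.y_axis, grid.x_axis)
    half = window_mm / 2.0
    sel_y = np.abs(grid.y_axis - cy) <= half
    sel_x = np.abs(grid.x_axis - cx) <= half
    if not sel_y.any() or not sel_x.any():
        raise MetricsError("averaging window contains no grid columns")
    sub = grid.values[:, sel_y][:, :, sel_x]
    sub_valid = grid.valid[:, sel_y][:, :, sel_x]
    profile = np.empty(len(grid.z_axis))
    for k in range(len(grid.z_axis)):
        v = sub[k][sub_valid[k]]
        if v.size == 0:
            raise MetricsError(
                f"no valid voxels in window at depth {grid.z_axis[k]:.3f} mm"
            )
        profile[k] = v.mean()
    return DepthDoseCurve(depths=grid.z_axis.copy(), values=np.clip(profile, 0.0, None))


def lateral_profile(grid: DoseGrid3D, depth_mm: float, axis: str = "x") -> LateralProfile:
    """Central line profile at a depth, interpolating between slices."""
    if axis not in ("x", "y"):
        raise MetricsError("axis must be 'x' or 'y'")
    z = grid.z_axis
    if not (z[0] <= depth_mm <= z[-1]):
        raise MetricsError(
            f"depth {depth_mm} mm outside grid range [{z[0]:.3f}, {z[-1]:.3f}]"
        )
    j = int(np.searchsorted(z, depth_mm))
    if j == 0 or abs(z[j if j < len(z) else -1] - depth_mm) < 1e-12:
        j = min(j, len(z) - 1)
        slice2d = grid.values[j]
        valid = grid.valid[j]
    elif abs(z[j - 1] - depth_mm) < 1e-12:
        slice2d = grid.values[j - 1]
        valid = grid.valid[j - 1]
    else:
        w = (depth_mm - z[j - 1]) / (z[j] - z[j - 1])
        slice2d = (1 - w) * grid.values[j - 1] + w * grid.values[j]
        valid = grid.valid[j - 1] & grid.valid[j]
    cy, cx = _field_centroid(slice2d, valid, grid.y_axis, grid.x_axis)
    if axis == "x":
        row = int(np.argmin(np.abs(grid.y_axis - cy)))
        return LateralProfile(
            coords_mm=grid.x_axis.copy(),
            values=slice2d[row, :].copy(),
            valid=valid[row, :].copy(),
            depth_mm=depth_mm,
            axis="x",
        )
    col = int(np.argmin(np.abs(grid.x_axis - cx)))
    return LateralProfile(
        coords_mm=grid.y_axis.copy(),
        values=slice2d[:, col].copy(),
        valid=valid[:, col].copy(),
        depth_mm=depth_mm,
        axis="y",
    )


def _distal_crossing(z: np.ndarray, v: np.ndarray, level: float, what: str) -> float:
    above = np.nonzero(v >= level)[0]
    if above.size == 0 or above[-1] == len(v) - 1:
        raise NoCrossingError(f"profile never falls through the {what} level ({level:.4g})")
    i = above[-1]
    dv = v[i + 1] - v[i]
    frac = 0.5 if dv == 0 else (level - v[i]) / dv
    return float(z[i] + frac * (z[i + 1] - z[i]))


def _proximal_crossing(z: np.ndarray, v: np.ndarray, level: float, what: str) -> float:
    above = np.nonzero(v >= level)[0]
    if above.size == 0 or above[0] == 0:
        raise NoCrossingError(f"profile never rises through the {what} level ({level:.4g})")
    i = above[0]
    dv = v[i] - v[i - 1]
    frac = 0.5 if dv == 0 else (level - v[i - 1]) / dv
    return float(z[i - 1] + frac * (z[i] - z[i - 1]))


def _erf_edge(z, r50, sigma, amp):
    return amp * special.ndtr((r50 - z) / sigma)


def _fit_distal_edge(
    z: np.ndarray, v: np.ndarray, plateau: float, r90_lin: float, r10_lin: float
):
    """Fit amp * Phi((R50 - z) / sigma) to the distal segment.

    Returns (r50, sigma, amp) or None when the segment is too short or
    the fit fails.  The fit window runs from the last near-plateau point
    to the first near-zero point, anchoring both asymptotes.
    """
    hi = np.nonzero(v >= 0.95 * plateau)[0]
    if hi.size == 0:
        return None
    i0 = hi[-1]
    lo = np.nonzero(v[i0:] < 0.02 * plateau)[0]
    i1 = i0 + (lo[0] if lo.size else len(v) - 1 - i0)
    i0 = max(i0 - 1, 0)
    zs, vs = z[i0 : i1 + 1], v[i0 : i1 + 1]
    interior = np.count_nonzero((vs > 0.02 * plateau) & (vs < 0.98 * plateau))
    if len(zs) < 4 or interior < 2:
        return None
    sigma0 = max((r10_lin - r90_lin) / (2 * _Z90), 1e-3)
    try:
        popt, _ = optimize.curve_fit(
            _erf_edge,
            zs,
            vs,
            p0=(0.5 * (r90_lin + r10_lin), sigma0, plateau),
            bounds=([zs[0], 1e-4, 0.3 * plateau], [zs[-1] + 5.0, 20.0, 1.7 * plateau]),
            maxfev=5000,
        )
    except RuntimeError:
        return None
    return tuple(float(p) for p in popt)


def sobp_metrics(curve: DepthDoseCurve, refine_edge: bool = True) -> SOBPMetrics:
    """Extract R90, R10, distal fall-off and modulation from a profile.

    The plateau level is the median of the values between the proximal
    and distal 90% crossings (estimated iteratively; the median is
    robust against the proximal ramp shoulder included in the window).
    Distal crossings use monotone linear interpolation and, when the
    sampling is coarse, the erf-edge refinement of the distal segment.
    All levels are relative to the plateau, so the metrics are invariant
    under global rescaling of the curve.
    """
    z, v = curve.depths, curve.values
    if len(z) < 4:
        raise MetricsError("profile too short for SOBP metrics")
    vmax = float(v.max())
    if vmax <= 0:
        raise MetricsError("profile has no positive values")
    v = v / vmax  # work on a unit scale: metrics are exactly scale-invariant
    plateau = float(v.max())
    for _ in range(3):
        zp = _proximal_crossing(z, v, 0.9 * plateau, "proximal 90%")
        zd = _distal_crossing(z, v, 0.9 * plateau, "distal 90%")
        sel = (z >= zp) & (z <= zd)
        if not sel.any():
            break
        plateau = float(np.median(v[sel]))
    r90 = _distal_crossing(z, v, 0.9 * plateau, "distal 90%")
    r10 = _distal_crossing(z, v, 0.1 * plateau, "distal 10%")
    if refine_edge:
        fit = _fit_distal_edge(z, v, plateau, r90, r10)
        if fit is not None:
            r50f, sigmaf, ampf = fit
            if abs(ampf - plateau) <= 0.05 * plateau:
                # the fitted edge amplitude is the plateau asymptote seen by
                # the distal edge; prefer it when consistent with the median
                plateau = ampf
            q90, q10 = 0.9 * plateau / ampf, 0.1 * plateau / ampf
            if 0 < q10 < q90 < 1:
                r90 = r50f - sigmaf * float(stats.norm.ppf(q90))
                r10 = r50f - sigmaf * float(stats.norm.ppf(q10))
    zp = _proximal_crossing(z, v, 0.9 * plateau, "proximal 90%")
    return SOBPMetrics(
        r90=r90,
        r10=r10,
        distal_falloff=r10 - r90,
        modulation=r90 - zp,
        plateau_level=plateau * vmax,
    )


def extract_isodose(
    slice2d: np.ndarray,
    levels: tuple[float, ...],
    x_axis: np.ndarray,
    y_axis: np.ndarray,
) -> IsodoseSet:
    """Marching-squares isodose contours at fractions of the slice maximum.

    Contours are returned as (x, y) polylines in millimetres, with
    linear interpolation along cell edges.
    """
    slice2d = np.asarray(slice2d, dtype=float)
    x_axis = np.asarray(x_axis, dtype=float)
    y_axis = np.asarray(y_axis, dtype=float)
    for level in levels:
        if not 0 < level < 1:
            raise MetricsError(f"isodose level must be in (0, 1), got {level}")
    m = float(slice2d.max())
    contours: dict[float, list[np.ndarray]] = {}
    for level in levels:
        paths = measure.find_contours(slice2d, level * m) if m > slice2d.min() else []
        converted = []
        for rc in paths:
            x = np.interp(rc[:, 1], np.arange(len(x_axis)), x_axis)
            y = np.interp(rc[:, 0], np.arange(len(y_axis)), y_axis)
            converted.append(np.column_stack([x, y]))
        contours[level] = converted
    return IsodoseSet(levels=tuple(levels), contours=contours)


def _profile_width50(coords: np.ndarray, values: np.ndarray) -> float:
    """Full width at 50% of the line maximum, by linear interpolation."""
    m = values.max()
    if m <= 0:
        raise MetricsError("profile has no positive maximum")
    half = 0.5 * m
    above = np.nonzero(values >= half)[0]
    if above.size == 0 or above[0] == 0 or above[-1] == len(values) - 1:
        raise NoCrossingError("50% level not bracketed by the lateral profile")
    i = above[0]
    left = coords[i - 1] + (half - values[i - 1]) / (values[i] - values[i - 1]) * (
        coords[i] - coords[i - 1]
    )
    j = above[-1]
    right = coords[j] + (values[j] - half) / (values[j] - values[j + 1]) * (
        coords[j + 1] - coords[j]
    )
    return float(right - left)


@dataclass
class DepthComparison:
    """Lateral agreement at one report depth."""

    depth_mm: float
    max_abs_diff: float
    mean_abs_diff: float
    width50_measured_mm: float
    width50_reference_mm: float
    measured_profile: LateralProfile
    reference_profile: LateralProfile

    @property
    def width50_diff_mm(self) -> float:
        return self.width50_measured_mm - self.width50_reference_mm


@dataclass
class ComparisonReport:
    """Quantitative agreement between a measured and a reference grid."""

    depth_comparisons: list[DepthComparison]
    profile_max_abs_diff: float
    profile_mean_abs_diff: float
    profile_rms_diff: float
    metrics_measured: SOBPMetrics
    metrics_reference: SOBPMetrics
    normalization_mode: str
    window_mm: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for dc in self.depth_comparisons:
            rows.append(("lateral_max_abs_diff", dc.depth_mm, dc.max_abs_diff))
            rows.append(("lateral_mean_abs_diff", dc.depth_mm, dc.mean_abs_diff))
            rows.append(("width50_diff_mm", dc.depth_mm, dc.width50_diff_mm))
        rows += [
            ("depth_profile_max_abs_diff", np.nan, self.profile_max_abs_diff),
            ("depth_profile_mean_abs_diff", np.nan, self.profile_mean_abs_diff),
            ("depth_profile_rms_diff", np.nan, self.profile_rms_diff),
            ("delta_r90_mm", np.nan, self.metrics_measured.r90 - self.metrics_reference.r90),
            (
                "delta_distal_falloff_mm",
                np.nan,
                self.metrics_measured.distal_falloff - self.metrics_reference.distal_falloff,
            ),
            (
                "delta_modulation_mm",
                np.nan,
                self.metrics_measured.modulation - self.metrics_reference.modulation,
            ),
        ]
        return pd.DataFrame(rows, columns=["metric", "depth_mm", "value"])

    def summary_text(self) -> str:
        lines = [
            f"grid comparison (normalization: {self.normalization_mode}, "
            f"central window {self.window_mm:g} mm)",
            f"  measured : R90={self.metrics_measured.r90:.2f} mm, "
            f"falloff={self.metrics_measured.distal_falloff:.2f} mm, "
            f"modulation={self.metrics_measured.modulation:.2f} mm",
            f"  reference: R90={self.metrics_reference.r90:.2f} mm, "
            f"falloff={self.metrics_reference.distal_falloff:.2f} mm, "
            f"modulation={self.metrics_reference.modulation:.2f} mm",
            f"  central depth profile: max|diff|={self.profile_max_abs_diff:.4f}, "
            f"mean|diff|={self.profile_mean_abs_diff:.4f}, rms={self.profile_rms_diff:.4f}",
        ]
        for dc in self.depth_comparisons:
            lines.append(
                f"  z={dc.depth_mm:5.1f} mm: max|diff|={dc.max_abs_diff:.4f}, "
                f"mean|diff|={dc.mean_abs_diff:.4f} (50% area), "
                f"width50 diff={dc.width50_diff_mm:+.2f} mm"
            )
        return "\n".join(lines)


def _lateral_slice_at(grid: DoseGrid3D, depth_mm: float):
    z = grid.z_axis
    j = int(np.clip(np.searchsorted(z, depth_mm), 1, len(z) - 1))
    w = (depth_mm - z[j - 1]) / (z[j] - z[j - 1])
    w = float(np.clip(w, 0.0, 1.0))
    slice2d = (1 - w) * grid.values[j - 1] + w * grid.values[j]
    valid = grid.valid[j - 1] & grid.valid[j]
    return slice2d, valid


def compare_grids(
    measured: DoseGrid3D,
    reference: DoseGrid3D,
    report_depths: tuple[float, ...] = (24.0, 29.0, 29.8),
    window_mm: float = 2.0,
) -> ComparisonReport:
    """Quantify agreement between two dose grids.

    At each report depth the measured grid is resampled onto the
    reference lateral axes and compared inside the area where the
    reference exceeds 50% of the cross-section maximum; the central
    depth profiles and their SOBP metrics are compared as well.  Both
    grids must carry the same recorded normalization mode — comparing
    differently normalised relative doses is meaningless.
    """
    if measured.normalization_mode != reference.normalization_mode:
        raise MetricsError(
            f"normalization modes differ: measured={measured.normalization_mode!r}, "
            f"reference={reference.normalization_mode!r}"
        )
    m_interp = RegularGridInterpolator(
        (measured.z_axis, measured.y_axis, measured.x_axis),
        measured.values,
        bounds_error=False,
        fill_value=np.nan,
    )
    m_valid_interp = RegularGridInterpolator(
        (measured.z_axis, measured.y_axis, measured.x_axis),
        measured.valid.astype(float),
        bounds_error=False,
        fill_value=0.0,
    )
    depth_comparisons = []
    for depth in report_depths:
        ref_slice, ref_valid = _lateral_slice_at(reference, depth)
        yy, xx = np.meshgrid(reference.y_axis, reference.x_axis, indexing="ij")
        pts = np.column_stack([np.full(xx.size, depth), yy.ravel(), xx.ravel()])
        meas = m_interp(pts).reshape(ref_slice.shape)
        meas_ok = m_valid_interp(pts).reshape(ref_slice.shape) >= 1.0 - 1e-9
        area = ref_slice >= 0.5 * ref_slice[ref_valid].max()
        sel = area & ref_valid & meas_ok & np.isfinite(meas)
        if not sel.any():
            raise MetricsError(f"no comparable voxels inside 50% area at {depth} mm")
        diff = np.abs(meas[sel] - ref_slice[sel])
        # central x-line through the reference field centroid, same row for both
        cy, _ = _field_centroid(ref_slice, ref_valid, reference.y_axis, reference.x_axis)
        row = int(np.argmin(np.abs(reference.y_axis - cy)))
        ref_prof = LateralProfile(
            coords_mm=reference.x_axis.copy(),
            values=ref_slice[row, :].copy(),
            valid=ref_valid[row, :].copy(),
            depth_mm=depth,
            axis="x",
        )
        meas_on_ref = LateralProfile(
            coords_mm=reference.x_axis.copy(),
            values=np.nan_to_num(meas[row, :]),
            valid=meas_ok[row, :].copy(),
            depth_mm=depth,
            axis="x",
        )
        depth_comparisons.append(
            DepthComparison(
                depth_mm=depth,
                max_abs_diff=float(diff.max()),
                mean_abs_diff=float(diff.mean()),
                width50_measured_mm=_profile_width50(
                    meas_on_ref.coords_mm, meas_on_ref.values
                ),
                width50_reference_mm=_profile_width50(
                    ref_prof.coords_mm, ref_prof.values
                ),
                measured_profile=meas_on_ref,
                reference_profile=ref_prof,
            )
        )
    prof_m = central_depth_profile(measured, window_mm)
    prof_r = central_depth_profile(reference, window_mm)
    lo = max(prof_m.depths[0], prof_r.depths[0])
    hi = min(prof_m.depths[-1], prof_r.depths[-1])
    sel = (prof_m.depths >= lo) & (prof_m.depths <= hi)
    ref_on_m = np.interp(prof_m.depths[sel], prof_r.depths, prof_r.values)
    d = prof_m.values[sel] - ref_on_m
    return ComparisonReport(
        depth_comparisons=depth_comparisons,
        profile_max_abs_diff=float(np.abs(d).max()),
        profile_mean_abs_diff=float(np.abs(d).mean()),
        profile_rms_diff=float(np.sqrt(np.mean(d**2))),
        metrics_measured=sobp_metrics(prof_m),
        metrics_reference=sobp_metrics(prof_r),
        normalization_mode=measured.normalization_mode,
        window_mm=window_mm,
    )
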