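"""Depth-dependent quenching calibration from a pristine-beam dataset.

Luminescent foils under-respond where the ionization density is high,
i.e. toward the end of the proton range.  A separate experiment —
single foils at known water depths in an unmodulated beam, read against
an ionization chamber — yields a depth-dependent correction factor
k(d): the ratio of the chamber depth dose to the foil signal, both
max-normalised.  A cross-validated smoothing spline through the (depth,
k) points gives a continuous calibration curve, which is applied
slice-by-slice to a reconstructed 3D grid.  Outside the measured depth
range the curve extrapolates as a constant (the nearest endpoint): a
ratio of two vanishing signals past the range is not extrapolable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import UnivariateSpline

from .stack import DoseGrid3D, normalize

__all__ = [
    "CalibrationError",
    "CalibrationDataset",
    "CalibrationCurve",
    "compute_k_points",
    "fit_calibration",
    "apply_calibration",
    "read_calibration_dataset",
    "write_calibration_dataset",
]


class CalibrationError(ValueError):
    """Invalid calibration data or fit request."""


@dataclass
class CalibrationDataset:
    """(depth, chamber dose, foil signal) triples from a pristine beam."""

    depth_mm: np.ndarray
    ref_dose: np.ndarray
    foil_signal: np.ndarray

    def __post_init__(self) -> None:
        self.depth_mm = np.asarray(self.depth_mm, dtype=float)
        self.ref_dose = np.asarray(self.ref_dose, dtype=float)
        self.foil_signal = np.asarray(self.foil_signal, dtype=float)
        if not (self.depth_mm.shape == self.ref_dose.shape == self.foil_signal.shape):
            raise CalibrationError("calibration columns must have equal length")
        if self.depth_mm.ndim != 1 or self.depth_mm.size < 1:
            raise CalibrationError("calibration dataset must be a non-empty 1D table")
        if not np.all(np.diff(self.depth_mm) > 0):
            raise CalibrationError("calibration depths must be strictly increasing")
        if np.any(self.ref_dose <= 0):
            raise CalibrationError("reference doses must be positive")
        if np.any(self.foil_signal < 0):
            raise CalibrationError("foil signals must be non-negative")

    def __len__(self) -> int:
        return self.depth_mm.size


def read_calibration_dataset(path: str | Path) -> CalibrationDataset:
    """Read a 3-column whitespace/comma table with a one-line header."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    expected = ["depth_mm", "ref_dose", "foil_signal"]
    if cols[:3] != expected:
        raise CalibrationError(
            f"expected columns {expected}, found {cols} in {path}"
        )
    return CalibrationDataset(
        depth_mm=df["depth_mm"].to_numpy(),
        ref_dose=df["ref_dose"].to_numpy(),
        foil_signal=df["foil_signal"].to_numpy(),
    )


def write_calibration_dataset(data: CalibrationDataset, path: str | Path) -> None:
    pd.DataFrame(
        {
            "depth_mm": data.depth_mm,
            "ref_dose": data.ref_dose,
            "foil_signal": data.foil_signal,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.8g")


def compute_k_points(data: CalibrationDataset) -> tuple[np.ndarray, np.ndarray]:
    """Per-depth correction factors k = ref / foil, both max-normalised."""
    zero = np.nonzero(data.foil_signal == 0)[0]
    if zero.size:
        raise CalibrationError(
            "zero foil signal at depth(s) "
            + ", ".join(f"{data.depth_mm[i]:g} mm" for i in zero)
        )
    ref = data.ref_dose / data.ref_dose.max()
    foil = data.foil_signal / data.foil_signal.max()
    return data.depth_mm.copy(), ref / foil


@dataclass
class CalibrationCurve:
    """Fitted, clamped evaluator for the depth correction factor k(d)."""

    knot_depths: np.ndarray
    k_values: np.ndarray
    valid_range: tuple[float, float]
    residual_rms: float
    smoothing: float
    _spline: UnivariateSpline

    def __call__(self, depth) -> np.ndarray | float:
        d = np.clip(np.asarray(depth, dtype=float), *self.valid_range)
        k = self._spline(d)
        if np.ndim(depth) == 0:
            return float(k)
        return np.asarray(k)


def fit_calibration(points, loo_smoothing_factors: np.ndarray | None = None) -> CalibrationCurve:
    """Smoothing-spline fit of (depth, k) with leave-one-out CV smoothing.

    ``points`` is either a sequence of (depth, k) pairs or a
    ``(depths, k)`` pair of arrays.  The spline smoothing parameter is
    chosen by leave-one-out cross-validation over a geometric grid
    (including the interpolating limit); outside the measured range the
    curve is clamped to its endpoint values.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 2 and pts.shape[0] == 2 and pts.shape[1] != 2:
        depths, k = pts[0], pts[1]
    elif pts.ndim == 2 and pts.shape[1] == 2:
        depths, k = pts[:, 0], pts[:, 1]
    else:
        raise CalibrationError("points must be (depth, k) pairs")
    order = np.argsort(depths)
    depths, k = depths[order], k[order]
    n = depths.size
    if n < 4:
        raise CalibrationError(f"need at least 4 calibration points, got {n}")
    if np.any(np.diff(depths) <= 0):
        raise CalibrationError("calibration depths must be distinct")
    if np.any(k <= 0):
        raise CalibrationError("correction factors must be strictly positive")

    scale = n * max(float(np.var(k)), 1e-12)
    if loo_smoothing_factors is None:
        loo_smoothing_factors = np.concatenate(
            [[0.0], np.geomspace(1e-6, 2.0, 12)]
        )
    best_s, best_err = None, np.inf
    idx = np.arange(n)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # spline maxit warnings for tiny s
        for factor in loo_smoothing_factors:
            s = factor * scale
            err = 0.0
            ok = True
            for i in idx:
                sel = idx != i
                deg = min(3, int(np.count_nonzero(sel)) - 1)
                try:
                    spl = UnivariateSpline(depths[sel], k[sel], k=deg, s=s)
                except Exception:
                    ok = False
                    break
                err += float((spl(depths[i]) - k[i]) ** 2)
            if ok and err < best_err - 1e-15:
                best_err, best_s = err, s
    if best_s is None:
        raise CalibrationError("no admissible spline smoothing found")
    deg = min(3, n - 1)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        spline = UnivariateSpline(depths, k, k=deg, s=best_s)
    fitted = spline(depths)
    if np.any(fitted <= 0):
        raise CalibrationError("fitted calibration curve is not strictly positive")
    return CalibrationCurve(
        knot_depths=depths,
        k_values=np.asarray(fitted),
        valid_range=(float(depths[0]), float(depths[-1])),
        residual_rms=float(np.sqrt(np.mean((fitted - k) ** 2))),
        smoothing=float(best_s),
        _spline=spline,
    )


def apply_calibration(grid: DoseGrid3D, curve: CalibrationCurve) -> DoseGrid3D:
    """Multiply each depth slice by k(z), then restore the recorded mode.

    Extrapolation beyond the calibration range is clamped by the curve's
    contract; after scaling, the grid is renormalised according to its
    recorded normalization mode.
    """
    lo, hi = curve.valid_range
    if grid.z_axis[-1] < lo or grid.z_axis[0] > hi:
        raise CalibrationError(
            "grid depth range does not overlap the calibration valid range"
        )
    factors = np.asarray(curve(grid.z_axis))
    out = replace(
        grid,
        values=grid.values * factors[:, None, None],
        provenance=grid.provenance + ("quench_corrected",),
    )
    if grid.normalization_mode != "none":
        out = normalize(out, grid.normalization_mode)
    return out
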