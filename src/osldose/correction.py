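"""Correction chain for raw 2D OSL foil readout frames.

A raw CCD frame of an irradiated luminescent foil mixes the dose signal
with dark counts, illumination non-uniformity of the stimulation optics,
and the per-foil heterogeneity of the phosphor distribution.  The chain
implemented here removes these step by step, always in the same order:

    subtract_background -> detect/clip ROI -> flatfield_correct
        -> median_filter -> iri_correct

The individual reference image (IRI) is a readout of the *same* foil
after a spatially uniform irradiation; dividing by it removes per-foil
sensitivity structure that no shared flat-field can capture.  Every
processed image carries a provenance tuple (``steps``) and the chain
functions refuse out-of-order application.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

__all__ = [
    "CorrectionError",
    "DetectionError",
    "RegistrationError",
    "FoilROI",
    "FoilImage",
    "CorrectionSet",
    "threshold_split",
    "subtract_background",
    "detect_foil_roi",
    "clip_to_roi",
    "flatfield_correct",
    "median_filter",
    "iri_correct",
    "correct_frame",
]

#: canonical processing order; any other order is rejected
CHAIN_ORDER = (
    "subtract_background",
    "clip_to_roi",
    "flatfield_correct",
    "median_filter",
    "iri_correct",
)


class CorrectionError(ValueError):
    """Invalid input or out-of-order use of the correction chain."""


class DetectionError(CorrectionError):
    """Foil disc could not be located in the live-view frame."""


class RegistrationError(CorrectionError):
    """Frames that must share a foil position do not."""


@dataclass(frozen=True)
class FoilROI:
    """Circular foil region, ``center`` as (row, col) pixels."""

    center: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.radius) or self.radius <= 0:
            raise CorrectionError(f"ROI radius must be positive, got {self.radius}")


@dataclass
class FoilImage:
    """One 2D readout frame plus its validity mask and provenance.

    ``origin`` is the (row, col) offset of this (possibly cropped) frame
    inside the original full camera frame, so ROI centers can always be
    compared in full-frame coordinates.
    """

    pixels: np.ndarray
    exposure_s: float = 30.0
    foil_index: int = 1
    mask: np.ndarray | None = None
    roi: FoilROI | None = None
    origin: tuple[int, int] = (0, 0)
    steps: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise CorrectionError("pixels must be a 2D array")
        if not np.all(np.isfinite(self.pixels)):
            raise CorrectionError("pixels must be finite")
        if self.foil_index < 1:
            raise CorrectionError("foil_index must be >= 1")
        if self.mask is None:
            self.mask = np.ones(self.pixels.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.pixels.shape:
                raise CorrectionError("mask shape must match pixels")

    @property
    def full_frame_center(self) -> tuple[float, float] | None:
        if self.roi is None:
            return None
        return (
            self.roi.center[0] + self.origin[0],
            self.roi.center[1] + self.origin[1],
        )


@dataclass
class CorrectionSet:
    """The four correction frames needed to process one foil readout."""

    background: np.ndarray
    live_view: np.ndarray
    flatfield: np.ndarray
    iri_raw: np.ndarray
    iri_corrected: FoilImage | None = None

    def validate(self) -> None:
        frames = {
            "background": self.background,
            "live_view": self.live_view,
            "flatfield": self.flatfield,
            "iri_raw": self.iri_raw,
        }
        shape = None
        for name, frame in frames.items():
            if frame is None:
                raise CorrectionError(f"correction set is missing the {name} frame")
            frame = np.asarray(frame)
            if shape is None:
                shape = frame.shape
            elif frame.shape != shape:
                raise CorrectionError(
                    f"{name} frame shape {frame.shape} != {shape}"
                )


def _as_pixels(frame: FoilImage | np.ndarray) -> np.ndarray:
    if isinstance(frame, FoilImage):
        return frame.pixels
    return np.asarray(frame, dtype=float)


def subtract_background(
    raw: FoilImage | np.ndarray, background: np.ndarray
) -> FoilImage:
    """Subtract the non-irradiated background frame, clamping at zero.

    Negative differences are clamped rather than kept: every later step
    divides by strictly positive reference images, and sub-noise pixels
    are excluded through the mask instead.
    """
    pixels = _as_pixels(raw)
    background = np.asarray(background, dtype=float)
    if pixels.shape != background.shape:
        raise CorrectionError(
            f"raw shape {pixels.shape} != background shape {background.shape}"
        )
    out = np.clip(pixels - background, 0.0, None)
    if isinstance(raw, FoilImage):
        if "subtract_background" in raw.steps:
            raise CorrectionError("background already subtracted")
        return replace(raw, pixels=out, steps=raw.steps + ("subtract_background",))
    return FoilImage(pixels=out, steps=("subtract_background",))


def threshold_split(values: np.ndarray) -> float:
    """Two-class split threshold of an intensity sample.

    The sample is split at the boundary maximising the between-class
    variance (evaluated exactly over every distinct-value split, not on
    a binned histogram); the returned threshold is the midpoint of the
    two class medians, which makes it invariant under adding a constant
    offset to all values.
    """
    v = np.sort(np.asarray(values, dtype=float).ravel())
    if v.size < 2 or v[0] == v[-1]:
        raise DetectionError("cannot split a (near-)constant intensity sample")
    n = v.size
    csum = np.cumsum(v)
    k = np.arange(1, n)  # size of the low class
    mean_low = csum[:-1] / k
    mean_high = (csum[-1] - csum[:-1]) / (n - k)
    crit = k * (n - k) * (mean_low - mean_high) ** 2
    crit[v[1:] <= v[:-1]] = -np.inf  # splits inside ties are not valid
    split = int(np.argmax(crit))
    low, high = v[: split + 1], v[split + 1 :]
    return float((np.median(low) + np.median(high)) / 2.0)


def detect_foil_roi(live_view: np.ndarray, min_area_frac: float = 0.05) -> FoilROI:
    """Locate the circular foil in a white-light live-view frame.

    The frame is thresholded with :func:`threshold_split`; the largest
    above-threshold connected component gives the disc.  Center is the
    intensity-weighted centroid (weights measured above the outside
    median so that a global offset changes nothing), radius is
    ``sqrt(area / pi)``.
    """
    frame = np.asarray(live_view, dtype=float)
    if frame.ndim != 2:
        raise CorrectionError("live view must be 2D")
    thr = threshold_split(frame)
    binary = frame >= thr
    labels, n_labels = ndimage.label(binary)
    if n_labels == 0:
        raise DetectionError("no above-threshold component in live view")
    areas = ndimage.sum_labels(np.ones_like(frame), labels, index=range(1, n_labels + 1))
    best = int(np.argmax(areas)) + 1
    area = float(areas[best - 1])
    if area < min_area_frac * frame.size:
        raise DetectionError(
            f"largest component covers {area / frame.size:.1%} of the frame "
            f"(< {min_area_frac:.0%}); no foil disc found"
        )
    component = labels == best
    outside_median = float(np.median(frame[~binary])) if (~binary).any() else 0.0
    weights = np.where(component, np.clip(frame - outside_median, 0.0, None), 0.0)
    total = weights.sum()
    if total <= 0:
        raise DetectionError("degenerate intensity weights in foil component")
    rows, cols = np.indices(frame.shape)
    center = (
        float((weights * rows).sum() / total),
        float((weights * cols).sum() / total),
    )
    radius = float(np.sqrt(area / np.pi))
    return FoilROI(center=center, radius=radius)


def clip_to_roi(
    frame: FoilImage | np.ndarray, roi: FoilROI, margin_px: int = 4
) -> FoilImage:
    """Crop to the disc's bounding square (+margin) and mask the disc.

    Output is square with side ``2 * (round(radius) + margin) + 1``; the
    mask is true strictly inside the disc.  A disc touching the frame
    edge is an error: the readout must always contain the whole foil.
    """
    if margin_px < 0:
        raise CorrectionError("margin_px must be >= 0")
    pixels = _as_pixels(frame)
    r = int(round(roi.radius))
    half = r + margin_px
    cr, cc = int(round(roi.center[0])), int(round(roi.center[1]))
    r0, r1 = cr - half, cr + half + 1
    c0, c1 = cc - half, cc + half + 1
    if r0 < 0 or c0 < 0 or r1 > pixels.shape[0] or c1 > pixels.shape[1]:
        raise CorrectionError(
            "foil disc (plus margin) touches the frame edge; cannot clip"
        )
    crop = pixels[r0:r1, c0:c1].copy()
    new_center = (roi.center[0] - r0, roi.center[1] - c0)
    rows, cols = np.indices(crop.shape)
    # half-pixel guard: rim pixels straddling the physical foil edge are
    # unreliable (partially outside the phosphor disc)
    guard = max(roi.radius - 0.5, 1.0)
    disc = (rows - new_center[0]) ** 2 + (cols - new_center[1]) ** 2 <= guard**2
    if isinstance(frame, FoilImage):
        mask = frame.mask[r0:r1, c0:c1] & disc
        origin = (frame.origin[0] + r0, frame.origin[1] + c0)
        return replace(
            frame,
            pixels=crop,
            mask=mask,
            roi=FoilROI(center=new_center, radius=roi.radius),
            origin=origin,
            steps=frame.steps + ("clip_to_roi",),
        )
    return FoilImage(
        pixels=crop,
        mask=disc,
        roi=FoilROI(center=new_center, radius=roi.radius),
        origin=(r0, c0),
        steps=("clip_to_roi",),
    )


def _require(img: FoilImage, present: tuple[str, ...], absent: tuple[str, ...], op: str) -> None:
    for step in present:
        if step not in img.steps:
            raise CorrectionError(
                f"{op} requires prior step '{step}' (have {list(img.steps)}); "
                "the correction chain order is fixed"
            )
    for step in absent:
        if step in img.steps:
            raise CorrectionError(
                f"{op} cannot run after '{step}' (have {list(img.steps)}); "
                "the correction chain order is fixed"
            )


def _crop_like(img: FoilImage, full_frame: np.ndarray) -> np.ndarray:
    full_frame = np.asarray(full_frame, dtype=float)
    r0, c0 = img.origin
    r1, c1 = r0 + img.pixels.shape[0], c0 + img.pixels.shape[1]
    if r0 < 0 or c0 < 0 or r1 > full_frame.shape[0] or c1 > full_frame.shape[1]:
        raise CorrectionError("correction frame does not cover the clipped region")
    return full_frame[r0:r1, c0:c1]


def flatfield_correct(
    img: FoilImage, flatfield: np.ndarray, background: np.ndarray
) -> FoilImage:
    """Divide by the dark-subtracted flat-field, shape-only.

    The flat-field is normalised to mean 1 over the ROI before division
    and the result is rescaled to preserve the image's ROI mean exactly:
    the correction changes shape, never scale.
    """
    _require(
        img,
        present=("clip_to_roi",),
        absent=("flatfield_correct", "median_filter", "iri_correct"),
        op="flatfield_correct",
    )
    ff = _crop_like(img, flatfield) - _crop_like(img, background)
    bad = int(np.count_nonzero((ff <= 0) & img.mask))
    if bad:
        raise CorrectionError(
            f"flat-field minus background is non-positive at {bad} ROI pixel(s)"
        )
    mean_before = float(img.pixels[img.mask].mean())
    norm = ff / ff[img.mask].mean()
    out = img.pixels.copy()
    out[img.mask] = img.pixels[img.mask] / norm[img.mask]
    mean_after = float(out[img.mask].mean())
    if mean_after > 0:
        out[img.mask] *= mean_before / mean_after
    return replace(img, pixels=out, steps=img.steps + ("flatfield_correct",))


def median_filter(img: FoilImage, kernel_px: int = 3) -> FoilImage:
    """Mask-aware median filter; invalid pixels neither contribute nor change."""
    if kernel_px < 1 or kernel_px % 2 == 0:
        raise CorrectionError(f"kernel_px must be odd and >= 1, got {kernel_px}")
    _require(img, present=(), absent=("iri_correct",), op="median_filter")
    if kernel_px == 1:
        return replace(img, steps=img.steps + ("median_filter",))
    pad = kernel_px // 2
    arr = np.where(img.mask, img.pixels, np.nan)
    padded = np.pad(arr, pad, constant_values=np.nan)
    windows = sliding_window_view(padded, (kernel_px, kernel_px))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        med = np.nanmedian(windows, axis=(-2, -1))
    out = np.where(img.mask & np.isfinite(med), med, img.pixels)
    return replace(img, pixels=out, steps=img.steps + ("median_filter",))


def iri_correct(img: FoilImage, iri_corrected: FoilImage) -> FoilImage:
    """Divide out per-foil sensitivity using the corrected reference image.

    The IRI must have been processed by the same chain and must show the
    foil at (nearly) the same position; division is by the IRI scaled to
    ROI mean 1, and the result is rescaled to preserve the image's ROI
    mean.  Applying the step twice is refused — division by the same
    reference is not idempotent.
    """
    _require(
        img,
        present=("flatfield_correct", "median_filter"),
        absent=("iri_correct",),
        op="iri_correct",
    )
    _require(iri_corrected, present=("flatfield_correct",), absent=(), op="iri_correct(IRI)")
    if img.pixels.shape != iri_corrected.pixels.shape:
        raise RegistrationError(
            f"image {img.pixels.shape} and IRI {iri_corrected.pixels.shape} shapes differ"
        )
    c_img, c_iri = img.full_frame_center, iri_corrected.full_frame_center
    if c_img is not None and c_iri is not None:
        offset = np.hypot(c_img[0] - c_iri[0], c_img[1] - c_iri[1])
        if offset > 2.0:
            raise RegistrationError(
                f"image and IRI foil centers differ by {offset:.2f} px (> 2 px)"
            )
    joint = img.mask & iri_corrected.mask
    if not joint.any():
        raise CorrectionError("image and IRI masks do not overlap")
    iri_vals = iri_corrected.pixels
    nonpos = joint & (iri_vals <= 0)
    n_bad = int(np.count_nonzero(nonpos))
    if n_bad:
        if n_bad > 0.01 * np.count_nonzero(joint):
            raise CorrectionError(
                f"IRI is non-positive at {n_bad} ROI pixel(s); cannot divide"
            )
        joint &= ~nonpos  # isolated dead reference pixels: drop from the mask
    mean_before = float(img.pixels[joint].mean())
    norm = iri_vals / iri_vals[joint].mean()
    out = img.pixels.copy()
    out[joint] = img.pixels[joint] / norm[joint]
    mean_after = float(out[joint].mean())
    if mean_after > 0:
        out[joint] *= mean_before / mean_after
    return replace(img, pixels=out, mask=joint, steps=img.steps + ("iri_correct",))


def correct_frame(
    raw: FoilImage | np.ndarray,
    corrections: CorrectionSet,
    margin_px: int = 4,
    median_kernel_px: int = 3,
) -> FoilImage:
    """Run the full correction chain on one raw readout frame.

    Order: background subtraction, ROI detection on the live view,
    clipping, flat-field division, median filtering, IRI division.  The
    corrected IRI is computed through the identical chain (and cached on
    the correction set) using the same ROI, since foil and reference
    readouts share the placement recorded by the live view.
    """
    corrections.validate()
    if isinstance(raw, FoilImage) and raw.steps:
        raise CorrectionError("raw frame has already been processed")
    roi = detect_foil_roi(np.asarray(corrections.live_view, dtype=float))
    work = subtract_background(raw, corrections.background)
    work = clip_to_roi(work, roi, margin_px=margin_px)
    work = flatfield_correct(work, corrections.flatfield, corrections.background)
    work = median_filter(work, kernel_px=median_kernel_px)
    if corrections.iri_corrected is None:
        iri = subtract_background(corrections.iri_raw, corrections.background)
        iri = clip_to_roi(iri, roi, margin_px=margin_px)
        iri = flatfield_correct(iri, corrections.flatfield, corrections.background)
        iri = median_filter(iri, kernel_px=median_kernel_px)
        corrections.iri_corrected = iri
    return iri_correct(work, corrections.iri_corrected)
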