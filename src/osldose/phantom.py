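"""Synthetic eyeball-phantom scenario generator with known ground truth.

Everything the analysis pipeline consumes is generated here under a
fixed seed: a spread-out Bragg peak (SOBP) depth-dose curve with stated
R90 / modulation / distal fall-off, a collimator-shaped lateral field
with Gaussian penumbra, depth-dependent luminescence quenching of the
foil response, per-foil CCD readout frames with sensitivity
heterogeneity, illumination vignette, dark counts and shot/read noise,
the matching correction frames, a reference 3D dose grid standing in
for the treatment-planning export, and a pristine-beam calibration
dataset.

Model choices (the measured beam publishes only its metrics, not a
functional form):

* SOBP: ``[e + (1 - e) * Phi((z - c) / s_r)] * Phi((R50 - z) / s_d)``
  — a Gaussian-CDF proximal ramp from the entrance ratio ``e`` to the
  plateau times a Gaussian-CDF distal edge.  ``s_d`` and ``R50`` are
  chosen so the 90%→10% distal distance and the depth of the distal
  90% crossing match the requested fall-off and R90 exactly; the ramp
  center ``c`` makes the curve cross 90% exactly at R90 − modulation.
* Quenching: Birks-type saturation ``eta = 1 / (1 + kB * L)`` on a
  residual-range LET proxy ``L = L0 + a / (range_end - z + delta)``,
  clamped beyond ``range_end``.  No measured LET-efficiency data exist
  for the foil material, so generator and calibration share this one
  self-consistent synthetic physics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from matplotlib.path import Path as MplPath
from scipy import ndimage, stats
from shapely.geometry import Polygon as ShapelyPolygon

from .calibration import CalibrationDataset
from .correction import FoilImage
from .metrics import DepthDoseCurve
from .stack import DoseGrid3D, StackGeometry, foil_depths

__all__ = [
    "BeamSpec",
    "AperturePolygon",
    "QuenchModel",
    "DetectorScene",
    "ScenarioBundle",
    "sobp_depth_dose",
    "pristine_depth_dose",
    "lateral_field",
    "quench_efficiency",
    "render_foil_frame",
    "render_correction_frames",
    "build_scenario",
    "make_scene",
    "default_beam",
    "default_geometry",
    "default_quench",
    "default_aperture",
]

_Z90 = float(stats.norm.ppf(0.9))
_MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class BeamSpec:
    """Clinical SOBP parameters, all depths in mm of water."""

    r90: float = 28.96
    modulation: float = 10.0
    distal_falloff: float = 0.88
    entrance_ratio: float = 0.7
    proximal_ramp_width: float = 2.0  # sigma of the Gaussian-CDF ramp

    def __post_init__(self) -> None:
        if not self.r90 > self.modulation > 0:
            raise ValueError("need r90 > modulation > 0")
        if self.distal_falloff <= 0:
            raise ValueError("distal_falloff must be positive")
        if not 0 < self.entrance_ratio < 1:
            raise ValueError("entrance_ratio must be in (0, 1)")
        if self.proximal_ramp_width <= 0:
            raise ValueError("proximal_ramp_width must be positive")

    @property
    def edge_sigma(self) -> float:
        """Sigma of the Gaussian-CDF distal edge: falloff / (2 * z_0.9)."""
        return self.distal_falloff / (2 * _Z90)

    @property
    def r50(self) -> float:
        """Depth of the distal 50% crossing."""
        return self.r90 + _Z90 * self.edge_sigma


@dataclass(frozen=True)
class AperturePolygon:
    """Brass-collimator aperture in the beam's-eye plane (mm)."""

    vertices: tuple[tuple[float, float], ...]
    penumbra_sigma: float = 1.0

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValueError("aperture needs at least 3 vertices")
        if self.penumbra_sigma < 0:
            raise ValueError("penumbra_sigma must be >= 0")
        poly = ShapelyPolygon(self.vertices)
        if not poly.is_simple or not poly.is_valid or poly.area <= 0:
            raise ValueError("aperture polygon must be simple with positive area")


@dataclass(frozen=True)
class QuenchModel:
    """Birks-type saturation on a residual-range LET proxy."""

    let_scale: float = 1.0
    let_offset: float = 0.5
    birks_k: float = 0.15
    range_end: float = 29.5
    softening_delta: float = 0.3

    def __post_init__(self) -> None:
        if self.birks_k < 0 or self.let_scale < 0 or self.let_offset < 0:
            raise ValueError("quench parameters must be non-negative")
        if self.range_end <= 0 or self.softening_delta <= 0:
            raise ValueError("range_end and softening_delta must be positive")


def quench_efficiency(q: QuenchModel, depth) -> np.ndarray | float:
    """Luminescence efficiency eta(depth) in (0, 1], non-increasing in depth."""
    d = np.asarray(depth, dtype=float)
    if np.any(d < 0):
        raise ValueError("depth must be non-negative")
    residual = np.clip(q.range_end - d, 0.0, None) + q.softening_delta
    let = q.let_offset + q.let_scale / residual
    eta = 1.0 / (1.0 + q.birks_k * let)
    if np.ndim(depth) == 0:
        return float(eta)
    return eta


@dataclass
class DetectorScene:
    """Camera/foil geometry and the per-pixel nuisance maps.

    ``foil_center`` is (row, col) in pixels; ``gain`` is expected counts
    per unit relative dose at efficiency 1 and unit sensitivity.  The
    amplitude parameters used to synthesise the maps are kept so that
    stack generation can draw an independent sensitivity map per foil.
    """

    image_shape: tuple[int, int] = (256, 256)
    pixel_pitch_mm: float = 0.1
    foil_center: tuple[float, float] = (127.5, 127.5)
    foil_radius_px: float = 100.0
    sensitivity_map: np.ndarray | None = None
    illumination_map: np.ndarray | None = None
    dark_level: float = 100.0
    gain: float = 20000.0
    read_noise_sigma: float = 5.0
    sensitivity_rms: float = 0.08
    sensitivity_corr_mm: float = 0.3
    vignette: float = 0.15

    def __post_init__(self) -> None:
        if self.gain < 0 or self.dark_level < 0 or self.read_noise_sigma < 0:
            raise ValueError("gain, dark_level and read_noise_sigma must be >= 0")
        if self.pixel_pitch_mm <= 0 or self.foil_radius_px <= 0:
            raise ValueError("pixel pitch and foil radius must be positive")
        r = self.foil_radius_px
        cy, cx = self.foil_center
        if (
            cy - r < 0
            or cx - r < 0
            or cy + r > self.image_shape[0] - 1
            or cx + r > self.image_shape[1] - 1
        ):
            raise ValueError("foil disc must lie fully inside the image")
        if self.sensitivity_map is None:
            self.sensitivity_map = np.ones(self.image_shape)
        if self.illumination_map is None:
            self.illumination_map = np.ones(self.image_shape)
        for name in ("sensitivity_map", "illumination_map"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != tuple(self.image_shape):
                raise ValueError(f"{name} shape must match image_shape")
            if np.any(m <= 0):
                raise ValueError(f"{name} must be strictly positive")
            setattr(self, name, m)

    def disc_mask(self) -> np.ndarray:
        rows, cols = np.indices(self.image_shape)
        return (rows - self.foil_center[0]) ** 2 + (
            cols - self.foil_center[1]
        ) ** 2 <= self.foil_radius_px**2

    def grid_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) axes in mm with the foil center at the origin."""
        x = (np.arange(self.image_shape[1]) - self.foil_center[1]) * self.pixel_pitch_mm
        y = (np.arange(self.image_shape[0]) - self.foil_center[0]) * self.pixel_pitch_mm
        return x, y


def _sensitivity_field(
    shape: tuple[int, int],
    rms: float,
    corr_px: float,
    rng: np.random.Generator,
    region: np.ndarray | None = None,
) -> np.ndarray:
    """Correlated multiplicative granularity field, mean 1 and given RMS.

    Mean and RMS are set over ``region`` (the foil disc) when given —
    the granularity amplitude describes the phosphor distribution of
    the foil, not of empty frame corners.
    """
    if rms == 0:
        return np.ones(shape)
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=max(corr_px, 1e-6), mode="reflect")
    ref = smooth[region] if region is not None else smooth
    sd = ref.std()
    if sd == 0:
        return np.ones(shape)
    return np.clip(1.0 + (smooth - ref.mean()) / sd * rms, 0.05, None)


def _illumination_field(
    shape: tuple[int, int],
    vignette: float,
    center: tuple[float, float],
    radius_px: float,
) -> np.ndarray:
    """Radial vignette: 1 on axis, (1 - vignette) at the foil-disc edge."""
    if vignette == 0:
        return np.ones(shape)
    rows, cols = np.indices(shape)
    r2 = (rows - center[0]) ** 2 + (cols - center[1]) ** 2
    return np.clip(1.0 - vignette * r2 / radius_px**2, 0.05, None)


def make_scene(
    seed: int = 0,
    image_shape: tuple[int, int] = (256, 256),
    pixel_pitch_mm: float = 0.1,
    foil_center: tuple[float, float] | None = None,
    foil_radius_px: float | None = None,
    sensitivity_rms: float = 0.08,
    sensitivity_corr_mm: float = 0.3,
    vignette: float = 0.15,
    dark_level: float = 100.0,
    gain: float = 20000.0,
    read_noise_sigma: float = 5.0,
) -> DetectorScene:
    """Build a detector scene with synthesised nuisance maps."""
    if foil_center is None:
        foil_center = ((image_shape[0] - 1) / 2.0, (image_shape[1] - 1) / 2.0)
    if foil_radius_px is None:
        foil_radius_px = 10.0 / pixel_pitch_mm  # 20 mm foil diameter
    rng = np.random.default_rng(seed)
    corr_px = sensitivity_corr_mm / pixel_pitch_mm
    rows, cols = np.indices(tuple(image_shape))
    disc = (rows - foil_center[0]) ** 2 + (cols - foil_center[1]) ** 2 <= float(
        foil_radius_px
    ) ** 2
    return DetectorScene(
        image_shape=tuple(image_shape),
        pixel_pitch_mm=pixel_pitch_mm,
        foil_center=tuple(foil_center),
        foil_radius_px=float(foil_radius_px),
        sensitivity_map=_sensitivity_field(
            tuple(image_shape), sensitivity_rms, corr_px, rng, region=disc
        ),
        illumination_map=_illumination_field(
            tuple(image_shape), vignette, tuple(foil_center), float(foil_radius_px)
        ),
        dark_level=dark_level,
        gain=gain,
        read_noise_sigma=read_noise_sigma,
        sensitivity_rms=sensitivity_rms,
        sensitivity_corr_mm=sensitivity_corr_mm,
        vignette=vignette,
    )


def _check_depths(depths) -> np.ndarray:
    d = np.asarray(depths, dtype=float)
    if d.ndim != 1 or d.size < 1:
        raise ValueError("depths must be a 1D array")
    if np.any(d < 0):
        raise ValueError("depths must be non-negative")
    if d.size > 1 and not np.all(np.diff(d) > 0):
        raise ValueError("depths must be strictly increasing")
    return d


def sobp_depth_dose(beam: BeamSpec, depths) -> DepthDoseCurve:
    """Analytic SOBP, normalised to 1.0 on the modulated plateau.

    By construction the distal 90% crossing is at ``beam.r90``, the
    90%→10% distance is ``beam.distal_falloff`` and the curve crosses
    90% proximally at ``beam.r90 - beam.modulation``.
    """
    d = _check_depths(depths)
    e = beam.entrance_ratio
    ramp_level = (0.9 - e) / (1.0 - e)  # ramp value at the proximal 90% depth
    c = beam.r90 - beam.modulation - beam.proximal_ramp_width * float(
        stats.norm.ppf(ramp_level)
    )
    ramp = stats.norm.cdf((d - c) / beam.proximal_ramp_width)
    edge = stats.norm.cdf((beam.r50 - d) / beam.edge_sigma)
    return DepthDoseCurve(depths=d, values=(e + (1.0 - e) * ramp) * edge)


def pristine_depth_dose(
    range_mm: float,
    falloff: float,
    peak_to_plateau: float,
    depths,
    rise_scale_mm: float = 2.0,
    saturation_mm: float = 0.5,
) -> DepthDoseCurve:
    """Single pristine Bragg peak, normalised to peak = 1.

    The rise toward the peak follows a residual-range factor
    ``min(1, a / (R50 + b - z))`` scaled between 1 and
    ``peak_to_plateau``; the distal edge is a Gaussian CDF whose distal
    90% crossing sits at ``range_mm``.
    """
    if range_mm <= 0:
        raise ValueError("range_mm must be positive")
    if falloff <= 0:
        raise ValueError("falloff must be positive")
    if peak_to_plateau < 1:
        raise ValueError("peak_to_plateau must be >= 1")
    d = _check_depths(depths)
    sigma = falloff / (2 * _Z90)
    r50 = range_mm + _Z90 * sigma
    rise = np.minimum(1.0, rise_scale_mm / np.clip(r50 + saturation_mm - d, 1e-9, None))
    base = 1.0 + (peak_to_plateau - 1.0) * rise
    values = base * stats.norm.cdf((r50 - d) / sigma)
    return DepthDoseCurve(depths=d, values=values / values.max())


def lateral_field(
    aperture: AperturePolygon, x_axis: np.ndarray, y_axis: np.ndarray
) -> np.ndarray:
    """Relative fluence map: aperture indicator blurred by the penumbra.

    The polygon indicator (evaluated at pixel centers) is convolved with
    an isotropic Gaussian of ``penumbra_sigma``; values lie in [0, 1].
    The grid must cover the polygon's bounding box.
    """
    x_axis = np.asarray(x_axis, dtype=float)
    y_axis = np.asarray(y_axis, dtype=float)
    verts = np.asarray(aperture.vertices, dtype=float)
    if (
        x_axis[0] > verts[:, 0].min()
        or x_axis[-1] < verts[:, 0].max()
        or y_axis[0] > verts[:, 1].min()
        or y_axis[-1] < verts[:, 1].max()
    ):
        raise ValueError("grid does not cover the aperture bounding box")
    xx, yy = np.meshgrid(x_axis, y_axis)
    inside = (
        MplPath(verts)
        .contains_points(np.column_stack([xx.ravel(), yy.ravel()]))
        .reshape(xx.shape)
        .astype(float)
    )
    if aperture.penumbra_sigma == 0:
        return inside
    dx = float(np.diff(x_axis).mean())
    dy = float(np.diff(y_axis).mean())
    blurred = ndimage.gaussian_filter(
        inside,
        sigma=(aperture.penumbra_sigma / dy, aperture.penumbra_sigma / dx),
        mode="constant",
    )
    return np.clip(blurred, 0.0, 1.0)


def _rng_from(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def render_foil_frame(
    scene: DetectorScene,
    dose_slice: np.ndarray,
    efficiency: float,
    seed=0,
    noise: bool = True,
    exposure_s: float = 30.0,
    foil_index: int = 1,
) -> FoilImage:
    """Simulate one CCD readout of an irradiated foil.

    Expected counts are ``gain * efficiency * dose * sensitivity *
    illumination`` inside the foil disc plus ``dark_level`` everywhere;
    with ``noise`` on, Poisson shot noise is applied to the expected
    counts followed by additive Gaussian read noise.  The same seed
    always yields the identical frame.
    """
    dose_slice = np.asarray(dose_slice, dtype=float)
    if dose_slice.shape != tuple(scene.image_shape):
        raise ValueError("dose_slice must be resampled to the scene pixel grid")
    if np.any(dose_slice < 0):
        raise ValueError("dose must be non-negative")
    if efficiency <= 0 or efficiency > 1:
        raise ValueError("efficiency must be in (0, 1]")
    expected = scene.dark_level + np.where(
        scene.disc_mask(),
        scene.gain
        * efficiency
        * dose_slice
        * scene.sensitivity_map
        * scene.illumination_map,
        0.0,
    )
    if noise:
        rng = _rng_from(seed)
        counts = rng.poisson(expected).astype(float)
        counts += rng.normal(0.0, scene.read_noise_sigma, size=counts.shape)
        counts = np.clip(counts, 0.0, None)
    else:
        counts = expected
    return FoilImage(pixels=counts, exposure_s=exposure_s, foil_index=foil_index)


def render_correction_frames(
    scene: DetectorScene,
    seed=0,
    noise: bool = True,
    flat_gain: float = 30000.0,
    live_inside: float = 30000.0,
    live_outside: float = 1000.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Simulate (background, live_view, flatfield, iri_raw) frames.

    Background is dark counts only; the live view is a short white-light
    exposure with strong disc/surround contrast; the flat-field records
    the stimulation-light illumination pattern; the IRI is a readout of
    the foil after a spatially uniform unit dose at efficiency 1.
    """
    rng = _rng_from(seed)
    disc = scene.disc_mask()

    def _noisy(expected: np.ndarray) -> np.ndarray:
        if not noise:
            return expected.astype(float)
        counts = rng.poisson(expected).astype(float)
        counts += rng.normal(0.0, scene.read_noise_sigma, size=counts.shape)
        return np.clip(counts, 0.0, None)

    background = _noisy(np.full(scene.image_shape, float(scene.dark_level)))
    live_view = _noisy(
        scene.dark_level + np.where(disc, live_inside, live_outside) * scene.illumination_map
    )
    flatfield = _noisy(scene.dark_level + flat_gain * scene.illumination_map)
    iri = render_foil_frame(
        scene,
        np.ones(scene.image_shape),
        efficiency=1.0,
        seed=rng,
        noise=noise,
    )
    return background, live_view, flatfield, iri.pixels


@dataclass
class ScenarioBundle:
    """Everything one simulated stack irradiation produces.

    Per foil: the raw 30 s OSL readout, a live-view frame sharing the
    foil placement, and the raw individual reference image.  Shared:
    background and flat-field frames, the unquenched ground-truth dose
    grid, and a pristine-beam calibration dataset generated through the
    same quench model.
    """

    raw_frames: list[FoilImage]
    live_view_frames: list[np.ndarray]
    iri_frames: list[np.ndarray]
    background_frame: np.ndarray
    flatfield_frame: np.ndarray
    ground_truth_dose: DoseGrid3D
    calibration_set: CalibrationDataset
    geometry: StackGeometry
    beam: BeamSpec
    quench: QuenchModel
    aperture: AperturePolygon
    scene: DetectorScene
    seed: int
    noise: bool = True
    center_jitter_mm: float = 0.5
    warnings_: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        n = self.geometry.n_foils
        if not (len(self.raw_frames) == len(self.live_view_frames) == len(self.iri_frames) == n):
            raise ValueError("frame counts must equal the number of foils")
        z = self.ground_truth_dose.z_axis
        depths = foil_depths(self.geometry)
        if depths[0] < z[0] or depths[-1] > z[-1]:
            raise ValueError("ground truth grid must cover all foil depths")


def default_beam() -> BeamSpec:
    return BeamSpec()


def default_geometry() -> StackGeometry:
    return StackGeometry()


def default_quench() -> QuenchModel:
    return QuenchModel()


def default_aperture(penumbra_sigma: float = 1.0) -> AperturePolygon:
    """A slightly irregular ~13.5 mm collimator opening (12-gon)."""
    radii = np.array([7.0, 6.8, 6.5, 6.6, 7.1, 7.3, 7.0, 6.6, 6.4, 6.7, 7.2, 7.4])
    angles = np.linspace(0.0, 2 * np.pi, len(radii), endpoint=False)
    verts = tuple(
        (float(r * np.cos(a)), float(r * np.sin(a))) for r, a in zip(radii, angles)
    )
    return AperturePolygon(vertices=verts, penumbra_sigma=penumbra_sigma)


#: depths (mm water) of the pristine-beam calibration foils
DEFAULT_CALIBRATION_DEPTHS = np.array(
    [2.0, 5.0, 8.0, 11.0, 14.0, 17.0, 20.0, 22.5, 24.5, 26.5, 27.5, 28.5, 29.2]
)


def build_scenario(
    geom: StackGeometry | None = None,
    beam: BeamSpec | None = None,
    aperture: AperturePolygon | None = None,
    quench: QuenchModel | None = None,
    scene: DetectorScene | None = None,
    seed: int = 0,
    noise: bool = True,
    center_jitter_mm: float = 0.5,
    calibration_depths: np.ndarray | None = None,
    calibration_foil_noise: float = 0.005,
    pristine_range_mm: float = 29.0,
    pristine_falloff_mm: float = 0.7,
    pristine_peak_to_plateau: float = 3.0,
    truth_z_step_mm: float = 0.1,
) -> ScenarioBundle:
    """Generate a complete synthetic stack-irradiation scenario.

    One raw readout frame is produced per foil at that foil's
    water-equivalent mid-plane depth; each foil gets its own sensitivity
    map and a placement jitter (uniform, ±``center_jitter_mm``) shared
    by its raw, live-view and reference readouts.  The ground-truth grid
    is the unquenched depth dose times the lateral field on a fine depth
    axis; the calibration set emulates single foils irradiated at
    various depths in a pristine beam, seen through the same quench
    model.
    """
    geom = geom or default_geometry()
    beam = beam or default_beam()
    aperture = aperture or default_aperture()
    quench = quench or default_quench()
    scene = scene or make_scene(seed)
    rng = np.random.default_rng(seed)
    depths = foil_depths(geom)
    sobp = sobp_depth_dose(beam, depths)
    eta = quench_efficiency(quench, depths)

    notes: list[str] = []
    r10 = beam.r90 + beam.distal_falloff
    if r10 > geom.total_water_range_mm:
        msg = (
            f"beam R10 ({r10:.2f} mm) exceeds the stack range "
            f"({geom.total_water_range_mm:.2f} mm): distal edge unmeasurable"
        )
        notes.append(msg)
        warnings.warn(msg, stacklevel=2)

    jitter_px = center_jitter_mm / scene.pixel_pitch_mm
    corr_px = scene.sensitivity_corr_mm / scene.pixel_pitch_mm
    raw_frames: list[FoilImage] = []
    live_frames: list[np.ndarray] = []
    iri_frames: list[np.ndarray] = []
    shared_bg, _, shared_flat, _ = render_correction_frames(
        scene, seed=np.random.default_rng(rng.integers(_MAX_SEED)), noise=noise
    )
    for i in range(geom.n_foils):
        foil_rng = np.random.default_rng(rng.integers(_MAX_SEED))
        jitter = foil_rng.uniform(-jitter_px, jitter_px, size=2) if center_jitter_mm > 0 else np.zeros(2)
        center_i = (scene.foil_center[0] + jitter[0], scene.foil_center[1] + jitter[1])
        rows_i, cols_i = np.indices(tuple(scene.image_shape))
        disc_i = (rows_i - center_i[0]) ** 2 + (
            cols_i - center_i[1]
        ) ** 2 <= scene.foil_radius_px**2
        scene_i = replace(
            scene,
            foil_center=center_i,
            sensitivity_map=_sensitivity_field(
                tuple(scene.image_shape),
                scene.sensitivity_rms,
                corr_px,
                foil_rng,
                region=disc_i,
            ),
        )
        x_i, y_i = scene_i.grid_mm()
        field_i = lateral_field(aperture, x_i, y_i)
        raw = render_foil_frame(
            scene_i,
            sobp.values[i] * field_i,
            efficiency=float(eta[i]),
            seed=foil_rng,
            noise=noise,
            foil_index=i + 1,
        )
        _, live, _, iri = render_correction_frames(scene_i, seed=foil_rng, noise=noise)
        raw_frames.append(raw)
        live_frames.append(live)
        iri_frames.append(iri)

    # unquenched ground truth on a fine depth axis, lateral field centered
    z0 = depths[0] - 4 * truth_z_step_mm
    z1 = depths[-1] + 1.0
    zt = np.arange(z0, z1 + truth_z_step_mm / 2, truth_z_step_mm)
    truth_depth = sobp_depth_dose(beam, zt)
    x0, y0 = scene.grid_mm()
    field0 = lateral_field(aperture, x0, y0)
    truth = DoseGrid3D(
        values=(truth_depth.values[:, None, None] * field0[None, :, :]).astype(
            np.float32
        ),
        x_axis=x0,
        y_axis=y0,
        z_axis=zt,
        normalization_mode="none",
        provenance=("ground_truth",),
    )

    cal_depths = (
        DEFAULT_CALIBRATION_DEPTHS.copy()
        if calibration_depths is None
        else np.asarray(calibration_depths, dtype=float)
    )
    pristine = pristine_depth_dose(
        pristine_range_mm, pristine_falloff_mm, pristine_peak_to_plateau, cal_depths
    )
    cal_eta = np.asarray(quench_efficiency(quench, cal_depths))
    cal_rng = np.random.default_rng(rng.integers(_MAX_SEED))
    foil_noise = (
        cal_rng.normal(0.0, calibration_foil_noise, size=cal_depths.size)
        if (noise and calibration_foil_noise > 0)
        else np.zeros(cal_depths.size)
    )
    calibration = CalibrationDataset(
        depth_mm=cal_depths,
        ref_dose=pristine.values,
        foil_signal=cal_eta * pristine.values * (1.0 + foil_noise),
    )

    return ScenarioBundle(
        raw_frames=raw_frames,
        live_view_frames=live_frames,
        iri_frames=iri_frames,
        background_frame=shared_bg,
        flatfield_frame=shared_flat,
        ground_truth_dose=truth,
        calibration_set=calibration,
        geometry=geom,
        beam=beam,
        quench=quench,
        aperture=aperture,
        scene=scene,
        seed=seed,
        noise=noise,
        center_jitter_mm=center_jitter_mm,
        warnings_=tuple(notes),
    )
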