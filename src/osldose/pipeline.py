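"""End-to-end orchestration: correct -> reconstruct -> calibrate -> compare.

Thin, testable glue over the library modules; the command-line
interface drives exactly these functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import (
    CalibrationCurve,
    compute_k_points,
    fit_calibration,
    apply_calibration,
)
from .correction import CorrectionSet, FoilImage, correct_frame
from .metrics import (
    ComparisonReport,
    DepthDoseCurve,
    SOBPMetrics,
    central_depth_profile,
    compare_grids,
    sobp_metrics,
)
from .phantom import ScenarioBundle
from .stack import DoseGrid3D, assemble_grid, normalize, register_slices

__all__ = ["PipelineParams", "PipelineResult", "correct_all", "reconstruct", "run_pipeline"]


@dataclass(frozen=True)
class PipelineParams:
    """Knobs of the analysis chain, with the defaults used throughout."""

    margin_px: int = 4
    median_kernel_px: int = 3
    register_margin_px: int = 2
    window_mm: float = 2.0
    normalization: str = "global_max"
    apply_quench_correction: bool = True
    report_depths: tuple[float, ...] = (24.0, 29.0, 29.8)


@dataclass
class PipelineResult:
    """Everything one pipeline run produces."""

    corrected_frames: list[FoilImage]
    grid_uncorrected: DoseGrid3D
    grid_corrected: DoseGrid3D | None
    calibration: CalibrationCurve | None
    profile_uncorrected: DepthDoseCurve
    profile_corrected: DepthDoseCurve | None
    truth_grid: DoseGrid3D
    truth_profile: DepthDoseCurve
    metrics: SOBPMetrics
    metrics_uncorrected: SOBPMetrics
    truth_metrics: SOBPMetrics
    report: ComparisonReport | None
    params: PipelineParams
    quench_corrected: bool

    @property
    def final_grid(self) -> DoseGrid3D:
        return self.grid_corrected if self.grid_corrected is not None else self.grid_uncorrected

    def truth_profile_at(self, depths: np.ndarray) -> np.ndarray:
        """Ground-truth central profile interpolated to arbitrary depths."""
        return np.interp(depths, self.truth_profile.depths, self.truth_profile.values)


def correct_all(
    bundle: ScenarioBundle, params: PipelineParams | None = None
) -> list[FoilImage]:
    """Run the full correction chain on every foil of a scenario."""
    params = params or PipelineParams()
    corrected = []
    for raw, live, iri in zip(
        bundle.raw_frames, bundle.live_view_frames, bundle.iri_frames
    ):
        cset = CorrectionSet(
            background=bundle.background_frame,
            live_view=live,
            flatfield=bundle.flatfield_frame,
            iri_raw=iri,
        )
        corrected.append(
            correct_frame(
                raw,
                cset,
                margin_px=params.margin_px,
                median_kernel_px=params.median_kernel_px,
            )
        )
    return corrected


def reconstruct(
    corrected: list[FoilImage],
    bundle: ScenarioBundle,
    params: PipelineParams | None = None,
) -> DoseGrid3D:
    """Register, stack and normalise the corrected slices."""
    params = params or PipelineParams()
    registered = register_slices(corrected, margin_px=params.register_margin_px)
    grid = assemble_grid(registered, bundle.geometry, bundle.scene.pixel_pitch_mm)
    return normalize(grid, params.normalization)


def run_pipeline(
    bundle: ScenarioBundle,
    params: PipelineParams | None = None,
    compare: bool = True,
) -> PipelineResult:
    """Full analysis of one scenario bundle.

    Corrects every frame, reconstructs the 3D grid, optionally fits and
    applies the quenching calibration, extracts the central depth
    profile and its SOBP metrics, and (optionally) compares the final
    grid against the scenario's ground truth.
    """
    params = params or PipelineParams()
    corrected = correct_all(bundle, params)
    grid_uncorrected = reconstruct(corrected, bundle, params)
    profile_uncorrected = central_depth_profile(grid_uncorrected, params.window_mm)
    metrics_uncorrected = sobp_metrics(profile_uncorrected)

    calibration = None
    grid_corrected = None
    profile_corrected = None
    if params.apply_quench_correction:
        calibration = fit_calibration(compute_k_points(bundle.calibration_set))
        grid_corrected = apply_calibration(grid_uncorrected, calibration)
        profile_corrected = central_depth_profile(grid_corrected, params.window_mm)

    truth_grid = normalize(bundle.ground_truth_dose, params.normalization)
    truth_profile = central_depth_profile(truth_grid, params.window_mm)
    final_profile = profile_corrected if profile_corrected is not None else profile_uncorrected

    report = None
    if compare:
        final = grid_corrected if grid_corrected is not None else grid_uncorrected
        report = compare_grids(
            final, truth_grid, report_depths=params.report_depths, window_mm=params.window_mm
        )

    return PipelineResult(
        corrected_frames=corrected,
        grid_uncorrected=grid_uncorrected,
        grid_corrected=grid_corrected,
        calibration=calibration,
        profile_uncorrected=profile_uncorrected,
        profile_corrected=profile_corrected,
        truth_grid=truth_grid,
        truth_profile=truth_profile,
        metrics=sobp_metrics(final_profile),
        metrics_uncorrected=metrics_uncorrected,
        truth_metrics=sobp_metrics(truth_profile),
        report=report,
        params=params,
        quench_corrected=params.apply_quench_correction,
    )
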