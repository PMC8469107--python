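"""File formats: TIFF frames, MetaImage dose grids, manifests, reports.

Raw and correction frames travel as 16-bit grayscale TIFF (the camera's
native depth), corrected frames as 32-bit float TIFF with NaN outside
the validity mask.  3D grids are MetaImage (.mhd + .raw) with spacing
in mm and the depth axis in water-equivalent mm (flagged in the
metadata).  Scenario parameters live in a YAML manifest so a run can be
reproduced from its directory alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import tifffile
import yaml

from .calibration import write_calibration_dataset
from .correction import FoilImage, FoilROI
from .phantom import (
    AperturePolygon,
    BeamSpec,
    QuenchModel,
    ScenarioBundle,
)
from .stack import DoseGrid3D, StackGeometry

__all__ = [
    "write_frame_u16",
    "read_frame",
    "write_corrected_frame",
    "read_corrected_frame",
    "write_metaimage",
    "read_metaimage",
    "write_scenario",
    "read_scenario_manifest",
    "file_sha256",
]


def write_frame_u16(path: str | Path, frame: np.ndarray) -> None:
    """Write a count frame as 16-bit grayscale TIFF (rounded, clipped)."""
    arr = np.clip(np.round(np.asarray(frame, dtype=float)), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), arr)


def read_frame(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path)), dtype=float)


def write_corrected_frame(path: str | Path, img: FoilImage) -> None:
    """Float32 TIFF with NaN outside the mask, plus a YAML sidecar.

    The sidecar records ROI, origin, foil index and the provenance
    steps, so the stack can be reassembled from files alone.
    """
    path = Path(path)
    arr = np.where(img.mask, img.pixels, np.nan).astype(np.float32)
    tifffile.imwrite(str(path), arr)
    meta = {
        "foil_index": int(img.foil_index),
        "exposure_s": float(img.exposure_s),
        "origin": [int(img.origin[0]), int(img.origin[1])],
        "steps": list(img.steps),
        "roi": None
        if img.roi is None
        else {
            "center": [float(img.roi.center[0]), float(img.roi.center[1])],
            "radius": float(img.roi.radius),
        },
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(meta, sort_keys=False))


def read_corrected_frame(path: str | Path) -> FoilImage:
    path = Path(path)
    arr = np.asarray(tifffile.imread(str(path)), dtype=float)
    meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
    mask = np.isfinite(arr)
    roi = None
    if meta.get("roi"):
        roi = FoilROI(
            center=tuple(meta["roi"]["center"]), radius=float(meta["roi"]["radius"])
        )
    return FoilImage(
        pixels=np.nan_to_num(arr),
        exposure_s=float(meta.get("exposure_s", 30.0)),
        foil_index=int(meta["foil_index"]),
        mask=mask,
        roi=roi,
        origin=tuple(meta.get("origin", (0, 0))),
        steps=tuple(meta.get("steps", ())),
    )


def write_metaimage(path: str | Path, grid: DoseGrid3D) -> None:
    """Write a dose grid as MetaImage; invalid voxels become NaN.

    Axes must be uniformly spaced (they are, for assembled stacks:
    constant pixel pitch laterally, constant foil pitch in depth).
    """
    path = Path(path)
    for name, ax in (("x", grid.x_axis), ("y", grid.y_axis), ("z", grid.z_axis)):
        d = np.diff(ax)
        if d.size and not np.allclose(d, d[0], rtol=1e-6):
            raise ValueError(f"{name} axis is not uniformly spaced; cannot write MetaImage")
    arr = np.where(grid.valid, grid.values, np.nan).astype(np.float32)
    img = sitk.GetImageFromArray(arr)  # array order [z, y, x]
    img.SetSpacing(
        (
            float(np.diff(grid.x_axis)[0]) if grid.x_axis.size > 1 else 1.0,
            float(np.diff(grid.y_axis)[0]) if grid.y_axis.size > 1 else 1.0,
            float(np.diff(grid.z_axis)[0]) if grid.z_axis.size > 1 else 1.0,
        )
    )
    img.SetOrigin((float(grid.x_axis[0]), float(grid.y_axis[0]), float(grid.z_axis[0])))
    img.SetMetaData("normalization_mode", grid.normalization_mode)
    img.SetMetaData("z_axis_unit", "mm_water_equivalent")
    img.SetMetaData("provenance", "|".join(grid.provenance))
    sitk.WriteImage(img, str(path))


def read_metaimage(path: str | Path) -> DoseGrid3D:
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img).astype(float)
    sx, sy, sz = img.GetSpacing()
    ox, oy, oz = img.GetOrigin()
    nz, ny, nx = arr.shape
    valid = np.isfinite(arr)
    keys = img.GetMetaDataKeys()
    mode = img.GetMetaData("normalization_mode") if "normalization_mode" in keys else "none"
    prov = (
        tuple(p for p in img.GetMetaData("provenance").split("|") if p)
        if "provenance" in keys
        else ()
    )
    return DoseGrid3D(
        values=np.nan_to_num(arr),
        x_axis=ox + sx * np.arange(nx),
        y_axis=oy + sy * np.arange(ny),
        z_axis=oz + sz * np.arange(nz),
        normalization_mode=mode if mode in ("none", "global_max", "per_slice_max") else "none",
        valid=valid,
        provenance=prov,
    )


def _aperture_dict(a: AperturePolygon) -> dict:
    return {
        "vertices": [[float(x), float(y)] for x, y in a.vertices],
        "penumbra_sigma": float(a.penumbra_sigma),
    }


def scenario_manifest(bundle: ScenarioBundle) -> dict:
    """All parameters needed to regenerate the scenario (maps excluded)."""
    scene = bundle.scene
    return {
        "seed": int(bundle.seed),
        "noise": bool(bundle.noise),
        "center_jitter_mm": float(bundle.center_jitter_mm),
        "geometry": dataclasses.asdict(bundle.geometry),
        "beam": dataclasses.asdict(bundle.beam),
        "quench": dataclasses.asdict(bundle.quench),
        "aperture": _aperture_dict(bundle.aperture),
        "scene": {
            "image_shape": [int(s) for s in scene.image_shape],
            "pixel_pitch_mm": float(scene.pixel_pitch_mm),
            "foil_center": [float(c) for c in scene.foil_center],
            "foil_radius_px": float(scene.foil_radius_px),
            "dark_level": float(scene.dark_level),
            "gain": float(scene.gain),
            "read_noise_sigma": float(scene.read_noise_sigma),
            "sensitivity_rms": float(scene.sensitivity_rms),
            "sensitivity_corr_mm": float(scene.sensitivity_corr_mm),
            "vignette": float(scene.vignette),
        },
        "warnings": list(bundle.warnings_),
    }


def write_scenario(bundle: ScenarioBundle, out_dir: str | Path) -> Path:
    """Write every scenario artifact into a directory; returns the path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, (raw, live, iri) in enumerate(
        zip(bundle.raw_frames, bundle.live_view_frames, bundle.iri_frames), start=1
    ):
        write_frame_u16(out / f"raw_{i:03d}.tif", raw.pixels)
        write_frame_u16(out / f"live_{i:03d}.tif", live)
        write_frame_u16(out / f"iri_{i:03d}.tif", iri)
    write_frame_u16(out / "background.tif", bundle.background_frame)
    write_frame_u16(out / "flatfield.tif", bundle.flatfield_frame)
    write_metaimage(out / "ground_truth.mhd", bundle.ground_truth_dose)
    write_calibration_dataset(bundle.calibration_set, out / "calibration.txt")
    (out / "manifest.yaml").write_text(
        yaml.safe_dump(scenario_manifest(bundle), sort_keys=False)
    )
    return out


def read_scenario_manifest(scenario_dir: str | Path) -> dict:
    return yaml.safe_load((Path(scenario_dir) / "manifest.yaml").read_text())


def manifest_objects(
    manifest: dict,
) -> tuple[StackGeometry, BeamSpec, QuenchModel, AperturePolygon]:
    """Rebuild parameter objects from a scenario manifest."""
    return (
        StackGeometry(**manifest["geometry"]),
        BeamSpec(**manifest["beam"]),
        QuenchModel(**manifest["quench"]),
        AperturePolygon(
            vertices=tuple(tuple(v) for v in manifest["aperture"]["vertices"]),
            penumbra_sigma=manifest["aperture"]["penumbra_sigma"],
        ),
    )


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
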