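"""Multi-angle maximum-intensity projections of SUV volumes.

The classifier consumes 64 x 64 gray images.  Each view is produced by
rotating the volume about the craniocaudal (z) axis by the view azimuth
(counterclockwise seen from superior), taking the per-ray maximum along the
anterior-posterior axis with trilinear interpolation, windowing SUV to
[0, 10] and resampling to 64 x 64 with aspect-preserving letterboxing.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .errors import ConfigurationError, EmptyInputError
from .phantom import ScannerProfile, Volume

__all__ = [
    "MIPImage",
    "SUV_WINDOW",
    "OUTPUT_SIZE",
    "mip_project",
    "window_and_resample",
    "generate_mip_set",
    "save_mip_set",
    "load_mip_set",
]

SUV_WINDOW = (0.0, 10.0)
OUTPUT_SIZE = 64


@dataclass
class MIPImage:
    """One windowed gray MIP view: 64 x 64, values in [0, 1]."""

    pixels: np.ndarray
    angle: float
    patient_id: str = ""
    scanner: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.shape != (OUTPUT_SIZE, OUTPUT_SIZE):
            raise ConfigurationError(
                f"MIP image must be {OUTPUT_SIZE}x{OUTPUT_SIZE}, got {self.pixels.shape}"
            )
        if not (0.0 <= self.angle < 360.0):
            raise ConfigurationError("angle must lie in [0, 360)")
        if np.any(self.pixels < -1e-6) or np.any(self.pixels > 1 + 1e-6):
            raise ConfigurationError("pixel values must lie in [0, 1]")
        np.clip(self.pixels, 0.0, 1.0, out=self.pixels)


def _snap(v: float, tol: float = 1e-12) -> float:
    # make axis-aligned angles exact so 0/90/180/270 degree projections are
    # pure grid permutations under trilinear interpolation
    for target in (-1.0, 0.0, 1.0):
        if abs(v - target) < tol:
            return target
    return v


def mip_project(volume: Volume, angle: float) -> np.ndarray:
    """Project a volume at one azimuth; returns a (nz, nx) array in SUV units.

    The volume is rotated by ``angle`` degrees about z (counterclockwise from
    superior) with trilinear interpolation, out-of-support samples contribute
    0, and the maximum is taken along the y (anterior-posterior) axis.
    """
    vol = volume.intensities
    if vol.size == 0:
        raise EmptyInputError("cannot project an empty volume")
    th = np.deg2rad(angle % 360.0)
    c, s = _snap(float(np.cos(th))), _snap(float(np.sin(th)))
    if c == 1.0 and s == 0.0:
        rotated = vol
    else:
        # affine acts on (z, y, x) index space; rotation mixes (y, x) only
        mat = np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])
        centre = (np.asarray(vol.shape) - 1) / 2.0
        offset = centre - mat @ centre
        rotated = ndimage.affine_transform(
            vol, mat, offset=offset, order=1, mode="constant", cval=0.0
        )
    return rotated.max(axis=1)


def window_and_resample(
    projection: np.ndarray,
    spacing: tuple[float, float] = (1.0, 1.0),
    suv_window: tuple[float, float] = SUV_WINDOW,
    out_size: int = OUTPUT_SIZE,
    letterbox: bool = True,
) -> np.ndarray:
    """Window SUV to gray in [0, 1] and resample to ``out_size`` square.

    ``spacing`` is (dz, dx): physical size of a projection pixel.  With
    ``letterbox`` the physical aspect ratio is preserved and the short side is
    centred and padded with 0 (air), rather than anisotropically stretched.
    """
    lo, hi = suv_window
    if not hi > lo:
        raise ConfigurationError("SUV window must have min < max")
    gray = np.clip((np.asarray(projection, dtype=np.float64) - lo) / (hi - lo), 0.0, 1.0)
    nz, nx = gray.shape
    if letterbox:
        phys_h = nz * spacing[0]
        phys_w = nx * spacing[1]
        scale = out_size / max(phys_h, phys_w)
        out_h = max(int(round(phys_h * scale)), 1)
        out_w = max(int(round(phys_w * scale)), 1)
    else:
        out_h = out_w = out_size
    resized = ndimage.zoom(gray, (out_h / nz, out_w / nx), order=1, grid_mode=True, mode="nearest")
    resized = np.clip(resized, 0.0, 1.0)
    canvas = np.zeros((out_size, out_size), dtype=np.float32)
    r0 = (out_size - out_h) // 2
    c0 = (out_size - out_w) // 2
    canvas[r0 : r0 + out_h, c0 : c0 + out_w] = resized
    return canvas


def generate_mip_set(volume: Volume, profile: ScannerProfile) -> list[MIPImage]:
    """One windowed 64 x 64 MIP per view angle of the profile, in angle order."""
    if profile.n_views == 0:
        raise ConfigurationError("profile has no view angles")
    dz = volume.spacing[2]
    dx = volume.spacing[0]
    images = []
    for ang in profile.view_angles:
        proj = mip_project(volume, ang)
        pix = window_and_resample(proj, spacing=(dz, dx))
        images.append(
            MIPImage(pixels=pix, angle=float(ang), patient_id=volume.patient_id, scanner=profile.name)
        )
    return images


# --------------------------------------------------------------------------
# PNG + sidecar I/O
# --------------------------------------------------------------------------


def save_mip_set(images: list[MIPImage], out_dir) -> Path:
    """Write 8-bit gray PNGs with JSON sidecars and a manifest CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["file", "patient_id", "angle", "scanner"])
        for i, im in enumerate(images):
            stem = f"{im.patient_id or 'image'}_{i:03d}"
            Image.fromarray(np.round(im.pixels * 255).astype(np.uint8)).save(out / f"{stem}.png")
            with open(out / f"{stem}.json", "w") as jh:
                json.dump(
                    {"patient_id": im.patient_id, "angle": im.angle, "scanner": im.scanner, **im.meta},
                    jh,
                )
            wr.writerow([f"{stem}.png", im.patient_id, im.angle, im.scanner])
    return manifest


def load_mip_set(in_dir) -> list[MIPImage]:
    out = []
    in_dir = Path(in_dir)
    for png in sorted(in_dir.glob("*.png")):
        side = png.with_suffix(".json")
        meta = json.loads(side.read_text()) if side.exists() else {}
        pix = np.asarray(Image.open(png), dtype=np.float32) / 255.0
        out.append(
            MIPImage(
                pixels=pix,
                angle=float(meta.get("angle", 0.0)),
                patient_id=meta.get("patient_id", ""),
                scanner=meta.get("scanner", ""),
            )
        )
    return out
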