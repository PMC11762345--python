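"""Synthetic ground truth: smooth reflectance spectra, a distortable virtual
camera, calibration fixtures and test scenes.

The virtual camera inverts the ideal colorimetric path (XYZ -> linear RGB via
the inverse conversion matrix) and then injects systematic defects — channel
crosstalk, a dark offset, optional Gaussian noise, and a mismatched encoding
gamma — before quantizing to 8-bit code values.  Calibration patches are
noiseless region averages, so only the systematic defects and quantization
remain for the correction stage to absorb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import color
from .cube import HyperCube
from .observer import (
    N_BANDS,
    WAVELENGTHS,
    Illuminant,
    cmf,
    daylight_illuminant,
    equal_energy_illuminant,
    illuminant_white_xyz,
    spectrum_to_xyz,
)

__all__ = [
    "cmf",
    "spectrum_to_xyz",
    "Illuminant",
    "equal_energy_illuminant",
    "daylight_illuminant",
    "illuminant_white_xyz",
    "CameraDistortion",
    "ColorPatchSet",
    "SyntheticScene",
    "generate_reflectances",
    "simulate_camera",
    "build_calibration_fixture",
    "build_scene",
    "write_calibration_csv",
    "WAVELENGTHS",
]


@dataclass(frozen=True)
class CameraDistortion:
    """Systematic defects of the virtual camera.

    ``gamma_encode=None`` means the standard sRGB inverse EOTF (a defect-free
    encoder); a float means a pure power law ``v ** (1/gamma)``, which
    mismatches the sRGB decoding used downstream.
    """

    gamma_encode: float | None = None
    crosstalk: np.ndarray = field(default_factory=lambda: np.eye(3))
    dark_offset: float = 0.0
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        ct = np.asarray(self.crosstalk, dtype=np.float64)
        if ct.shape != (3, 3):
            raise ValueError("crosstalk must be a 3x3 matrix")
        if np.any(np.abs(ct.sum(axis=1) - 1.0) > 0.2):
            raise ValueError("crosstalk rows must sum to 1 +/- 0.2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(self, "crosstalk", ct)

    @classmethod
    def identity(cls) -> "CameraDistortion":
        return cls()

    @classmethod
    def default(cls) -> "CameraDistortion":
        """Fixture default: gamma-2.2 encode, 5% symmetric crosstalk,
        dark offset 0.02, no noise."""
        ct = np.full((3, 3), 0.05) + np.eye(3) * 0.85
        return cls(gamma_encode=2.2, crosstalk=ct, dark_offset=0.02, noise_sd=0.0)


def generate_reflectances(
    n: int,
    seed: int,
    n_lobes: tuple[int, int] = (2, 4),
    min_fwhm: float = 50.0,
    fwhm_range: tuple[float, float] = (200.0, 400.0),
    amp_range: tuple[float, float] = (5.0, 30.0),
    base_range: tuple[float, float] = (10.0, 35.0),
) -> np.ndarray:
    """Smooth synthetic reflectance spectra: a constant baseline plus a
    clipped sum of Gaussian lobes with random centers, widths and amplitudes.

    Returns an (n, 401) array in percent, values in [0, 100].  Deterministic
    per seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if min_fwhm <= 0 or fwhm_range[0] < min_fwhm or fwhm_range[1] < fwhm_range[0]:
        raise ValueError("invalid FWHM configuration")
    if n_lobes[0] < 1 or n_lobes[1] < n_lobes[0]:
        raise ValueError("invalid n_lobes range")
    rng = np.random.default_rng(seed)
    sig_factor = 2.0 * np.sqrt(2.0 * np.log(2.0))
    out = np.empty((n, N_BANDS))
    for i in range(n):
        k = int(rng.integers(n_lobes[0], n_lobes[1] + 1))
        s = np.full(N_BANDS, rng.uniform(*base_range))
        for _ in range(k):
            center = rng.uniform(380.0, 780.0)
            sigma = rng.uniform(*fwhm_range) / sig_factor
            amp = rng.uniform(*amp_range)
            s = s + amp * np.exp(-0.5 * ((WAVELENGTHS - center) / sigma) ** 2)
        out[i] = np.clip(s, 0.0, 100.0)
    return out


def simulate_camera(xyz_true, distortion: CameraDistortion | None = None) -> np.ndarray:
    """Render true XYZ (Y=100 scale) to distorted 8-bit camera sRGB values.

    Path: inverse conversion matrix -> crosstalk -> dark offset -> optional
    Gaussian noise -> clip to [0, 1] -> gamma encode -> quantize.
    """
    d = distortion or CameraDistortion.identity()
    xyz = np.asarray(xyz_true, dtype=np.float64)
    if xyz.shape[-1] != 3:
        raise ValueError("XYZ input must have 3 components on the last axis")
    minv = np.linalg.inv(color.SRGB_TO_XYZ)
    rgb = (xyz / 100.0) @ minv.T
    rgb = rgb @ d.crosstalk.T + d.dark_offset
    if d.noise_sd > 0:
        rng = np.random.default_rng(d.seed)
        rgb = rgb + rng.normal(0.0, d.noise_sd, rgb.shape)
    rgb = np.clip(rgb, 0.0, 1.0)
    if d.gamma_encode is None:
        return color.linear_to_srgb(rgb)
    enc = rgb ** (1.0 / d.gamma_encode)
    return np.round(enc * 255.0).astype(np.uint8)


@dataclass
class ColorPatchSet:
    """Calibration target: per-patch true spectra, true XYZ and camera sRGB."""

    patch_ids: list[str]
    spectra: np.ndarray  # (n, 401) percent
    xyz: np.ndarray  # (n, 3) spectrometer-derived, Y_white = 100
    srgb: np.ndarray  # (n, 3) uint8 camera code values
    wavelengths: np.ndarray = field(default_factory=lambda: WAVELENGTHS.copy())

    def __len__(self) -> int:
        return len(self.patch_ids)


def build_calibration_fixture(
    seed: int = 42,
    n_patches: int = 24,
    distortion: CameraDistortion | None = None,
    illuminant: Illuminant | None = None,
) -> ColorPatchSet:
    """Deterministic 24-patch color-target fixture under the default distorted
    camera (gamma-2.2 encode, 5% crosstalk, dark offset 0.02, no noise)."""
    d = CameraDistortion.default() if distortion is None else distortion
    spectra = generate_reflectances(n_patches, seed)
    xyz = spectrum_to_xyz(spectra, illuminant)
    srgb = simulate_camera(xyz, d)
    ids = [f"patch{str(i + 1).zfill(2)}" for i in range(n_patches)]
    return ColorPatchSet(ids, spectra, xyz, srgb)


def write_calibration_csv(patches: ColorPatchSet, path) -> None:
    """Emit the calibration CSV consumed by :func:`endospec.color.read_calibration_csv`."""
    cols = {"patch_id": patches.patch_ids}
    cols.update(
        {
            "R": patches.srgb[:, 0],
            "G": patches.srgb[:, 1],
            "B": patches.srgb[:, 2],
        }
    )
    df = pd.DataFrame(cols)
    refl = pd.DataFrame(
        patches.spectra, columns=[f"{int(w)}" for w in patches.wavelengths]
    )
    pd.concat([df, refl], axis=1).to_csv(path, index=False, float_format="%.6f")


@dataclass
class SyntheticScene:
    """RGB rendering plus ground-truth cube for end-to-end conversion tests."""

    rgb: np.ndarray  # (H, W, 3) uint8
    truth: HyperCube
    layout: np.ndarray  # (H, W) patch index per pixel


def build_scene(
    spectra,
    layout,
    distortion: CameraDistortion | None = None,
    size: tuple[int, int] = (608, 608),
    illuminant: Illuminant | None = None,
) -> SyntheticScene:
    """Build a patchwork scene: `layout` is a small 2-D grid of patch indices
    that is nearest-neighbor upsampled to `size`.

    The truth cube carries the generator spectra; the RGB image is rendered
    through the distorted camera.
    """
    spectra = np.asarray(spectra, dtype=np.float64)
    lay = np.asarray(layout)
    if lay.ndim != 2:
        raise ValueError("layout must be a 2-D grid of patch indices")
    if np.any(lay < 0) or np.any(lay >= spectra.shape[0]):
        raise ValueError(
            "layout gap: every cell must index a patch in [0, n_patches)"
        )
    h, w = size
    rows = (np.arange(h) * lay.shape[0] // h).astype(int)
    cols = (np.arange(w) * lay.shape[1] // w).astype(int)
    full = lay[np.ix_(rows, cols)]
    xyz = spectrum_to_xyz(spectra, illuminant)
    d = CameraDistortion.default() if distortion is None else distortion
    patch_rgb = simulate_camera(xyz, d)  # (n, 3)
    rgb = patch_rgb[full]
    truth = HyperCube(spectra[full].astype(np.float32))
    return SyntheticScene(rgb=rgb, truth=truth, layout=full)
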