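"""Hyperspectral cubes: per-pixel conversion of RGB images, band extraction,
narrow-band composite synthesis, detector-input renderings, and cube I/O
(ENVI hdr+raw and a single-file compressed archive).
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np

from .observer import N_BANDS, WAVELENGTHS
from .pipeline import ConversionModel

#: Default narrow-band centers (nm) and display mapping: the blue band feeds
#: the blue and green display channels, the green band feeds red.
DEFAULT_NBI_CENTERS = (415.0, 540.0)
DEFAULT_CHANNEL_MAP = {"r": 540.0, "g": 415.0, "b": 415.0}


@dataclass
class HyperCube:
    """H x W x 401 reflectance cube (percent) on the 380-780 nm grid."""

    data: np.ndarray
    wavelengths: np.ndarray = field(default_factory=lambda: WAVELENGTHS.copy())
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.data.ndim != 3 or self.data.shape[2] != N_BANDS:
            raise ValueError(f"cube must be (H, W, {N_BANDS}), got {self.data.shape}")
        if self.wavelengths.shape != (N_BANDS,) or np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be 401 strictly increasing values")
        if float(self.data.min()) < -1e-4 or float(self.data.max()) > 100.0 + 1e-3:
            raise ValueError("cube values must lie in [0, 100] percent reflectance")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def convert_image(rgb_image, model: ConversionModel) -> HyperCube:
    """Convert an 8-bit RGB image (H, W, 3) to a hypercube via the fitted model.

    Unique-color caching: each distinct RGB triplet is reconstructed once and
    broadcast, so identical pixels get bit-identical spectra.
    """
    img = np.asarray(rgb_image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB image, got shape {img.shape}")
    h, w, _ = img.shape
    flat = img.reshape(-1, 3)
    colors, inverse = np.unique(flat, axis=0, return_inverse=True)
    spectra_per_color = model.rgb_to_spectrum(colors).astype(np.float32)
    data = spectra_per_color[inverse].reshape(h, w, N_BANDS)
    src_hash = hashlib.sha1(np.ascontiguousarray(img).tobytes()).hexdigest()[:12]
    return HyperCube(
        data,
        metadata={"model_id": model.model_id, "source_hash": src_hash},
    )


def _band_index(cube: HyperCube, wavelength_nm: float) -> int:
    wl = float(wavelength_nm)
    lo, hi = cube.wavelengths[0], cube.wavelengths[-1]
    idx = int(np.argmin(np.abs(cube.wavelengths - wl)))
    if abs(cube.wavelengths[idx] - wl) > 0.5:
        raise ValueError(
            f"wavelength {wl} nm outside the grid (valid range {lo}-{hi} nm)"
        )
    return idx


def extract_band(cube: HyperCube, wavelength_nm: float) -> np.ndarray:
    """2-D slice at the nearest grid wavelength (snap tolerance 0.5 nm)."""
    return cube.data[:, :, _band_index(cube, wavelength_nm)]


def _gaussian_band_weights(cube: HyperCube, center: float, fwhm: float) -> np.ndarray:
    _band_index(cube, center)  # validates the center is on the grid
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    w = np.exp(-0.5 * ((cube.wavelengths - center) / sigma) ** 2)
    return w / w.sum()


def narrow_band_image(cube: HyperCube, center: float, fwhm: float = 30.0) -> np.ndarray:
    """Gaussian-weighted average of cube bands around a center wavelength."""
    w = _gaussian_band_weights(cube, center, fwhm)
    return cube.data @ w.astype(np.float32)


def _encode_reflectance(band: np.ndarray) -> np.ndarray:
    # fixed affine map: 0 percent -> 0, 100 percent -> 255
    return np.clip(np.round(band * (255.0 / 100.0)), 0, 255).astype(np.uint8)


def simulate_nbi(
    cube: HyperCube,
    centers=DEFAULT_NBI_CENTERS,
    fwhm: float = 30.0,
    channel_map: dict | None = None,
):
    """Synthesize a pseudo narrow-band composite from the cube.

    Each configured band is a normalized Gaussian-weighted average of cube
    bands; the channel map assigns a band center to each of the three display
    channels (default: 415 nm -> blue and green, 540 nm -> red).  Returns an
    8-bit (H, W, 3) image.
    """
    cmap = dict(DEFAULT_CHANNEL_MAP if channel_map is None else channel_map)
    if set(cmap) != {"r", "g", "b"}:
        raise ValueError("channel_map must assign exactly the keys 'r', 'g', 'b'")
    centers = [float(c) for c in centers]
    for c in set(cmap.values()):
        if c not in centers:
            raise ValueError(f"channel_map center {c} nm not among configured centers")
    bands = {c: narrow_band_image(cube, c, fwhm) for c in centers}
    img = np.stack(
        [_encode_reflectance(bands[cmap[ch]]) for ch in ("r", "g", "b")], axis=-1
    )
    return img


def render_detector_view(cube: HyperCube, mode: str, basis=None) -> np.ndarray:
    """Deterministic 3-channel rendering of a cube for detector input.

    Modes: ``bands-415-540-700`` stacks those three bands (fixed affine
    encoding); ``pc-composite`` projects each pixel spectrum onto the first
    three principal components of a fitted basis and min-max scales each
    channel over the image.
    """
    if mode == "bands-415-540-700":
        chans = [extract_band(cube, wl) for wl in (415.0, 540.0, 700.0)]
        return np.stack([_encode_reflectance(c) for c in chans], axis=-1)
    if mode == "pc-composite":
        if basis is None:
            raise ValueError("pc-composite rendering requires a fitted SpectralBasis")
        if basis.n_pc < 3:
            raise ValueError("pc-composite requires a basis with at least 3 components")
        scores = basis.project(cube.data.astype(np.float64))[:, :, :3]
        out = np.zeros(scores.shape, dtype=np.uint8)
        for j in range(3):
            ch = scores[:, :, j]
            lo, hi = float(ch.min()), float(ch.max())
            if hi > lo:
                out[:, :, j] = np.round((ch - lo) / (hi - lo) * 255.0).astype(np.uint8)
        return out
    raise ValueError(f"unknown render mode {mode!r}")


# ---------------------------------------------------------------------------
# Cube I/O
# ---------------------------------------------------------------------------

_ENVI_DTYPES = {4: np.float32}


def write_cube(cube: HyperCube, path, fmt: str = "npz") -> None:
    """Write a cube either as an ENVI pair (``path`` raw + ``path.hdr``) or as
    a single-file compressed archive with arrays ``data``, ``wavelengths``
    and a JSON ``meta`` string."""
    path = os.fspath(path)
    if fmt == "npz":
        np.savez_compressed(
            path,
            data=cube.data,
            wavelengths=cube.wavelengths,
            meta=json.dumps(cube.metadata, sort_keys=True),
        )
    elif fmt == "envi":
        h, w, b = cube.data.shape
        wl_list = ", ".join(f"{v:.1f}" for v in cube.wavelengths)
        header = (
            "ENVI\n"
            f"samples = {w}\n"
            f"lines = {h}\n"
            f"bands = {b}\n"
            "header offset = 0\n"
            "file type = ENVI Standard\n"
            "data type = 4\n"
            "interleave = bsq\n"
            "byte order = 0\n"
            "wavelength units = nm\n"
            f"wavelength = {{ {wl_list} }}\n"
        )
        with open(path + ".hdr", "w") as fh:
            fh.write(header)
        # BSQ: band-sequential, little-endian float32
        bsq = np.ascontiguousarray(np.moveaxis(cube.data, 2, 0)).astype("<f4")
        bsq.tofile(path)
    else:
        raise ValueError(f"unknown cube format {fmt!r}; use 'npz' or 'envi'")


def _parse_envi_header(path: str) -> dict:
    with open(path) as fh:
        text = fh.read()
    if not text.lstrip().startswith("ENVI"):
        raise ValueError(f"malformed ENVI header {path}: missing 'ENVI' magic")
    fields: dict[str, str] = {}
    buf = text.split("\n", 1)[1] if "\n" in text else ""
    # join brace-delimited multi-line values
    import re

    for m in re.finditer(r"(?ms)^\s*([^=\n]+?)\s*=\s*(\{.*?\}|[^\n]*)$", buf):
        fields[m.group(1).strip().lower()] = m.group(2).strip()
    for required in ("samples", "lines", "bands", "data type", "interleave"):
        if required not in fields:
            raise ValueError(f"malformed ENVI header: missing field '{required}'")
    return fields


def read_cube(path, fmt: str = "npz") -> HyperCube:
    """Read a cube written by :func:`write_cube`; bit-exact round trip."""
    path = os.fspath(path)
    if fmt == "npz":
        p = path if path.endswith(".npz") else path + ".npz"
        with np.load(p, allow_pickle=False) as z:
            return HyperCube(
                z["data"], z["wavelengths"], json.loads(str(z["meta"]))
            )
    if fmt == "envi":
        fields = _parse_envi_header(path + ".hdr")
        dtype_code = int(fields["data type"])
        if dtype_code not in _ENVI_DTYPES:
            raise ValueError(f"malformed ENVI header: unsupported data type {dtype_code}")
        if fields["interleave"].lower() != "bsq":
            raise ValueError(
                f"malformed ENVI header: unsupported interleave '{fields['interleave']}'"
            )
        h, w, b = int(fields["lines"]), int(fields["samples"]), int(fields["bands"])
        expected = h * w * b * 4
        actual = os.path.getsize(path)
        if actual != expected:
            raise ValueError(
                f"truncated or oversized ENVI binary: expected {expected} bytes, "
                f"found {actual}"
            )
        raw = np.fromfile(path, dtype="<f4").reshape(b, h, w)
        wl = WAVELENGTHS
        if "wavelength" in fields:
            inner = fields["wavelength"].strip("{} \n")
            wl = np.array([float(v) for v in inner.split(",")])
        return HyperCube(np.moveaxis(raw, 0, 2), wl)
    raise ValueError(f"unknown cube format {fmt!r}; use 'npz' or 'envi'")
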