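"""Colorimetric front end: sRGB decoding, XYZ conversion, polynomial camera
correction, CIELAB conversion and the CIEDE2000 color difference.

All XYZ values in this package live on a scale where the reference white has
Y = 100.  Camera-side XYZ is obtained by decoding 8-bit sRGB code values with
the standard piecewise electro-optical transfer function and applying a 3x3
RGB->XYZ matrix; spectrometer-side XYZ comes from tristimulus integration
(see :mod:`endospec.observer`).  The correction model maps a polynomial
expansion of camera XYZ onto the spectrometer XYZ via a pseudoinverse
least-squares fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Standard sRGB (D65) linear-RGB -> XYZ matrix (IEC 61966-2-1 primaries).
SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)

#: D65 white point on the Y=100 scale (row sums of SRGB_TO_XYZ, times 100).
D65_WHITE = 100.0 * SRGB_TO_XYZ.sum(axis=1)

# Ordered exponent triples (a, b, c) for the monomial X^a * Y^b * Z^c.
# The constant term is always first; ordering is fixed for reproducibility.
_AFFINE = ((0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1))
_POLY2 = _AFFINE + ((1, 1, 0), (1, 0, 1), (0, 1, 1), (2, 0, 0), (0, 2, 0), (0, 0, 2))
_POLY3 = _POLY2 + (
    (1, 1, 1),
    (2, 1, 0),
    (2, 0, 1),
    (1, 2, 0),
    (0, 2, 1),
    (1, 0, 2),
    (0, 1, 2),
    (3, 0, 0),
    (0, 3, 0),
    (0, 0, 3),
)

TERM_PRESETS: dict[str, tuple[tuple[int, int, int], ...]] = {
    "affine": _AFFINE,
    "poly2": _POLY2,
    "poly3": _POLY3,
}


def resolve_term_spec(term_spec) -> tuple[tuple[int, int, int], ...]:
    """Resolve a preset name or explicit exponent list to a tuple of triples."""
    if isinstance(term_spec, str):
        try:
            return TERM_PRESETS[term_spec]
        except KeyError:
            raise ValueError(
                f"unknown term preset {term_spec!r}; choose from {sorted(TERM_PRESETS)}"
            ) from None
    terms = tuple(tuple(int(e) for e in t) for t in term_spec)
    if len(terms) == 0:
        raise ValueError("term_spec must contain at least one term")
    if any(len(t) != 3 for t in terms):
        raise ValueError("each term must be an (a, b, c) exponent triple")
    if terms[0] != (0, 0, 0):
        raise ValueError("first term must be the constant (0, 0, 0)")
    return terms


def srgb_to_linear(rgb) -> np.ndarray:
    """Decode 8-bit sRGB code values to linear-light fractions in [0, 1].

    Uses the standard piecewise sRGB EOTF: the linear segment below 0.04045,
    otherwise ``((v + 0.055) / 1.055) ** 2.4``.
    """
    arr = np.asarray(rgb, dtype=np.float64)
    if np.any(arr < 0) or np.any(arr > 255):
        raise ValueError("sRGB code values must lie in [0, 255]")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("sRGB code values must be integers (8-bit convention)")
    v = arr / 255.0
    return np.where(v <= 0.04045, v / 12.92, ((v + 0.055) / 1.055) ** 2.4)


def linear_to_srgb(linear) -> np.ndarray:
    """Encode linear-light fractions to 8-bit sRGB code values (inverse EOTF)."""
    v = np.clip(np.asarray(linear, dtype=np.float64), 0.0, 1.0)
    enc = np.where(v <= 0.0031308, 12.92 * v, 1.055 * v ** (1.0 / 2.4) - 0.055)
    return np.round(enc * 255.0).astype(np.uint8)


def linear_to_xyz(rgb, matrix: np.ndarray | None = None) -> np.ndarray:
    """Convert linear RGB (..., 3) to XYZ on the Y=100 scale via a 3x3 matrix."""
    m = SRGB_TO_XYZ if matrix is None else np.asarray(matrix, dtype=np.float64)
    if m.shape != (3, 3):
        raise ValueError(f"conversion matrix must be 3x3, got {m.shape}")
    if abs(np.linalg.det(m)) < 1e-12:
        raise ValueError("conversion matrix is singular")
    arr = np.asarray(rgb, dtype=np.float64)
    if arr.shape[-1] != 3:
        raise ValueError("linear RGB input must have 3 channels on the last axis")
    return 100.0 * arr @ m.T


def expand_features(xyz, term_spec) -> np.ndarray:
    """Evaluate the ordered polynomial monomials of (X, Y, Z).

    Returns shape ``(..., n_terms)``; the constant term is first.
    """
    terms = resolve_term_spec(term_spec)
    arr = np.asarray(xyz, dtype=np.float64)
    if arr.shape[-1] != 3:
        raise ValueError("XYZ input must have 3 components on the last axis")
    x, y, z = arr[..., 0], arr[..., 1], arr[..., 2]
    cols = [x**a * y**b * z**c for (a, b, c) in terms]
    return np.stack(cols, axis=-1)


@dataclass
class CameraCorrectionModel:
    """Polynomial XYZ error-correction model.

    ``C`` (3 x n_terms) solves ``reference ~= C @ V`` in the least-squares
    sense, where V stacks the expanded camera-XYZ feature columns.
    """

    C: np.ndarray
    term_spec: tuple[tuple[int, int, int], ...]
    rgb_to_xyz: np.ndarray = field(default_factory=lambda: SRGB_TO_XYZ.copy())
    white_point: np.ndarray = field(default_factory=lambda: D65_WHITE.copy())
    brightness_ratio: float = 1.0

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=np.float64)
        self.term_spec = resolve_term_spec(self.term_spec)
        self.rgb_to_xyz = np.asarray(self.rgb_to_xyz, dtype=np.float64)
        self.white_point = np.asarray(self.white_point, dtype=np.float64)
        if self.C.shape != (3, len(self.term_spec)):
            raise ValueError(
                f"C must be 3 x {len(self.term_spec)} for this term_spec, got {self.C.shape}"
            )

    def to_dict(self) -> dict:
        return {
            "C": self.C.tolist(),
            "term_spec": [list(t) for t in self.term_spec],
            "rgb_to_xyz": self.rgb_to_xyz.tolist(),
            "white_point": self.white_point.tolist(),
            "brightness_ratio": float(self.brightness_ratio),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraCorrectionModel":
        return cls(
            C=np.array(d["C"]),
            term_spec=tuple(tuple(t) for t in d["term_spec"]),
            rgb_to_xyz=np.array(d["rgb_to_xyz"]),
            white_point=np.array(d["white_point"]),
            brightness_ratio=float(d["brightness_ratio"]),
        )


def fit_correction(
    camera_xyz,
    reference_xyz,
    term_spec="poly3",
    *,
    rgb_to_xyz: np.ndarray | None = None,
    white_point: np.ndarray | None = None,
    brightness_ratio: float = 1.0,
) -> CameraCorrectionModel:
    """Fit the correction matrix C via Moore-Penrose pseudoinverse.

    Solves ``C = reference.T @ pinv(V.T)`` where V holds one expanded feature
    row per calibration patch.  Requires at least as many patches as terms and
    a full-rank feature matrix; rank deficiency raises rather than silently
    regularizing.
    """
    cam = np.asarray(camera_xyz, dtype=np.float64)
    ref = np.asarray(reference_xyz, dtype=np.float64)
    if cam.shape != ref.shape or cam.ndim != 2 or cam.shape[1] != 3:
        raise ValueError(
            f"camera and reference XYZ must be aligned (n, 3) arrays, "
            f"got {cam.shape} and {ref.shape}"
        )
    terms = resolve_term_spec(term_spec)
    n, t = cam.shape[0], len(terms)
    if n < t:
        raise ValueError(
            f"rank-deficient fit: {n} patches for {t} polynomial terms; "
            f"need at least as many patches as terms"
        )
    V = expand_features(cam, terms)  # (n, t)
    if np.linalg.matrix_rank(V) < t:
        raise ValueError(
            f"rank-deficient feature matrix: rank {np.linalg.matrix_rank(V)} < {t} terms"
        )
    C = ref.T @ np.linalg.pinv(V.T)
    return CameraCorrectionModel(
        C=C,
        term_spec=terms,
        rgb_to_xyz=SRGB_TO_XYZ if rgb_to_xyz is None else rgb_to_xyz,
        white_point=D65_WHITE if white_point is None else np.asarray(white_point, float),
        brightness_ratio=brightness_ratio,
    )


def apply_correction(model: CameraCorrectionModel, xyz) -> np.ndarray:
    """Apply the fitted correction: ``XYZ_corrected = C @ V(xyz)``.

    Negative components are clamped to zero (physical nonnegativity) with a
    logged warning.
    """
    if not isinstance(model, CameraCorrectionModel):
        raise TypeError("model must be a fitted CameraCorrectionModel")
    V = expand_features(xyz, model.term_spec)
    out = V @ model.C.T
    if np.any(out < 0):
        logger.warning(
            "apply_correction: clamping %d negative XYZ component(s) to 0",
            int(np.sum(out < 0)),
        )
        out = np.clip(out, 0.0, None)
    return out


def xyz_to_lab(xyz, white) -> np.ndarray:
    """Convert XYZ to CIELAB using the piecewise helper

        f(n) = n^(1/3)            if n > 0.008856
             = 7.787 n + 0.137931 otherwise

    The reference white maps to (100, 0, 0).
    """
    w = np.asarray(white, dtype=np.float64)
    if w.shape[-1] != 3 or np.any(w <= 0):
        raise ValueError("white point must have three strictly positive components")
    arr = np.asarray(xyz, dtype=np.float64)
    if arr.shape[-1] != 3:
        raise ValueError("XYZ input must have 3 components on the last axis")
    n = arr / w

    def f(v):
        v = np.asarray(v, dtype=np.float64)
        return np.where(v > 0.008856, np.cbrt(v), 7.787 * v + 0.137931)

    fx, fy, fz = f(n[..., 0]), f(n[..., 1]), f(n[..., 2])
    L = 116.0 * fy - 16.0
    a = 500.0 * (fx - fy)
    b = 200.0 * (fy - fz)
    return np.stack([L, a, b], axis=-1)


def ciede2000(lab1, lab2) -> np.ndarray | float:
    """CIEDE2000 color difference with kL = kC = kH = 1.

    Vectorized over leading dimensions; symmetric; zero iff inputs identical.
    """
    a = np.asarray(lab1, dtype=np.float64)
    b = np.asarray(lab2, dtype=np.float64)
    if a.shape[-1] != 3 or b.shape[-1] != 3:
        raise ValueError("Lab inputs must have 3 components on the last axis")
    L1, a1, b1 = a[..., 0], a[..., 1], a[..., 2]
    L2, a2, b2 = b[..., 0], b[..., 1], b[..., 2]

    C1 = np.hypot(a1, b1)
    C2 = np.hypot(a2, b2)
    Cbar = 0.5 * (C1 + C2)
    G = 0.5 * (1.0 - np.sqrt(Cbar**7 / (Cbar**7 + 25.0**7)))
    a1p = (1.0 + G) * a1
    a2p = (1.0 + G) * a2
    C1p = np.hypot(a1p, b1)
    C2p = np.hypot(a2p, b2)

    h1p = np.degrees(np.arctan2(b1, a1p)) % 360.0
    h2p = np.degrees(np.arctan2(b2, a2p)) % 360.0
    h1p = np.where((np.abs(a1p) < 1e-300) & (np.abs(b1) < 1e-300), 0.0, h1p)
    h2p = np.where((np.abs(a2p) < 1e-300) & (np.abs(b2) < 1e-300), 0.0, h2p)

    dLp = L2 - L1
    dCp = C2p - C1p
    dh = h2p - h1p
    dh = np.where(dh > 180.0, dh - 360.0, dh)
    dh = np.where(dh < -180.0, dh + 360.0, dh)
    dh = np.where(C1p * C2p == 0.0, 0.0, dh)
    dHp = 2.0 * np.sqrt(C1p * C2p) * np.sin(np.radians(dh) / 2.0)

    Lbp = 0.5 * (L1 + L2)
    Cbp = 0.5 * (C1p + C2p)
    hsum = h1p + h2p
    hdiff = np.abs(h1p - h2p)
    hbp = np.where(
        C1p * C2p == 0.0,
        hsum,
        np.where(
            hdiff <= 180.0,
            0.5 * hsum,
            np.where(hsum < 360.0, 0.5 * (hsum + 360.0), 0.5 * (hsum - 360.0)),
        ),
    )

    T = (
        1.0
        - 0.17 * np.cos(np.radians(hbp - 30.0))
        + 0.24 * np.cos(np.radians(2.0 * hbp))
        + 0.32 * np.cos(np.radians(3.0 * hbp + 6.0))
        - 0.20 * np.cos(np.radians(4.0 * hbp - 63.0))
    )
    dtheta = 30.0 * np.exp(-(((hbp - 275.0) / 25.0) ** 2))
    RC = 2.0 * np.sqrt(Cbp**7 / (Cbp**7 + 25.0**7))
    SL = 1.0 + 0.015 * (Lbp - 50.0) ** 2 / np.sqrt(20.0 + (Lbp - 50.0) ** 2)
    SC = 1.0 + 0.045 * Cbp
    SH = 1.0 + 0.015 * Cbp * T
    RT = -np.sin(np.radians(2.0 * dtheta)) * RC

    dE = np.sqrt(
        (dLp / SL) ** 2
        + (dCp / SC) ** 2
        + (dHp / SH) ** 2
        + RT * (dCp / SC) * (dHp / SH)
    )
    return float(dE) if dE.ndim == 0 else dE


def xyz_rmse(set_a, set_b) -> tuple[np.ndarray, float]:
    """Per-patch RMSE over the three XYZ components, plus the mean over patches."""
    a = np.asarray(set_a, dtype=np.float64)
    b = np.asarray(set_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"aligned (n, 3) XYZ arrays required, got {a.shape}, {b.shape}")
    per = np.sqrt(np.mean((a - b) ** 2, axis=1))
    return per, float(per.mean())


def read_calibration_csv(path) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Read a calibration table: patch_id, R, G, B, then reflectance at
    380..780 nm in 1 nm steps (401 columns).  Header row mandatory.

    Returns (patch ids, sRGB uint8 array (n, 3), reflectance array (n, 401)).
    """
    df = pd.read_csv(path)
    required = ["patch_id", "R", "G", "B"]
    if list(df.columns[:4]) != required:
        raise ValueError(
            f"calibration CSV must start with columns {required}, got {list(df.columns[:4])}"
        )
    if df.shape[1] != 4 + 401:
        raise ValueError(
            f"calibration CSV must have 401 reflectance columns (380..780 nm), "
            f"got {df.shape[1] - 4}"
        )
    srgb = df[["R", "G", "B"]].to_numpy()
    if np.any(srgb < 0) or np.any(srgb > 255):
        raise ValueError("RGB columns must lie in [0, 255]")
    spectra = df.iloc[:, 4:].to_numpy(dtype=np.float64)
    return df["patch_id"].astype(str).tolist(), srgb.astype(np.uint8), spectra
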