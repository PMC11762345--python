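"""PCA spectral basis and XYZ-feature regression for spectrum reconstruction.

The reconstruction chain is: corrected XYZ -> polynomial feature vector ->
principal-component scores (via the regression matrix) -> spectrum (via the
PCA loadings plus mean).  The product ``loadings @ M_reg`` is the combined
transform applied to the expanded feature column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import color, observer
from .observer import N_BANDS, WAVELENGTHS

logger = logging.getLogger(__name__)


@dataclass
class SpectralBasis:
    """Mean spectrum plus orthonormal PCA loadings.

    ``loadings`` has shape (401, n_pc); ``explained_variance_ratio`` covers
    the retained components only (nonincreasing, each in [0, 1]).
    """

    mean_spectrum: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray

    def __post_init__(self):
        self.mean_spectrum = np.asarray(self.mean_spectrum, dtype=np.float64)
        self.loadings = np.asarray(self.loadings, dtype=np.float64)
        self.explained_variance_ratio = np.asarray(
            self.explained_variance_ratio, dtype=np.float64
        )
        if self.mean_spectrum.shape != (N_BANDS,):
            raise ValueError(f"mean spectrum must have {N_BANDS} bands")
        if self.loadings.ndim != 2 or self.loadings.shape[0] != N_BANDS:
            raise ValueError(f"loadings must be ({N_BANDS}, n_pc)")
        if self.explained_variance_ratio.shape != (self.loadings.shape[1],):
            raise ValueError("explained_variance_ratio length must match n_pc")

    @property
    def n_pc(self) -> int:
        return self.loadings.shape[1]

    def project(self, spectra) -> np.ndarray:
        """Principal-component scores of spectra, shape (..., n_pc)."""
        arr = np.asarray(spectra, dtype=np.float64)
        return (arr - self.mean_spectrum) @ self.loadings

    def reconstruct(self, scores) -> np.ndarray:
        """Inverse of :meth:`project` (up to truncation)."""
        s = np.asarray(scores, dtype=np.float64)
        return self.mean_spectrum + s @ self.loadings.T

    def to_dict(self) -> dict:
        return {
            "mean_spectrum": self.mean_spectrum.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpectralBasis":
        return cls(
            np.array(d["mean_spectrum"]),
            np.array(d["loadings"]),
            np.array(d["explained_variance_ratio"]),
        )


@dataclass
class SpectralRegression:
    """Regression matrix mapping expanded corrected-XYZ features to PC scores."""

    M_reg: np.ndarray
    term_spec: tuple[tuple[int, int, int], ...]

    def __post_init__(self):
        self.M_reg = np.asarray(self.M_reg, dtype=np.float64)
        self.term_spec = color.resolve_term_spec(self.term_spec)
        if self.M_reg.ndim != 2 or self.M_reg.shape[1] != len(self.term_spec):
            raise ValueError(
                f"M_reg must be (n_pc, {len(self.term_spec)}), got {self.M_reg.shape}"
            )

    def to_dict(self) -> dict:
        return {
            "M_reg": self.M_reg.tolist(),
            "term_spec": [list(t) for t in self.term_spec],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpectralRegression":
        return cls(np.array(d["M_reg"]), tuple(tuple(t) for t in d["term_spec"]))


def fit_pca(spectra, n_pc: int = 6) -> SpectralBasis:
    """Mean-centered PCA of reflectance spectra via SVD.

    Signs are fixed so each loading's largest-magnitude element is positive,
    making serialization reproducible.  Requires at least ``n_pc + 1`` spectra.
    """
    arr = np.asarray(spectra, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != N_BANDS:
        raise ValueError(f"spectra must be (n, {N_BANDS})")
    n = arr.shape[0]
    if n_pc < 1 or n_pc > n - 1:
        raise ValueError(
            f"n_pc must be in [1, n_samples-1]; got n_pc={n_pc} with {n} spectra"
        )
    mean = arr.mean(axis=0)
    centered = arr - mean
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    var = s**2
    total = var.sum()
    evr_all = var / total if total > 0 else np.zeros_like(var)
    loadings = vt[:n_pc].T  # (401, n_pc)
    # deterministic sign: largest-magnitude loading element positive
    for j in range(n_pc):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    return SpectralBasis(mean, loadings, evr_all[:n_pc])


def fit_spectral_regression(
    xyz_correct, basis: SpectralBasis, spectra, term_spec="poly3"
) -> SpectralRegression:
    """Least-squares fit of PC scores on expanded corrected-XYZ features."""
    xyz = np.asarray(xyz_correct, dtype=np.float64)
    arr = np.asarray(spectra, dtype=np.float64)
    if xyz.ndim != 2 or xyz.shape[1] != 3:
        raise ValueError("xyz_correct must be (n, 3)")
    if arr.shape != (xyz.shape[0], N_BANDS):
        raise ValueError("spectra must align with xyz_correct on the standard grid")
    terms = color.resolve_term_spec(term_spec)
    n, t = xyz.shape[0], len(terms)
    if n < t:
        raise ValueError(f"rank-deficient fit: {n} samples for {t} terms")
    V = color.expand_features(xyz, terms)  # (n, t)
    if np.linalg.matrix_rank(V) < t:
        raise ValueError(
            f"rank-deficient feature matrix: rank {np.linalg.matrix_rank(V)} < {t}"
        )
    scores = basis.project(arr)  # (n, n_pc)
    M_reg = scores.T @ np.linalg.pinv(V.T)
    return SpectralRegression(M_reg, terms)


def reconstruct_spectrum(
    xyz_correct, basis: SpectralBasis, reg: SpectralRegression
) -> np.ndarray:
    """Reconstruct spectra from corrected XYZ: mean + loadings @ M_reg @ V.

    Output is clamped to [0, 100] percent reflectance (with a logged warning
    when clamping occurs).  Vectorized over leading dimensions.
    """
    if basis.n_pc != reg.M_reg.shape[0]:
        raise ValueError(
            f"basis has {basis.n_pc} components but regression expects "
            f"{reg.M_reg.shape[0]}"
        )
    V = color.expand_features(xyz_correct, reg.term_spec)
    scores = V @ reg.M_reg.T
    out = basis.reconstruct(scores)
    n_out = int(np.sum((out < 0) | (out > 100)))
    if n_out:
        logger.warning(
            "reconstruct_spectrum: clamping %d value(s) outside [0, 100]", n_out
        )
        out = np.clip(out, 0.0, 100.0)
    return out


def spectral_rmse(analog, measured) -> tuple[np.ndarray, float]:
    """Per-patch RMSE over the 401 bands (percent units), plus the mean."""
    a = np.asarray(analog, dtype=np.float64)
    b = np.asarray(measured, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != N_BANDS:
        raise ValueError(
            f"aligned (n, {N_BANDS}) spectra required, got {a.shape}, {b.shape}"
        )
    per = np.sqrt(np.mean((a - b) ** 2, axis=1))
    return per, float(per.mean())


def validate_color_fidelity(analog, measured, illuminant=None) -> dict:
    """Per-patch CIEDE2000 between Lab coordinates derived from reconstructed
    and measured spectra (both integrated under the same illuminant).

    Returns ``{"delta_e": per-patch array, "mean_delta_e": float}``.
    """
    a = np.asarray(analog, dtype=np.float64)
    b = np.asarray(measured, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != N_BANDS:
        raise ValueError("aligned spectra on the standard grid required")
    white = observer.illuminant_white_xyz(illuminant)
    lab_a = color.xyz_to_lab(observer.spectrum_to_xyz(a, illuminant), white)
    lab_b = color.xyz_to_lab(observer.spectrum_to_xyz(b, illuminant), white)
    de = np.atleast_1d(color.ciede2000(lab_a, lab_b))
    return {"delta_e": de, "mean_delta_e": float(de.mean())}


__all__ = [
    "SpectralBasis",
    "SpectralRegression",
    "fit_pca",
    "fit_spectral_regression",
    "reconstruct_spectrum",
    "spectral_rmse",
    "validate_color_fidelity",
    "WAVELENGTHS",
]
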