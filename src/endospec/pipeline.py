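"""End-to-end conversion model: sRGB -> linear RGB -> camera XYZ -> corrected
XYZ -> reconstructed 401-band spectrum, bundled into one serializable object.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from . import color, observer, spectra

FORMAT_TAG = "endospec-model/1"


@dataclass
class ConversionModel:
    """Fitted calibration bundle: camera correction + spectral basis +
    feature regression, serialized as a single JSON document."""

    correction: color.CameraCorrectionModel
    basis: spectra.SpectralBasis
    regression: spectra.SpectralRegression
    illuminant_name: str = "equal-energy"
    metadata: dict = field(default_factory=dict)

    def camera_xyz(self, srgb) -> np.ndarray:
        """Uncorrected camera XYZ from 8-bit sRGB code values."""
        lin = color.srgb_to_linear(srgb)
        return color.linear_to_xyz(lin, self.correction.rgb_to_xyz)

    def corrected_xyz(self, srgb) -> np.ndarray:
        return color.apply_correction(self.correction, self.camera_xyz(srgb))

    def rgb_to_spectrum(self, srgb) -> np.ndarray:
        """Full chain: (..., 3) sRGB -> (..., 401) reflectance percent."""
        return spectra.reconstruct_spectrum(
            self.corrected_xyz(srgb), self.basis, self.regression
        )

    def to_json(self) -> str:
        doc = {
            "format": FORMAT_TAG,
            "correction": self.correction.to_dict(),
            "basis": self.basis.to_dict(),
            "regression": self.regression.to_dict(),
            "illuminant_name": self.illuminant_name,
            "metadata": self.metadata,
        }
        return json.dumps(doc, sort_keys=True)

    @property
    def model_id(self) -> str:
        """Content hash of the serialized model (provenance identifier)."""
        return hashlib.sha1(self.to_json().encode()).hexdigest()[:12]

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "ConversionModel":
        doc = json.loads(text)
        if doc.get("format") != FORMAT_TAG:
            raise ValueError(
                f"not a conversion-model document (format={doc.get('format')!r})"
            )
        return cls(
            correction=color.CameraCorrectionModel.from_dict(doc["correction"]),
            basis=spectra.SpectralBasis.from_dict(doc["basis"]),
            regression=spectra.SpectralRegression.from_dict(doc["regression"]),
            illuminant_name=doc.get("illuminant_name", "equal-energy"),
            metadata=doc.get("metadata", {}),
        )

    @classmethod
    def load(cls, path) -> "ConversionModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def calibrate(
    srgb,
    reflectance_spectra,
    term_spec="poly3",
    n_pc: int = 6,
    illuminant=None,
    rgb_to_xyz: np.ndarray | None = None,
    metadata: dict | None = None,
) -> tuple[ConversionModel, dict]:
    """Fit the full conversion model from a color-target calibration set.

    Parameters
    ----------
    srgb : (n, 3) 8-bit camera code values, one row per patch.
    reflectance_spectra : (n, 401) spectrometer reflectance in percent.

    Returns the fitted :class:`ConversionModel` and a quality report with
    per-patch and mean corrected-XYZ RMSE, spectral RMSE, cumulative explained
    variance and mean CIEDE2000.
    """
    srgb = np.asarray(srgb)
    refl = np.asarray(reflectance_spectra, dtype=np.float64)
    if srgb.ndim != 2 or srgb.shape[1] != 3 or refl.shape[0] != srgb.shape[0]:
        raise ValueError("srgb (n, 3) and spectra (n, 401) must be aligned")

    ill = illuminant
    ill_name = getattr(ill, "name", "equal-energy") if ill is not None else "equal-energy"
    xyz_ref = observer.spectrum_to_xyz(refl, ill)
    white = observer.illuminant_white_xyz(ill)
    power = observer._as_power(ill)
    k = 100.0 / float(np.sum(power * observer.CMF_TABLE[:, 1]))

    lin = color.srgb_to_linear(srgb)
    xyz_cam = color.linear_to_xyz(lin, rgb_to_xyz)
    correction = color.fit_correction(
        xyz_cam,
        xyz_ref,
        term_spec,
        rgb_to_xyz=rgb_to_xyz,
        white_point=white,
        brightness_ratio=k,
    )
    xyz_corr = color.apply_correction(correction, xyz_cam)

    basis = spectra.fit_pca(refl, n_pc=n_pc)
    regression = spectra.fit_spectral_regression(xyz_corr, basis, refl, term_spec)
    model = ConversionModel(
        correction=correction,
        basis=basis,
        regression=regression,
        illuminant_name=ill_name,
        metadata=metadata or {},
    )

    analog = spectra.reconstruct_spectrum(xyz_corr, basis, regression)
    xyz_per, xyz_mean = color.xyz_rmse(xyz_corr, xyz_ref)
    xyz_per_unc, xyz_mean_unc = color.xyz_rmse(xyz_cam, xyz_ref)
    sp_per, sp_mean = spectra.spectral_rmse(analog, refl)
    fidelity = spectra.validate_color_fidelity(analog, refl, ill)
    report = {
        "n_patches": int(srgb.shape[0]),
        "xyz_rmse_per_patch": xyz_per,
        "xyz_rmse_mean": xyz_mean,
        "uncorrected_xyz_rmse_mean": xyz_mean_unc,
        "uncorrected_xyz_rmse_per_patch": xyz_per_unc,
        "spectral_rmse_per_patch": sp_per,
        "spectral_rmse_mean": sp_mean,
        "explained_variance_ratio": basis.explained_variance_ratio,
        "cumulative_explained_variance": float(basis.explained_variance_ratio.sum()),
        "delta_e_per_patch": fidelity["delta_e"],
        "delta_e_mean": fidelity["mean_delta_e"],
    }
    return model, report
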