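"""Analytic CIE 1931 2-degree observer, illuminants, and tristimulus
integration on the package's fixed 380-780 nm / 1 nm wavelength grid.

The color-matching functions use the multi-lobe Gaussian fit of Wyman, Sloan
& Shirley (2013), which stays within a few percent of the tabulated observer
over the visible range and needs no bundled data table.  Tiny negative values
of the x-bar fit are clamped to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: The fixed spectral grid: 401 bands, 380-780 nm, 1 nm step.
WAVELENGTHS = np.arange(380.0, 781.0, 1.0)
N_BANDS = WAVELENGTHS.size


def _lobe(x, mu, sigma_lo, sigma_hi):
    s = np.where(x < mu, sigma_lo, sigma_hi)
    return np.exp(-0.5 * ((x - mu) / s) ** 2)


def cmf(wavelength_nm) -> np.ndarray:
    """Color-matching functions (x̄, ȳ, z̄) at the given wavelength(s) in nm.

    Accepts a scalar or array; returns shape ``(..., 3)``.  Wavelengths must
    lie within [380, 780].
    """
    wl = np.asarray(wavelength_nm, dtype=np.float64)
    if np.any(wl < 380.0) or np.any(wl > 780.0):
        raise ValueError("wavelength out of range: valid range is [380, 780] nm")
    x = (
        1.056 * _lobe(wl, 599.8, 37.9, 31.0)
        + 0.362 * _lobe(wl, 442.0, 16.0, 26.7)
        - 0.065 * _lobe(wl, 501.1, 20.4, 26.2)
    )
    y = 0.821 * _lobe(wl, 568.8, 46.9, 40.5) + 0.286 * _lobe(wl, 530.9, 16.3, 31.1)
    z = 1.217 * _lobe(wl, 437.0, 11.8, 36.0) + 0.681 * _lobe(wl, 459.0, 26.0, 13.8)
    return np.clip(np.stack([x, y, z], axis=-1), 0.0, None)


#: CMFs pre-evaluated on the standard grid, shape (401, 3).
CMF_TABLE = cmf(WAVELENGTHS)


@dataclass(frozen=True)
class Illuminant:
    """Spectral power distribution on the standard grid."""

    power: np.ndarray
    name: str = "custom"

    def __post_init__(self):
        p = np.asarray(self.power, dtype=np.float64)
        if p.shape != (N_BANDS,):
            raise ValueError(f"illuminant power must have shape ({N_BANDS},)")
        if np.any(p < 0) or not np.any(p > 0):
            raise ValueError("illuminant power must be nonnegative and not all zero")
        object.__setattr__(self, "power", p)


def equal_energy_illuminant() -> Illuminant:
    """Flat (equal-energy) illuminant — the package default."""
    return Illuminant(np.ones(N_BANDS), name="equal-energy")


def daylight_illuminant(temperature_k: float = 6504.0) -> Illuminant:
    """D65-like analytic approximation: a Planckian radiator at ~6504 K,
    normalized to unit mean power."""
    h, c, kb = 6.62607015e-34, 2.99792458e8, 1.380649e-23
    lam = WAVELENGTHS * 1e-9
    p = (2 * h * c**2 / lam**5) / (np.exp(h * c / (lam * kb * temperature_k)) - 1.0)
    return Illuminant(p / p.mean(), name=f"planckian-{temperature_k:.0f}K")


def _as_power(illuminant) -> np.ndarray:
    if illuminant is None:
        return np.ones(N_BANDS)
    if isinstance(illuminant, Illuminant):
        return illuminant.power
    p = np.asarray(illuminant, dtype=np.float64)
    if p.shape != (N_BANDS,):
        raise ValueError(f"illuminant must be on the {N_BANDS}-point grid")
    return p


def spectrum_to_xyz(reflectance_percent, illuminant=None) -> np.ndarray:
    """Ideal tristimulus integration of reflectance (percent, 0-100) under an
    illuminant, normalized so the perfect reflector has Y = 100.

    Vectorized: accepts shape ``(..., 401)`` and returns ``(..., 3)``.
    """
    refl = np.asarray(reflectance_percent, dtype=np.float64)
    if refl.shape[-1] != N_BANDS:
        raise ValueError(
            f"reflectance must be on the {N_BANDS}-point 380-780 nm grid, "
            f"got last-axis length {refl.shape[-1]}"
        )
    power = _as_power(illuminant)
    k = 100.0 / float(np.sum(power * CMF_TABLE[:, 1]))
    weighted = (refl / 100.0) * power  # (..., 401)
    return k * weighted @ CMF_TABLE


def illuminant_white_xyz(illuminant=None) -> np.ndarray:
    """XYZ of the perfect reflector under the illuminant (Y = 100 exactly)."""
    return spectrum_to_xyz(np.full(N_BANDS, 100.0), illuminant)
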