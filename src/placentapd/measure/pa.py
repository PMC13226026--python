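"""Dual-wavelength photoacoustic oximetry: forward model and linear spectral unmixing.

Forward model for the ROI-mean photoacoustic amplitude at wavelength lambda:

    p_lambda = Phi_lambda * (eps_HbO2,lambda * C_HbO2 + eps_Hb,lambda * C_Hb) + noise

with C_HbO2 = sO2 * C_total and C_Hb = (1 - sO2) * C_total.  Unmixing solves the
2x2 linear system for the two chromophore concentrations under the equal-fluence
assumption and returns sO2 = C_HbO2 / (C_HbO2 + C_Hb).

Default molar extinction coefficients are standard compiled hemoglobin spectra
at 750/850 nm; 850 nm is the HbO2-dominant wavelength, so the estimated sO2 is
monotone in the signal ratio p850/p750.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ..errors import ConfigurationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExtinctionMatrix:
    """2x2 molar extinction coefficients over {HbO2, Hb} x wavelengths (cm^-1 M^-1)."""

    wavelengths: tuple[float, float] = (750.0, 850.0)
    hbo2: tuple[float, float] = (518.0, 1058.0)
    hb: tuple[float, float] = (1405.24, 691.32)

    def __post_init__(self) -> None:
        if len(self.wavelengths) != 2:
            raise ConfigurationError("exactly two wavelengths required")
        if any(v <= 0 for v in self.hbo2 + self.hb):
            raise ConfigurationError("extinction coefficients must be positive")
        if np.linalg.cond(self.matrix) > 1e12:
            raise ConfigurationError("extinction matrix is singular or near-singular")

    @property
    def matrix(self) -> np.ndarray:
        """Rows index wavelength, columns (HbO2, Hb)."""
        return np.array([[self.hbo2[0], self.hb[0]],
                         [self.hbo2[1], self.hb[1]]])


@dataclass(frozen=True)
class PaSignalPair:
    """ROI-mean signal amplitudes at the two excitation wavelengths."""

    wavelengths: tuple[float, float]
    signals: tuple[float, float]          # a.u., clipped at zero
    fluence: tuple[float, float] = (1.0, 1.0)
    noise_sd: float = 0.0


def simulate_pa_signals(so2_true: float, total_hb: float, eps: ExtinctionMatrix,
                        fluence: tuple[float, float] = (1.0, 1.0),
                        noise_sd: float = 0.0,
                        rng: np.random.Generator | None = None) -> PaSignalPair:
    """Forward-simulate the amplitude pair for a ground-truth saturation."""
    if not 0.0 <= so2_true <= 1.0:
        raise ConfigurationError(f"so2_true must be in [0, 1], got {so2_true}")
    if total_hb <= 0:
        raise ConfigurationError("total_hb must be positive")
    conc = np.array([so2_true * total_hb, (1.0 - so2_true) * total_hb])
    clean = np.asarray(fluence) * (eps.matrix @ conc)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        clean = clean + noise_sd * rng.standard_normal(2)
    signals = np.maximum(clean, 0.0)
    return PaSignalPair(wavelengths=eps.wavelengths, signals=tuple(signals),
                        fluence=tuple(fluence), noise_sd=noise_sd)


def unmix_so2(pair: PaSignalPair, eps: ExtinctionMatrix) -> float:
    """Estimate sO2 by inverting the forward model (equal fluence assumed).

    Negative concentration estimates (possible under noise) and out-of-range
    ratios are clipped to [0, 1] with a logged warning.
    """
    p = np.asarray(pair.signals, dtype=float)
    conc = np.linalg.solve(eps.matrix, p)
    if np.any(conc < 0):
        logger.warning("unmix_so2: negative concentration estimate %s, clipping", conc)
        conc = np.maximum(conc, 0.0)
    total = conc.sum()
    if total == 0:
        logger.warning("unmix_so2: zero total hemoglobin estimate, returning 0")
        return 0.0
    so2 = conc[0] / total
    if not 0.0 <= so2 <= 1.0:
        logger.warning("unmix_so2: estimate %.4f outside [0, 1], clipping", so2)
        so2 = float(np.clip(so2, 0.0, 1.0))
    return float(so2)
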