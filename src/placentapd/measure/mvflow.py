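"""Microvascular flow imaging (MV-flow): vascular maps and the vascular index.

The placental parenchyma is modelled as a binary vessel field whose occupancy
equals the ground-truth microvascular density fraction; vessel pixels carry a
flow-signal magnitude of ``contrast`` and Gaussian noise is added everywhere.
The vascular index is the percentage of ROI pixels above a constant colour
threshold, applied identically across subjects and sessions.

Vessel pixels are placed by exact count (round(density * n_pixels) pixels drawn
without replacement) rather than per-pixel Bernoulli sampling, so the noiseless
map reproduces the true density up to single-pixel quantization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ConfigurationError, InvalidMeasurementError


@dataclass
class VascularMap:
    """A 2-D flow-magnitude grid with its ROI mask and colour threshold."""

    magnitudes: np.ndarray
    roi: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        self.roi = np.asarray(self.roi, dtype=bool)
        if self.magnitudes.shape != self.roi.shape:
            raise ConfigurationError("grid and ROI mask must be congruent")
        if not self.roi.any():
            raise InvalidMeasurementError("empty ROI")


def simulate_vascular_map(density_true: float, grid_shape: tuple[int, int] = (256, 256),
                          contrast: float = 100.0, noise_sd: float = 0.0,
                          threshold: float = 50.0,
                          rng: np.random.Generator | None = None) -> VascularMap:
    """Simulate a flow map with vessel occupancy equal to *density_true*."""
    if not 0.0 <= density_true <= 1.0:
        raise ConfigurationError("density_true must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng()
    n_pix = int(np.prod(grid_shape))
    n_vessel = int(round(density_true * n_pix))
    flat = np.zeros(n_pix)
    if n_vessel:
        idx = rng.choice(n_pix, size=n_vessel, replace=False)
        flat[idx] = contrast
    if noise_sd > 0:
        flat = flat + noise_sd * rng.standard_normal(n_pix)
    return VascularMap(magnitudes=flat.reshape(grid_shape),
                       roi=np.ones(grid_shape, dtype=bool), threshold=threshold)


def compute_vi(vmap: VascularMap) -> float:
    """Vascular index: 100 x (ROI pixels above threshold) / (ROI pixels)."""
    roi_vals = vmap.magnitudes[vmap.roi]
    if roi_vals.size == 0:
        raise InvalidMeasurementError("empty ROI")
    return float(100.0 * np.mean(roi_vals > vmap.threshold))
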