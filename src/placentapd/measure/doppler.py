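"""Pulse-wave Doppler of the uterine artery: cycle sampling and resistance index.

RI = (PSV - EDV) / PSV per cardiac cycle, averaged over 3-5 consecutive cycles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ..errors import ConfigurationError, InvalidMeasurementError

logger = logging.getLogger(__name__)


@dataclass
class DopplerCycles:
    """Per-cycle peak-systolic and end-diastolic velocities (mm/s)."""

    psv: np.ndarray
    edv: np.ndarray

    def __post_init__(self) -> None:
        self.psv = np.atleast_1d(np.asarray(self.psv, dtype=float))
        self.edv = np.atleast_1d(np.asarray(self.edv, dtype=float))
        if len(self.psv) != len(self.edv):
            raise ConfigurationError("PSV and EDV cycle counts differ")
        if not 1 <= len(self.psv) <= 5:
            raise ConfigurationError("cycle count must be in [1, 5]")
        if np.any(self.edv < 0) or np.any(self.edv > self.psv):
            raise ConfigurationError("cycles must satisfy 0 <= EDV <= PSV")

    @property
    def n_cycles(self) -> int:
        return len(self.psv)


def simulate_doppler_cycles(psv_true: float, edv_true: float, n_cycles: int = 5,
                            noise_sd: float = 0.0,
                            rng: np.random.Generator | None = None) -> DopplerCycles:
    """Sample per-cycle velocities as truth plus independent Gaussian noise.

    The physical order constraint 0 <= EDV <= PSV is enforced by clipping with
    a logged warning (never silently resampled).
    """
    if not 0.0 <= edv_true <= psv_true:
        raise ConfigurationError("need 0 <= edv_true <= psv_true")
    if not 3 <= n_cycles <= 5:
        raise ConfigurationError("n_cycles must be in [3, 5]")
    if rng is None:
        rng = np.random.default_rng()
    psv = psv_true + noise_sd * rng.standard_normal(n_cycles)
    edv = edv_true + noise_sd * rng.standard_normal(n_cycles)
    n_bad = int(np.sum((edv < 0) | (edv > psv)))
    if n_bad:
        logger.warning("simulate_doppler_cycles: clipped EDV on %d cycle(s)", n_bad)
    edv = np.clip(edv, 0.0, np.maximum(psv, 0.0))
    return DopplerCycles(psv=psv, edv=edv)


def compute_ri(cycles: DopplerCycles) -> float:
    """Mean over cycles of (PSV - EDV)/PSV; in [0, 1] by the cycle invariants."""
    if np.any(cycles.psv <= 0):
        raise InvalidMeasurementError("RI undefined: non-positive PSV in a cycle")
    return float(np.mean((cycles.psv - cycles.edv) / cycles.psv))
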