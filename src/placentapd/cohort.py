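"""Synthetic three-arm cohort generation.

Ground truth for each dam follows its group-mean trajectory plus a between-dam
random intercept and a per-session residual:

    truth_i(gd) = anchor_g - slope_g * (gd_final - gd) + b_i + e_{i,gd}

with b_i ~ N(0, sd_intercept^2) and e ~ N(0, sd_residual^2).  A latent
"functional rescue" z-score per dam couples, in the treated arm only, the
intercepts of the functional markers (sO2, WiAUC) to the GD18 fetal-weight
endpoint, emulating the observation that functional — but not resistance —
recovery tracks fetal outcome.

Values violating a marker's physiological range are clipped, never resampled,
and every clip is counted and logged (auditability over silent repair).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .calibration import EndpointModel, MarkerCalibration, StudyConfig, StudyDesign
from .errors import ConfigurationError

logger = logging.getLogger(__name__)

ENDPOINT_NAMES = ("fetal_weight", "placental_weight", "hif1a", "cd31")

TRUTH_COLUMNS = ["dam_id", "group", "gd", "marker", "value"]
ENDPOINT_COLUMNS = ["dam_id", "group", "rescue_z"] + list(ENDPOINT_NAMES)


def build_group_trajectory(calibration: MarkerCalibration, group: str,
                           gd_grid, final_gd: int | None = None) -> np.ndarray:
    """Deterministic group-mean trajectory of a marker on a GD grid.

    The anchor-and-slope line ``value(gd) = anchor - slope * (gd_final - gd)``
    hits the calibrated anchor exactly at the final gestational day.
    """
    line = calibration.line(group)
    gd = np.asarray(gd_grid, dtype=float)
    if final_gd is None:
        final_gd = gd.max()
    return line.anchor - line.slope * (final_gd - gd)


@dataclass
class DamRecord:
    """Per-dam view of ground truths and endpoints (one monitored placenta)."""

    dam_id: str
    group: str
    rescue_z: float
    truths: Mapping[str, Mapping[int, float]]   # marker -> {gd: value}
    endpoints: Mapping[str, float]

    def series(self, marker: str) -> tuple[np.ndarray, np.ndarray]:
        data = self.truths[marker]
        gds = np.array(sorted(data), dtype=float)
        return gds, np.array([data[int(g)] for g in gds])


@dataclass
class Cohort:
    """A generated cohort: tidy ground-truth table plus per-dam endpoints."""

    design: StudyDesign
    truths: pd.DataFrame          # columns TRUTH_COLUMNS
    endpoints: pd.DataFrame       # columns ENDPOINT_COLUMNS
    seed: int | None
    config_hash: str
    n_clipped: int = 0
    measured: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n_expected = self.design.n_total
        if self.truths["dam_id"].nunique() != n_expected:
            raise ConfigurationError(
                f"cohort has {self.truths['dam_id'].nunique()} dams, expected {n_expected}"
            )

    @property
    def dam_ids(self) -> list[str]:
        return sorted(self.truths["dam_id"].unique())

    def truth_at(self, marker: str, gd: int) -> pd.DataFrame:
        sel = self.truths[(self.truths["marker"] == marker) & (self.truths["gd"] == gd)]
        return sel[["dam_id", "group", "value"]].reset_index(drop=True)

    @property
    def records(self) -> Iterator[DamRecord]:
        ep = self.endpoints.set_index("dam_id")
        for dam_id, sub in self.truths.groupby("dam_id", sort=True):
            truths = {
                marker: dict(zip(msub["gd"].astype(int), msub["value"]))
                for marker, msub in sub.groupby("marker")
            }
            row = ep.loc[dam_id]
            yield DamRecord(
                dam_id=dam_id, group=row["group"], rescue_z=float(row["rescue_z"]),
                truths=truths,
                endpoints={name: float(row[name]) for name in ENDPOINT_NAMES},
            )


def _clip_logged(values: np.ndarray, lo: float, hi: float, label: str) -> tuple[np.ndarray, int]:
    n_out = int(np.sum((values < lo) | (values > hi)))
    if n_out:
        logger.warning("%s: clipped %d value(s) to [%g, %g]", label, n_out, lo, hi)
    return np.clip(values, lo, hi), n_out


def sample_endpoints(group: np.ndarray, rescue_z: np.ndarray, so2_final: np.ndarray,
                     vi_final: np.ndarray, model: EndpointModel,
                     rng: np.random.Generator) -> tuple[pd.DataFrame, int]:
    """Draw GD18 endpoints for an array of dams.

    fetal weight  = group mean + loading_g * z + noise
    HIF-1a % area = a_H + b_H * sO2(GD18)     + noise   (b_H < 0: hypoxia marker)
    CD31 % area   = a_C + b_C * VI(GD18)      + noise   (microvessel density marker)
    """
    n = len(group)
    mean_fw = np.array([model.fetal_weight_means[g] for g in group])
    load_fw = np.array([model.fetal_weight_loading[g] for g in group])
    sd_fw = np.array([model.fetal_weight_noise[g] for g in group])
    fetal = mean_fw + load_fw * rescue_z + sd_fw * rng.standard_normal(n)
    mean_pw = np.array([model.placental_weight_means[g] for g in group])
    plac = mean_pw + model.placental_weight_noise * rng.standard_normal(n)
    hif = (model.hif1a_intercept + model.hif1a_slope_per_so2 * so2_final
           + model.hif1a_noise * rng.standard_normal(n))
    cd31 = (model.cd31_intercept + model.cd31_slope_per_vi * vi_final
            + model.cd31_noise * rng.standard_normal(n))

    n_clip = 0
    fetal, c = _clip_logged(fetal, *model.fetal_weight_range, "fetal_weight"); n_clip += c
    plac, c = _clip_logged(plac, *model.placental_weight_range, "placental_weight"); n_clip += c
    hif, c = _clip_logged(hif, *model.hif1a_range, "hif1a"); n_clip += c
    cd31, c = _clip_logged(cd31, *model.cd31_range, "cd31"); n_clip += c
    return (
        pd.DataFrame({"fetal_weight": fetal, "placental_weight": plac,
                      "hif1a": hif, "cd31": cd31}),
        n_clip,
    )


def generate_cohort(config: StudyConfig, seed: int | None = None) -> Cohort:
    """Generate a seeded cohort under *config*.

    Identical (config, seed) pairs yield bit-identical cohorts: the random
    stream is consumed in a fixed order (rescue z, then markers in config
    order, then endpoints), independent of any runtime dict ordering.
    """
    design = config.design
    if seed is None:
        seed = design.seed
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    groups = np.repeat(list(design.groups), design.n_per_group)
    dam_ids = np.array([
        f"{g[:1].upper()}{i + 1:02d}"
        for g in design.groups for i in range(design.n_per_group)
    ])
    n = len(dam_ids)
    treated_mask = groups == "treated"
    rescue_z = rng.standard_normal(n)
    rho = config.endpoints.rescue_coupling

    frames = []
    n_clipped = 0
    final_so2 = final_vi = None
    for cal in config.markers:
        grid = np.array(design.grid(cal.grid), dtype=float)
        traj = {g: build_group_trajectory(cal, g, grid, design.final_gd)
                for g in design.groups}
        base = np.vstack([traj[g] for g in groups])          # (n, len(grid))
        eps_int = rng.standard_normal(n)
        if cal.coupled_to_rescue and rho != 0.0:
            # treated-arm intercepts share the rescue factor; other arms stay iid
            mixed = rho * rescue_z + np.sqrt(1.0 - rho**2) * eps_int
            eps_int = np.where(treated_mask, mixed, eps_int)
        b = cal.sd_intercept * eps_int
        e = cal.sd_residual * rng.standard_normal((n, len(grid)))
        if cal.intercept_scaling == "proportional":
            # intercept scales with the trajectory level (relative to the anchor),
            # for strictly-positive markers whose mean spans a wide dynamic range:
            # keeps the anchored endpoint dispersion while avoiding floor clipping
            # (and slope bias) at early gestational days
            anchors = np.array([cal.line(g).anchor for g in groups])
            truth = base * (1.0 + (b / anchors)[:, None]) + e
        else:
            truth = base + b[:, None] + e
        truth, c = _clip_logged(truth, *cal.valid_range, cal.name)
        n_clipped += c
        frames.append(pd.DataFrame({
            "dam_id": np.repeat(dam_ids, len(grid)),
            "group": np.repeat(groups, len(grid)),
            "gd": np.tile(grid.astype(int), n),
            "marker": cal.name,
            "value": truth.ravel(),
        }))
        if cal.name == "so2":
            final_so2 = truth[:, -1]
        elif cal.name == "vi":
            final_vi = truth[:, -1]

    if final_so2 is None:
        final_so2 = np.zeros(n)
    if final_vi is None:
        final_vi = np.zeros(n)
    ep, c = sample_endpoints(groups, rescue_z, final_so2, final_vi, config.endpoints, rng)
    n_clipped += c
    endpoints = pd.concat(
        [pd.DataFrame({"dam_id": dam_ids, "group": groups, "rescue_z": rescue_z}), ep],
        axis=1,
    )

    truths = pd.concat(frames, ignore_index=True)
    return Cohort(design=design, truths=truths, endpoints=endpoints, seed=seed,
                  config_hash=config.config_hash, n_clipped=n_clipped)
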