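"""Study configuration: design, marker calibrations, endpoint couplings, measurement settings.

The packaged default configuration (``data/default_calibration.yaml``) encodes a
three-arm rat preeclampsia study (control / L-NAME disease / L-NAME + pravastatin,
n = 8 dams per arm) with linear group-mean trajectories per marker, anchored at the
final gestational day.  Anchors that are not observable in a real study (healthy
controls for systemic markers; the treated arm for imaging markers) are derived by
inverting the Functional Recovery Index

    FRI = 100 * (X_treated - X_disease) / (X_control - X_disease)

so that the calibrated cohort reproduces the intended endpoint profile by
construction.  See :func:`control_anchor_from_fri` / :func:`treated_anchor_from_fri`.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field, fields
from importlib import resources
from typing import Mapping

import yaml

from .errors import ConfigurationError

GROUPS = ("control", "disease", "treated")
ORIENTATIONS = ("increase", "decrease")
GRIDS = ("systemic", "imaging")


def control_anchor_from_fri(disease: float, treated: float, fri_percent: float) -> float:
    """Invert the FRI relation for the (unprinted) control group mean."""
    if fri_percent == 0:
        raise ConfigurationError("cannot invert FRI = 0 for a control anchor")
    return disease + (treated - disease) / (fri_percent / 100.0)


def treated_anchor_from_fri(control: float, disease: float, fri_percent: float) -> float:
    """Treated-arm GD18 mean implied by a printed FRI and the two reference means."""
    return disease + (fri_percent / 100.0) * (control - disease)


@dataclass(frozen=True)
class StudyDesign:
    """Arms, sample size and sampling grids of the longitudinal study."""

    groups: tuple[str, ...] = GROUPS
    n_per_group: int = 8
    systemic_gd_grid: tuple[int, ...] = (7, 10, 13, 18)
    imaging_gd_grid: tuple[int, ...] = (14, 16, 18)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ConfigurationError("n_per_group must be >= 2")
        for name in ("systemic_gd_grid", "imaging_gd_grid"):
            grid = getattr(self, name)
            if len(grid) < 2 or any(b <= a for a, b in zip(grid, grid[1:])):
                raise ConfigurationError(f"{name} must be strictly increasing with >= 2 points")
        lo, hi = min(self.systemic_gd_grid), max(self.systemic_gd_grid)
        if not all(lo <= gd <= hi for gd in self.imaging_gd_grid):
            raise ConfigurationError("imaging grid must lie within the systemic GD span")
        if len(set(self.groups)) != len(self.groups):
            raise ConfigurationError("duplicate group labels")

    @property
    def final_gd(self) -> int:
        return max(self.systemic_gd_grid)

    def grid(self, which: str) -> tuple[int, ...]:
        if which == "systemic":
            return self.systemic_gd_grid
        if which == "imaging":
            return self.imaging_gd_grid
        raise ConfigurationError(f"unknown grid {which!r}")

    @property
    def n_total(self) -> int:
        return self.n_per_group * len(self.groups)


@dataclass(frozen=True)
class GroupLine:
    """Anchor-and-slope parameterization of a group-mean trajectory.

    value(gd) = anchor - slope * (gd_final - gd); the anchor is the group mean at
    the final gestational day and slope the true rate of change in units/day.
    """

    anchor: float
    slope: float


@dataclass(frozen=True)
class MarkerCalibration:
    """Ground-truth trajectory model for one marker across the three arms."""

    name: str
    unit: str
    orientation: str                      # 'increase' or 'decrease' = recovery direction
    grid: str                             # 'systemic' or 'imaging'
    groups: Mapping[str, GroupLine]
    sd_intercept: float                   # between-dam SD of the random intercept
    sd_residual: float                    # per-session biological/measurement scatter
    valid_range: tuple[float, float]
    coupled_to_rescue: bool = False
    intercept_scaling: str = "additive"   # 'additive' | 'proportional' (to trajectory level)

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ConfigurationError(f"{self.name}: orientation must be one of {ORIENTATIONS}")
        if self.intercept_scaling not in ("additive", "proportional"):
            raise ConfigurationError(
                f"{self.name}: intercept_scaling must be 'additive' or 'proportional'"
            )
        if self.grid not in GRIDS:
            raise ConfigurationError(f"{self.name}: grid must be one of {GRIDS}")
        if self.sd_intercept < 0 or self.sd_residual < 0:
            raise ConfigurationError(f"{self.name}: SDs must be non-negative")
        lo, hi = self.valid_range
        if not lo < hi:
            raise ConfigurationError(f"{self.name}: invalid range {self.valid_range}")
        for grp, line in self.groups.items():
            if grp not in GROUPS:
                raise ConfigurationError(f"{self.name}: unknown group {grp!r}")
            if not lo <= line.anchor <= hi:
                raise ConfigurationError(
                    f"{self.name}: {grp} anchor {line.anchor} outside range {self.valid_range}"
                )
        missing = set(GROUPS) - set(self.groups)
        if missing:
            raise ConfigurationError(f"{self.name}: missing calibration for groups {sorted(missing)}")

    @property
    def increase_is_recovery(self) -> bool:
        return self.orientation == "increase"

    def line(self, group: str) -> GroupLine:
        try:
            return self.groups[group]
        except KeyError:
            raise ConfigurationError(f"{self.name}: no calibration for group {group!r}") from None


@dataclass(frozen=True)
class EndpointModel:
    """GD18 endpoint generation: weights and immunohistochemistry couplings."""

    rescue_coupling: float
    fetal_weight_means: Mapping[str, float]
    fetal_weight_loading: Mapping[str, float]
    fetal_weight_noise: Mapping[str, float]
    fetal_weight_range: tuple[float, float]
    placental_weight_means: Mapping[str, float]
    placental_weight_noise: float
    placental_weight_range: tuple[float, float]
    hif1a_intercept: float
    hif1a_slope_per_so2: float
    hif1a_noise: float
    hif1a_range: tuple[float, float]
    cd31_intercept: float
    cd31_slope_per_vi: float
    cd31_noise: float
    cd31_range: tuple[float, float]

    def __post_init__(self) -> None:
        if not -1.0 <= self.rescue_coupling <= 1.0:
            raise ConfigurationError("rescue_coupling must be a correlation in [-1, 1]")
        for mapping in (self.fetal_weight_noise,):
            if any(v < 0 for v in mapping.values()):
                raise ConfigurationError("endpoint noise SDs must be non-negative")
        if self.placental_weight_noise < 0 or self.hif1a_noise < 0 or self.cd31_noise < 0:
            raise ConfigurationError("endpoint noise SDs must be non-negative")


@dataclass(frozen=True)
class PaConfig:
    wavelengths: tuple[float, float] = (750.0, 850.0)
    extinction_hbo2: tuple[float, float] = (518.0, 1058.0)
    extinction_hb: tuple[float, float] = (1405.24, 691.32)
    total_hb: float = 1.0
    fluence: tuple[float, float] = (1.0, 1.0)
    noise_sd: float = 5.0


@dataclass(frozen=True)
class CeusConfig:
    t0: float = 5.0
    mu: float = 3.0
    sigma: float = 0.5
    baseline: float = 100.0
    duration: float = 60.0
    dt: float = 0.5
    noise_sd: float = 2.0


@dataclass(frozen=True)
class DopplerConfig:
    psv_ref: float = 80.0
    n_cycles: int = 5
    noise_sd: float = 1.5


@dataclass(frozen=True)
class MvflowConfig:
    grid_shape: tuple[int, int] = (256, 256)
    contrast: float = 100.0
    noise_sd: float = 10.0
    threshold: float = 50.0


@dataclass(frozen=True)
class MeasurementConfig:
    pa: PaConfig = field(default_factory=PaConfig)
    ceus: CeusConfig = field(default_factory=CeusConfig)
    doppler: DopplerConfig = field(default_factory=DopplerConfig)
    mvflow: MvflowConfig = field(default_factory=MvflowConfig)


@dataclass(frozen=True)
class AnalysisConfig:
    alpha: float = 0.05
    strong_alpha: float = 0.01
    fri_guard_rel: float = 1e-9
    fri_near_complete: float = 80.0
    gg_correction: bool = True


@dataclass(frozen=True)
class StudyConfig:
    """Complete, validated study configuration."""

    design: StudyDesign
    markers: tuple[MarkerCalibration, ...]
    endpoints: EndpointModel
    measurement: MeasurementConfig = field(default_factory=MeasurementConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def __post_init__(self) -> None:
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate marker names")

    def marker(self, name: str) -> MarkerCalibration:
        for m in self.markers:
            if m.name == name:
                return m
        raise ConfigurationError(f"unknown marker {name!r}")

    @property
    def marker_names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.markers)

    def to_dict(self) -> dict:
        return _asdict(self)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _asdict(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {f.name: _asdict(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, Mapping):
        return {k: _asdict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_asdict(v) for v in obj]
    return obj


# ---------------------------------------------------------------------------
# YAML loading


def _require(mapping: Mapping, key: str, context: str):
    if key not in mapping:
        raise ConfigurationError(f"{context}: missing key {key!r}")
    return mapping[key]


def _parse_group_line(name: str, group: str, raw: Mapping, resolved: dict[str, GroupLine],
                      pending: dict[str, tuple[float, float]]) -> None:
    slope = float(_require(raw, "slope", f"{name}.{group}"))
    if "anchor" in raw:
        resolved[group] = GroupLine(anchor=float(raw["anchor"]), slope=slope)
    elif "anchor_from_fri" in raw:
        pending[group] = (float(raw["anchor_from_fri"]), slope)
    else:
        raise ConfigurationError(f"{name}.{group}: need 'anchor' or 'anchor_from_fri'")


def _parse_marker(name: str, raw: Mapping) -> MarkerCalibration:
    resolved: dict[str, GroupLine] = {}
    pending: dict[str, tuple[float, float]] = {}
    for group, line in _require(raw, "groups", name).items():
        _parse_group_line(name, group, line, resolved, pending)
    if len(pending) > 1:
        raise ConfigurationError(f"{name}: at most one group may use anchor_from_fri")
    for group, (fri, slope) in pending.items():
        others = {g: gl.anchor for g, gl in resolved.items()}
        if group == "control":
            anchor = control_anchor_from_fri(others["disease"], others["treated"], fri)
        elif group == "treated":
            anchor = treated_anchor_from_fri(others["control"], others["disease"], fri)
        else:
            raise ConfigurationError(f"{name}: anchor_from_fri not supported for group {group!r}")
        resolved[group] = GroupLine(anchor=anchor, slope=slope)
    return MarkerCalibration(
        name=name,
        unit=str(raw.get("unit", "")),
        orientation=_require(raw, "orientation", name),
        grid=_require(raw, "grid", name),
        groups=resolved,
        sd_intercept=float(_require(raw, "sd_intercept", name)),
        sd_residual=float(_require(raw, "sd_residual", name)),
        valid_range=tuple(float(v) for v in _require(raw, "valid_range", name)),
        coupled_to_rescue=bool(raw.get("coupled_to_rescue", False)),
        intercept_scaling=str(raw.get("intercept_scaling", "additive")),
    )


def _per_group(raw, context: str) -> dict[str, float]:
    if isinstance(raw, Mapping):
        return {g: float(v) for g, v in raw.items()}
    return {g: float(raw) for g in GROUPS}


def _parse_endpoints(raw: Mapping) -> EndpointModel:
    fw = _require(raw, "fetal_weight", "endpoints")
    pw = _require(raw, "placental_weight", "endpoints")
    hif = _require(raw, "hif1a", "endpoints")
    cd31 = _require(raw, "cd31", "endpoints")
    return EndpointModel(
        rescue_coupling=float(raw.get("rescue_coupling", 0.0)),
        fetal_weight_means=_per_group(_require(fw, "group_means", "fetal_weight"), "fetal_weight"),
        fetal_weight_loading=_per_group(fw.get("rescue_loading", 0.0), "fetal_weight"),
        fetal_weight_noise=_per_group(_require(fw, "noise_sd", "fetal_weight"), "fetal_weight"),
        fetal_weight_range=tuple(float(v) for v in fw["valid_range"]),
        placental_weight_means=_per_group(_require(pw, "group_means", "placental_weight"), "pw"),
        placental_weight_noise=float(_require(pw, "noise_sd", "placental_weight")),
        placental_weight_range=tuple(float(v) for v in pw["valid_range"]),
        hif1a_intercept=float(_require(hif, "intercept", "hif1a")),
        hif1a_slope_per_so2=float(_require(hif, "slope_per_so2", "hif1a")),
        hif1a_noise=float(_require(hif, "noise_sd", "hif1a")),
        hif1a_range=tuple(float(v) for v in hif["valid_range"]),
        cd31_intercept=float(_require(cd31, "intercept", "cd31")),
        cd31_slope_per_vi=float(_require(cd31, "slope_per_vi", "cd31")),
        cd31_noise=float(_require(cd31, "noise_sd", "cd31")),
        cd31_range=tuple(float(v) for v in cd31["valid_range"]),
    )


def _parse_measurement(raw: Mapping | None) -> MeasurementConfig:
    raw = raw or {}

    def build(cls, key, tuple_keys=()):
        block = dict(raw.get(key, {}))
        for k in list(block):
            if isinstance(block[k], list):
                block[k] = tuple(block[k])
        return cls(**block)

    return MeasurementConfig(
        pa=build(PaConfig, "pa"),
        ceus=build(CeusConfig, "ceus"),
        doppler=build(DopplerConfig, "doppler"),
        mvflow=build(MvflowConfig, "mvflow"),
    )


def config_from_dict(raw: Mapping) -> StudyConfig:
    """Build and validate a :class:`StudyConfig` from a parsed YAML mapping."""
    design_raw = dict(_require(raw, "design", "config"))
    for k in ("groups", "systemic_gd_grid", "imaging_gd_grid"):
        if k in design_raw:
            design_raw[k] = tuple(design_raw[k])
    design = StudyDesign(**design_raw)
    markers = tuple(
        _parse_marker(name, block) for name, block in _require(raw, "markers", "config").items()
    )
    endpoints = _parse_endpoints(_require(raw, "endpoints", "config"))
    measurement = _parse_measurement(raw.get("measurement"))
    analysis = AnalysisConfig(**raw.get("analysis", {}))
    return StudyConfig(design=design, markers=markers, endpoints=endpoints,
                       measurement=measurement, analysis=analysis)


def load_config(path) -> StudyConfig:
    """Load and validate a study configuration from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ConfigurationError(f"{path}: not a mapping")
    return config_from_dict(raw)


def default_config() -> StudyConfig:
    """The packaged default calibration (see module docstring)."""
    ref = resources.files("placentapd.data").joinpath("default_calibration.yaml")
    raw = yaml.safe_load(ref.read_text())
    return config_from_dict(raw)


def zero_noise(config: StudyConfig) -> StudyConfig:
    """A copy of *config* with every source of randomness silenced.

    Used for the noiseless pipeline identity: all generator SDs, endpoint noise
    and instrument noise are set to zero, so every pipeline estimate must land
    on its calibrated value (up to documented numerical tolerances).
    """
    raw = copy.deepcopy(config.to_dict())
    for marker in raw["markers"]:
        marker["sd_intercept"] = 0.0
        marker["sd_residual"] = 0.0
    ep = raw["endpoints"]
    ep["fetal_weight_noise"] = {g: 0.0 for g in ep["fetal_weight_noise"]}
    ep["fetal_weight_loading"] = {g: 0.0 for g in ep["fetal_weight_loading"]}
    ep["placental_weight_noise"] = 0.0
    ep["hif1a_noise"] = 0.0
    ep["cd31_noise"] = 0.0
    for mod in raw["measurement"].values():
        mod["noise_sd"] = 0.0
    return _config_from_plain_dict(raw)


def _config_from_plain_dict(raw: Mapping) -> StudyConfig:
    """Rebuild a StudyConfig from the dict produced by :meth:`StudyConfig.to_dict`."""
    design_raw = dict(raw["design"])
    for k in ("groups", "systemic_gd_grid", "imaging_gd_grid"):
        design_raw[k] = tuple(design_raw[k])
    design = StudyDesign(**design_raw)
    markers = []
    for m in raw["markers"]:
        groups = {g: GroupLine(**gl) for g, gl in m["groups"].items()}
        markers.append(MarkerCalibration(
            name=m["name"], unit=m["unit"], orientation=m["orientation"], grid=m["grid"],
            groups=groups, sd_intercept=m["sd_intercept"], sd_residual=m["sd_residual"],
            valid_range=tuple(m["valid_range"]), coupled_to_rescue=m["coupled_to_rescue"],
            intercept_scaling=m.get("intercept_scaling", "additive"),
        ))
    ep = raw["endpoints"]
    endpoints = EndpointModel(
        rescue_coupling=ep["rescue_coupling"],
        fetal_weight_means=dict(ep["fetal_weight_means"]),
        fetal_weight_loading=dict(ep["fetal_weight_loading"]),
        fetal_weight_noise=dict(ep["fetal_weight_noise"]),
        fetal_weight_range=tuple(ep["fetal_weight_range"]),
        placental_weight_means=dict(ep["placental_weight_means"]),
        placental_weight_noise=ep["placental_weight_noise"],
        placental_weight_range=tuple(ep["placental_weight_range"]),
        hif1a_intercept=ep["hif1a_intercept"], hif1a_slope_per_so2=ep["hif1a_slope_per_so2"],
        hif1a_noise=ep["hif1a_noise"], hif1a_range=tuple(ep["hif1a_range"]),
        cd31_intercept=ep["cd31_intercept"], cd31_slope_per_vi=ep["cd31_slope_per_vi"],
        cd31_noise=ep["cd31_noise"], cd31_range=tuple(ep["cd31_range"]),
    )
    meas = raw["measurement"]

    def tup(d):
        return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}

    measurement = MeasurementConfig(
        pa=PaConfig(**tup(meas["pa"])), ceus=CeusConfig(**tup(meas["ceus"])),
        doppler=DopplerConfig(**tup(meas["doppler"])), mvflow=MvflowConfig(**tup(meas["mvflow"])),
    )
    analysis = AnalysisConfig(**raw["analysis"])
    return StudyConfig(design=design, markers=tuple(markers), endpoints=endpoints,
                       measurement=measurement, analysis=analysis)
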