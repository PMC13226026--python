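"""Configuration loading, validation and the FRI anchor-inversion algebra."""

import pytest

from placentapd import (
    ConfigurationError,
    StudyDesign,
    control_anchor_from_fri,
    treated_anchor_from_fri,
    zero_noise,
)
from placentapd.calibration import GroupLine, MarkerCalibration, config_from_dict


class TestFriInversion:
    def test_control_anchor_recovers_printed_systemic_values(self):
        # SBP: disease 162.9, treated 143.9, FRI 51.1% -> control 125.718 mmHg
        assert control_anchor_from_fri(162.9, 143.9, 51.1) == pytest.approx(125.718, abs=1e-3)
        # proteinuria: FRI 32.0% -> control 174.16 mg/L
        assert control_anchor_from_fri(662.6, 506.3, 32.0) == pytest.approx(174.1625, abs=1e-3)

    def test_treated_anchor_from_fri_is_exact_inverse(self):
        anchor = treated_anchor_from_fri(70.0, 48.0, 92.7)
        assert anchor == pytest.approx(48.0 + 0.927 * 22.0)
        # round trip: the FRI of the derived anchor is the printed FRI
        assert 100 * (anchor - 48.0) / (70.0 - 48.0) == pytest.approx(92.7)

    def test_fri_zero_cannot_be_inverted(self):
        with pytest.raises(ConfigurationError):
            control_anchor_from_fri(10.0, 5.0, 0.0)


class TestDefaultConfig:
    def test_all_markers_present_with_three_arms(self, cfg):
        assert cfg.marker_names == ("sbp", "urinary_protein", "so2", "wiauc", "vi", "uta_ri")
        for m in cfg.markers:
            assert set(m.groups) == {"control", "disease", "treated"}

    def test_derived_anchors(self, cfg):
        assert cfg.marker("so2").line("treated").anchor == pytest.approx(68.394)
        assert cfg.marker("wiauc").line("treated").anchor == pytest.approx(28572.0)
        assert cfg.marker("vi").line("treated").anchor == pytest.approx(35.245)
        assert cfg.marker("uta_ri").line("treated").anchor == pytest.approx(0.6622)
        assert cfg.marker("sbp").line("control").anchor == pytest.approx(125.718, abs=1e-3)

    def test_implied_common_gd7_sbp_baseline(self, cfg):
        # consistency: both L-NAME arms extrapolate to ~120 mmHg at GD7
        sbp = cfg.marker("sbp")
        for group in ("disease", "treated"):
            line = sbp.line(group)
            gd7 = line.anchor - line.slope * 11
            assert gd7 == pytest.approx(120.0, abs=1.0)

    def test_config_hash_stable_and_sensitive(self, cfg):
        assert cfg.config_hash == default_hash(cfg)
        noiseless = zero_noise(cfg)
        assert noiseless.config_hash != cfg.config_hash

    def test_zero_noise_silences_every_sd(self, cfg):
        nz = zero_noise(cfg)
        for m in nz.markers:
            assert m.sd_intercept == 0.0 and m.sd_residual == 0.0
        assert all(v == 0.0 for v in nz.endpoints.fetal_weight_noise.values())
        assert nz.measurement.pa.noise_sd == 0.0
        assert nz.measurement.ceus.noise_sd == 0.0
        assert nz.measurement.doppler.noise_sd == 0.0
        assert nz.measurement.mvflow.noise_sd == 0.0
        # anchors and slopes are untouched
        assert nz.marker("sbp").line("disease") == cfg.marker("sbp").line("disease")


def default_hash(cfg):
    return cfg.config_hash


class TestValidation:
    def test_design_invariants(self):
        with pytest.raises(ConfigurationError):
            StudyDesign(n_per_group=1)
        with pytest.raises(ConfigurationError):
            StudyDesign(systemic_gd_grid=(7, 7, 13, 18))
        with pytest.raises(ConfigurationError):
            StudyDesign(imaging_gd_grid=(14, 16, 21))   # outside systemic span

    def test_marker_invariants(self):
        groups = {g: GroupLine(50.0, 1.0) for g in ("control", "disease", "treated")}
        ok = dict(name="m", unit="", orientation="increase", grid="imaging",
                  groups=groups, sd_intercept=1.0, sd_residual=1.0, valid_range=(0.0, 100.0))
        MarkerCalibration(**ok)
        with pytest.raises(ConfigurationError):
            MarkerCalibration(**{**ok, "sd_intercept": -1.0})
        with pytest.raises(ConfigurationError):
            MarkerCalibration(**{**ok, "orientation": "sideways"})
        bad_groups = dict(groups)
        bad_groups["disease"] = GroupLine(500.0, 1.0)    # outside range
        with pytest.raises(ConfigurationError):
            MarkerCalibration(**{**ok, "groups": bad_groups})
        with pytest.raises(ConfigurationError):
            MarkerCalibration(**{**ok, "groups": {"control": GroupLine(50.0, 1.0)}})

    def test_schema_errors_are_raised_before_computation(self):
        broken = {"design": {"n_per_group": 8}}          # no markers section
        with pytest.raises(ConfigurationError):
            config_from_dict(broken)

    def test_at_most_one_fri_derived_anchor_per_marker(self):
        raw = {
            "design": {},
            "markers": {
                "m": {
                    "orientation": "increase", "grid": "imaging",
                    "valid_range": [0, 100], "sd_intercept": 1, "sd_residual": 1,
                    "groups": {
                        "control": {"anchor_from_fri": 50.0, "slope": 0},
                        "disease": {"anchor": 10.0, "slope": 0},
                        "treated": {"anchor_from_fri": 50.0, "slope": 0},
                    },
                }
            },
        }
        with pytest.raises(ConfigurationError):
            config_from_dict(raw)
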