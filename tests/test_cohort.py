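"""Cohort generator: trajectories, determinism, structural invariants, couplings."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from placentapd import build_group_trajectory, generate_cohort, pearson, zero_noise
from placentapd.calibration import GroupLine, MarkerCalibration, StudyDesign


class TestGroupTrajectory:
    def test_final_gd_hits_printed_sbp_anchors_exactly(self, cfg):
        sbp = cfg.marker("sbp")
        grid = cfg.design.systemic_gd_grid
        assert build_group_trajectory(sbp, "disease", grid)[-1] == 162.9
        assert build_group_trajectory(sbp, "treated", grid)[-1] == 143.9

    def test_zero_slope_gives_constant_trajectory(self):
        cal = MarkerCalibration(
            name="m", unit="", orientation="increase", grid="imaging",
            groups={g: GroupLine(7.0, 0.0) for g in ("control", "disease", "treated")},
            sd_intercept=0.0, sd_residual=0.0, valid_range=(0.0, 10.0))
        np.testing.assert_array_equal(
            build_group_trajectory(cal, "control", (14, 16, 18)), [7.0, 7.0, 7.0])

    def test_slope_is_per_day_rate(self, cfg):
        so2 = cfg.marker("so2")
        traj = build_group_trajectory(so2, "disease", (14, 16, 18))
        assert np.diff(traj) == pytest.approx([2 * -0.70, 2 * -0.70])


class TestGenerateCohort:
    def test_default_design_yields_24_dams(self, cfg):
        cohort = generate_cohort(cfg, seed=5)
        assert cohort.endpoints.shape[0] == 24
        assert cohort.truths["dam_id"].nunique() == 24
        # every dam has a value on every grid GD of every marker
        for cal in cfg.markers:
            sub = cohort.truths[cohort.truths["marker"] == cal.name]
            assert len(sub) == 24 * len(cfg.design.grid(cal.grid))

    def test_same_seed_bit_identical_different_seed_differs(self, cfg):
        a = generate_cohort(cfg, seed=11)
        b = generate_cohort(cfg, seed=11)
        c = generate_cohort(cfg, seed=12)
        pd.testing.assert_frame_equal(a.truths, b.truths)
        pd.testing.assert_frame_equal(a.endpoints, b.endpoints)
        assert not a.truths["value"].equals(c.truths["value"])

    def test_zero_sd_collapses_onto_group_trajectory(self, cfg):
        cohort = generate_cohort(zero_noise(cfg), seed=3)
        for cal in cfg.markers:
            for group in ("control", "disease", "treated"):
                traj = dict(zip(cfg.design.grid(cal.grid),
                                build_group_trajectory(cal, group, cfg.design.grid(cal.grid))))
                sub = cohort.truths[(cohort.truths["marker"] == cal.name)
                                    & (cohort.truths["group"] == group)]
                expected = sub["gd"].map(traj)
                np.testing.assert_allclose(sub["value"], expected, rtol=0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(100))
    def test_structural_invariants_hold_across_seeds(self, cfg, seed):
        cohort = generate_cohort(cfg, seed=seed)
        t = cohort.truths.set_index("marker")
        for name, (lo, hi) in {"so2": (0, 100), "vi": (0, 100), "uta_ri": (0, 1)}.items():
            vals = t.loc[name, "value"]
            assert vals.between(lo, hi).all()
        ep = cohort.endpoints
        assert (ep["fetal_weight"] > 0).all() and (ep["placental_weight"] > 0).all()
        assert ep["hif1a"].between(0, 100).all() and ep["cd31"].between(0, 100).all()

    def test_group_means_converge_to_trajectory(self, cfg):
        # many dams, fixed seed: sample group means within 3 SEM of the calibrated line
        big = dataclasses.replace(cfg, design=StudyDesign(n_per_group=600))
        cohort = generate_cohort(big, seed=7)
        for name in ("sbp", "so2", "uta_ri"):
            cal = cfg.marker(name)
            grid = cfg.design.grid(cal.grid)
            sd = np.hypot(cal.sd_intercept, cal.sd_residual)
            for group in ("control", "disease", "treated"):
                traj = build_group_trajectory(cal, group, grid)
                sub = cohort.truths[(cohort.truths["marker"] == name)
                                    & (cohort.truths["group"] == group)]
                means = sub.groupby("gd")["value"].mean().reindex(list(grid)).to_numpy()
                tol = 3 * sd / np.sqrt(600) + 1e-9
                np.testing.assert_allclose(means, traj, atol=4 * tol, rtol=0)

    def test_clipping_is_logged_not_silent(self, cfg, caplog):
        # force heavy clipping via an extreme fetal-weight noise
        noisy_ep = dataclasses.replace(
            cfg.endpoints, fetal_weight_noise={g: 50.0 for g in ("control", "disease", "treated")})
        noisy = dataclasses.replace(cfg, endpoints=noisy_ep)
        with caplog.at_level("WARNING"):
            cohort = generate_cohort(noisy, seed=0)
        assert cohort.n_clipped > 0
        assert any("clipped" in rec.message for rec in caplog.records)


class TestEndpointCouplings:
    def _big_cohort(self, cfg, endpoints, n=3000, seed=99):
        big = dataclasses.replace(cfg, design=StudyDesign(n_per_group=n), endpoints=endpoints)
        return generate_cohort(big, seed=seed)

    def test_zero_couplings_give_null_correlation(self, cfg):
        ep = dataclasses.replace(
            cfg.endpoints, rescue_coupling=0.0,
            fetal_weight_loading={g: 0.0 for g in ("control", "disease", "treated")})
        cohort = self._big_cohort(cfg, ep, n=1500)
        treated = cohort.endpoints[cohort.endpoints["group"] == "treated"]
        so2_final = cohort.truth_at("so2", 18).set_index("dam_id")["value"]
        r = pearson(treated["fetal_weight"],
                    so2_final.loc[treated["dam_id"]].to_numpy()).r
        assert abs(r) < 3 / np.sqrt(len(treated))

    def test_linear_gaussian_correlation_matches_closed_form(self, cfg):
        # r(sO2, HIF-1a) = b*sigma_x / sqrt(b^2 sigma_x^2 + sigma_noise^2), per group
        cohort = self._big_cohort(cfg, cfg.endpoints, n=3000)
        ep = cfg.endpoints
        ctrl = cohort.endpoints[cohort.endpoints["group"] == "control"]
        so2_final = cohort.truth_at("so2", 18).set_index("dam_id")["value"]
        x = so2_final.loc[ctrl["dam_id"]].to_numpy()
        r_emp = pearson(x, ctrl["hif1a"]).r
        b = ep.hif1a_slope_per_so2
        sx = x.std(ddof=1)
        r_theory = b * sx / np.hypot(b * sx, ep.hif1a_noise)
        assert r_emp == pytest.approx(r_theory, abs=0.03)

    def test_noiseless_linear_map_gives_perfect_correlation(self, cfg):
        ep = dataclasses.replace(cfg.endpoints, cd31_noise=0.0)
        cohort = self._big_cohort(cfg, ep, n=200)
        ctrl = cohort.endpoints[cohort.endpoints["group"] == "control"]
        vi_final = cohort.truth_at("vi", 18).set_index("dam_id")["value"]
        r = pearson(vi_final.loc[ctrl["dam_id"]].to_numpy(), ctrl["cd31"]).r
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_rescue_couples_functional_but_not_resistance_truth(self, cfg):
        cohort = self._big_cohort(cfg, cfg.endpoints, n=3000)
        treated_ids = cohort.endpoints.loc[cohort.endpoints["group"] == "treated", "dam_id"]
        z = cohort.endpoints.set_index("dam_id").loc[treated_ids, "rescue_z"].to_numpy()
        for marker, coupled in (("so2", True), ("wiauc", True), ("uta_ri", False)):
            vals = cohort.truth_at(marker, 18).set_index("dam_id").loc[treated_ids, "value"]
            r = pearson(z, vals.to_numpy()).r
            if coupled:
                assert r > 0.5
            else:
                assert abs(r) < 3 / np.sqrt(len(z))
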