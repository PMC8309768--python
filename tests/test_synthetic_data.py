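import numpy as np
import pytest

from zfsentinel.core_io import CalibrationInfo, ConfigError
from zfsentinel.morphometrics import gpa_align, procrustes_distance
from zfsentinel.social_metrics import interindividual_distance
from zfsentinel.synthetic_data import (
    LandmarkSimConfig,
    SiteTrajectoryParams,
    TrajectorySimConfig,
    config_to_dict,
    deformation_for_ratio,
    landmark_config_from_dict,
    load_template,
    null_landmark_config,
    paper_like_landmark_config,
    paper_like_trajectory_config,
    simulate_group,
    simulate_landmarks,
    simulate_site,
    simulate_study,
    trajectory_config_from_dict,
)


def small_cfg(seed=1, **site_kw):
    params = dict(
        mean_speed_mm_s=10.0,
        speed_shape=4.0,
        heading_persistence=0.0,
        cohesion_weight=0.0,
        heading_noise_kappa=1.0,
    )
    params.update(site_kw)
    p = SiteTrajectoryParams(**params)
    return TrajectorySimConfig(
        sites={"site1": p, "site2": p},
        seed=seed,
        n_tanks_per_site=4,
        duration_s=20.0,
        frame_rate=10.0,
        calibration=CalibrationInfo(px_per_mm=10.0, frame_rate=10.0),
    )


def expected_uniform_rectangle_distance(a, b):
    """Closed-form mean distance between two independent uniform points
    in an a x b rectangle."""
    d = np.hypot(a, b)
    return (
        a**3 / b**2 / 15
        + b**3 / a**2 / 15
        + d * (3 - a**2 / b**2 - b**2 / a**2) / 15
        + (b**2 / a * np.arcsinh(a / b) + a**2 / b * np.arcsinh(b / a)) / 6
    )


class TestTrajectorySimulation:
    def test_frame_count_matches_duration(self):
        cfg = paper_like_trajectory_config(1)
        assert cfg.n_frames == 5400  # 180 s at 30 fps
        g = simulate_group(small_cfg(), "site1", "t1")
        assert all(tr.n_frames == 200 for tr in g.trajectories)

    def test_same_seed_is_bit_identical(self):
        g1 = simulate_group(small_cfg(5), "site1", "t1")
        g2 = simulate_group(small_cfg(5), "site1", "t1")
        assert np.array_equal(g1.positions_array(), g2.positions_array())

    def test_different_seeds_differ(self):
        g1 = simulate_group(small_cfg(5), "site1", "t1")
        g2 = simulate_group(small_cfg(6), "site1", "t1")
        assert not np.array_equal(g1.positions_array(), g2.positions_array())

    def test_batched_site_simulation_equals_per_tank(self):
        cfg = small_cfg(3)
        site = simulate_site(cfg, "site2")
        for i, g in enumerate(site):
            single = simulate_group(cfg, "site2", g.tank_id, tank_index=i)
            assert np.array_equal(g.positions_array(), single.positions_array())

    def test_positions_never_leave_arena(self):
        cfg = small_cfg(9, cohesion_weight=0.5, heading_persistence=0.9)
        for g in simulate_site(cfg, "site1"):
            mm = g.positions_array() / cfg.calibration.px_per_mm
            assert mm[..., 0].min() >= 0 and mm[..., 0].max() <= 308.0
            assert mm[..., 1].min() >= 0 and mm[..., 1].max() <= 340.0

    def test_adding_a_fish_preserves_existing_streams_without_cohesion(self):
        cfg6 = small_cfg(4)
        cfg7 = TrajectorySimConfig(
            sites=cfg6.sites, seed=4, n_fish=7, n_tanks_per_site=4,
            duration_s=20.0, frame_rate=10.0, calibration=cfg6.calibration,
        )
        g6 = simulate_group(cfg6, "site1", "t1")
        g7 = simulate_group(cfg7, "site1", "t1")
        assert np.array_equal(g6.positions_array(), g7.positions_array()[:6])

    def test_uncorrelated_walk_matches_uniform_pair_distance(self):
        """With no persistence and no cohesion the per-frame position
        marginal is uniform over the arena, so mean IID equals the
        closed-form expected distance between two uniform points."""
        cfg = small_cfg(2)
        cfg = TrajectorySimConfig(
            sites=cfg.sites, seed=2, n_tanks_per_site=12,
            duration_s=30.0, frame_rate=10.0, calibration=cfg.calibration,
        )
        means = [interindividual_distance(g).mean() for g in simulate_site(cfg, "site1")]
        expected = expected_uniform_rectangle_distance(308.0, 340.0)
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - expected) < 3 * se

    def test_realized_speed_matches_mean_speed(self):
        cfg = small_cfg(8)
        per_tank = []
        for g in simulate_site(cfg, "site1"):
            mm = g.positions_array() / cfg.calibration.px_per_mm
            steps = np.linalg.norm(np.diff(mm, axis=1), axis=-1)
            per_tank.append(steps.mean() * cfg.frame_rate)
        se = np.std(per_tank, ddof=1) / np.sqrt(len(per_tank))
        assert abs(np.mean(per_tank) - 10.0) < 3 * se + 0.05

    def test_mean_iid_strictly_decreasing_in_cohesion(self):
        """Tank-mean IID falls as centroid attraction rises, with
        non-overlapping 95% CIs across 0 / 0.4 / 0.8."""
        cis = []
        for w in (0.0, 0.4, 0.8):
            cfg = small_cfg(7, cohesion_weight=w, heading_persistence=0.5,
                            cohesion_length_mm=100.0)
            cfg = TrajectorySimConfig(
                sites=cfg.sites, seed=7, n_tanks_per_site=8,
                duration_s=60.0, frame_rate=10.0, calibration=cfg.calibration,
            )
            means = [interindividual_distance(g).mean() for g in simulate_site(cfg, "site1")]
            m, se = np.mean(means), np.std(means, ddof=1) / np.sqrt(len(means))
            cis.append((m - 1.96 * se, m + 1.96 * se))
        assert cis[0][0] > cis[1][1] > cis[1][0] > cis[2][1]

    def test_invalid_site_rejected(self):
        with pytest.raises(ConfigError):
            simulate_group(small_cfg(), "siteX", "t1")


class TestLandmarkSimulation:
    def test_nuisance_only_specimens_align_back_to_template(self):
        cfg = paper_like_landmark_config(3, landmark_noise_sd=0.0)
        lms = simulate_landmarks(cfg, "site1", "male", n=6)  # zero deformation group
        res = gpa_align([lm for lm in lms], project_tangent=False)
        both = gpa_align(
            np.vstack([res.consensus[None], cfg.template_array[None]]), project_tangent=False
        )
        assert procrustes_distance(both.aligned[0], both.aligned[1]) < 1e-8

    def test_single_landmark_deformation_concentrates_at_that_landmark(self):
        """A displacement planted at a near-centroid landmark (ventral
        surface) keeps >= 80% of the squared consensus difference at
        that landmark.  (A far-from-centroid landmark such as the caudal
        fin necessarily leaks displacement into the removed similarity
        modes — the classic Pinocchio effect — so concentration is
        asserted where alignment theory predicts it.)"""
        template = load_template()
        delta = np.zeros((7, 2))
        delta[5] = (0.0, 0.06)
        cfg = paper_like_landmark_config(20210712)
        cfg = LandmarkSimConfig(
            template=cfg.template,
            deformations={("s", "a"): np.zeros((7, 2)), ("s", "b"): delta},
            size_median_mm={("s", "a"): 15.0, ("s", "b"): 15.0},
            size_log_sd={("s", "a"): 0.1, ("s", "b"): 0.1},
            n_per_group={("s", "a"): 100, ("s", "b"): 100},
            landmark_noise_sd=0.007,
            seed=20210712,
        )
        lms = simulate_landmarks(cfg, "s", "a") + simulate_landmarks(cfg, "s", "b")
        res = gpa_align(lms)
        ga = res.aligned[:100].mean(axis=0)
        gb = res.aligned[100:].mean(axis=0)
        sq = ((ga - gb) ** 2).sum(axis=1)
        assert sq[5] / sq.sum() >= 0.80
        assert np.argmax(sq) == 5

    def test_centroid_size_recovered_within_five_percent(self):
        cfg = paper_like_landmark_config(5)
        lms = simulate_landmarks(cfg, "site2", "male", n=100)
        from zfsentinel.morphometrics import centroid_size

        sizes = np.array([centroid_size(lm.landmarks_mm) for lm in lms])
        key = ("site2", "male")
        true_mean = cfg.size_median_mm[key] * np.exp(cfg.size_log_sd[key] ** 2 / 2)
        assert abs(sizes.mean() - true_mean) / true_mean < 0.05

    def test_deformation_for_ratio_hits_target(self):
        t = load_template()
        for target in (1.5, 1.3, 1.0):
            d = deformation_for_ratio(t, target)
            from zfsentinel.synthetic_data import _ratio

            assert _ratio(t + d) == pytest.approx(target, abs=1e-9)

    def test_noise_bound_enforced(self):
        with pytest.raises(ConfigError, match="landmark_noise_sd"):
            paper_like_landmark_config(1, landmark_noise_sd=0.2)


class TestStudy:
    def test_paper_like_speed_contrast_in_most_tank_pairings(self):
        """Site 1 tank-mean swim speed exceeds its paired Site 2 tank in
        at least 11 of 12 pairings at the fixed seed."""
        from zfsentinel.activity_metrics import swim_speed

        cfg = paper_like_trajectory_config(20210712)
        cfg = TrajectorySimConfig(
            sites=cfg.sites, seed=20210712, duration_s=30.0, frame_rate=15.0,
            calibration=cfg.calibration,
        )
        means = {}
        for site in ("site1", "site2"):
            means[site] = [
                np.mean([swim_speed(tr, g.calibration) for tr in g.trajectories])
                for g in simulate_site(cfg, site)
            ]
        wins = sum(a > b for a, b in zip(means["site1"], means["site2"]))
        assert wins >= 11

    def test_study_shape_and_labels(self):
        tcfg = paper_like_trajectory_config(1)
        tcfg = TrajectorySimConfig(
            sites=tcfg.sites, seed=1, duration_s=5.0, frame_rate=10.0,
            n_tanks_per_site=2, calibration=tcfg.calibration,
        )
        lcfg = paper_like_landmark_config(
            1, n_per_group={k: 5 for k in (("site1", "male"), ("site1", "female"),
                                           ("site2", "male"), ("site2", "female"))}
        )
        study = simulate_study(tcfg, lcfg)
        assert len(study.groups) == 4
        assert len(study.landmarks) == 20
        assert {g.site for g in study.groups} == {"site1", "site2"}

    def test_ground_truth_round_trips_through_config_serializer(self):
        tcfg = paper_like_trajectory_config(6)
        lcfg = paper_like_landmark_config(6)
        t2 = trajectory_config_from_dict(config_to_dict(tcfg))
        assert t2 == tcfg
        l2 = landmark_config_from_dict(config_to_dict(lcfg))
        assert l2.seed == lcfg.seed
        np.testing.assert_allclose(l2.template_array, lcfg.template_array)
        for k in lcfg.n_per_group:
            np.testing.assert_allclose(l2.deformations[k], lcfg.deformations[k])
            assert l2.size_median_mm[k] == lcfg.size_median_mm[k]

    def test_null_preset_has_no_group_differences(self):
        cfg = null_landmark_config(1)
        vals = set()
        for k in cfg.n_per_group:
            vals.add(
                (cfg.size_median_mm[k], cfg.size_log_sd[k], float(np.abs(cfg.deformations[k]).sum()))
            )
        assert len(vals) == 1
        eq = null_landmark_config(1, equal_regions=True)
        from zfsentinel.synthetic_data import _ratio

        shaped = eq.template_array + np.asarray(eq.deformations[("site1", "male")])
        assert _ratio(shaped) == pytest.approx(1.0, abs=1e-6)

    def test_synthetic_outputs_read_back_through_the_parsers(self, tmp_path):
        from zfsentinel.core_io import read_tps, read_trajectory_table, write_tps, write_trajectory_table

        cfg = small_cfg(11)
        g = simulate_group(cfg, "site1", "t1")
        p = tmp_path / "t1.csv"
        write_trajectory_table(g, p)
        g2 = read_trajectory_table(p, "generic-csv", cfg.calibration)
        np.testing.assert_allclose(g2.positions_array(), g.positions_array())

        lcfg = paper_like_landmark_config(11)
        lms = simulate_landmarks(lcfg, "site1", "male", n=3)
        tps = tmp_path / "lm.tps"
        write_tps(lms, tps)
        back = read_tps(tps)
        for a, b in zip(lms, back):
            np.testing.assert_allclose(a.landmarks_mm, b.landmarks_mm)
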