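"""The paired-modality knee generator: template, cohorts, renders, retest."""

import numpy as np
import pytest

from kneeshape.agreement import sdd
from kneeshape.measures import AREA_REGIONS, jsw_3d, tab_area
from kneeshape.mesh import LandmarkSurface, surface_area, vertex_normals
from kneeshape.oa_score import build_oa_vector, score_shape
from kneeshape.shape_model import (ShapePopulation, build_shape_model,
                                   procrustes_align, project)
from kneeshape.synthetic import (SyntheticConfig, make_template_knee,
                                 make_test_retest, parallel_patch_fixture,
                                 render_modality, sample_population)


def quiet_config(**kw):
    base = dict(n_subjects=6, seed=7, shape_noise_mm=0.0, size_sd=0.0,
                surface_noise_mm=0.0, distortion_amplitude_mm=0.0,
                mr_flexion_deg=0.0, mr_tibial_rotation_deg=0.0,
                reposition_deg=0.0, reposition_mm=0.0,
                modality_offset_mm=0.0)
    base.update(kw)
    return SyntheticConfig(**base)


class TestTemplate:
    def test_central_regions_balanced(self, template):
        n_med = template.regions["cMT"].size
        n_lat = template.regions["cLT"].size
        assert abs(n_med - n_lat) / max(n_med, n_lat) < 0.10

    def test_central_regions_minimum_size(self, template):
        assert template.regions["cMT"].size >= 200
        assert template.regions["cLT"].size >= 200

    def test_resolution_too_low_rejected(self):
        with pytest.raises(ValueError, match="resolution"):
            make_template_knee(1)

    def test_parallel_fixture_matches_closed_form(self):
        tibia, femur, region = parallel_patch_fixture(separation=3.7)
        res = jsw_3d(tibia, femur, region)
        assert res.mean_mm == pytest.approx(3.7, rel=0.01)

    def test_all_region_areas_positive_and_rigid_invariant(self, template):
        from kneeshape.mesh import RigidTransform
        T = RigidTransform.from_axis_angle((1, 0, 2), 21.0, (4, 4, -9))
        for name in AREA_REGIONS:
            surf = (template.femur if name.startswith(("MF", "LF", "Tr"))
                    else template.tibia)
            a = tab_area(surf, template.regions[name])
            assert a > 0
            assert tab_area(surf.transformed(T),
                            template.regions[name]) == pytest.approx(a,
                                                                     rel=1e-9)


class TestSamplePopulation:
    def test_zero_severity_zero_noise_equals_template(self, template):
        cfg = quiet_config(t_min=0.0, t_max=0.0)
        _, knees = sample_population(cfg, template)
        for k in knees:
            assert np.allclose(k.truth_femur.points, template.femur.points,
                               atol=1e-12)
            assert np.allclose(k.truth_tibia.points, template.tibia.points,
                               atol=1e-12)

    def test_same_seed_bit_identical(self, template):
        cfg = SyntheticConfig(n_subjects=5, seed=13)
        _, a = sample_population(cfg, template)
        _, b = sample_population(SyntheticConfig(n_subjects=5, seed=13),
                                 template)
        for ka, kb in zip(a, b):
            assert ka.t == kb.t
            assert np.array_equal(ka.truth_femur.points, kb.truth_femur.points)
            assert np.array_equal(ka.truth_tibia.points, kb.truth_tibia.points)

    def test_area_increases_with_severity(self, template):
        """Marginal (osteophyte-like) growth adds bone area monotonically
        in the latent severity, on noise-free draws."""
        cfg = quiet_config(n_subjects=10, seed=5)
        _, knees = sample_population(cfg, template)
        order = np.argsort([k.t for k in knees])
        areas = [tab_area(knees[i].truth_femur, template.regions["MF.tAB"])
                 + tab_area(knees[i].truth_tibia, template.regions["MT.tAB"])
                 for i in order]
        assert np.all(np.diff(areas) > 0)

    def test_group_labels_follow_thresholds(self, template):
        cfg = SyntheticConfig(n_subjects=30, seed=3)
        _, knees = sample_population(cfg, template)
        for k in knees:
            if k.t <= cfg.non_oa_max_t:
                assert k.group == "nonOA"
            elif k.t >= cfg.oa_min_t:
                assert k.group == "OA"
            else:
                assert k.group == "intermediate"

    def test_outputs_are_valid_surfaces_on_template_topology(self, template):
        cfg = SyntheticConfig(n_subjects=4, seed=9)
        _, knees = sample_population(cfg, template)
        for k in knees:
            for m in ("CT", "MR"):
                femur, tibia = render_modality(k, m, cfg)
                assert femur.same_topology(template.femur)
                assert tibia.same_topology(template.tibia)
                assert np.isfinite(femur.points).all()


class TestRenderModality:
    def test_null_modality_effect_mr_equals_ct(self, template):
        cfg = quiet_config()
        _, knees = sample_population(cfg, template)
        ct = render_modality(knees[0], "CT", cfg)
        mr = render_modality(knees[0], "MR", cfg)
        assert np.allclose(ct[0].points, mr[0].points, atol=1e-12)
        assert np.allclose(ct[1].points, mr[1].points, atol=1e-12)

    def test_inward_offset_shrinks_convex_areas(self, template):
        cfg = quiet_config(modality_offset_mm=0.2)
        _, knees = sample_population(cfg, template)
        ct_f, ct_t = render_modality(knees[0], "CT", cfg)
        mr_f, mr_t = render_modality(knees[0], "MR", cfg)
        for name in AREA_REGIONS:
            fem = name.startswith(("MF", "LF", "Tr"))
            a_ct = tab_area(ct_f if fem else ct_t, template.regions[name])
            a_mr = tab_area(mr_f if fem else mr_t, template.regions[name])
            assert a_mr < a_ct

    def test_offset_widens_joint_space_by_two_delta(self, template):
        delta = 0.2
        cfg = quiet_config(modality_offset_mm=delta)
        _, knees = sample_population(cfg, template)
        ct_f, ct_t = render_modality(knees[0], "CT", cfg)
        mr_f, mr_t = render_modality(knees[0], "MR", cfg)
        for reg in ("cMT", "cLT"):
            widen = (jsw_3d(mr_t, mr_f, template.regions[reg]).mean_mm
                     - jsw_3d(ct_t, ct_f, template.regions[reg]).mean_mm)
            assert widen == pytest.approx(2 * delta, rel=0.10)

    def test_excessive_offset_raises(self, template):
        cfg = quiet_config(modality_offset_mm=30.0)
        _, knees = sample_population(cfg, template)
        with pytest.raises(ValueError, match="self-intersect"):
            render_modality(knees[0], "MR", cfg)

    def test_pose_change_only_leaves_shape_scores_unchanged(self, template):
        """Flexion + external rotation move the bones but Procrustes
        alignment removes pose: shape parameters agree to high precision
        while raw coordinates differ."""
        cfg_posed = quiet_config(n_subjects=8, seed=17, shape_noise_mm=0.4,
                                 mr_flexion_deg=5.0,
                                 mr_tibial_rotation_deg=15.0,
                                 reposition_deg=2.0, reposition_mm=2.0)
        _, knees = sample_population(cfg_posed, template)
        mr = [render_modality(k, "MR", cfg_posed)[0] for k in knees]
        ct = [render_modality(k, "CT", cfg_posed)[0] for k in knees]
        model = build_shape_model(procrustes_align(ShapePopulation(mr)), 0.98)
        for i in (0, 3):
            assert not np.allclose(mr[i].points, ct[i].points, atol=1e-3)
            b_mr = project(model, mr[i])
            b_ct = project(model, ct[i])
            assert np.allclose(b_mr, b_ct, atol=1e-6)

    def test_screw_home_rotation_biases_medial_more_than_lateral(self,
                                                                 template):
        """With the ~15 degree external tibial rotation in the MR pose, the
        medial joint-space bias exceeds the lateral one (direction, not
        magnitude) in >= 90% of seeded subjects."""
        cfg = SyntheticConfig(n_subjects=12, seed=31)
        _, knees = sample_population(cfg, template)
        wins = 0
        for k in knees:
            ct_f, ct_t = render_modality(k, "CT", cfg)
            mr_f, mr_t = render_modality(k, "MR", cfg)
            bm = (jsw_3d(mr_t, mr_f, template.regions["cMT"]).mean_mm
                  - jsw_3d(ct_t, ct_f, template.regions["cMT"]).mean_mm)
            bl = (jsw_3d(mr_t, mr_f, template.regions["cLT"]).mean_mm
                  - jsw_3d(ct_t, ct_f, template.regions["cLT"]).mean_mm)
            wins += (bm > bl)
        assert wins >= 0.9 * len(knees)


class TestTestRetest:
    def test_noise_free_replicates_give_zero_sdd(self, template):
        cfg = quiet_config(n_subjects=4)
        _, knees = sample_population(cfg, template)
        reps = make_test_retest(knees[0], cfg)
        # identical up to the (disabled) repositioning
        assert np.allclose(reps[0][0].points, reps[1][0].points, atol=1e-12)

    def test_replicates_differ_between_subjects(self, template):
        cfg = SyntheticConfig(n_subjects=4, seed=23)
        _, knees = sample_population(cfg, template)
        r0 = make_test_retest(knees[0], cfg)
        r1 = make_test_retest(knees[1], cfg)
        assert not np.allclose(r0[0][0].points, r1[0][0].points, atol=1e-3)

    def test_sdd_matches_single_scan_noise_oracle(self, template):
        """Monte-Carlo consistency: the SDD estimated from replicate pairs
        agrees within 15% with 1.96*sqrt(2)*sigma, where sigma is the
        score SD over independent single re-renders of one knee."""
        cfg = SyntheticConfig(n_subjects=16, seed=41)
        _, knees = sample_population(cfg, template)
        mr = [render_modality(k, "MR", cfg)[0] for k in knees]
        model = build_shape_model(procrustes_align(ShapePopulation(mr)), 0.98)
        non = ShapePopulation([mr[i] for i, k in enumerate(knees)
                               if k.group == "nonOA"])
        oa = ShapePopulation([mr[i] for i, k in enumerate(knees)
                              if k.group == "OA"])
        oav = build_oa_vector(model, non, oa)

        knee = knees[0]
        # pathway A: 100 replicate pairs of one knee through the sdd()
        # estimator (fresh retest stream per pair)
        rng = np.random.default_rng(100)
        t0, t1 = [], []
        for _ in range(100):
            reps = make_test_retest(knee, cfg, n_replicates=2)
            knee.render_seeds["retest"] = int(rng.integers(2 ** 31))
            t0.append(score_shape(oav, project(model, reps[0][0])))
            t1.append(score_shape(oav, project(model, reps[1][0])))
        est = sdd(t0, t1).sdd
        # pathway B: closed form 1.96*sqrt(2)*sigma from the single-scan
        # score SD (all draws re-render the same knee, so the pooled SD is
        # pure measurement noise)
        sigma = np.std(np.concatenate([t0, t1]), ddof=1)
        assert est == pytest.approx(1.96 * np.sqrt(2) * sigma, rel=0.15)
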