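"""Synthetic frame and ROI generation: planted truth must be recoverable."""

import numpy as np
import pytest

from nemadetect.detect import extract_roi, find_low_order_regions
from nemadetect.fields import build_director_grid, order_parameter_field
from nemadetect.records import CLASSES
from nemadetect.synthetic import (
    ConfigError,
    Defect,
    SingularPointError,
    SynthConfig,
    defect_velocity_template,
    generate_frame,
    generate_labeled_rois,
    ideal_defect_angle,
    true_polarity,
)
from nemadetect.winding import classify_roi_winding, winding_number


class TestIdealField:
    def test_single_plus_half_at_phi_pi(self):
        # theta = k*phi: at phi = pi the director is pi/2
        theta = ideal_defect_angle(-1.0, 0.0, [Defect(0, 0, 0.5)])
        assert theta == pytest.approx(np.pi / 2, abs=1e-12)

    @pytest.mark.parametrize("charge", [0.5, -0.5])
    def test_loop_winding_recovers_planted_charge(self, charge):
        phi = np.linspace(0, 2 * np.pi, 101)[:-1]
        loop = ideal_defect_angle(
            2 * np.cos(phi), 2 * np.sin(phi), [Defect(0, 0, charge, 0.8)]
        )
        assert winding_number(loop) == pytest.approx(charge, abs=1e-9)

    def test_pair_encloses_zero_charge(self):
        defs = [Defect(-3.0, 0.0, 0.5), Defect(3.0, 0.0, -0.5)]
        phi = np.linspace(0, 2 * np.pi, 201)[:-1]
        loop = ideal_defect_angle(9 * np.cos(phi), 9 * np.sin(phi), defs)
        assert winding_number(loop) == pytest.approx(0.0, abs=1e-9)

    def test_core_evaluation_is_singular(self):
        with pytest.raises(SingularPointError):
            ideal_defect_angle(0.0, 0.0, [Defect(0, 0, 0.5)])

    def test_torus_field_is_periodic_and_winds_correctly(self):
        box = (30.0, 30.0)
        defs = [Defect(9.0, 15.0, 0.5, 0.2), Defect(21.0, 15.0, -0.5)]
        xs = np.linspace(0, 29.3, 31)
        t0 = ideal_defect_angle(xs, xs, defs, box=box, periodic=True)
        tx = ideal_defect_angle(xs + 30.0, xs, defs, box=box, periodic=True)
        ty = ideal_defect_angle(xs, xs + 30.0, defs, box=box, periodic=True)
        assert np.abs(np.exp(2j * t0) - np.exp(2j * tx)).max() < 1e-9
        assert np.abs(np.exp(2j * t0) - np.exp(2j * ty)).max() < 1e-9
        phi = np.linspace(0, 2 * np.pi, 201)[:-1]
        for d in defs:
            loop = ideal_defect_angle(
                d.x + np.cos(phi), d.y + np.sin(phi), defs, box=box, periodic=True
            )
            assert winding_number(loop) == pytest.approx(d.charge, abs=1e-9)


class TestConfigValidation:
    def test_periodic_frames_must_be_charge_neutral(self):
        with pytest.raises(ConfigError):
            SynthConfig(defects=[Defect(10, 10, 0.5)], periodic=True)

    def test_cores_must_be_resolvable(self):
        with pytest.raises(ConfigError):
            SynthConfig(defects=[Defect(10, 10, 0.5), Defect(11, 10, -0.5)])

    def test_negative_kappa_rejected(self):
        with pytest.raises(ConfigError):
            SynthConfig(kappa=-1.0)


class TestGenerateFrame:
    def test_reproducible_from_seed(self):
        cfg = SynthConfig(defects=[Defect(9, 15, 0.5), Defect(21, 15, -0.5)],
                          kappa=5.0, seed=17)
        f1, t1 = generate_frame(cfg)
        f2, t2 = generate_frame(cfg)
        assert np.array_equal(f1.x, f2.x)
        assert np.array_equal(f1.theta, f2.theta)
        assert np.array_equal(f1.vx, f2.vx)
        assert [(r.x, r.y, r.charge, r.psi) for r in t1] == [
            (r.x, r.y, r.charge, r.psi) for r in t2
        ]

    def test_noise_free_defect_free_frame_is_fully_ordered(self):
        frame, truth = generate_frame(SynthConfig(defects=[], kappa=None, seed=2))
        assert truth == []
        grid = build_director_grid(frame)
        S = order_parameter_field(grid, 1.5 * frame.cell_diameter)
        assert S.S.min() > 0.999

    def test_isotropic_noise_gives_low_order(self):
        # kappa = 0: orientations uniform; mean S well below the aligned value
        frame, _ = generate_frame(SynthConfig(defects=[], kappa=0.0, seed=2))
        grid = build_director_grid(frame)
        S = order_parameter_field(grid, 1.5 * frame.cell_diameter)
        assert S.S.mean() < 0.5

    def test_pipeline_recovers_planted_pair(self):
        defs = [Defect(9.0, 15.0, 0.5, 0.2), Defect(21.0, 15.0, -0.5)]
        cfg = SynthConfig(defects=defs, kappa=8.0, seed=4, v0=0.0)
        frame, truth = generate_frame(cfg)
        d = frame.cell_diameter
        grid = build_director_grid(frame)
        order = order_parameter_field(grid, 1.5 * d)
        regions = find_low_order_regions(order)
        assert len(regions) == 2
        got = {}
        for r in regions:
            roi = extract_roi(grid, r.centroid, 9, roi_span=6 * d)
            got[classify_roi_winding(roi)] = r.centroid
        for rec in truth:
            assert rec.charge in got
            cx, cy = got[rec.charge]
            assert np.hypot(cx - rec.x, cy - rec.y) < 1.5 * d

    def test_velocities_present_only_with_positive_defects(self):
        frame, _ = generate_frame(SynthConfig(defects=[], seed=1))
        assert frame.vx is None
        cfg = SynthConfig(defects=[Defect(9, 15, 0.5, 0.3), Defect(21, 15, -0.5)],
                          seed=1, v0=1.0)
        frame2, truth = generate_frame(cfg)
        assert frame2.vx is not None
        # flow at cells near the +1/2 core points along its true polarity
        psi = truth[0].psi
        near = np.hypot(frame2.x - 9, frame2.y - 15) < 1.0
        v = np.array([frame2.vx[near].mean(), frame2.vy[near].mean()])
        ang = np.arctan2(v[1], v[0])
        assert np.abs(np.angle(np.exp(1j * (ang - psi)))) < 0.4


class TestTruePolarity:
    def test_plane_single_defect_polarity_is_twice_the_phase(self):
        for phase in (0.0, 0.4, 1.3):
            psi = true_polarity(Defect(0, 0, 0.5, phase), [Defect(0, 0, 0.5, phase)])
            expect = (2 * phase) % (2 * np.pi)
            assert np.abs(np.angle(np.exp(1j * (psi - expect)))) < 1e-3

    def test_negative_core_rejected(self):
        with pytest.raises(ConfigError):
            true_polarity(Defect(0, 0, -0.5), [Defect(0, 0, -0.5)])


class TestVelocityTemplate:
    def test_core_speed_and_direction(self):
        for psi in (0.0, 1.1, 4.0):
            vx, vy = defect_velocity_template(0.0, 0.0, (0.0, 0.0), psi, v0=2.0)
            assert np.hypot(vx, vy) == pytest.approx(2.0, abs=1e-12)
            assert np.arctan2(vy, vx) % (2 * np.pi) == pytest.approx(
                psi % (2 * np.pi), abs=1e-9
            )

    def test_mirror_symmetry_about_polarity_axis(self):
        x = np.linspace(-3, 3, 13)
        X, Y = np.meshgrid(x, x)
        vx, vy = defect_velocity_template(X, Y, (0.0, 0.0), 0.0)
        assert np.allclose(vx, vx[::-1, :], atol=1e-12)   # vx even in y
        assert np.allclose(vy, -vy[::-1, :], atol=1e-12)  # vy odd in y

    def test_rotation_equivariance(self):
        alpha = 0.8
        pt = np.array([1.3, -0.4])
        vx0, vy0 = defect_velocity_template(pt[0], pt[1], (0.0, 0.0), 0.0)
        c, s = np.cos(alpha), np.sin(alpha)
        rx, ry = c * pt[0] - s * pt[1], s * pt[0] + c * pt[1]
        vx1, vy1 = defect_velocity_template(rx, ry, (0.0, 0.0), alpha)
        assert vx1 == pytest.approx(c * vx0 - s * vy0, abs=1e-12)
        assert vy1 == pytest.approx(s * vx0 + c * vy0, abs=1e-12)


class TestLabeledRois:
    def test_balanced_counts(self):
        ds = generate_labeled_rois(10, (None,), seed=1)
        assert len(ds) == 30
        assert np.array_equal(np.bincount(ds.labels, minlength=3), [10, 10, 10])

    def test_zero_noise_rois_match_winding_oracle_exactly(self):
        ds = generate_labeled_rois(40, (None,), seed=3)
        for patch, label in zip(ds.patches, ds.labels):
            assert classify_roi_winding(patch) == CLASSES[label]

    def test_same_seed_is_byte_identical(self):
        a = generate_labeled_rois(15, (None, 3.0), seed=21)
        b = generate_labeled_rois(15, (None, 3.0), seed=21)
        assert np.array_equal(a.patches, b.patches)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.kappas, b.kappas)

    def test_winding_accuracy_monotone_in_noise_concentration(self):
        accs = []
        for kappa in (1.0, 3.0, 8.0):
            ds = generate_labeled_rois(100, (kappa,), seed=42)
            preds = [classify_roi_winding(p) for p in ds.patches]
            accs.append(np.mean([p == CLASSES[l]
                                 for p, l in zip(preds, ds.labels)]))
        assert accs[0] <= accs[1] <= accs[2]

    def test_invalid_count_rejected(self):
        with pytest.raises(ConfigError):
            generate_labeled_rois(0, (None,))
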